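"""Helix-axis fitting and proline-kink distortion parameters.

The bend angle of a proline-containing TM helix is the angle between the axes of
the helical segments preceding and following the proline; the face-shift is the
rotation of the post-segment helical face about the pre-segment axis relative to
an ideal unkinked continuation.  Axes are fitted to the track of local helical
origins (sliding 4-Cα centroids), which cancels the ~2.3 Å radial excursion of
individual Cα atoms and is the standard approach for kink analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bwmap import BWMap, parse_bw
from .exceptions import GeometryError
from .model import Frame, Selection, TimeSeries, Trajectory

__all__ = ["HelixAxis", "KinkResult", "fit_axis", "proline_kink", "helix_tilt", "kink_series"]


@dataclass(frozen=True)
class HelixAxis:
    """A fitted helix axis: centroid ``point`` and unit ``direction`` (Å)."""

    point: np.ndarray
    direction: np.ndarray
    residues: tuple

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-9:
            raise GeometryError("axis direction must be a unit vector")


@dataclass(frozen=True)
class KinkResult:
    """Bend and face-shift angles (degrees) around a proline."""

    bend_deg: float
    face_shift_deg: float
    pre_axis: HelixAxis
    post_axis: HelixAxis
    proline: str
    degenerate: bool = False


#: weight of the two middle Cα in a 4-residue local-origin window, solving
#: 1 + a*e^(i*100°) + a*e^(i*200°) + e^(i*300°) = 0 (exact wobble cancellation)
_WOBBLE_WEIGHT = 1.3472963553338606


def _axis_from_points(points: np.ndarray, residues: tuple) -> HelixAxis:
    """Total-least-squares line through the local-origin track; sign along the track."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    direction = vt[0]
    track = points[-1] - points[0]
    if np.dot(direction, track) < 0:
        direction = -direction
    return HelixAxis(point=centroid, direction=direction / np.linalg.norm(direction), residues=residues)


def fit_axis(frame: Frame, ca_selection: Selection) -> HelixAxis:
    """Fit a helix axis to Cα atoms, oriented from the first to the last residue.

    With ≥5 Cα atoms the line is fitted to sliding 4-Cα centroids ("local helical
    origins"); with exactly 4, to the raw Cα positions.  Fewer than 4 is an error.
    """
    coords = frame.coords[ca_selection.indices]
    return fit_axis_points(coords, tuple(int(i) for i in ca_selection.indices))


def helix_tilt(axis: HelixAxis, normal: np.ndarray) -> float:
    """Angle (degrees, [0, 90]) between a helix axis and the membrane normal.

    Sign-invariant: reversing either vector leaves the tilt unchanged.
    """
    normal = np.asarray(normal, float)
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise GeometryError("membrane normal must be a non-zero vector")
    cosang = abs(float(np.dot(axis.direction, normal) / nn))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _ca_coords(frame: Frame, bw_map: BWMap, codes: list[str]) -> np.ndarray:
    idx = []
    for code in codes:
        chain, res_seq = bw_map.resolve(code)
        idx.append(frame.table.index_of(chain, res_seq, "CA"))
    return frame.coords[np.asarray(idx)]


def _radial_phase(coords: np.ndarray, axis: HelixAxis, e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    rel = coords - axis.point
    r = rel - np.outer(rel @ axis.direction, axis.direction)
    return np.arctan2(r @ e2, r @ e1)


def proline_kink(
    frame: Frame,
    bw_map: BWMap,
    proline: str,
    flank: int = 6,
) -> KinkResult:
    """Prokink-style bend and face-shift angles around a proline.

    Pre-segment: residues ``P-1-flank .. P-2``; post-segment: ``P+2 .. P+1+flank``
    (the distorted turn P±1 and the proline itself are excluded).  The bend is the
    angle between the two fitted axes.  The face-shift compares the observed radial
    direction of Cα(P+4) about the pre-axis with the direction predicted by
    extrapolating the pre-segment's fitted helical phase — i.e. the rotation of the
    post-helical face relative to an ideal unkinked continuation, signed by the
    right-hand rule about the pre-axis.
    """
    if flank < 4:
        raise GeometryError("flank must be >=4 residues to fit a segment axis")
    helix, pos = parse_bw(proline)
    pre_codes = [f"{helix}.{nn:02d}" for nn in range(pos - 1 - flank, pos - 1)]
    post_codes = [f"{helix}.{nn:02d}" for nn in range(pos + 2, pos + 2 + flank)]
    try:
        pre_ca = _ca_coords(frame, bw_map, pre_codes)
        post_ca = _ca_coords(frame, bw_map, post_codes)
    except Exception as exc:
        raise GeometryError(f"insufficient flanking residues around {proline}: {exc}") from exc

    pre_axis = fit_axis_points(pre_ca, tuple(pre_codes))
    post_axis = fit_axis_points(post_ca, tuple(post_codes))
    cosb = np.clip(np.dot(pre_axis.direction, post_axis.direction), -1.0, 1.0)
    bend = float(np.degrees(np.arccos(cosb)))

    # Helical-phase extrapolation: fit phase-vs-position on the pre-segment,
    # predict the phase of residue P+4, compare with its observed phase.
    u = pre_axis.direction
    ref = pre_ca[0] - pre_axis.point
    ref = ref - np.dot(ref, u) * u
    nref = np.linalg.norm(ref)
    if nref < 1e-9:
        raise GeometryError("pre-segment Calpha lies on the axis; cannot define a helical face")
    e1 = ref / nref
    e2 = np.cross(u, e1)

    ks = np.arange(pos - 1 - flank, pos - 1, dtype=float)
    phases = np.unwrap(_radial_phase(pre_ca, pre_axis, e1, e2))
    slope, intercept = np.polyfit(ks, phases, 1)
    k_probe = float(pos + 4)
    phi_ideal = intercept + slope * k_probe

    probe_ca = _ca_coords(frame, bw_map, [f"{helix}.{pos + 4:02d}"])[0]
    phi_obs = float(_radial_phase(probe_ca[None, :], pre_axis, e1, e2)[0])

    face_shift = float(np.degrees(np.angle(np.exp(1j * (phi_obs - phi_ideal)))))
    degenerate = bend < 0.1
    return KinkResult(
        bend_deg=bend,
        face_shift_deg=face_shift,
        pre_axis=pre_axis,
        post_axis=post_axis,
        proline=proline,
        degenerate=degenerate,
    )


def fit_axis_points(ca_coords: np.ndarray, residues: tuple) -> HelixAxis:
    """Axis fit on raw Cα coordinates (see :func:`fit_axis`).

    Direction: total-least-squares line through the track of local helical
    origins — weighted centroids of 4 consecutive Cα with weights that cancel
    the 100°/residue radial wobble exactly, so the fit is exact on ideal
    α-helical geometry and robust to coordinate noise.  Point: the centre of the
    circle fitted to the Cα cloud in the plane normal to the axis.  With exactly
    4 Cα (one origin only) a plain TLS line through the raw Cα is used.
    """
    ca_coords = np.asarray(ca_coords, float)
    n = ca_coords.shape[0]
    if n < 4:
        raise GeometryError(f"helix-axis fit needs >=4 Calpha atoms, got {n}")
    if n == 4:
        return _axis_from_points(ca_coords, residues)
    # local helical origins: weighted 4-Calpha windows with weights chosen so the
    # 100 deg/residue radial wobble cancels exactly (sum of w_k * exp(i*100k) = 0)
    w = np.array([1.0, _WOBBLE_WEIGHT, _WOBBLE_WEIGHT, 1.0])
    w = w / w.sum()
    origins = np.stack([(ca_coords[i : i + 4] * w[:, None]).sum(axis=0) for i in range(n - 3)])
    centroid_o = origins.mean(axis=0)
    _, s, vt = np.linalg.svd(origins - centroid_o)
    if s[0] < 1e-9:
        return _axis_from_points(ca_coords, residues)
    direction = vt[0]
    track = ca_coords[-1] - ca_coords[0]
    if np.dot(direction, track) < 0:
        direction = -direction
    # circle (Kasa) fit in the plane normal to the direction
    e1 = np.cross(direction, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(direction, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    centroid = ca_coords.mean(axis=0)
    rel = ca_coords - centroid
    p2 = np.column_stack([rel @ e1, rel @ e2])
    a = np.column_stack([2.0 * p2, np.ones(n)])
    b = (p2**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    point = centroid + sol[0] * e1 + sol[1] * e2
    return HelixAxis(point=point, direction=direction, residues=residues)


def kink_series(
    traj: Trajectory,
    bw_map: BWMap,
    proline: str,
    flank: int = 6,
) -> tuple[TimeSeries, TimeSeries]:
    """Per-frame bend and face-shift traces around one proline."""
    bends = np.empty(traj.n_frames)
    shifts = np.empty(traj.n_frames)
    for i, frame in enumerate(traj):
        res = proline_kink(frame, bw_map, proline, flank=flank)
        bends[i] = res.bend_deg
        shifts[i] = res.face_shift_deg
    return (
        TimeSeries(label=f"bend_{proline}", times=traj.times, values=bends, units="deg"),
        TimeSeries(label=f"face_shift_{proline}", times=traj.times, values=shifts, units="deg"),
    )
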