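"""Synthetic ground-truth structures and trajectories.

A kinematic (not dynamical) generator for a 7-TM helix bundle in a two-leaflet
slab of pseudo-lipids with C2 marker atoms and cholesterol-like particles.
Conformational events — proline-kink changes, side-chain rotamer flips, rigid
segment shifts (ionic-lock opening/closing), cholesterol approach/departure,
membrane thickness profiles — are scripted frame ranges with exact ground truth,
so every analysis stage of the package can be validated against known answers.

Pseudo-lipids carry only the atoms the analyses read (one C2 marker plus two
tail beads); cholesterol-like particles are rigid 3-bead "CHL" residues.
Gaussian positional noise (default sigma 0.2 Å) is applied after all event
geometry, so the scripted ground truth remains exact underneath the noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .bwmap import BWMap
from .exceptions import ParameterError, ScriptError
from .model import AtomTable, Frame, Trajectory

__all__ = [
    "AA_THREE",
    "make_ideal_helix",
    "make_bundle",
    "make_membrane",
    "ScriptedEvent",
    "ScenarioScript",
    "run_scenario",
    "agonist_script",
    "inverse_script",
    "static_script",
    "HELIX_RISE",
    "HELIX_TWIST",
    "HELIX_RADIUS",
]

HELIX_RISE = 1.5     # Å per residue along the axis
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3   # Å, Calpha helix radius

AA_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# gamma heavy atom name per residue type (None: no chi1)
_GAMMA_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "SER": "OG", "THR": "OG1", "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}

_TRP_RING = ("CD2", "CE3", "CZ3", "CH2", "CZ2", "CE2")  # hexagon order


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d bonded to c with angle(b,c,d) and dihedral(a,b,c,d)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    d2 = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(dih),
        bond * math.sin(ang) * math.sin(dih),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _element_of(atom_name: str) -> str:
    for prefix, el in (("O", "O"), ("N", "N"), ("S", "S"), ("C", "C"), ("H", "H")):
        if atom_name.startswith(prefix):
            return el
    return atom_name[0]


def _build_residue_atoms(
    res_name: str,
    minor_phase_deg: float,
    z: float,
    chi1: float,
    chi2: float,
) -> list[tuple[str, np.ndarray]]:
    """Atoms of one residue of an ideal helix along +z (helix axis = z axis)."""

    def cyl(radius: float, phase_deg: float, zz: float) -> np.ndarray:
        p = math.radians(phase_deg)
        return np.array([radius * math.cos(p), radius * math.sin(p), zz])

    ca = cyl(HELIX_RADIUS, minor_phase_deg, z)
    n = cyl(1.56, minor_phase_deg - 28.0, z - 0.90)
    c = cyl(1.75, minor_phase_deg + 32.0, z + 0.78)
    radial = np.array([math.cos(math.radians(minor_phase_deg)),
                       math.sin(math.radians(minor_phase_deg)), 0.0])
    o = c + 1.23 * radial
    atoms = [("N", n), ("CA", ca), ("C", c), ("O", o)]
    if res_name == "GLY":
        return atoms
    cb_dir = radial - 0.45 * np.array([0.0, 0.0, 1.0])
    cb = ca + 1.53 * cb_dir / np.linalg.norm(cb_dir)
    atoms.append(("CB", cb))
    gamma = _GAMMA_ATOM.get(res_name)
    if gamma is None:  # PRO keeps just CB here
        return atoms
    g = _nerf(n, ca, cb, 1.52, 114.0, chi1)
    atoms.append((gamma, g))
    if res_name == "TRP":
        cd1 = _nerf(ca, cb, g, 1.37, 127.0, chi2)
        cd2 = _nerf(ca, cb, g, 1.43, 127.0, chi2 + 180.0)
        atoms.append(("CD1", cd1))
        # regular hexagon for the six-membered indole ring, first vertex CD2
        normal = np.cross(cd1 - g, cd2 - g)
        normal /= np.linalg.norm(normal)
        u = cd2 - cb
        u = u - np.dot(u, normal) * normal
        u /= np.linalg.norm(u)
        w = np.cross(normal, u)
        center = cd2 + 1.40 * u
        for k, name in enumerate(_TRP_RING):
            ang = math.radians(60.0 * k)
            atoms.append((name, center + 1.40 * (-math.cos(ang) * u + math.sin(ang) * w)))
    return atoms


@dataclass
class _HelixAtoms:
    """Working representation of one helix: per-atom arrays plus residue bookkeeping."""

    helix_id: int
    chain: str
    minors: np.ndarray          # per atom: BW minor number of the owning residue
    res_seqs: np.ndarray        # per atom
    res_names: list[str]        # per atom
    atom_names: list[str]       # per atom
    coords: np.ndarray          # (n_atoms, 3), local helix frame (axis = +z)


def _build_helix_local(
    minors: Sequence[int],
    letters: Sequence[str],
    helix_id: int,
    chain: str,
    anchor_res_seq: int,
    center_minor: float,
    direction: int,
    phase0: float = 0.0,
    chi1: dict | None = None,
    chi2: dict | None = None,
) -> _HelixAtoms:
    chi1 = chi1 or {}
    chi2 = chi2 or {}
    all_minors, all_seqs, all_resnames, all_names, all_coords = [], [], [], [], []
    for nn, letter in zip(minors, letters):
        if letter not in AA_THREE:
            raise ParameterError(f"unknown residue letter {letter!r}")
        res_name = AA_THREE[letter]
        z = direction * (nn - center_minor) * HELIX_RISE
        phase = phase0 + direction * nn * HELIX_TWIST
        atoms = _build_residue_atoms(res_name, phase, z,
                                     chi1.get(nn, -60.0), chi2.get(nn, 90.0))
        for name, xyz in atoms:
            all_minors.append(nn)
            all_seqs.append(anchor_res_seq + (nn - 50))
            all_resnames.append(res_name)
            all_names.append(name)
            all_coords.append(xyz)
    return _HelixAtoms(
        helix_id=helix_id,
        chain=chain,
        minors=np.array(all_minors),
        res_seqs=np.array(all_seqs),
        res_names=all_resnames,
        atom_names=all_names,
        coords=np.asarray(all_coords),
    )


def make_ideal_helix(
    n_res: int,
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST,
    sequence: str | None = None,
    chain: str = "A",
    start_res_seq: int = 1,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Frame:
    """An ideal α-helix along +z with backbone, CB and (for Trp) χ-bearing atoms.

    ``rise``/``twist`` override the canonical 1.5 Å / 100° only for the Cα spiral;
    the default geometry gives Cα(i)-Cα(i+1) ≈ 3.8 Å.
    """
    if n_res < 4:
        raise ParameterError("make_ideal_helix needs n_res >= 4")
    if sequence is None:
        sequence = "L" * n_res
    if len(sequence) != n_res:
        raise ParameterError("sequence length must equal n_res")
    names, resn, seqs, coords = [], [], [], []
    for i, letter in enumerate(sequence):
        if letter not in AA_THREE:
            raise ParameterError(f"unknown residue letter {letter!r}")
        res_name = AA_THREE[letter]
        z = i * rise
        phase = i * twist
        for name, xyz in _build_residue_atoms(res_name, phase, z, -60.0, 90.0):
            names.append(name)
            resn.append(res_name)
            seqs.append(start_res_seq + i)
            coords.append(xyz)
    coords = np.asarray(coords)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
    table = AtomTable(names, resn, seqs, [chain] * len(names),
                      element=[_element_of(n) for n in names])
    return Frame(table, coords)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

#: Residue identities at functionally special BW positions; every other
#: position is leucine.  These place the ionic lock (R3.50/E6.30), the DRY
#: aspartate (D3.49), the anchor D3.32, the toggle switch W6.48, the TM6/TM7
#: prolines, the NPxxY tyrosines (7.53/7.60) and the cholesterol-contact sets.
DEFAULT_BW_RESIDUES: dict[str, str] = {
    "3.32": "D", "3.36": "S", "3.49": "D", "3.50": "R",
    "5.46": "S", "5.59": "F", "5.62": "I",
    "6.30": "E", "6.35": "K", "6.39": "I", "6.40": "V", "6.42": "F", "6.46": "V",
    "6.48": "W", "6.50": "P", "6.52": "F", "6.53": "I", "6.55": "N",
    "6.57": "M", "6.60": "I", "6.61": "C",
    "7.44": "L", "7.48": "V", "7.50": "P", "7.52": "V", "7.53": "Y",
    "7.55": "L", "7.56": "F", "7.60": "Y",
}

# xy of each helix axis at the membrane midplane (z = 0), Å
_BUNDLE_XY: dict[int, tuple[float, float]] = {
    1: (15.5, -2.0), 2: (8.0, -10.0), 3: (0.0, -4.0), 4: (-9.0, -8.0),
    5: (-11.0, 3.0), 6: (2.0, 7.0), 7: (9.0, 3.0),
}

# per-helix lean of the axis: xy displacement of the intracellular (z = -21 Å)
# end relative to the midplane position; TM6 leans its IC end toward TM3 so the
# ionic-lock Calpha distance sits in the closed (<9 Å) range at baseline.
_BUNDLE_IC_LEAN: dict[int, tuple[float, float]] = {6: (-0.58, -3.18)}

# z of the BW minor number mapped to the membrane midplane (span midpoints)
_CENTER_MINOR: dict[int, float] = {1: 44.0, 2: 52.5, 3: 38.5, 4: 51.0, 5: 50.5, 6: 46.0, 7: 43.0}

# helices whose residue numbers increase toward the extracellular side
_DIRECTION: dict[int, int] = {1: -1, 2: 1, 3: -1, 4: 1, 5: -1, 6: 1, 7: -1}

# BW minor-number extent of each modelled helix (covers the TM span plus the
# juxtamembrane residues the observables need, e.g. 6.30 and 7.60)
_MINOR_RANGES: dict[int, tuple[int, int]] = {
    1: (29, 59), 2: (38, 67), 3: (24, 53), 4: (39, 63),
    5: (38, 63), 6: (30, 61), 7: (30, 60),
}

# azimuthal phase of each helix spiral; 3 and 6 are set so that the R3.50 and
# E6.30 Calphas face each other across the TM3-TM6 interface
_PHASE0: dict[int, float] = {1: 37.0, 2: 74.0, 3: 40.0, 4: 148.0, 5: 185.0, 6: 140.0, 7: 259.0}


@dataclass
class BundleSpec:
    """Build parameters of the synthetic 7-TM bundle."""

    chain: str = "A"
    minor_ranges: dict = field(default_factory=lambda: dict(_MINOR_RANGES))
    residues: dict = field(default_factory=lambda: dict(DEFAULT_BW_RESIDUES))
    tilts: dict = field(default_factory=dict)        # helix -> (tilt_deg, azimuth_deg)
    kinks: dict = field(default_factory=dict)        # helix -> (pivot_minor, bend, azimuth, spin)
    chi1: dict = field(default_factory=dict)         # (helix, minor) -> chi1 deg
    seg_shifts: tuple = ()                           # (helix, lo_minor, hi_minor, dx, dy, dz)


def _anchor_seq(helix: int) -> int:
    return 100 * helix + 50


def _helix_minors(spec: BundleSpec, helix: int) -> np.ndarray:
    lo, hi = spec.minor_ranges[helix]
    return np.arange(lo, hi + 1)


def _bundle_helices(spec: BundleSpec) -> list[_HelixAtoms]:
    helices = []
    for h in range(1, 8):
        minors = _helix_minors(spec, h)
        letters = [spec.residues.get(f"{h}.{nn:02d}", "L") for nn in minors]
        chi1 = {nn: spec.chi1[(h, nn)] for (hh, nn) in spec.chi1 if hh == h} if spec.chi1 else {}
        hel = _build_helix_local(
            minors, letters, h, spec.chain, _anchor_seq(h),
            _CENTER_MINOR[h], _DIRECTION[h], phase0=_PHASE0[h], chi1=chi1,
        )
        # scripted kink in the local frame (exact ground truth: the rotation angle)
        if h in spec.kinks:
            pivot_minor, bend, azimuth, spin = spec.kinks[h]
            _apply_kink(hel, pivot_minor, bend, azimuth, spin)
        # per-helix rigid placement: lean + translation to the bundle site
        coords = hel.coords
        lean = np.array(_BUNDLE_IC_LEAN.get(h, (0.0, 0.0)))
        if np.any(lean):
            # shear-free lean: rotate about the horizontal axis that realizes the
            # requested IC-end xy displacement at z = -21
            disp = np.array([lean[0], lean[1], 0.0])
            angle = math.degrees(math.atan2(np.linalg.norm(disp), 21.0))
            axis = np.cross(np.array([0.0, 0.0, -1.0]), disp / np.linalg.norm(disp))
            coords = coords @ _rotation(axis, angle).T
        if h in spec.tilts:
            tilt_deg, az = spec.tilts[h]
            axis = np.array([-math.sin(math.radians(az)), math.cos(math.radians(az)), 0.0])
            coords = coords @ _rotation(axis, tilt_deg).T
        xy = _BUNDLE_XY[h]
        coords = coords + np.array([xy[0], xy[1], 0.0])
        hel.coords = coords
        helices.append(hel)
    for h, lo, hi, dx, dy, dz in spec.seg_shifts:
        hel = helices[h - 1]
        mask = (hel.minors >= lo) & (hel.minors <= hi)
        hel.coords[mask] += np.array([dx, dy, dz])
    return helices


def _apply_kink(hel: _HelixAtoms, pivot_minor: int, bend_deg: float,
                azimuth_deg: float, spin_deg: float) -> None:
    """Rotate the post-pivot segment by ``bend`` about a horizontal axis through
    the pivot Cα, then by ``spin`` about the rotated helix axis (exact ground truth)."""
    ca_mask = (hel.minors == pivot_minor) & (np.array(hel.atom_names) == "CA")
    if not np.any(ca_mask):
        raise ScriptError(f"kink pivot {pivot_minor} missing from helix {hel.helix_id}")
    pivot = hel.coords[ca_mask][0]
    post = hel.minors > pivot_minor
    if spin_deg:
        # pure helical-phase rotation: about the local helix-axis *line* (x = y = 0)
        rot = _rotation(np.array([0.0, 0.0, 1.0]), spin_deg)
        hel.coords[post] = hel.coords[post] @ rot.T
    if bend_deg:
        az = math.radians(azimuth_deg)
        axis = np.array([math.cos(az), math.sin(az), 0.0])
        rot = _rotation(axis, bend_deg)
        hel.coords[post] = (hel.coords[post] - pivot) @ rot.T + pivot


def make_bundle(spec: BundleSpec | None = None) -> tuple[Frame, BWMap]:
    """The synthetic 7-TM bundle and the BW map addressing it."""
    spec = spec or BundleSpec()
    helices = _bundle_helices(spec)
    names, resn, seqs, chains, coords = [], [], [], [], []
    for hel in helices:
        names.extend(hel.atom_names)
        resn.extend(hel.res_names)
        seqs.extend(hel.res_seqs.tolist())
        chains.extend([hel.chain] * len(hel.atom_names))
        coords.append(hel.coords)
    table = AtomTable(names, resn, seqs, chains, element=[_element_of(n) for n in names])
    frame = Frame(table, np.concatenate(coords))
    bw_map = BWMap(anchors={h: (spec.chain, _anchor_seq(h)) for h in range(1, 8)})
    return frame, bw_map


# ---------------------------------------------------------------------------
# Membrane
# ---------------------------------------------------------------------------


def make_membrane(
    thickness: float | Callable[[np.ndarray, np.ndarray], np.ndarray] = 28.0,
    spacing: float = 4.0,
    half_width: float = 36.0,
    exclude_xy: Sequence[tuple[float, float]] = tuple(_BUNDLE_XY.values()),
    exclude_radius: float = 4.5,
    center: tuple[float, float] = (0.0, 0.0),
) -> tuple[list[str], list[str], list[int], list[str], np.ndarray]:
    """Pseudo-lipid slab columns: per-site C2 marker + two tail beads per leaflet.

    ``thickness`` is either a constant or a profile function t(x, y) > 0; the two
    leaflet C2 planes sit at ±t/2.  Returns raw atom columns for table assembly.
    """
    xs = np.arange(center[0] - half_width, center[0] + half_width + 1e-9, spacing)
    ys = np.arange(center[1] - half_width, center[1] + half_width + 1e-9, spacing)
    names, resn, seqs, chains, coords = [], [], [], [], []
    res_seq = 5000
    # one contiguous chain per leaflet (keeps atom order stable through PDB I/O)
    for leaflet, sign in (("U", 1.0), ("D", -1.0)):
        for x in xs:
            for y in ys:
                if any((x - ex) ** 2 + (y - ey) ** 2 < exclude_radius**2 for ex, ey in exclude_xy):
                    continue
                t = thickness(np.asarray(x), np.asarray(y)) if callable(thickness) else thickness
                t = float(t)
                if t <= 0:
                    raise ParameterError("thickness profile must be positive everywhere")
                res_seq += 1
                z2 = sign * t / 2.0
                for name, dz in (("C2", 0.0), ("C3", -sign * 3.0), ("C4", -sign * 6.0)):
                    names.append(name)
                    resn.append("LIP")
                    seqs.append(res_seq)
                    chains.append(leaflet)
                    coords.append([x, y, z2 + dz])
    return names, resn, seqs, chains, np.asarray(coords) if coords else np.empty((0, 3))


# ---------------------------------------------------------------------------
# Scenario scripting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScriptedEvent:
    """One scripted change: starts at ``frame``, ramps linearly over ``ramp`` frames.

    kinds and params:
      kink-change:  helix, to_bend (deg); optional pivot_minor, azimuth, spin
      rotamer-flip: helix, minor, to_chi1 (deg)   (instantaneous at ``frame``)
      helix-shift:  helix, lo_minor, hi_minor, toward (helix id or xy), shift (Å)
      lock-open / lock-close: sugar for a TM6 IC-segment shift away from / toward TM3
      chol-approach / chol-depart: chol_id, to_distance (Å)
    """

    frame: int
    kind: str
    params: dict = field(default_factory=dict)
    event_id: int | None = None
    ramp: int = 4


@dataclass
class CholParticle:
    """A cholesterol-like 3-bead particle tethered at ``distance`` from a BW residue."""

    chol_id: int
    target_bw: str
    distance: float = 4.0
    azimuth: float | None = None  # lab-frame approach azimuth; None = radially outward


@dataclass
class ScenarioScript:
    """Deterministic recipe for a synthetic trajectory with ground truth."""

    seed: int = 0
    n_frames: int = 100
    stride: float = 0.1
    noise_sigma: float = 0.2
    events: list = field(default_factory=list)
    bundle: BundleSpec = field(default_factory=BundleSpec)
    chols: list = field(default_factory=list)
    membrane_thickness: float | Callable | None = None  # None = no lipid slab
    membrane_spacing: float = 4.0
    membrane_half_width: float = 36.0

    def validate(self) -> None:
        for ev in self.events:
            if not (0 <= ev.frame < self.n_frames):
                raise ScriptError(f"event at frame {ev.frame} outside 0..{self.n_frames - 1}")
        seen: dict[tuple, int] = {}
        for ev in self.events:
            key = None
            if ev.kind == "kink-change":
                key = ("kink", ev.params["helix"])
            elif ev.kind in ("lock-open", "lock-close", "helix-shift"):
                key = ("shift", ev.params.get("helix", 6))
            if key is not None:
                prev = seen.get(key)
                if prev is not None and abs(prev - ev.frame) < ev.ramp:
                    raise ScriptError(f"conflicting {key[0]} events on helix {key[1]}")
                seen[key] = ev.frame


def _ramp_value(frame: int, start: int, ramp: int, v0: float, v1: float) -> float:
    if frame < start:
        return v0
    if frame >= start + ramp:
        return v1
    return v0 + (v1 - v0) * (frame - start + 1) / ramp


def run_scenario(script: ScenarioScript) -> tuple[Trajectory, dict]:
    """Realize a scenario script as a trajectory plus machine-readable ground truth.

    The ground-truth dict holds per-frame scripted values ('bend' per kinked
    helix, 'chi1' per flipped residue, 'chol_distance' per particle), the event
    list [(frame, kind, event_id)], per-helix static tilts and the membrane
    profile parameters.
    """
    script.validate()
    rng = np.random.default_rng(script.seed)
    n = script.n_frames
    spec = script.bundle

    # ---- per-frame scripted parameter tracks -------------------------------
    kink_tracks: dict[int, np.ndarray] = {}     # helix -> bend per frame
    kink_meta: dict[int, tuple] = {}            # helix -> (pivot, azimuth, spin)
    chi_tracks: dict[tuple[int, int], np.ndarray] = {}
    shift_tracks: list[tuple[int, int, int, np.ndarray, np.ndarray]] = []
    chol_tracks: dict[int, np.ndarray] = {}

    for h, (pivot, bend, az, spin) in spec.kinks.items():
        kink_tracks[h] = np.full(n, float(bend))
        kink_meta[h] = (pivot, az, spin)
    for ev in script.events:
        if ev.kind == "kink-change":
            h = ev.params["helix"]
            pivot = ev.params.get("pivot_minor", 50)
            az = ev.params.get("azimuth", spec.kinks.get(h, (50, 0.0, 0.0, 0.0))[2])
            spin = ev.params.get("spin", 0.0)
            if h not in kink_tracks:
                kink_tracks[h] = np.zeros(n)
            kink_meta[h] = (pivot, az, spin)
            v0 = kink_tracks[h][ev.frame]
            v1 = float(ev.params["to_bend"])
            for f in range(ev.frame, n):
                kink_tracks[h][f] = _ramp_value(f, ev.frame, ev.ramp, v0, v1)
        elif ev.kind == "rotamer-flip":
            key = (ev.params["helix"], ev.params["minor"])
            if key not in chi_tracks:
                chi_tracks[key] = np.full(n, spec.chi1.get(key, -60.0))
            chi_tracks[key][ev.frame :] = float(ev.params["to_chi1"])

    for chol in script.chols:
        chol_tracks[chol.chol_id] = np.full(n, float(chol.distance))
    for ev in script.events:
        if ev.kind in ("chol-approach", "chol-depart"):
            cid = ev.params["chol_id"]
            if cid not in chol_tracks:
                raise ScriptError(f"no cholesterol particle with id {cid}")
            v0 = chol_tracks[cid][ev.frame]
            v1 = float(ev.params["to_distance"])
            for f in range(ev.frame, n):
                chol_tracks[cid][f] = _ramp_value(f, ev.frame, ev.ramp, v0, v1)

    # segment shifts (lock events are TM6 IC-segment shifts relative to TM3)
    for ev in script.events:
        if ev.kind in ("helix-shift", "lock-open", "lock-close"):
            h = ev.params.get("helix", 6)
            if ev.kind == "lock-open":
                lo = ev.params.get("lo_minor", spec.minor_ranges[6][0])
                hi = ev.params.get("hi_minor", 36)
                toward, sign = 3, -1.0
            elif ev.kind == "lock-close":
                lo = ev.params.get("lo_minor", spec.minor_ranges[6][0])
                hi = ev.params.get("hi_minor", 36)
                toward, sign = 3, 1.0
            else:
                lo, hi = ev.params["lo_minor"], ev.params["hi_minor"]
                toward, sign = ev.params.get("toward", 3), ev.params.get("sign", 1.0)
            target_xy = np.array(_BUNDLE_XY[toward]) if isinstance(toward, int) else np.asarray(toward)
            self_xy = np.array(_BUNDLE_XY[h])
            u = target_xy - self_xy
            u = sign * u / np.linalg.norm(u)
            magnitude = float(ev.params.get("shift", 3.0))
            track = np.array([_ramp_value(f, ev.frame, ev.ramp, 0.0, magnitude) for f in range(n)])
            shift_tracks.append((h, lo, hi, np.array([u[0], u[1], 0.0]), track))

    # ---- static membrane ---------------------------------------------------
    mem_cols = None
    if script.membrane_thickness is not None:
        mem_cols = make_membrane(
            script.membrane_thickness,
            spacing=script.membrane_spacing,
            half_width=script.membrane_half_width,
        )

    # ---- assemble the atom table from frame 0 ------------------------------
    def build_protein(frame_idx: int) -> list[_HelixAtoms]:
        s = spec
        kinks = dict(s.kinks)
        for h, track in kink_tracks.items():
            pivot, az, spin = kink_meta[h]
            kinks[h] = (pivot, float(track[frame_idx]), az, spin)
        chi1 = dict(s.chi1)
        for (h, minor), track in chi_tracks.items():
            chi1[(h, minor)] = float(track[frame_idx])
        frame_spec = replace(s, kinks=kinks, chi1=chi1)
        helices = _bundle_helices(frame_spec)
        for h, lo, hi, u, track in shift_tracks:
            hel = helices[h - 1]
            mask = (hel.minors >= lo) & (hel.minors <= hi)
            hel.coords[mask] += track[frame_idx] * u
        return helices

    helices0 = build_protein(0)
    names, resn, seqs, chains = [], [], [], []
    for hel in helices0:
        names.extend(hel.atom_names)
        resn.extend(hel.res_names)
        seqs.extend(hel.res_seqs.tolist())
        chains.extend([hel.chain] * len(hel.atom_names))
    n_protein = len(names)
    if mem_cols is not None:
        mn, mr, ms, mc, mxyz = mem_cols
        names.extend(mn)
        resn.extend(mr)
        seqs.extend(ms)
        chains.extend(mc)
    chol_targets: dict[int, tuple[str, int]] = {}
    bw_map = BWMap(anchors={h: (spec.chain, _anchor_seq(h)) for h in range(1, 8)})
    for chol in script.chols:
        chol_targets[chol.chol_id] = bw_map.resolve(chol.target_bw)
        for bead in ("C1", "C2", "C3"):
            names.append(bead)
            resn.append("CHL")
            seqs.append(9000 + chol.chol_id)
            chains.append("X")
    table = AtomTable(names, resn, seqs, chains, element=[_element_of(x) for x in names])

    # ---- per-frame coordinates --------------------------------------------
    n_atoms = len(names)
    coords = np.empty((n, n_atoms, 3))
    bundle_center = np.mean(list(_BUNDLE_XY.values()), axis=0)
    gt_chol = {cid: np.empty(n) for cid in chol_tracks}
    for f in range(n):
        helices = helices0 if f == 0 else build_protein(f)
        prot = np.concatenate([hel.coords for hel in helices])
        coords[f, :n_protein] = prot
        pos = n_protein
        if mem_cols is not None:
            m = mem_cols[4].shape[0]
            coords[f, pos : pos + m] = mem_cols[4]
            pos += m
        for chol in script.chols:
            chain_t, seq_t = chol_targets[chol.chol_id]
            # tether to the target residue's heavy atoms, along the outward azimuth
            res_mask = (table.chain[:n_protein] == chain_t) & (table.res_seq[:n_protein] == seq_t)
            res_xyz = prot[res_mask[:n_protein]]
            ca_idx = np.flatnonzero(res_mask[:n_protein] & (table.name[:n_protein] == "CA"))[0]
            ca = prot[ca_idx]
            if chol.azimuth is None:
                u = np.array([ca[0] - bundle_center[0], ca[1] - bundle_center[1], 0.0])
            else:
                a = math.radians(chol.azimuth)
                u = np.array([math.cos(a), math.sin(a), 0.0])
            u /= np.linalg.norm(u)
            d_target = float(chol_tracks[chol.chol_id][f])
            center = ca + d_target * u
            # correct so the min heavy-atom distance equals the scripted distance
            for _ in range(2):
                beads = center + np.array([[0.0, 0.0, -2.0], [0.0, 0.0, 0.0], [0.0, 0.0, 2.0]])
                dmin = min(np.linalg.norm(beads[:, None, :] - res_xyz[None, :, :], axis=2).min(), 1e9)
                center = center + (d_target - dmin) * u
            beads = center + np.array([[0.0, 0.0, -2.0], [0.0, 0.0, 0.0], [0.0, 0.0, 2.0]])
            coords[f, pos : pos + 3] = beads
            pos += 3
            gt_chol[chol.chol_id][f] = d_target
    if script.noise_sigma > 0:
        coords = coords + rng.normal(0.0, script.noise_sigma, coords.shape)
    traj = Trajectory(table, coords, stride=script.stride)

    ground_truth = {
        "events": [(ev.frame, ev.kind, ev.event_id) for ev in script.events],
        "bend": {h: track.copy() for h, track in kink_tracks.items()},
        "chi1": {key: track.copy() for key, track in chi_tracks.items()},
        "chol_distance": gt_chol,
        "tilts": dict(spec.tilts),
        "membrane_thickness": script.membrane_thickness,
        "bw_map": bw_map,
    }
    return traj, ground_truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def _baseline_bundle() -> BundleSpec:
    """Inactive-like baseline: TM6 kinked ~33°, TM7 kinked ~20°, toggle g-."""
    return BundleSpec(
        kinks={6: (50, 33.0, 200.0, 0.0), 7: (50, 20.0, 330.0, 0.0)},
        tilts={4: (16.0, 250.0)},
    )


def agonist_script(
    n_frames: int = 500,
    seed: int = 0,
    event_frames: Sequence[int] | None = None,
    noise_sigma: float = 0.2,
) -> ScenarioScript:
    """The six-event agonist activation sequence.

    Events (in scripted order): 1 TM6 straightens, 2 EC-TM6 approaches TM3,
    3 TM6 re-kinks, 4 toggle-switch χ1 flips g- to trans, 5 IC-TM6 leaves TM3,
    6 ionic lock opens.  A cholesterol particle at the EC end of TM6 departs
    during the straightening interval, mirroring the coupled cholesterol motion.
    """
    if event_frames is None:
        event_frames = [int(n_frames * k / 10) for k in (1, 2, 3, 4, 5, 6)]
    f1, f2, f3, f4, f5, f6 = event_frames
    events = [
        ScriptedEvent(f1, "kink-change", {"helix": 6, "to_bend": 8.0}, event_id=1),
        ScriptedEvent(f2, "helix-shift",
                      {"helix": 6, "lo_minor": 52, "hi_minor": 65, "toward": 3, "shift": 3.0},
                      event_id=2),
        ScriptedEvent(f3, "kink-change", {"helix": 6, "to_bend": 28.0}, event_id=3),
        ScriptedEvent(f4, "rotamer-flip", {"helix": 6, "minor": 48, "to_chi1": 180.0}, event_id=4),
        ScriptedEvent(f5, "helix-shift",
                      {"helix": 6, "lo_minor": 37, "hi_minor": 42, "toward": 3,
                       "sign": -1.0, "shift": 4.0},
                      event_id=5),
        ScriptedEvent(f6, "lock-open", {"shift": 5.0}, event_id=6),
        ScriptedEvent(max(f1 - 10, 0), "chol-depart", {"chol_id": 1, "to_distance": 14.0}),
    ]
    return ScenarioScript(
        seed=seed,
        n_frames=n_frames,
        noise_sigma=noise_sigma,
        events=events,
        bundle=_baseline_bundle(),
        chols=[CholParticle(1, "6.57", 4.0)],
    )


def inverse_script(n_frames: int = 200, seed: int = 0, close_frame: int | None = None) -> ScenarioScript:
    """Inverse-agonist-like scenario: lock starts open and closes; no toggle flip."""
    if close_frame is None:
        close_frame = n_frames // 2
    spec = _baseline_bundle()
    # start with the IC segment of TM6 displaced away from TM3 (lock open)
    xy3 = np.array(_BUNDLE_XY[3])
    xy6 = np.array(_BUNDLE_XY[6])
    u = (xy3 - xy6) / np.linalg.norm(xy3 - xy6)
    spec.seg_shifts = ((6, spec.minor_ranges[6][0], 36, -5.5 * u[0], -5.5 * u[1], 0.0),)
    events = [
        ScriptedEvent(close_frame, "lock-close", {"shift": 5.5}, event_id=6),
    ]
    return ScenarioScript(seed=seed, n_frames=n_frames, events=events, bundle=spec)


def static_script(
    n_frames: int = 20,
    seed: int = 0,
    membrane_thickness: float | Callable | None = 28.0,
    noise_sigma: float = 0.2,
) -> ScenarioScript:
    """No events: a static bundle in a membrane slab (thickness-map fixtures)."""
    return ScenarioScript(
        seed=seed,
        n_frames=n_frames,
        noise_sigma=noise_sigma,
        events=[],
        bundle=_baseline_bundle(),
        membrane_thickness=membrane_thickness,
    )
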