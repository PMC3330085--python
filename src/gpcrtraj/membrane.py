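"""Membrane hydrophobic-thickness mapping and residual hydrophobic mismatch.

Local hydrophobic thickness is the vertical distance between the lipid
glycerol-backbone C2 markers of the two leaflets, collected on a square xy grid
(2 Å bins by default) and averaged over an analysis window.  Per-TM profiles
compare each helix's hydrophobic length with the local membrane thickness in the
membrane sector facing that helix; residues whose hydropathy mismatches their
vertical environment contribute their lipid-facing solvent-accessible surface
area (SASA) to the TM's residual exposure — the quantity proposed to drive
mismatch-mediated receptor oligomerization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .bwmap import BWMap
from .exceptions import GeometryError, ParameterError
from .helix import fit_axis_points
from .model import Frame, Selection, Trajectory, PROTEIN_RESNAMES, select

__all__ = [
    "ThicknessMap",
    "TMEntry",
    "TMProfile",
    "assign_leaflets",
    "thickness_map",
    "tm_hydrophobic_length",
    "sasa",
    "residue_sasa",
    "residual_exposure",
    "rank_interface",
    "HYDROPHOBIC_RESNAMES",
    "POLAR_RESNAMES",
    "DEFAULT_RADII",
]

#: Binary hydropathy classification (config-overridable at call sites).
HYDROPHOBIC_RESNAMES = frozenset("ALA CYS PHE GLY ILE LEU MET VAL TRP TYR".split())
POLAR_RESNAMES = frozenset("ASP GLU LYS ASN GLN ARG SER THR HIS PRO".split())

#: Van der Waals radii (Å) for SASA; probe radius 1.4 Å.
DEFAULT_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

_MIN_LEAFLET_SEPARATION = 5.0  # Å; below this the two "leaflets" are one layer


@dataclass(frozen=True)
class ThicknessMap:
    """Time-averaged inter-leaflet C2-C2 distance on a square xy grid.

    ``values[i, j]`` is the mean thickness of bin (i, j) in Å (NaN where no lipid
    pair was observed or the bin is under the protein); ``midplane`` is the mean
    z of the bilayer midplane per bin; ``counts`` the number of frame-samples.
    """

    origin: np.ndarray          # (2,) lower-left corner, Å
    bin_size: float
    values: np.ndarray          # (nx, ny), Å, NaN where masked
    midplane: np.ndarray        # (nx, ny), Å, NaN where masked
    counts: np.ndarray          # (nx, ny)
    protein_mask: np.ndarray    # (nx, ny) True where the protein occupies the bin

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.bin_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.bin_size
        return xs, ys


@dataclass(frozen=True)
class TMEntry:
    tm: int
    span: tuple[str, str]
    hydrophobic_length: float
    d_memb: float
    residual_area: float
    residues: tuple[str, ...]


@dataclass(frozen=True)
class TMProfile:
    """Per-TM hydrophobic length, local membrane thickness and residual exposure."""

    entries: dict

    def total_residual_area(self) -> float:
        areas = [e.residual_area for e in self.entries.values() if np.isfinite(e.residual_area)]
        return float(sum(areas))


def assign_leaflets(
    frame: Frame, c2_selection: Selection, normal: np.ndarray = (0.0, 0.0, 1.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Partition C2 marker atoms into upper/lower leaflets by z about the median.

    Returns (upper_indices, lower_indices) into the frame's atom table.  If the
    two groups are separated by less than ~5 Å the input is a single layer and a
    geometry error is raised.
    """
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    z = frame.coords[c2_selection.indices] @ normal
    if z.size < 2:
        raise GeometryError("need at least one C2 atom per leaflet")
    median = np.median(z)
    upper = c2_selection.indices[z > median]
    lower = c2_selection.indices[z <= median]
    if upper.size == 0 or lower.size == 0:
        raise GeometryError("all C2 atoms on one side of the median plane")
    sep = frame.coords[upper] @ normal
    sep_lo = frame.coords[lower] @ normal
    if sep.mean() - sep_lo.mean() < _MIN_LEAFLET_SEPARATION:
        raise GeometryError("C2 atoms do not form two separated leaflets")
    return upper, lower


def thickness_map(
    traj: Trajectory,
    c2_selection: Selection,
    bin_size: float = 2.0,
    window: int | None = None,
    protein_selection: Selection | None = None,
    normal: np.ndarray = (0.0, 0.0, 1.0),
) -> ThicknessMap:
    """Binned time-averaged hydrophobic thickness over the last ``window`` frames.

    Each bin's per-frame value is (mean upper-leaflet C2 z in bin) minus (mean
    lower-leaflet C2 z in bin); bins where either leaflet is absent contribute no
    sample.  Bins containing protein heavy atoms (xy, any frame of the window)
    are masked.
    """
    if bin_size <= 0:
        raise ParameterError("bin size must be positive")
    traj = traj.window(window)
    if traj.n_frames < 1:
        raise ParameterError("empty analysis window")

    c2_xy = traj.coords[:, c2_selection.indices][:, :, :2]
    lo = c2_xy.reshape(-1, 2).min(axis=0)
    hi = c2_xy.reshape(-1, 2).max(axis=0)
    origin = np.floor(lo / bin_size) * bin_size
    nx = int(np.ceil((hi[0] - origin[0]) / bin_size)) + 1
    ny = int(np.ceil((hi[1] - origin[1]) / bin_size)) + 1

    sums = np.zeros((nx, ny))
    mids = np.zeros((nx, ny))
    counts = np.zeros((nx, ny), dtype=int)
    for k in range(traj.n_frames):
        frame = traj.frame(k)
        upper, lower = assign_leaflets(frame, c2_selection, normal)
        ux = np.floor((frame.coords[upper][:, 0] - origin[0]) / bin_size).astype(int)
        uy = np.floor((frame.coords[upper][:, 1] - origin[1]) / bin_size).astype(int)
        lx = np.floor((frame.coords[lower][:, 0] - origin[0]) / bin_size).astype(int)
        ly = np.floor((frame.coords[lower][:, 1] - origin[1]) / bin_size).astype(int)
        uz = frame.coords[upper][:, 2]
        lz = frame.coords[lower][:, 2]
        up_sum = np.zeros((nx, ny))
        up_n = np.zeros((nx, ny), dtype=int)
        lo_sum = np.zeros((nx, ny))
        lo_n = np.zeros((nx, ny), dtype=int)
        np.add.at(up_sum, (ux, uy), uz)
        np.add.at(up_n, (ux, uy), 1)
        np.add.at(lo_sum, (lx, ly), lz)
        np.add.at(lo_n, (lx, ly), 1)
        both = (up_n > 0) & (lo_n > 0)
        mu_up = np.where(up_n > 0, up_sum / np.maximum(up_n, 1), 0.0)
        mu_lo = np.where(lo_n > 0, lo_sum / np.maximum(lo_n, 1), 0.0)
        sums[both] += (mu_up - mu_lo)[both]
        mids[both] += ((mu_up + mu_lo) / 2.0)[both]
        counts[both] += 1

    protein_mask = np.zeros((nx, ny), dtype=bool)
    if protein_selection is not None and len(protein_selection) > 0:
        pxy = traj.coords[:, protein_selection.indices][:, :, :2].reshape(-1, 2)
        px = np.floor((pxy[:, 0] - origin[0]) / bin_size).astype(int)
        py = np.floor((pxy[:, 1] - origin[1]) / bin_size).astype(int)
        inside = (px >= 0) & (px < nx) & (py >= 0) & (py < ny)
        protein_mask[px[inside], py[inside]] = True

    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        midplane = np.where(counts > 0, mids / np.maximum(counts, 1), np.nan)
    values[protein_mask] = np.nan
    midplane[protein_mask] = np.nan
    return ThicknessMap(
        origin=np.asarray(origin, float),
        bin_size=float(bin_size),
        values=values,
        midplane=midplane,
        counts=counts,
        protein_mask=protein_mask,
    )


def tm_hydrophobic_length(
    frame: Frame,
    bw_map: BWMap,
    tm: int,
    hydrophobic: frozenset[str] = HYDROPHOBIC_RESNAMES,
    normal: np.ndarray = (0.0, 0.0, 1.0),
) -> float:
    """Extent along the membrane normal of the hydrophobic Cα of one TM span (Å).

    Returns 0.0 (flagged by being exactly zero) if the span contains no
    hydrophobic residue.
    """
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    zs = []
    for chain, res_seq in bw_map.span_residues(tm):
        mask = frame.table.residue_mask(chain, res_seq) & (frame.table.name == "CA")
        idx = np.flatnonzero(mask)
        if idx.size != 1:
            continue
        if str(frame.table.res_name[idx[0]]) in hydrophobic:
            zs.append(float(frame.coords[idx[0]] @ normal))
    if not zs:
        return 0.0
    return float(max(zs) - min(zs))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere point set."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    frame: Frame,
    selection: Selection | None = None,
    probe: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] = DEFAULT_RADII,
) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area per atom (Å²).

    Each atom's expanded sphere (vdW + probe) is sampled with a fixed
    deterministic golden-spiral point set; points buried inside any neighbour's
    expanded sphere are inaccessible.  Occluders are the atoms of ``selection``
    (default: all atoms of the frame).
    """
    if selection is None:
        idx = np.arange(frame.n_atoms)
    else:
        idx = selection.indices
    elements = [str(e) for e in frame.table.element[idx]]
    try:
        r = np.array([radii[e] for e in elements])
    except KeyError as exc:
        raise ParameterError(f"no SASA radius for element {exc.args[0]!r}") from None
    coords = frame.coords[idx]
    expanded = r + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.zeros(idx.size)
    for i in range(idx.size):
        pts = coords[i] + expanded[i] * unit
        neighbours = tree.query_ball_point(coords[i], expanded[i] + expanded.max())
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > expanded[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas


def residue_sasa(
    frame: Frame,
    selection: Selection | None = None,
    probe: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] = DEFAULT_RADII,
) -> dict[tuple[str, int], float]:
    """Per-residue SASA: per-atom areas summed over each (chain, res_seq)."""
    if selection is None:
        idx = np.arange(frame.n_atoms)
    else:
        idx = selection.indices
    areas = sasa(frame, selection, probe=probe, n_points=n_points, radii=radii)
    out: dict[tuple[str, int], float] = {}
    for a, i in zip(areas, idx):
        key = (str(frame.table.chain[i]), int(frame.table.res_seq[i]))
        out[key] = out.get(key, 0.0) + float(a)
    return out


def _sector_thickness(
    tmap: ThicknessMap,
    axis_xy: np.ndarray,
    outward: np.ndarray,
    r_inner: float = 5.0,
    r_outer: float = 12.0,
    half_angle_deg: float = 45.0,
) -> tuple[float, float]:
    """Mean thickness and midplane z of the annular wedge facing away from the bundle."""
    xs, ys = tmap.bin_centers()
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    dx = gx - axis_xy[0]
    dy = gy - axis_xy[1]
    rr = np.hypot(dx, dy)
    norm_out = np.linalg.norm(outward)
    if norm_out < 1e-9:
        cos_ok = np.ones_like(rr, dtype=bool)  # axis at bundle center: use full annulus
    else:
        cosang = (dx * outward[0] + dy * outward[1]) / (np.maximum(rr, 1e-9) * norm_out)
        cos_ok = cosang >= np.cos(np.radians(half_angle_deg))
    in_sector = (rr >= r_inner) & (rr <= r_outer) & cos_ok & np.isfinite(tmap.values)
    if not np.any(in_sector):
        return float("nan"), float("nan")
    return float(tmap.values[in_sector].mean()), float(tmap.midplane[in_sector].mean())


def residual_exposure(
    frame: Frame,
    bw_map: BWMap,
    tmap: ThicknessMap,
    hydrophobic: frozenset[str] = HYDROPHOBIC_RESNAMES,
    contact_cutoff: float = 6.0,
    probe: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] = DEFAULT_RADII,
    sector: tuple[float, float, float] = (5.0, 12.0, 45.0),
) -> TMProfile:
    """Per-TM residual hydrophobic exposure from SASA and the local thickness sector.

    For each TM: the local membrane thickness d_memb is averaged over the annular
    sector (r in [5, 12] Å of the helix axis, 90° wedge facing away from the
    bundle center); residues whose hydropathy class mismatches their vertical
    position relative to the hydrophobic slab [mid - d/2, mid + d/2] — hydrophobic
    residues outside it, polar residues inside it — contribute their lipid-facing
    SASA.  TMs whose sector contains no lipid are flagged with NaN.
    """
    t = frame.table
    protein_sel = select(frame, "protein")
    atom_areas = sasa(frame, protein_sel, probe=probe, n_points=n_points, radii=radii)
    area_by_index = dict(zip(protein_sel.indices.tolist(), atom_areas))

    heavy = np.array([not str(e).upper().startswith("H") for e in t.element])
    protein_mask = np.isin(np.asarray(t.res_name, dtype="U4"), list(PROTEIN_RESNAMES))
    lipid_idx = np.flatnonzero(~protein_mask & heavy)
    have_lipids = lipid_idx.size > 0
    if have_lipids:
        lipid_tree = cKDTree(frame.coords[lipid_idx])
        dist_to_lipid, _ = lipid_tree.query(frame.coords[protein_sel.indices])
        lipid_facing = dict(zip(protein_sel.indices.tolist(), dist_to_lipid <= contact_cutoff))

    # helix axes and bundle center (xy)
    axes_xy: dict[int, np.ndarray] = {}
    for tm in bw_map.tm_spans:
        cas = []
        for chain, res_seq in bw_map.span_residues(tm):
            mask = t.residue_mask(chain, res_seq) & (t.name == "CA")
            idx = np.flatnonzero(mask)
            if idx.size == 1:
                cas.append(frame.coords[idx[0]])
        if len(cas) >= 4:
            axes_xy[tm] = np.asarray(cas).mean(axis=0)[:2]
    center_xy = np.mean(list(axes_xy.values()), axis=0)

    entries: dict[int, TMEntry] = {}
    for tm, span in bw_map.tm_spans.items():
        if tm not in axes_xy:
            continue
        outward = axes_xy[tm] - center_xy
        d_memb, mid_z = _sector_thickness(tmap, axes_xy[tm], outward, *sector)
        hydro_len = tm_hydrophobic_length(frame, bw_map, tm, hydrophobic=hydrophobic)
        if not np.isfinite(d_memb):
            entries[tm] = TMEntry(tm, span, hydro_len, d_memb, float("nan"), ())
            continue
        z_lo, z_hi = mid_z - d_memb / 2.0, mid_z + d_memb / 2.0
        area = 0.0
        contributing: list[str] = []
        for code, (chain, res_seq) in zip(bw_map.span_codes(tm), bw_map.span_residues(tm)):
            res_idx = np.flatnonzero(t.residue_mask(chain, res_seq))
            if res_idx.size == 0:
                continue
            res_name = str(t.res_name[res_idx[0]])
            ca = np.flatnonzero(t.residue_mask(chain, res_seq) & (t.name == "CA"))
            if ca.size != 1:
                continue
            z = float(frame.coords[ca[0], 2])
            inside = z_lo <= z <= z_hi
            is_hydrophobic = res_name in hydrophobic
            mismatched = (is_hydrophobic and not inside) or ((not is_hydrophobic) and inside)
            if not mismatched:
                continue
            res_area = 0.0
            for i in res_idx:
                if int(i) not in area_by_index:
                    continue
                if have_lipids:
                    facing = lipid_facing[int(i)]
                else:
                    rel = frame.coords[i, :2] - axes_xy[tm]
                    facing = float(np.dot(rel, outward)) > 0.0
                if facing:
                    res_area += area_by_index[int(i)]
            if res_area > 0.0:
                area += res_area
                contributing.append(code)
        entries[tm] = TMEntry(tm, span, hydro_len, d_memb, float(area), tuple(contributing))
    return TMProfile(entries=entries)


def rank_interface(profile: TMProfile) -> tuple[list[tuple[int, float]], float]:
    """TMs sorted by descending residual exposed area, plus the summed total (Å²).

    NaN (masked-sector) entries sort last with zero score; ties keep TM order.
    """
    items = []
    for tm, e in profile.entries.items():
        score = e.residual_area if np.isfinite(e.residual_area) else 0.0
        items.append((tm, float(score)))
    items.sort(key=lambda p: (-p[1], p[0]))
    return items, profile.total_residual_area()
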