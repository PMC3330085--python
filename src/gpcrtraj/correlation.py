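"""Cholesterol-contact time series and rank-correlation matrices.

Pairwise coupling between slow degrees of freedom (helix bend/face-shift angles,
cholesterol-residue minimum distances) is scored by the squared Spearman rank
correlation, which is insensitive to the (unknown) functional form linking the
variables.  Two canonical variable sets are defined: the 8-variable set couples
the TM6/TM7 kink parameters to the cholesterol at the extracellular end of TM6,
the 12-variable set to the cholesterol at the intracellular TM6-TM7 interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .bwmap import BWMap
from .exceptions import ParameterError, SelectionError
from .model import Selection, TimeSeries, Trajectory, select

__all__ = [
    "CorrelationMatrix",
    "OccupancyTable",
    "spearman_r2",
    "pearson_r2",
    "correlation_matrix",
    "chol_min_distance",
    "chol_occupancy",
    "M8_VARIABLES",
    "M12_VARIABLES",
]

#: m = 8 set: TM6/TM7 bend and face-shift + Chol(EC-TM6) minimum distances.
M8_VARIABLES: tuple[str, ...] = (
    "bend_6.50", "face_shift_6.50", "bend_7.50", "face_shift_7.50",
    "chol_6.53", "chol_6.57", "chol_6.60", "chol_6.61",
)

#: m = 12 set: TM6/TM7 bend and face-shift + Chol(IC TM6-7) minimum distances.
M12_VARIABLES: tuple[str, ...] = (
    "bend_6.50", "face_shift_6.50", "bend_7.50", "face_shift_7.50",
    "chol_6.35", "chol_6.39", "chol_6.42", "chol_6.46",
    "chol_7.44", "chol_7.48", "chol_7.52", "chol_7.55",
)

_VARIABLE_SETS = {"m8": M8_VARIABLES, "m12": M12_VARIABLES}


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric matrix of squared rank (or Pearson) correlations, unit diagonal."""

    labels: tuple[str, ...]
    r2: np.ndarray
    n_frames: int
    method: str = "spearman"

    def __post_init__(self) -> None:
        m = len(self.labels)
        if self.r2.shape != (m, m):
            raise ParameterError("R2 matrix shape does not match labels")


@dataclass(frozen=True)
class OccupancyTable:
    """Per-region cholesterol occupancy: mean contact count and fraction of frames occupied."""

    regions: tuple[str, ...]           # sorted by descending fractional occupancy
    mean_count: dict[str, float]
    fraction: dict[str, float]


def spearman_r2(x: np.ndarray | TimeSeries, y: np.ndarray | TimeSeries) -> float:
    """Squared Spearman rank correlation; ties get average ranks.

    Equivalent to Pearson's r^2 computed on ranks, which reduces to
    (1 - 6*sum(d^2)/(N(N^2-1)))^2 when there are no ties.  A constant input has
    no defined rank correlation and returns NaN.
    """
    xv = x.values if isinstance(x, TimeSeries) else np.asarray(x, float)
    yv = y.values if isinstance(y, TimeSeries) else np.asarray(y, float)
    if xv.shape != yv.shape or xv.size < 3:
        raise ParameterError("spearman_r2 needs two equal-length series of >=3 points")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return float("nan")
    rho = stats.spearmanr(xv, yv).statistic
    return float(rho * rho)


def pearson_r2(x: np.ndarray | TimeSeries, y: np.ndarray | TimeSeries) -> float:
    """Squared Pearson correlation (comparison mode)."""
    xv = x.values if isinstance(x, TimeSeries) else np.asarray(x, float)
    yv = y.values if isinstance(y, TimeSeries) else np.asarray(y, float)
    if xv.shape != yv.shape or xv.size < 3:
        raise ParameterError("pearson_r2 needs two equal-length series of >=3 points")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return float("nan")
    r = stats.pearsonr(xv, yv).statistic
    return float(r * r)


def correlation_matrix(
    variables: Mapping[str, TimeSeries],
    variable_set: str | Sequence[str] = "custom",
    method: str = "spearman",
) -> CorrelationMatrix:
    """All-pairs squared correlation matrix over named time series.

    ``variable_set`` may be 'm8', 'm12' (canonical label lists) or an explicit
    sequence of labels; 'custom' uses every entry of ``variables`` in insertion
    order.  All series must share one time grid.
    """
    if isinstance(variable_set, str):
        if variable_set == "custom":
            labels = tuple(variables.keys())
        elif variable_set in _VARIABLE_SETS:
            labels = _VARIABLE_SETS[variable_set]
        else:
            raise ParameterError(f"unknown variable set {variable_set!r}")
    else:
        labels = tuple(variable_set)
    missing = [l for l in labels if l not in variables]
    if missing:
        raise ParameterError(f"missing variables for correlation matrix: {missing}")
    series = [variables[l] for l in labels]
    t0 = series[0].times
    for s in series[1:]:
        if s.times.shape != t0.shape or not np.allclose(s.times, t0):
            raise ParameterError(f"series {s.label!r} is not on the common time grid")
    score = spearman_r2 if method == "spearman" else pearson_r2
    if method not in {"spearman", "pearson"}:
        raise ParameterError(f"unknown correlation method {method!r}")
    m = len(labels)
    r2 = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            r2[i, j] = r2[j, i] = score(series[i], series[j])
    return CorrelationMatrix(labels=labels, r2=r2, n_frames=t0.size, method=method)


def _chol_selection(traj: Trajectory, chol_res_seq: int, chol_resname: str) -> Selection:
    sel = select(
        traj, f"resname {chol_resname} and resid {chol_res_seq} and not name H* and not element H",
        allow_empty=True,
    )
    if len(sel) == 0:
        raise SelectionError(f"no cholesterol-like residue {chol_resname} {chol_res_seq}")
    return sel


def chol_min_distance(
    traj: Trajectory,
    bw_map: BWMap,
    chol_res_seq: int,
    residues: Sequence[str],
    chol_resname: str = "CHL",
) -> dict[str, TimeSeries]:
    """Per-residue minimum heavy-atom distance to one cholesterol-like residue (Å)."""
    chol = _chol_selection(traj, chol_res_seq, chol_resname)
    out: dict[str, TimeSeries] = {}
    for code in residues:
        chain, res_seq = bw_map.resolve(code)
        mask = traj.table.residue_mask(chain, res_seq)
        mask &= np.array([not str(e).upper().startswith("H") for e in traj.table.element])
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(f"residue {code} absent from trajectory")
        vals = np.empty(traj.n_frames)
        for k in range(traj.n_frames):
            vals[k] = cdist(traj.coords[k, idx], traj.coords[k, chol.indices]).min()
        out[code] = TimeSeries(label=f"chol_{code}", times=traj.times, values=vals, units="Angstrom")
    return out


def chol_occupancy(
    traj: Trajectory,
    regions: Mapping[str, Selection],
    cutoff: float = 5.5,
    chol_resname: str = "CHL",
) -> OccupancyTable:
    """Cholesterol occupancy of labelled protein regions.

    For each region: the fraction of frames with at least one cholesterol heavy
    atom within ``cutoff`` Å of any region atom, and the mean number of distinct
    cholesterol residues in contact.  Regions come out ranked by fraction.
    """
    if not regions:
        raise ParameterError("no regions supplied")
    t = traj.table
    heavy = np.array([not str(e).upper().startswith("H") for e in t.element])
    chol_mask = (t.res_name == chol_resname) & heavy
    chol_idx = np.flatnonzero(chol_mask)
    chol_ids = t.res_seq[chol_idx]
    fraction: dict[str, float] = {}
    mean_count: dict[str, float] = {}
    for label, sel in regions.items():
        if chol_idx.size == 0 or cutoff <= 0:
            fraction[label] = 0.0
            mean_count[label] = 0.0
            continue
        counts = np.zeros(traj.n_frames)
        for k in range(traj.n_frames):
            d = cdist(traj.coords[k, chol_idx], traj.coords[k, sel.indices]).min(axis=1)
            in_contact = np.unique(chol_ids[d <= cutoff])
            counts[k] = in_contact.size
        fraction[label] = float(np.mean(counts >= 1))
        mean_count[label] = float(counts.mean())
    order = tuple(sorted(regions, key=lambda l: fraction[l], reverse=True))
    return OccupancyTable(regions=order, mean_count=mean_count, fraction=fraction)
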