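"""Structural-motif / functional-microdomain (SM/FM) observables and the
activation-event timeline.

The observables are the standard reporters of class-A GPCR activation state:
Cα distances across the TM3-TM6 interface (ionic lock R3.50-E6.30, EC approach
D3.32-F6.52 / D3.32-N6.55), the toggle-switch W6.48 side-chain rotamer (χ1/χ2)
and aromatic-ring tilt, the TM6 proline-kink bend, and TM backbone RMSDs.
Event detection turns these traces into a time-ordered activation sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .bwmap import BWMap
from .exceptions import ConfigurationError, ParameterError, SelectionError
from .fitting import dihedral, plane_normal, rmsd_after_fit
from .model import Frame, Selection, TimeSeries, Trajectory

__all__ = [
    "RotamerState",
    "LockState",
    "EventRecord",
    "EventTimeline",
    "EventRule",
    "DEFAULT_EVENT_RULES",
    "ca_distance",
    "min_distance",
    "chi_angles",
    "classify_rotamer",
    "ring_tilt",
    "backbone_rmsd",
    "running_average",
    "lock_state",
    "detect_activation_events",
    "TRP_RING_ATOMS",
]

#: Heavy atoms of the tryptophan indole six-membered ring (used for ring tilt).
TRP_RING_ATOMS = ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")

_CHI1_GAMMA = ("CG", "CG1", "OG", "OG1", "SG")
_CHI2_DELTA = ("CD1", "CD", "OD1", "ND1", "SD")


@dataclass(frozen=True)
class RotamerState:
    """χ1 rotamer classification: g- = [-120, 0), g+ = [0, 120), trans otherwise."""

    label: str
    chi1_deg: float
    chi2_deg: float = float("nan")


@dataclass(frozen=True)
class LockState:
    """Ionic-lock state from the R3.50-E6.30 Cα distance; ties (== threshold) are closed."""

    label: str
    distance: float


@dataclass(frozen=True)
class EventRecord:
    event_id: int
    onset_ns: float
    rule: str


@dataclass(frozen=True)
class EventTimeline:
    """Detected activation events ordered by onset time."""

    events: tuple[EventRecord, ...]

    def __post_init__(self) -> None:
        onsets = [e.onset_ns for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ParameterError("timeline events must be ordered by non-decreasing onset")

    def event_ids(self) -> list[int]:
        return [e.event_id for e in self.events]

    def __len__(self) -> int:
        return len(self.events)


def ca_distance(traj: Trajectory, bw_map: BWMap, code_a: str, code_b: str) -> TimeSeries:
    """Per-frame Cα-Cα Euclidean distance between two BW-addressed residues (Å)."""
    ca, ra = bw_map.resolve(code_a)
    cb, rb = bw_map.resolve(code_b)
    ia = traj.table.index_of(ca, ra, "CA")
    ib = traj.table.index_of(cb, rb, "CA")
    d = np.linalg.norm(traj.coords[:, ia] - traj.coords[:, ib], axis=1)
    return TimeSeries(label=f"dCA_{code_a}_{code_b}", times=traj.times, values=d, units="Angstrom")


def min_distance(traj: Trajectory, sel_a: Selection, sel_b: Selection) -> TimeSeries:
    """Per-frame minimum distance over all cross pairs of two selections (Å)."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise SelectionError("min_distance requires two non-empty selections")
    vals = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        vals[k] = cdist(traj.coords[k, sel_a.indices], traj.coords[k, sel_b.indices]).min()
    return TimeSeries(
        label=f"mindist[{sel_a.spec}|{sel_b.spec}]", times=traj.times, values=vals, units="Angstrom"
    )


def _residue_atom(frame_or_traj, chain: str, res_seq: int, candidates: Sequence[str]) -> int:
    table = frame_or_traj.table
    for name in candidates:
        try:
            return table.index_of(chain, res_seq, name)
        except SelectionError:
            continue
    raise SelectionError(
        f"residue (chain={chain!r}, res_seq={res_seq}) has none of {list(candidates)}"
    )


def chi_angles(traj: Trajectory, bw_map: BWMap, code: str) -> tuple[TimeSeries, TimeSeries]:
    """χ1 (N-CA-CB-Cγ) and χ2 (CA-CB-Cγ-Cδ) side-chain dihedral traces, degrees."""
    chain, res_seq = bw_map.resolve(code)
    t = traj.table
    i_n = t.index_of(chain, res_seq, "N")
    i_ca = t.index_of(chain, res_seq, "CA")
    i_cb = t.index_of(chain, res_seq, "CB")
    i_g = _residue_atom(traj, chain, res_seq, _CHI1_GAMMA)
    i_d = _residue_atom(traj, chain, res_seq, _CHI2_DELTA)
    chi1 = np.empty(traj.n_frames)
    chi2 = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        c = traj.coords[k]
        chi1[k] = dihedral(c[i_n], c[i_ca], c[i_cb], c[i_g])
        chi2[k] = dihedral(c[i_ca], c[i_cb], c[i_g], c[i_d])
    return (
        TimeSeries(label=f"chi1_{code}", times=traj.times, values=chi1, units="deg"),
        TimeSeries(label=f"chi2_{code}", times=traj.times, values=chi2, units="deg"),
    )


def classify_rotamer(chi1_deg: float, chi2_deg: float = float("nan")) -> RotamerState:
    """Assign the χ1 rotamer bin: g- = [-120, 0), g+ = [0, 120), trans elsewhere."""
    a = float(np.degrees(np.angle(np.exp(1j * np.radians(chi1_deg)))))  # fold to (-180, 180]
    if -120.0 <= a < 0.0:
        label = "g-"
    elif 0.0 <= a < 120.0:
        label = "g+"
    else:
        label = "trans"
    return RotamerState(label=label, chi1_deg=a, chi2_deg=chi2_deg)


def ring_tilt(traj: Trajectory, bw_map: BWMap, code: str, normal: np.ndarray) -> TimeSeries:
    """Tilt of the W6.48-type aromatic ring plane relative to the membrane normal.

    The angle between the least-squares ring-plane normal and the membrane normal,
    folded to [0, 90] degrees; 0 means the ring lies parallel to the membrane plane.
    """
    chain, res_seq = bw_map.resolve(code)
    idx = []
    for name in TRP_RING_ATOMS:
        try:
            idx.append(traj.table.index_of(chain, res_seq, name))
        except SelectionError:
            continue
    if len(idx) < 3:
        raise SelectionError(f"residue {code} has fewer than 3 ring atoms")
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    vals = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        pn = plane_normal(traj.coords[k, idx])
        cosang = abs(float(np.dot(pn, normal)))
        vals[k] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return TimeSeries(label=f"ring_tilt_{code}", times=traj.times, values=vals, units="deg")


def backbone_rmsd(traj: Trajectory, reference: Frame, selection: Selection) -> TimeSeries:
    """RMSD of a selection after Kabsch superposition onto the same selection of a reference."""
    if not traj.table.same_atoms(reference.table):
        raise ParameterError("reference frame must share the trajectory's atom table")
    ref = reference.coords[selection.indices]
    vals = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        vals[k] = rmsd_after_fit(traj.coords[k, selection.indices], ref)
    return TimeSeries(label=f"rmsd[{selection.spec}]", times=traj.times, values=vals, units="Angstrom")


def running_average(series: TimeSeries, window: int = 10) -> TimeSeries:
    """Trailing mean over the previous ``window`` samples, aligned to the window's last sample.

    Output has ``len(series) - window + 1`` points; e.g. a 10-point window on data
    collected every 100 ps reproduces the 1-ns running averages of the trace figures.
    """
    if window < 1:
        raise ParameterError("window must be >=1")
    if window > len(series):
        raise ParameterError(f"window {window} exceeds series length {len(series)}")
    kernel = np.full(window, 1.0 / window)
    vals = np.convolve(series.values, kernel, mode="valid")
    return TimeSeries(
        label=f"ravg{window}_{series.label}",
        times=series.times[window - 1 :],
        values=vals,
        units=series.units,
    )


def lock_state(series: TimeSeries, threshold: float = 9.0, dwell: int = 5) -> list[LockState]:
    """Per-frame open/closed ionic-lock labels with flicker suppression.

    Open means distance > threshold, closed means <= threshold (ties closed).  A
    change of label is accepted only when the new label persists for at least
    ``dwell`` consecutive frames; shorter excursions keep the previous label.
    """
    raw = np.where(series.values > threshold, "open", "closed")
    if dwell > 1 and raw.size:
        filtered = raw.copy()
        current = raw[0]
        i = 0
        while i < raw.size:
            j = i
            while j < raw.size and raw[j] == raw[i]:
                j += 1
            run = j - i
            if raw[i] == current or run >= dwell:
                current = raw[i]
                filtered[i:j] = raw[i]
            else:
                filtered[i:j] = current
            i = j
        raw = filtered
    return [LockState(label=str(l), distance=float(d)) for l, d in zip(raw, series.values)]


# ---------------------------------------------------------------------------
# Activation-event sequencing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventRule:
    """A threshold-crossing rule for one activation event.

    ``kind`` is 'below' / 'above' (on a TimeSeries) or 'rotamer_trans' (on a χ1
    trace).  The onset is the start of the first sustained (>= dwell frames)
    period satisfying the condition that follows a sustained period violating it;
    an initial satisfying period is baseline state, not an event.
    """

    event_id: int
    label: str
    series: str
    kind: str
    threshold: float = float("nan")
    dwell: int = 5


#: Default rules for the six-event agonist activation sequence:
#: 1 TM6 straightens, 2 EC-TM6 approaches TM3, 3 TM6 re-kinks, 4 toggle-switch
#: χ1 flips g- -> trans, 5 IC-TM6 leaves TM3, 6 ionic lock opens (>9 Å).
DEFAULT_EVENT_RULES: tuple[EventRule, ...] = (
    EventRule(1, "TM6 straightens", "tm6_bend", "below", 20.0),
    EventRule(2, "EC TM6 approaches TM3", "d_3.32_6.52", "below", 8.2),
    EventRule(3, "TM6 re-kinks", "tm6_bend", "above", 20.0),
    EventRule(4, "toggle switch flips", "chi1_6.48", "rotamer_trans"),
    EventRule(5, "IC TM6 leaves TM3", "d_3.32_6.40", "above", 21.2),
    EventRule(6, "ionic lock opens", "d_3.50_6.30", "above", 9.0),
)


#: Closing of the ionic lock (inverse-agonist behaviour); same microdomain as
#: event 6 but the opposite transition, hence the shared event id.
LOCK_CLOSE_RULE = EventRule(6, "ionic lock closes", "d_3.50_6.30", "below", 9.0)


def activation_metrics(traj, bw_map, normal=(0.0, 0.0, 1.0)) -> dict[str, TimeSeries]:
    """The observable bundle needed by the default activation-event rules.

    Computes the TM6 proline-kink bend, the EC-approach distances
    (D3.32-F6.52, D3.32-N6.55), the toggle χ1 trace, the IC-departure distance
    (D3.32-V6.40) and the ionic-lock distance (R3.50-E6.30).
    """
    from .helix import kink_series  # local import to avoid a module cycle

    bend, face_shift = kink_series(traj, bw_map, "6.50")
    chi1, chi2 = chi_angles(traj, bw_map, "6.48")
    return {
        "tm6_bend": bend,
        "tm6_face_shift": face_shift,
        "d_3.32_6.52": ca_distance(traj, bw_map, "3.32", "6.52"),
        "d_3.32_6.55": ca_distance(traj, bw_map, "3.32", "6.55"),
        "chi1_6.48": chi1,
        "chi2_6.48": chi2,
        "d_3.32_6.40": ca_distance(traj, bw_map, "3.32", "6.40"),
        "d_3.50_6.30": ca_distance(traj, bw_map, "3.50", "6.30"),
    }


def _sustained_onset(cond: np.ndarray, dwell: int) -> int | None:
    """Index of the first sustained True run following a sustained False run."""
    n = cond.size
    runs: list[tuple[bool, int, int]] = []  # (value, start, length)
    i = 0
    while i < n:
        j = i
        while j < n and cond[j] == cond[i]:
            j += 1
        runs.append((bool(cond[i]), i, j - i))
        i = j
    seen_false = False
    for value, start, length in runs:
        if not value:
            if length >= dwell:
                seen_false = True
        elif value and seen_false and length >= dwell:
            return start
    return None


def detect_activation_events(
    metrics: Mapping[str, TimeSeries],
    rules: Sequence[EventRule] = DEFAULT_EVENT_RULES,
) -> EventTimeline:
    """Detect activation events from a bundle of observable traces.

    ``metrics`` maps series keys (as named in each rule) to TimeSeries.  Events
    whose rule is never satisfied are simply absent from the timeline; a missing
    required series is a configuration error.
    """
    records = []
    for rule in rules:
        if rule.series not in metrics:
            raise ConfigurationError(f"event {rule.event_id} needs series {rule.series!r}")
        ts = metrics[rule.series]
        if rule.kind == "below":
            cond = ts.values < rule.threshold
        elif rule.kind == "above":
            cond = ts.values > rule.threshold
        elif rule.kind == "rotamer_trans":
            cond = np.array([classify_rotamer(v).label == "trans" for v in ts.values])
        else:
            raise ConfigurationError(f"unknown event rule kind {rule.kind!r}")
        onset = _sustained_onset(cond, rule.dwell)
        if onset is not None:
            records.append(EventRecord(rule.event_id, float(ts.times[onset]), rule.label))
    records.sort(key=lambda r: (r.onset_ns, r.event_id))
    return EventTimeline(events=tuple(records))
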