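"""Core containers: atom table, frames, trajectories, time series and selections.

A :class:`Trajectory` stores one immutable :class:`AtomTable` (names, residues,
chains) shared by all frames, plus a ``(n_frames, n_atoms, 3)`` coordinate array
in Å and a strictly increasing time vector in ns.  A :class:`Frame` is a single
snapshot with the same table.  All analysis modules operate on these containers.
"""

from __future__ import annotations

import fnmatch
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .exceptions import IntegrityError, ParameterError, SelectionError

__all__ = [
    "AtomRecord",
    "AtomTable",
    "Frame",
    "Trajectory",
    "TimeSeries",
    "Selection",
    "select",
    "PROTEIN_RESNAMES",
]

#: Three-letter codes treated as protein residues by the ``protein`` selection keyword.
PROTEIN_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame; ``xyz`` is in Å."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    xyz: np.ndarray

    def __post_init__(self) -> None:
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise IntegrityError(f"atom {self.serial} {self.name}: xyz must be a finite 3-vector")
        object.__setattr__(self, "xyz", xyz)


class AtomTable:
    """Per-atom identity columns shared by all frames of a trajectory.

    ``(chain, res_seq, name)`` must be unique; this is checked on construction.
    """

    __slots__ = ("serial", "name", "element", "res_name", "res_seq", "chain", "_key_index")

    def __init__(
        self,
        name: Sequence[str],
        res_name: Sequence[str],
        res_seq: Sequence[int],
        chain: Sequence[str],
        element: Sequence[str] | None = None,
        serial: Sequence[int] | None = None,
    ) -> None:
        n = len(name)
        self.name = np.asarray(name, dtype=object)
        self.res_name = np.asarray(res_name, dtype=object)
        self.res_seq = np.asarray(res_seq, dtype=int)
        self.chain = np.asarray(chain, dtype=object)
        if element is None:
            element = [_guess_element(a) for a in name]
        self.element = np.asarray(element, dtype=object)
        self.serial = np.asarray(serial if serial is not None else np.arange(1, n + 1), dtype=int)
        for col in (self.res_name, self.res_seq, self.chain, self.element, self.serial):
            if len(col) != n:
                raise IntegrityError("atom table columns have unequal lengths")
        keys = list(zip(self.chain, self.res_seq, self.name))
        self._key_index = {}
        for i, k in enumerate(keys):
            if k in self._key_index:
                raise IntegrityError(f"duplicate atom (chain={k[0]!r}, res_seq={k[1]}, name={k[2]!r})")
            self._key_index[k] = i

    def __len__(self) -> int:
        return len(self.name)

    def index_of(self, chain: str, res_seq: int, name: str) -> int:
        try:
            return self._key_index[(chain, res_seq, name)]
        except KeyError:
            raise SelectionError(f"no atom (chain={chain!r}, res_seq={res_seq}, name={name!r})") from None

    def residue_mask(self, chain: str, res_seq: int) -> np.ndarray:
        return (self.chain == chain) & (self.res_seq == res_seq)

    def subset(self, indices: np.ndarray) -> "AtomTable":
        """A new table restricted to ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return AtomTable(
            name=self.name[idx],
            res_name=self.res_name[idx],
            res_seq=self.res_seq[idx],
            chain=self.chain[idx],
            element=self.element[idx],
            serial=self.serial[idx],
        )

    def same_atoms(self, other: "AtomTable") -> bool:
        return (
            len(self) == len(other)
            and bool(np.all(self.name == other.name))
            and bool(np.all(self.res_seq == other.res_seq))
            and bool(np.all(self.chain == other.chain))
        )


def _guess_element(atom_name: str) -> str:
    """Element from an atom name: leading letters, two-letter only for common cases."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[:2].upper() in {"CL", "BR", "FE", "ZN", "MG", "NA", "SE"} and len(stripped) >= 2:
        return stripped[:2].capitalize()
    return stripped[0].upper()


class Frame:
    """A single coordinate snapshot over an :class:`AtomTable`."""

    __slots__ = ("table", "coords", "time", "box")

    def __init__(
        self,
        table: AtomTable,
        coords: np.ndarray,
        time: float = 0.0,
        box: np.ndarray | None = None,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(table), 3):
            raise IntegrityError(
                f"coordinate array shape {coords.shape} does not match {len(table)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise IntegrityError("non-finite coordinates")
        self.table = table
        self.coords = coords
        self.time = float(time)
        self.box = None if box is None else np.asarray(box, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.table)

    def atoms(self) -> Iterator[AtomRecord]:
        t = self.table
        for i in range(len(t)):
            yield AtomRecord(
                serial=int(t.serial[i]),
                name=str(t.name[i]),
                element=str(t.element[i]),
                res_name=str(t.res_name[i]),
                res_seq=int(t.res_seq[i]),
                chain=str(t.chain[i]),
                xyz=self.coords[i],
            )

    def copy(self) -> "Frame":
        return Frame(self.table, self.coords.copy(), self.time, None if self.box is None else self.box.copy())


class Trajectory:
    """Ordered frames over one atom table.

    ``times`` are strictly increasing (ns); ``stride`` is the nominal spacing
    between stored frames and defaults to the first time difference.
    """

    __slots__ = ("table", "coords", "times", "stride")

    def __init__(
        self,
        table: AtomTable,
        coords: np.ndarray,
        times: np.ndarray | None = None,
        stride: float = 0.1,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (len(table), 3):
            raise IntegrityError(f"trajectory coordinate shape {coords.shape} invalid for {len(table)} atoms")
        if coords.shape[0] < 1:
            raise IntegrityError("a trajectory needs at least one frame")
        if times is None:
            times = np.arange(coords.shape[0], dtype=float) * float(stride)
        times = np.asarray(times, dtype=float)
        if times.shape != (coords.shape[0],):
            raise IntegrityError("times length does not match frame count")
        if coords.shape[0] > 1 and not np.all(np.diff(times) > 0):
            raise IntegrityError("frame times must be strictly increasing")
        self.table = table
        self.coords = coords
        self.times = times
        self.stride = float(stride)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.table)

    def frame(self, i: int) -> Frame:
        return Frame(self.table, self.coords[i], time=self.times[i])

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def __len__(self) -> int:
        return self.n_frames

    @classmethod
    def from_frames(cls, frames: Sequence[Frame], stride: float = 0.1, times=None) -> "Trajectory":
        if not frames:
            raise IntegrityError("a trajectory needs at least one frame")
        table = frames[0].table
        for f in frames[1:]:
            if f.n_atoms != frames[0].n_atoms:
                raise IntegrityError(
                    f"frame atom-count mismatch: {f.n_atoms} vs {frames[0].n_atoms}"
                )
            if not f.table.same_atoms(table):
                raise IntegrityError("frame atom tables differ")
        coords = np.stack([f.coords for f in frames])
        return cls(table, coords, times=times, stride=stride)

    def window(self, last: int | None) -> "Trajectory":
        """The last ``last`` frames (analysis window); ``None`` keeps everything."""
        if last is None or last >= self.n_frames:
            return self
        if last < 1:
            raise ParameterError("window must contain at least one frame")
        return Trajectory(self.table, self.coords[-last:], self.times[-last:], self.stride)


@dataclass
class TimeSeries:
    """A labelled scalar observable sampled along a trajectory."""

    label: str
    times: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ParameterError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------

_KEYWORDS = {"and", "or", "not", "name", "resname", "resid", "chain", "element", "all", "protein", "(", ")"}

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class Selection:
    """A resolved, order-preserving atom index list with the expression that produced it."""

    spec: str
    indices: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.indices.size


class _SelParser:
    """Recursive-descent parser for expressions like ``name CA and resid 10-20``."""

    def __init__(self, tokens: list[str], table: AtomTable) -> None:
        self.toks = tokens
        self.pos = 0
        self.table = table

    def peek(self) -> str | None:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens near {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parenthesis in selection")
            return mask
        return self.primitive()

    def _values(self) -> list[str]:
        vals: list[str] = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.take())
        if not vals:
            raise SelectionError("selection keyword expects at least one value")
        return vals

    def primitive(self) -> np.ndarray:
        tok = self.take()
        t = self.table
        n = len(t)
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "protein":
            return np.isin(np.asarray(t.res_name, dtype="U4"), list(PROTEIN_RESNAMES))
        if tok in {"name", "resname", "chain", "element"}:
            col = {"name": t.name, "resname": t.res_name, "chain": t.chain, "element": t.element}[tok]
            mask = np.zeros(n, dtype=bool)
            for pat in self._values():
                if any(c in pat for c in "*?[]"):
                    mask |= np.array([fnmatch.fnmatchcase(str(v), pat) for v in col])
                else:
                    mask |= col == pat
            return mask
        if tok == "resid":
            mask = np.zeros(n, dtype=bool)
            for val in self._values():
                m = re.fullmatch(r"(-?\d+)-(-?\d+)", val)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                    mask |= (t.res_seq >= lo) & (t.res_seq <= hi)
                elif re.fullmatch(r"-?\d+", val):
                    mask |= t.res_seq == int(val)
                else:
                    raise SelectionError(f"bad resid token {val!r}")
            return mask
        raise SelectionError(f"unknown selection keyword {tok!r}")


def select(obj: Trajectory | Frame | AtomTable, spec: str, allow_empty: bool = False) -> Selection:
    """Resolve a selection expression to an ordered atom index list.

    Resolution is deterministic and order-preserving: indices come out in atom-table
    order.  An empty result raises :class:`SelectionError` unless ``allow_empty``.
    """
    table = obj if isinstance(obj, AtomTable) else obj.table
    tokens = _TOKEN_RE.findall(spec)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _SelParser(tokens, table).parse()
    idx = np.flatnonzero(mask)
    if idx.size == 0 and not allow_empty:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    return Selection(spec=spec, indices=idx)
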