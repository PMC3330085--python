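"""Ballesteros-Weinstein generic residue numbering.

A BW code ``H.NN`` addresses position NN of transmembrane helix H relative to the
most conserved residue of that helix, which is assigned 50.  Within one helix the
arithmetic ``res_seq(H.NN) = res_seq(H.50) + (NN - 50)`` holds as long as the TM
span contains no insertions; maps with gaps must list every residue explicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

from .exceptions import IntegrityError, LookupErrorBW

__all__ = ["BWMap", "parse_bw", "TM_DEFINITIONS"]

#: TM helix spans used for membrane / hydrophobic-length analysis (BW codes).
TM_DEFINITIONS: dict[int, tuple[str, str]] = {
    1: ("1.29", "1.59"),
    2: ("2.38", "2.67"),
    3: ("3.24", "3.53"),
    4: ("4.39", "4.63"),
    5: ("5.38", "5.63"),
    6: ("6.33", "6.59"),
    7: ("7.30", "7.56"),
}

_BW_RE = re.compile(r"([1-8])\.(\d{2})")


def parse_bw(code: str) -> tuple[int, int]:
    """Split 'H.NN' into (helix, position); anything else raises."""
    m = _BW_RE.fullmatch(code.strip())
    if not m:
        raise LookupErrorBW(f"malformed BW code {code!r} (expected 'H.NN')")
    return int(m.group(1)), int(m.group(2))


@dataclass
class BWMap:
    """BW code -> residue address, with per-helix anchors and TM span definitions.

    ``anchors`` maps helix index -> (chain, res_seq) of the x.50 residue; codes not
    listed in ``entries`` are resolved by anchor arithmetic.  Explicit ``entries``
    take precedence and are validated for consecutiveness within each TM span.
    """

    anchors: Mapping[int, tuple[str, int]]
    tm_spans: Mapping[int, tuple[str, str]] = field(default_factory=lambda: dict(TM_DEFINITIONS))
    entries: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.anchors = dict(self.anchors)
        self.tm_spans = dict(self.tm_spans)
        for tm, (start, end) in self.tm_spans.items():
            h1, _ = parse_bw(start)
            h2, _ = parse_bw(end)
            if h1 != tm or h2 != tm:
                raise IntegrityError(f"TM{tm} span {start}-{end} names a different helix")
        self._validate_entries()

    def _validate_entries(self) -> None:
        by_helix: dict[int, list[tuple[int, int]]] = {}
        for code, (chain, res_seq) in self.entries.items():
            h, nn = parse_bw(code)
            by_helix.setdefault(h, []).append((nn, res_seq))
        for h, pairs in by_helix.items():
            pairs.sort()
            for (n0, r0), (n1, r1) in zip(pairs, pairs[1:]):
                if r1 - r0 != n1 - n0:
                    raise IntegrityError(
                        f"helix {h}: BW positions {n0}->{n1} map to res_seq {r0}->{r1}; "
                        "minor numbers must map to consecutive residues"
                    )

    def resolve(self, code: str) -> tuple[str, int]:
        """Residue address of a BW code (explicit entry, else anchor arithmetic)."""
        helix, pos = parse_bw(code)
        key = f"{helix}.{pos:02d}"
        if key in self.entries:
            return self.entries[key]
        if helix not in self.anchors:
            raise LookupErrorBW(f"no anchor for helix {helix} (code {code!r})")
        chain, anchor_seq = self.anchors[helix]
        return chain, anchor_seq + (pos - 50)

    def span_codes(self, tm: int) -> list[str]:
        """All BW codes of one TM span, in order."""
        if tm not in self.tm_spans:
            raise LookupErrorBW(f"no span recorded for TM{tm}")
        start, end = self.tm_spans[tm]
        h, lo = parse_bw(start)
        _, hi = parse_bw(end)
        return [f"{h}.{nn:02d}" for nn in range(lo, hi + 1)]

    def span_residues(self, tm: int) -> list[tuple[str, int]]:
        return [self.resolve(c) for c in self.span_codes(tm)]


def resolve_bw(bw_map: BWMap, code: str) -> tuple[str, int]:
    """Functional alias for :meth:`BWMap.resolve`."""
    return bw_map.resolve(code)
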