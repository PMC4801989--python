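"""Sliding-average beta-strand contiguity profiles.

A window of every size from ``w_min`` (4) to ``min(w_max, len)`` (20) is slid
across the sequence.  Each window is scored as

    sum(P_beta) / (0.5 * (sum(P_alpha) + sum(P_turn)))

using per-residue Chou-Fasman propensities; windows scoring below the cutoff
(1.2) are discarded, and the per-residue profile value is the sum of retained
window scores covering that position.  Propensities exist only for the 20
canonical residues: any window containing a non-canonical residue is skipped
entirely rather than partially summed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

from .chem import PEPTIDE, _data_path, _read_tsv
from .errors import (
    FragmentUnscorableError,
    ProfileUnavailableError,
    UnsupportedOperationError,
)
from .sequence import PolymerSequence

MIN_PROFILE_LENGTH = 10
DEFAULT_W_MIN = 4
DEFAULT_W_MAX = 20
DEFAULT_CUTOFF = 1.2


class ChouFasmanTable(Mapping[str, tuple[float, float, float]]):
    """residue code -> (P_alpha, P_beta, P_turn), canonical residues only."""

    def __init__(self, values: Mapping[str, tuple[float, float, float]]):
        self._values = dict(values)
        if len(self._values) != 20:
            raise ValueError(f"expected 20 canonical entries, got {len(self._values)}")
        for code, triple in self._values.items():
            if len(triple) != 3 or any(not v > 0 for v in triple):
                raise ValueError(f"non-positive propensity for {code}: {triple}")

    def __getitem__(self, code: str) -> tuple[float, float, float]:
        return self._values[code]

    def __iter__(self):
        return iter(self._values)

    def __len__(self):
        return len(self._values)

    @classmethod
    def from_tsv(cls, path: str | Path | None = None) -> "ChouFasmanTable":
        path = path or _data_path("chou_fasman.tsv")
        return cls(
            {
                row["code"]: (float(row["p_alpha"]), float(row["p_beta"]), float(row["p_turn"]))
                for row in _read_tsv(path)
            }
        )


@lru_cache(maxsize=1)
def default_chou_fasman() -> ChouFasmanTable:
    return ChouFasmanTable.from_tsv()


@dataclass(frozen=True)
class WindowScore:
    start: int  # 0-based
    length: int
    score: float


@dataclass(frozen=True)
class ContiguityProfile:
    values: tuple[float, ...]  # one per residue, >= 0
    windows: tuple[WindowScore, ...]  # retained (score >= cutoff) windows
    w_min: int
    w_max: int
    cutoff: float


def window_score(codes: Sequence[str], table: ChouFasmanTable | None = None) -> float:
    """Score one fragment; raises FragmentUnscorableError on unknown residues."""
    table = table or default_chou_fasman()
    missing = [c for c in codes if c not in table]
    if missing:
        raise FragmentUnscorableError(
            f"fragment contains residues without propensity parameters: {missing}"
        )
    sa = sum(table[c][0] for c in codes)
    sb = sum(table[c][1] for c in codes)
    st = sum(table[c][2] for c in codes)
    return sb / (0.5 * (sa + st))


def contiguity_profile(
    seq: PolymerSequence,
    table: ChouFasmanTable | None = None,
    w_min: int = DEFAULT_W_MIN,
    w_max: int = DEFAULT_W_MAX,
    cutoff: float = DEFAULT_CUTOFF,
) -> ContiguityProfile:
    if seq.polymer_class != PEPTIDE:
        raise UnsupportedOperationError("strand-contiguity profiles are peptide-only")
    n = len(seq)
    if n < MIN_PROFILE_LENGTH:
        raise ProfileUnavailableError(
            f"profile unavailable: requires >= {MIN_PROFILE_LENGTH} residues, got {n}"
        )
    table = table or default_chou_fasman()
    codes = seq.codes

    scorable = [c in table for c in codes]
    # prefix sums over scorable positions (unscorable contribute 0 but poison windows)
    pa = [0.0] * (n + 1)
    pb = [0.0] * (n + 1)
    pt = [0.0] * (n + 1)
    bad = [0] * (n + 1)
    for i, c in enumerate(codes):
        a, b, t = table[c] if scorable[i] else (0.0, 0.0, 0.0)
        pa[i + 1] = pa[i] + a
        pb[i + 1] = pb[i] + b
        pt[i + 1] = pt[i] + t
        bad[i + 1] = bad[i] + (0 if scorable[i] else 1)

    values = [0.0] * n
    retained: list[WindowScore] = []
    for length in range(w_min, min(w_max, n) + 1):
        for start in range(0, n - length + 1):
            end = start + length
            if bad[end] - bad[start]:
                continue
            score = (pb[end] - pb[start]) / (0.5 * ((pa[end] - pa[start]) + (pt[end] - pt[start])))
            if score < cutoff:
                continue
            retained.append(WindowScore(start, length, score))
            for i in range(start, end):
                values[i] += score
    return ContiguityProfile(tuple(values), tuple(retained), w_min, min(w_max, n), cutoff)
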