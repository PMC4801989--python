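"""Iterative-deepening assignment of m/z peaks to deletion/adduct variants.

Iteration N considers every combination of at most N residue deletions and at
most N modifications (metal adducts, unremoved protecting groups).  A peak is
assigned when a candidate's neutral mass falls within the tolerance of the
entered m/z (singly-charged assumption; the +-1.0 u window absorbs the
ionizing proton).  Assigned peaks are omitted from later iterations; the
iteration cap shrinks with sequence length to bound the combinatorics.

Deletions are compositional (keyed by residue code, not position): positional
variants are mass-identical and would only duplicate report rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .chem import (
    ChemDatabases,
    Modification,
    N_TERMINUS_SITE,
    default_databases,
)
from .errors import CandidateBudgetExceededError, InvalidPeakError, PepkitError
from .properties import FREE_N_TERMINUS, molecular_weight
from .sequence import PolymerSequence

DEFAULT_TOLERANCE = 1.0
DEFAULT_BUDGET = 5_000_000
# (max length, iteration cap) in ascending length order
DEFAULT_LENGTH_CAPS = ((30, 5), (60, 4), (150, 3))


@dataclass(frozen=True)
class Peak:
    mz: float

    def __post_init__(self):
        if not self.mz > 0:
            raise InvalidPeakError(f"m/z must be positive, got {self.mz}")


@dataclass(frozen=True)
class AssignmentConfig:
    tolerance: float = DEFAULT_TOLERANCE
    candidate_budget: int = DEFAULT_BUDGET
    length_caps: tuple[tuple[int, int], ...] = DEFAULT_LENGTH_CAPS

    def __post_init__(self):
        if not self.tolerance > 0:
            raise PepkitError(f"tolerance must be positive, got {self.tolerance}")


def iteration_cap(length: int, config: AssignmentConfig | None = None) -> int:
    config = config or AssignmentConfig()
    for max_len, cap in config.length_caps:
        if length <= max_len:
            return cap
    raise PepkitError(f"sequence length {length} exceeds the assignable maximum")


@dataclass(frozen=True)
class AssignmentCandidate:
    deletions: tuple[str, ...]  # residue codes, multiset as a sorted tuple
    modifications: tuple[str, ...]  # modification names, sorted tuple
    calculated_mass: float
    delta: float  # |calculated - peak m/z|

    @property
    def n_changes(self) -> int:
        return len(self.deletions) + len(self.modifications)


@dataclass
class PeakAssignment:
    peak: Peak
    candidates: list[AssignmentCandidate] = field(default_factory=list)
    iteration: int | None = None  # iteration at which first assigned

    @property
    def assigned(self) -> bool:
        return self.iteration is not None


@dataclass
class AssignmentReport:
    sequence: PolymerSequence
    assignments: list[PeakAssignment]
    config: AssignmentConfig
    iterations_run: int = 0


# ---------------------------------------------------------------------------
# combination enumeration (streamed; nothing is materialized per deletion set)


def enumerate_deletions(seq: PolymerSequence, n: int) -> Iterator[tuple[str, ...]]:
    """All multisets of at most *n* residue deletions, as sorted code tuples.

    Multiplicities are bounded by the sequence composition; the empty multiset
    (no deletion) is always included.
    """
    if n < 0:
        raise PepkitError(f"deletion count must be >= 0, got {n}")
    items = sorted(seq.composition().items())

    def rec(i: int, remaining: int) -> Iterator[tuple[str, ...]]:
        if i == len(items):
            yield ()
            return
        code, avail = items[i]
        for k in range(min(avail, remaining) + 1):
            head = (code,) * k
            for rest in rec(i + 1, remaining - k):
                yield head + rest

    yield from rec(0, n)


def licensed_count(seq: PolymerSequence, mod: Modification) -> int | None:
    """Maximum occurrences of *mod* on *seq*; None = unbounded (metals)."""
    if mod.unrestricted:
        return None
    count = sum(1 for r in seq.residues if r.code in mod.sites)
    if N_TERMINUS_SITE in mod.sites and seq.n_terminus.name == FREE_N_TERMINUS:
        count += 1
    return count * mod.max_per_site


def enumerate_modifications(
    seq: PolymerSequence, n: int, mods: Iterable[Modification]
) -> Iterator[tuple[str, ...]]:
    """All multisets of at most *n* modifications, respecting site licensing."""
    if n < 0:
        raise PepkitError(f"modification count must be >= 0, got {n}")
    bounded = []
    for mod in mods:
        cap = licensed_count(seq, mod)
        cap = n if cap is None else min(cap, n)
        if cap > 0:
            bounded.append((mod.name, cap))
    bounded.sort()

    def rec(i: int, remaining: int) -> Iterator[tuple[str, ...]]:
        if i == len(bounded):
            yield ()
            return
        name, cap = bounded[i]
        for k in range(min(cap, remaining) + 1):
            head = (name,) * k
            for rest in rec(i + 1, remaining - k):
                yield head + rest

    yield from rec(0, n)


def candidate_mass(
    seq: PolymerSequence,
    deletions: Sequence[str] = (),
    modifications: Sequence[str | Modification] = (),
    db: ChemDatabases | None = None,
) -> float:
    """Neutral mass of *seq* minus deleted residues plus modification deltas."""
    db = db or default_databases()
    composition = seq.composition()
    deleted = {}
    for code in deletions:
        deleted[code] = deleted.get(code, 0) + 1
    for code, k in deleted.items():
        if k > composition.get(code, 0):
            raise PepkitError(
                f"cannot delete {k} x {code!r}: sequence contains {composition.get(code, 0)}"
            )
    mass = molecular_weight(seq, db.masses)
    for code in deletions:
        mass -= seq.residues[seq.codes.index(code)].formula.mass(db.masses)
    for mod in modifications:
        if isinstance(mod, str):
            mod = db.modifications[mod]
        mass += mod.delta_mass(db.masses)
    return mass


def assign_peaks(
    seq: PolymerSequence,
    peaks: Sequence[float | Peak],
    config: AssignmentConfig | None = None,
    mods: Iterable[Modification] | None = None,
    db: ChemDatabases | None = None,
) -> AssignmentReport:
    """Run the iterative-deepening assignment for *peaks* against *seq*.

    Returns a report listing, per peak, every candidate within tolerance at
    the iteration where the peak was first assigned (all such candidates are
    reported), ordered by (number of changes, |delta|).
    """
    if not peaks:
        raise InvalidPeakError("at least one peak is required")
    db = db or default_databases()
    config = config or AssignmentConfig()
    mod_list = list(mods) if mods is not None else list(db.modifications.values())
    peak_objs = [p if isinstance(p, Peak) else Peak(float(p)) for p in peaks]

    assignments = [PeakAssignment(p) for p in peak_objs]
    cap = iteration_cap(len(seq), config)
    base_mass = molecular_weight(seq, db.masses)
    residue_mass = {r.code: r.formula.mass(db.masses) for r in seq.residues}
    mod_delta = {m.name: m.delta_mass(db.masses) for m in mod_list}

    unassigned = list(range(len(peak_objs)))
    iterations_run = 0
    for n in range(1, cap + 1):
        if not unassigned:
            break
        iterations_run = n
        mod_sets = list(enumerate_modifications(seq, n, mod_list))
        mod_masses = [sum(mod_delta[name] for name in ms) for ms in mod_sets]
        checked = 0
        hits: dict[int, list[AssignmentCandidate]] = {}
        for dels in enumerate_deletions(seq, n):
            del_mass = sum(residue_mass[c] for c in dels)
            for ms, mod_mass in zip(mod_sets, mod_masses):
                checked += 1
                if checked > config.candidate_budget:
                    raise CandidateBudgetExceededError(
                        f"iteration {n} exceeded the candidate budget "
                        f"({config.candidate_budget}); narrow the modification set "
                        "or raise the budget"
                    )
                calc = base_mass - del_mass + mod_mass
                for idx in unassigned:
                    delta = abs(calc - peak_objs[idx].mz)
                    if delta <= config.tolerance:
                        hits.setdefault(idx, []).append(
                            AssignmentCandidate(dels, ms, calc, delta)
                        )
        for idx, cands in hits.items():
            cands.sort(key=lambda c: (c.n_changes, c.delta, c.deletions, c.modifications))
            assignments[idx].candidates = cands
            assignments[idx].iteration = n
        unassigned = [i for i in unassigned if i not in hits]

    return AssignmentReport(seq, assignments, config, iterations_run)
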