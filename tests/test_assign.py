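import itertools

import pytest

from pepkit import (
    AssignmentConfig,
    assign_peaks,
    candidate_mass,
    enumerate_deletions,
    enumerate_modifications,
    iteration_cap,
    parse_peptide,
)
from pepkit.assign import licensed_count
from pepkit.errors import CandidateBudgetExceededError, InvalidPeakError, PepkitError
from pepkit.fixtures import generate_fixture, random_sequence


def oracle_assignment(seq, peaks, db, cap, tol=1.0, element_masses=None):
    """Flat-enumeration oracle, independent of the iterative engine.

    Deletion multisets come from position combinations; modification multisets
    from per-name count products.  Masses are recomputed from formula dicts
    with an externally supplied element-mass function when given.
    """
    if element_masses is None:
        element_masses = lambda s: db.masses[s]

    def fmass(formula):
        return sum(n * element_masses(sym) for sym, n in formula.items())

    base = (
        sum(fmass(r.formula) for r in seq.residues)
        + fmass(seq.n_terminus.formula)
        + fmass(seq.c_terminus.formula)
    )
    res_mass = {r.code: fmass(r.formula) for r in seq.residues}

    del_sets = set()
    for k in range(cap + 1):
        for positions in itertools.combinations(range(len(seq)), k):
            del_sets.add(tuple(sorted(seq.codes[i] for i in positions)))

    mods = list(db.modifications.values())
    caps = []
    for mod in mods:
        c = licensed_count(seq, mod)
        caps.append(cap if c is None else min(c, cap))
    mod_sets = []
    for counts in itertools.product(*(range(c + 1) for c in caps)):
        if sum(counts) <= cap:
            names = []
            for mod, k in zip(mods, counts):
                names.extend([mod.name] * k)
            mod_sets.append(tuple(sorted(names)))
    mod_mass = {
        m.name: fmass(m.gain) - fmass(m.loss) for m in mods
    }

    out = []
    for mz in peaks:
        matches = []
        for dels in del_sets:
            dm = sum(res_mass[c] for c in dels)
            for ms in mod_sets:
                mm = sum(mod_mass[name] for name in ms)
                calc = base - dm + mm
                if abs(calc - mz) <= tol:
                    matches.append((dels, ms, max(len(dels), len(ms))))
        if not matches:
            out.append((None, set()))
            continue
        # the engine's first pass is iteration 1 and includes null entries
        n_assign = max(1, min(m[2] for m in matches))
        chosen = {
            (dels, ms)
            for dels, ms, _ in matches
            if len(dels) <= n_assign and len(ms) <= n_assign
        }
        out.append((n_assign, chosen))
    return out


class TestEnumerateDeletions:
    def test_single_deletions_distinct_codes(self, db):
        seq = parse_peptide("AAG", db=db)
        assert set(enumerate_deletions(seq, 1)) == {(), ("A",), ("G",)}

    def test_double_deletions(self, db):
        seq = parse_peptide("AAG", db=db)
        assert set(enumerate_deletions(seq, 2)) == {
            (),
            ("A",),
            ("G",),
            ("A", "A"),
            ("A", "G"),
        }

    def test_zero_gives_null_only(self, db):
        assert list(enumerate_deletions(parse_peptide("AAG", db=db), 0)) == [()]

    def test_multiplicity_bounded_by_composition(self, db, rng):
        for _ in range(20):
            seq = random_sequence(rng, length=rng.randint(1, 8), db=db)
            comp = seq.composition()
            for dels in enumerate_deletions(seq, 3):
                for code in set(dels):
                    assert dels.count(code) <= comp[code]


class TestEnumerateModifications:
    def test_pbf_requires_arg(self, db):
        seq = parse_peptide("GAG", db=db)
        mods = [db.modifications["Pbf"]]
        assert list(enumerate_modifications(seq, 2, mods)) == [()]

    def test_single_arg_licenses_single_pbf(self, db):
        seq = parse_peptide("GRG", db=db)
        mods = [db.modifications["Pbf"]]
        assert set(enumerate_modifications(seq, 2, mods)) == {(), ("Pbf",)}

    def test_metal_unbounded_within_n(self, db):
        seq = parse_peptide("GAG", db=db)
        mods = [db.modifications["Na"]]
        assert set(enumerate_modifications(seq, 1, mods)) == {(), ("Na",)}
        assert set(enumerate_modifications(seq, 2, mods)) == {(), ("Na",), ("Na", "Na")}

    def test_boc_counts_free_n_terminus(self, db):
        free = parse_peptide("GAG", "unmodified", "acid", db=db)
        capped = parse_peptide("GAG", "acetyl", "acid", db=db)
        assert licensed_count(free, db.modifications["Boc"]) == 1
        assert licensed_count(capped, db.modifications["Boc"]) == 0


class TestCandidateMass:
    def test_identity(self, db):
        from pepkit import molecular_weight

        seq = parse_peptide("GAG", db=db)
        assert candidate_mass(seq) == pytest.approx(molecular_weight(seq))
        assert candidate_mass(seq) == pytest.approx(203.0906, abs=1e-4)

    def test_single_deletion(self, db):
        seq = parse_peptide("GAG", db=db)
        assert candidate_mass(seq, ["A"]) == pytest.approx(132.0535, abs=1e-4)

    def test_sodium_adduct(self, db):
        seq = parse_peptide("GAG", db=db)
        delta = candidate_mass(seq, [], ["Na"]) - candidate_mass(seq)
        assert delta == pytest.approx(21.9819, abs=1e-4)

    def test_overdeletion_errors(self, db):
        seq = parse_peptide("GAG", db=db)
        with pytest.raises(PepkitError):
            candidate_mass(seq, ["A", "A"])


class TestIterationCap:
    @pytest.mark.parametrize(
        "length,cap", [(1, 5), (30, 5), (31, 4), (60, 4), (61, 3), (150, 3)]
    )
    def test_caps(self, length, cap):
        assert iteration_cap(length) == cap

    def test_over_maximum_rejected(self):
        with pytest.raises(PepkitError):
            iteration_cap(151)


class TestAssignPeaks:
    def test_full_sequence_match(self, db):
        report = assign_peaks(parse_peptide("GAG", db=db), [203.1])
        pa = report.assignments[0]
        assert pa.iteration == 1
        top = pa.candidates[0]
        assert top.deletions == () and top.modifications == ()
        assert top.delta == pytest.approx(0.0094, abs=1e-3)

    def test_single_deletion_match(self, db):
        report = assign_peaks(parse_peptide("GAG", db=db), [132.05])
        cands = report.assignments[0].candidates
        assert [(c.deletions, c.modifications) for c in cands] == [(("A",), ())]
        assert cands[0].calculated_mass == pytest.approx(132.0535, abs=1e-4)

    def test_unassignable_peak(self, db):
        report = assign_peaks(parse_peptide("GAG", db=db), [500.0])
        pa = report.assignments[0]
        assert not pa.assigned and pa.candidates == []

    def test_nonpositive_mz_rejected(self, db):
        with pytest.raises(InvalidPeakError):
            assign_peaks(parse_peptide("GAG", db=db), [-5.0])

    def test_empty_peak_list_rejected(self, db):
        with pytest.raises(InvalidPeakError):
            assign_peaks(parse_peptide("GAG", db=db), [])

    def test_budget_guardrail(self, db):
        seq = parse_peptide("ACDEFGHIKL", db=db)
        config = AssignmentConfig(candidate_budget=10)
        with pytest.raises(CandidateBudgetExceededError):
            assign_peaks(seq, [500.0], config)

    def test_candidate_invariants(self, db, rng):
        for _ in range(20):
            seq = random_sequence(rng, length=rng.randint(3, 8), db=db)
            from pepkit import molecular_weight

            mw = molecular_weight(seq)
            peaks = [max(1.0, mw - rng.uniform(0, 250)) for _ in range(3)]
            report = assign_peaks(seq, peaks)
            comp = seq.composition()
            for pa in report.assignments:
                for c in pa.candidates:
                    assert c.delta <= report.config.tolerance
                    for code in set(c.deletions):
                        assert c.deletions.count(code) <= comp[code]
                    for name in set(c.modifications):
                        cap = licensed_count(seq, db.modifications[name])
                        if cap is not None:
                            assert c.modifications.count(name) <= cap

    def test_matches_flat_oracle(self, db, rng, rdkit_masses):
        for _ in range(25):
            seq = random_sequence(rng, length=rng.randint(2, 8), db=db)
            records = generate_fixture(
                rng.randint(0, 10**6), n_spectra=1, length_range=(4, 8), db=db
            )
            peaks = [p.mz for p in records[0].peaks][:2]
            peaks += [candidate_mass(seq, db=db) - rng.uniform(0, 200) for _ in range(2)]
            peaks = [p for p in peaks if p > 0] or [100.0]
            cap = iteration_cap(len(seq))
            expected = oracle_assignment(seq, peaks, db, cap, element_masses=rdkit_masses)
            report = assign_peaks(seq, peaks, db=db)
            for pa, (n_exp, set_exp) in zip(report.assignments, expected):
                assert pa.iteration == n_exp
                got = {(c.deletions, c.modifications) for c in pa.candidates}
                assert got == set_exp

    def test_iteration_monotonicity(self, db, rng):
        for _ in range(10):
            seq = random_sequence(rng, length=rng.randint(3, 8), db=db)
            records = generate_fixture(rng.randint(0, 10**6), n_spectra=1, db=db)
            peaks = [p.mz for p in records[0].peaks]
            assigned_prev: set[int] = set()
            for cap in (1, 2, 3):
                config = AssignmentConfig(length_caps=((150, cap),))
                report = assign_peaks(seq, peaks, config, db=db)
                assigned = {i for i, pa in enumerate(report.assignments) if pa.assigned}
                assert assigned_prev <= assigned
                assigned_prev = assigned

    def test_ground_truth_recovery(self, db):
        records = generate_fixture(42, n_spectra=30, length_range=(5, 12), db=db)
        for record in records:
            seq = record.parsed(db)
            report = assign_peaks(seq, [p.mz for p in record.peaks], db=db)
            for peak, pa in zip(record.peaks, report.assignments):
                found = {(c.deletions, c.modifications) for c in pa.candidates}
                assert (peak.deletions, peak.modifications) in found

    def test_candidate_ordering(self, db):
        seq = parse_peptide("GAG", db=db)
        report = assign_peaks(seq, [203.1])
        cands = report.assignments[0].candidates
        keys = [(c.n_changes, c.delta) for c in cands]
        assert keys == sorted(keys)
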