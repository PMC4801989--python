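import numpy as np
import pytest

from pepkit import (
    charge_summary,
    default_pka,
    extinction_280,
    isoelectric_point,
    molecular_formula,
    molecular_weight,
    net_charge,
    parse_formula,
    parse_peptide,
    parse_peptoid,
)
from pepkit.errors import IsoelectricPointUndefinedError, UnsupportedOperationError
from pepkit.fixtures import random_sequence
from pepkit.properties import ACIDIC, BASIC, PKaSet, charge_at, charge_curve, ionizable_groups


def grid_scan_pi(groups, step=1e-4):
    """Independent oracle: locate the sign change of the charge on a pH grid."""
    phs = np.arange(0.0, 14.0 + step, step)
    charge = np.zeros_like(phs)
    for pka, sign in groups:
        if sign == ACIDIC:
            charge += -1.0 / (1.0 + 10.0 ** (pka - phs))
        else:
            charge += 1.0 / (1.0 + 10.0 ** (phs - pka))
    below = np.nonzero(charge < 0)[0]
    if len(below) == 0 or below[0] == 0:
        return None
    i = below[0]
    return 0.5 * (phs[i - 1] + phs[i])


class TestMolecularFormula:
    def test_gly_free_peptide(self):
        assert molecular_formula(parse_peptide("G")).hill() == "C2H5NO2"

    def test_digly(self):
        assert molecular_formula(parse_peptide("GG")).hill() == "C4H8N2O3"

    def test_additivity_of_one_gly(self):
        a = molecular_formula(parse_peptide("ACDG"))
        b = molecular_formula(parse_peptide("ACD"))
        assert a - b == parse_formula("C2H3NO")

    def test_weights(self):
        assert molecular_weight(parse_peptide("G")) == pytest.approx(75.0320, abs=1e-4)
        assert molecular_weight(parse_peptide("GG")) == pytest.approx(132.0535, abs=1e-4)

    def test_concatenation_law(self, db, rng):
        water = parse_formula("H2O").mass(db.masses)
        for _ in range(20):
            a = random_sequence(rng, length=rng.randint(1, 10), db=db)
            b = random_sequence(rng, length=rng.randint(1, 10), db=db)
            ab = parse_peptide("".join(a.codes) + "".join(b.codes), db=db)
            assert molecular_weight(ab) == pytest.approx(
                molecular_weight(a) + molecular_weight(b) - water, abs=1e-9
            )

    def test_peptoid_weight(self, db):
        seq = parse_peptoid("Nme", db=db)
        # sarcosine free: C3H7NO2
        assert molecular_formula(seq).hill() == "C3H7NO2"


class TestExtinction:
    def test_single_trp(self):
        ext = extinction_280(parse_peptide("GWG"))
        assert ext.epsilon_oxidized == ext.epsilon_reduced == 5500

    def test_no_chromophores(self):
        ext = extinction_280(parse_peptide("GAGA"))
        assert ext.epsilon_oxidized == ext.epsilon_reduced == 0

    def test_mixed(self):
        ext = extinction_280(parse_peptide("WWYYYCC"))
        assert ext.epsilon_oxidized == 15595
        assert ext.epsilon_reduced == 15470

    def test_invariant_on_random_sequences(self, db, rng):
        for _ in range(300):
            seq = random_sequence(rng, length=rng.randint(1, 30), db=db)
            ext = extinction_280(seq)
            n_cys = sum(1 for c in seq.codes if c == "C")
            assert ext.epsilon_oxidized - ext.epsilon_reduced == 125 * (n_cys // 2)
            assert ext.epsilon_reduced <= ext.epsilon_oxidized

    def test_peptoid_rejected(self, db):
        with pytest.raises(UnsupportedOperationError):
            extinction_280(parse_peptoid("Nme-Npe", db=db))


class TestChargeSummary:
    def test_dkg(self):
        s = charge_summary(parse_peptide("DKG"))
        assert (s.n_acidic, s.n_basic, s.n_other) == (1, 1, 1)

    def test_all_other(self):
        s = charge_summary(parse_peptide("GGGG"))
        assert (s.n_acidic, s.n_basic, s.n_other) == (0, 0, 4)
        assert s.fractions == (0.0, 0.0, 1.0)

    def test_nonstandard_counts_as_other(self):
        s = charge_summary(parse_peptide("AC(pS)G"))
        # Cys is acidic (it carries a pKa term); pS is Other
        assert s.n_acidic == 1
        assert s.n_other == 3

    def test_fractions_sum_to_one(self, db, rng):
        for _ in range(100):
            s = charge_summary(random_sequence(rng, length=rng.randint(1, 40), db=db))
            assert sum(s.fractions) == pytest.approx(1.0, abs=1e-9)
            assert s.total == s.n_acidic + s.n_basic + s.n_other


class TestNetCharge:
    def test_single_acid_at_its_pka(self):
        assert charge_at([(4.0, ACIDIC)], 4.0) == pytest.approx(-0.5)

    def test_single_base_at_its_pka(self):
        assert charge_at([(10.0, BASIC)], 10.0) == pytest.approx(0.5)

    def test_symmetric_pair_neutral_at_midpoint(self):
        groups = [(4.0, ACIDIC), (10.0, BASIC)]
        assert abs(charge_at(groups, 7.0)) < 2.1e-3

    def test_terminal_groups_only_when_free(self, db):
        free = parse_peptide("GGG", "unmodified", "acid", db=db)
        capped = parse_peptide("GGG", "acetyl", "amide", db=db)
        assert len(ionizable_groups(free)) == 2
        assert len(ionizable_groups(capped)) == 0

    def test_monotone_decreasing_in_ph(self, db, rng):
        for _ in range(50):
            seq = random_sequence(rng, length=rng.randint(1, 25), db=db)
            values = [net_charge(seq, ph) for ph in np.arange(0, 14.01, 0.5)]
            assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_bounds(self, db, rng):
        for _ in range(50):
            seq = random_sequence(rng, length=rng.randint(1, 25), db=db)
            groups = ionizable_groups(seq)
            n_acid = sum(1 for _, s in groups if s == ACIDIC)
            n_base = sum(1 for _, s in groups if s == BASIC)
            for ph in (0.0, 7.0, 14.0):
                c = net_charge(seq, ph)
                assert -n_acid - 1e-9 <= c <= n_base + 1e-9


class TestIsoelectricPoint:
    def test_symmetric_pair(self):
        assert grid_scan_pi([(4.0, ACIDIC), (10.0, BASIC)]) == pytest.approx(7.0, abs=1e-3)
        seq = parse_peptide("GG")  # termini only; not symmetric, just sanity below
        isoelectric_point(seq)

    def test_no_groups_undefined(self, db):
        capped = parse_peptide("GGG", "acetyl", "amide", db=db)
        with pytest.raises(IsoelectricPointUndefinedError):
            isoelectric_point(capped)

    def test_acid_only_undefined(self, db):
        seq = parse_peptide("DDD", "acetyl", "amide", db=db)
        with pytest.raises(IsoelectricPointUndefinedError):
            isoelectric_point(seq)

    def test_matches_grid_scan_on_random_sequences(self, db, rng):
        for _ in range(100):
            seq = random_sequence(rng, length=rng.randint(1, 20), db=db)
            expected = grid_scan_pi(ionizable_groups(seq))
            assert expected is not None  # free termini guarantee a root
            assert isoelectric_point(seq) == pytest.approx(expected, abs=1e-3)

    def test_peptoid_rejected(self, db):
        with pytest.raises(UnsupportedOperationError):
            isoelectric_point(parse_peptoid("Nme-Nce", db=db))


class TestPKaSet:
    def test_default_loads(self):
        pka = default_pka()
        assert len(pka) == 9
        assert pka["R"][1] == BASIC
        assert pka["D"][1] == ACIDIC

    def test_wrong_groups_rejected(self):
        with pytest.raises(ValueError):
            PKaSet({"D": (3.9, ACIDIC)})

    def test_curve_export_shape(self, db):
        curve = charge_curve(parse_peptide("DKG", db=db), step=0.1)
        assert len(curve) == 141
        assert curve[0][0] == 0.0 and curve[-1][0] == pytest.approx(14.0)
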