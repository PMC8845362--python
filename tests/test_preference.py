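import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats

from pocketmotion.preference import test_frequency_difference as two_proportion_pvalue
from pocketmotion import (
    FrequencyTable,
    classify_philic_phobic,
    motion_frequency_by_residue,
    mue,
    mue_profile,
    preference_table,
    residue_frequencies,
)
from pocketmotion import synthetic as syn
from pocketmotion.preference import POCKETPHILIC, POCKETPHOBIC
from pocketmotion.structures import AA_ORDER


def _table(counts, context="overall"):
    return FrequencyTable(counts=counts, context=context)


# ------------------------------------------------------------------ counting


def test_overall_frequency_counts_each_occurrence():
    s = syn.make_binding_site_structure(
        shells=[(2.5, ["ARG", "ARG", "ALA", "GLY"]), (4.5, ["LEU"] * 6)], seed=0
    )
    table = residue_frequencies([s])
    assert table.n_total == 10
    assert table.freqs["ARG"] == pytest.approx(0.2)
    assert table.freqs["LEU"] == pytest.approx(0.6)


def test_pocket_frequency_counts_only_residues_within_cutoff():
    s = syn.make_binding_site_structure(
        shells=[(2.5, ["ARG", "ARG", "ALA", "GLY"]), (5.5, ["LEU"] * 6)], seed=0
    )
    table = residue_frequencies([s], pocket_cutoff=5.0)
    assert table.n_total == 4
    assert table.freqs["ARG"] == pytest.approx(0.5)


def test_pocket_context_requires_holo():
    s = syn.make_binding_site_structure(shells=[(2.5, ["ALA"] * 40)], seed=0)
    s.ligands = []
    with pytest.raises(ValueError):
        residue_frequencies([s], pocket_cutoff=5.0)
    with pytest.raises(ValueError):
        residue_frequencies([])


def test_degenerate_cutoff_gives_empty_table():
    s = syn.make_binding_site_structure(shells=[(2.5, ["ALA"] * 40)], seed=0)
    table = residue_frequencies([s], pocket_cutoff=0.0)
    assert table.n_total == 0
    assert sum(table.freqs.values()) == 0.0


def test_frequencies_sum_to_one():
    structs, _ = syn.make_composition_corpus(n_structures=3, seed=5)
    for cutoff in (None, 3.0, 5.0):
        table = residue_frequencies(structs, pocket_cutoff=cutoff)
        assert sum(table.freqs.values()) == pytest.approx(1.0, abs=1e-12)


def test_tables_match_generator_bookkeeping_exactly():
    structs, counts = syn.make_composition_corpus(n_structures=4, seed=11)
    assert residue_frequencies(structs).counts == counts["overall"]
    for c in (2.0, 3.0, 4.0, 5.0, 6.0):
        assert residue_frequencies(structs, pocket_cutoff=c).counts == counts[f"{c:.1f}"]


# ------------------------------------------------------------------ MUE


def test_mue_of_identical_tables_is_zero():
    t = _table({aa: 5 for aa in AA_ORDER})
    assert mue(t, t) == 0.0


def test_mue_of_constructed_mass_shift():
    # moving 0.1 probability mass from Ala to Arg changes two coordinates by
    # 0.1 each: MUE = (0.1 + 0.1)/20 = 0.01
    a = _table({"ALA": 5, "ARG": 5})
    b = _table({"ALA": 4, "ARG": 6})
    assert mue(a, b) == pytest.approx(0.01)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(st.integers(min_value=0, max_value=500), min_size=20, max_size=20),
    st.lists(st.integers(min_value=0, max_value=500), min_size=20, max_size=20),
    st.lists(st.integers(min_value=0, max_value=500), min_size=20, max_size=20),
)
def test_mue_symmetry_and_triangle_inequality(ca, cb, cc):
    assume(sum(ca) > 0 and sum(cb) > 0 and sum(cc) > 0)
    ta, tb, tc = (_table(dict(zip(AA_ORDER, c))) for c in (ca, cb, cc))
    assert mue(ta, tb) == pytest.approx(mue(tb, ta))
    assert mue(ta, tc) <= mue(ta, tb) + mue(tb, tc) + 1e-12


def test_mue_profile_peaks_at_three_angstrom_by_construction():
    structs, _ = syn.make_composition_corpus(n_structures=6, seed=2)
    overall = residue_frequencies(structs)
    pockets = {
        c: residue_frequencies(structs, pocket_cutoff=c) for c in (2.0, 3.0, 4.0, 5.0, 6.0)
    }
    profile = mue_profile(overall, pockets)
    assert max(profile, key=profile.get) == 3.0


# ------------------------------------------------------------------ significance test


def test_identical_counts_give_p_one():
    t = _table({aa: 5 for aa in AA_ORDER})
    assert two_proportion_pvalue("ALA", t, t) == pytest.approx(1.0)
    a = _table({"ALA": 50, "ARG": 50})
    b = _table({"ALA": 50, "ARG": 50})
    assert two_proportion_pvalue("ALA", a, b) == pytest.approx(1.0)


def test_z_test_matches_chi_square_oracle():
    overall = _table({"ALA": 10, "ARG": 90})
    pocket = _table({"ALA": 30, "ARG": 70}, context="pocket(3 A)")
    p = two_proportion_pvalue("ALA", overall, pocket)
    chi2, p_ref, _dof, _exp = stats.chi2_contingency(
        [[30, 70], [10, 90]], correction=False
    )
    assert p == pytest.approx(p_ref, abs=1e-6)


def test_zero_counts_in_both_tables_warn_and_return_one():
    a = _table({"ALA": 10})
    b = _table({"ALA": 20})
    with pytest.warns(UserWarning):
        assert two_proportion_pvalue("TRP", a, b) == 1.0


def test_null_calibration_rejects_at_nominal_rate():
    rng = np.random.default_rng(123)
    n_rep = 2000
    rejections = 0
    for _ in range(n_rep):
        overall, pocket = syn.sample_null_tables(rng)
        rejections += two_proportion_pvalue("LEU", overall, pocket) < 0.05
    rate = rejections / n_rep
    half_width = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rate - 0.05) <= half_width


# ------------------------------------------------------------------ labels


def test_philic_phobic_partition_is_exhaustive():
    structs, _ = syn.make_composition_corpus(n_structures=4, seed=7)
    table = preference_table(
        residue_frequencies(structs),
        residue_frequencies(structs, pocket_cutoff=3.0),
        residue_frequencies(structs, pocket_cutoff=5.0),
    )
    assert len(table) == 20
    assert set(table["label"]) <= {POCKETPHILIC, POCKETPHOBIC}


@pytest.mark.parametrize(
    "fo,f3,f5,expected",
    [
        (0.05, 0.08, 0.06, POCKETPHILIC),   # enriched at 3 A
        (0.05, 0.03, 0.02, POCKETPHOBIC),   # depleted at both
        (0.05, 0.03, 0.07, POCKETPHILIC),   # long-range interactor
        (0.05, 0.08, 0.03, POCKETPHILIC),   # short-range interactor
    ],
)
def test_philic_phobic_rules_and_reversal(fo, f3, f5, expected):
    assert classify_philic_phobic(fo, f3, f5) == expected
    # reversing the frequency relations flips the label when both flip below
    flipped = classify_philic_phobic(fo, 2 * fo - f3, 2 * fo - f5)
    if expected == POCKETPHOBIC:
        assert flipped == POCKETPHILIC


# ------------------------------------------------------------------ motion frequency


def test_motion_frequency_counts_moving_fraction_per_residue_type(classified_suite):
    records = [ana.record for _p, _t, ana in classified_suite]
    freq = motion_frequency_by_residue(records)
    # in the fixture suite exactly the designed gate residues move
    moving_types = {aa for r in records for _id, aa, rmsd in r.moving_residues}
    for aa in AA_ORDER:
        if aa not in moving_types:
            assert freq[aa] == 0.0
    assert any(v > 0 for v in freq.values())


def test_motion_frequency_share_normalization_sums_to_one(classified_suite):
    records = [ana.record for _p, _t, ana in classified_suite]
    share = motion_frequency_by_residue(records, normalize="all_moving")
    assert sum(share.values()) == pytest.approx(1.0)


def test_motion_frequency_empty_records_all_zero():
    assert set(motion_frequency_by_residue([]).values()) == {0.0}
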