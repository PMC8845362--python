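import itertools

import numpy as np
import pytest

from pocketmotion import (
    MotionRecord,
    analyze_pair,
    classify_overall,
    kabsch_superpose,
    select_typical_pair,
    summarize_corpus,
)
from pocketmotion import synthetic as syn
from pocketmotion.motion import POCKET_CLASSES, ClassificationError, classify_pocket_motion
from pocketmotion.structures import APO_APO, APO_HOLO
from pocketmotion.superpose import ProfileEntry, ResidueRMSDProfile


def _record(pair_id, overall=1.0, pocket_max=None, pocket_class=None, category=APO_APO):
    return MotionRecord(
        pair_id=pair_id,
        category=category,
        overall_rmsd=overall,
        motionless=overall < 2.0,
        pocket_max_rmsd=pocket_max,
        pocket_class=pocket_class,
    )


# ------------------------------------------------------------------- overall


@pytest.mark.parametrize(
    "target,expect_motionless", [(1.2, True), (1.99, True), (2.01, False), (3.2, False)]
)
def test_overall_motionless_threshold(target, expect_motionless):
    pair, truth = syn.make_overall_pair(APO_APO, target_rmsd=target, seed=21)
    sup = kabsch_superpose(pair)
    assert sup.overall_rmsd == pytest.approx(truth.overall_rmsd, abs=1e-6)
    motionless, category = classify_overall(pair, sup)
    assert motionless is expect_motionless
    assert category == APO_APO


def test_boundary_exactly_two_angstrom_counts_as_motion():
    pair, _ = syn.make_overall_pair(APO_APO, target_rmsd=2.0, seed=22)
    sup = kabsch_superpose(pair)
    motionless, _ = classify_overall(pair, sup, threshold=sup.overall_rmsd)
    assert motionless is False


def test_raising_threshold_never_unfreezes_a_pair():
    pair, _ = syn.make_overall_pair(APO_APO, target_rmsd=2.4, seed=23)
    sup = kabsch_superpose(pair)
    flags = [classify_overall(pair, sup, threshold=t)[0] for t in (1.0, 2.0, 2.5, 3.0, 5.0)]
    # once motionless at some threshold, motionless at every larger one
    assert flags == sorted(flags)


# ------------------------------------------------------------------- pocket classes


def test_fixture_suite_recovers_designed_classes(classified_suite):
    for _pair, truth, ana in classified_suite:
        assert ana.record.pocket_class == truth.pocket_class, truth.pair_id


def test_every_moving_pocket_gets_exactly_one_class(classified_suite):
    for _pair, truth, ana in classified_suite:
        r = ana.record
        if r.pocket_max_rmsd is not None and r.pocket_max_rmsd > 2.0:
            assert r.pocket_class in POCKET_CLASSES
        else:
            assert r.pocket_class is None


def test_still_pocket_is_unclassified():
    profile = ResidueRMSDProfile(
        entries=[ProfileEntry("A:1", "ALA", "A", 1, rmsd=0.4, n_atoms=5)]
    )
    assert classify_pocket_motion(profile, None, None) is None


def test_missing_models_with_moving_pocket_raise():
    profile = ResidueRMSDProfile(
        entries=[ProfileEntry("A:1", "ALA", "A", 1, rmsd=3.4, n_atoms=5)]
    )
    with pytest.raises(ClassificationError):
        classify_pocket_motion(profile, None, None)


def test_side_chain_flip_with_stable_volume_is_other_motion():
    """A flipped side chain that leaves volume and topology alone is OM."""
    pair, truth = syn.make_pocket_pair("OM", seed=17)
    ana = analyze_pair(pair)
    assert truth.pocket_class == "OM"
    assert ana.record.pocket_class == "OM"
    rel = abs(ana.record.vol_holo - ana.record.vol_apo) / ana.record.vol_apo
    assert rel < 0.25


# ------------------------------------------------------------------- typical pair


def test_typical_pair_takes_largest_pocket_rmsd():
    records = [
        _record("p1", pocket_max=2.2, pocket_class="PE"),
        _record("p2", pocket_max=4.1, pocket_class="PE"),
        _record("p3", pocket_max=3.0, pocket_class="PE"),
    ]
    assert select_typical_pair(records).pair_id == "p2"


def test_typical_pair_overall_motion_and_singleton():
    records = [_record("a", overall=2.5), _record("b", overall=3.5)]
    assert select_typical_pair(records).pair_id == "b"
    assert select_typical_pair([records[0]]).pair_id == "a"


def test_typical_pair_tie_breaks_lexicographically_and_order_invariant():
    records = [
        _record("zz", pocket_max=3.0, pocket_class="PS"),
        _record("aa", pocket_max=3.0, pocket_class="PS"),
        _record("mm", pocket_max=3.0, pocket_class="PS"),
    ]
    for perm in itertools.permutations(records):
        assert select_typical_pair(list(perm)).pair_id == "aa"


def test_typical_pair_empty_group_raises():
    with pytest.raises(ValueError):
        select_typical_pair([])


# ------------------------------------------------------------------- summary


def test_summary_counts_and_proportions():
    records = [_record(f"p{i}", overall=1.0) for i in range(9)] + [_record("p9", overall=3.0)]
    df = summarize_corpus(records)
    row = df.loc[APO_APO]
    assert row["n"] == 10
    assert row["prop_motionless"] == pytest.approx(0.9)
    assert row["overall_rmsd_mean"] == pytest.approx(1.2)
    assert row["overall_rmsd_max"] == pytest.approx(3.0)


def test_summary_of_empty_corpus_is_empty():
    assert summarize_corpus([]).empty


def test_summary_mean_max_arithmetic():
    records = [
        _record("a", overall=1.0, category=APO_HOLO),
        _record("b", overall=3.0, category=APO_HOLO),
    ]
    row = summarize_corpus(records).loc[APO_HOLO]
    assert row["overall_rmsd_mean"] == pytest.approx(2.0)
    assert row["overall_rmsd_max"] == pytest.approx(3.0)


def test_records_roundtrip_to_tsv(tmp_path, classified_suite):
    from pocketmotion.motion import records_to_frame, write_records_tsv

    records = [ana.record for _p, _t, ana in classified_suite]
    df = records_to_frame(records)
    assert set(df["pocket_class"]) <= set(POCKET_CLASSES) | {"none"}
    out = tmp_path / "records.tsv"
    write_records_tsv(records, out)
    assert out.read_text().count("\n") == len(records) + 1
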