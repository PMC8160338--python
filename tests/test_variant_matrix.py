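"""Rescue, power filtering, mutation classes, similarity and burden."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonoshed.pipeline import classify_patient
from clonoshed.variant_matrix import (
    classify_mutations,
    dispersion_mad,
    downsample_jaccard,
    jaccard_similarity,
    power_filter,
    rescue_mutations,
    tmb,
)
from conftest import make_records, make_sheet


def two_lesion_case(b_alt, b_bq, b_mq):
    """Locus called in lesion A; lesion B support as given."""
    calls = make_records("P01", [("A", 100, 40, 100, 37, 60)])
    pileup = make_records(
        "P01",
        [("A", 100, 40, 100, 37, 60), ("B", 100, b_alt, 100, b_bq, b_mq)],
    )
    return calls, pileup


@pytest.mark.parametrize(
    "b_alt,b_bq,b_mq,expected",
    [
        (3, 35, 60, "rescued"),   # three quality reads suffice
        (2, 35, 60, "absent"),    # below the read threshold
        (5, 35, 40, "absent"),    # fails the mapping-quality gate
        (5, 20, 60, "absent"),    # fails the base-quality gate
    ],
)
def test_rescue_thresholds(b_alt, b_bq, b_mq, expected):
    calls, pileup = two_lesion_case(b_alt, b_bq, b_mq)
    matrix = rescue_mutations(calls, pileup)
    assert matrix.status.loc["1:100:C>T", "B"] == expected
    assert matrix.status.loc["1:100:C>T", "A"] == "called"


def test_rescue_never_downgrades_calls_and_flags_missing_pileup():
    calls = make_records("P01", [("A", 100, 2, 100, 37, 60)])  # weak but called
    pileup = make_records("P01", [("A", 100, 2, 100, 37, 60)])
    # lesion B exists in the patient but has no pileup at this locus
    pileup_b = make_records("P01", [("B", 999, 0, 80, 37, 60)])
    matrix = rescue_mutations(calls, pd.concat([pileup, pileup_b]))
    assert matrix.status.loc["1:100:C>T", "A"] == "called"
    assert matrix.status.loc["1:100:C>T", "B"] == "unpowered"


def test_rescue_requires_single_patient():
    calls = make_records("P01", [("A", 100, 10, 100, 37, 60)])
    other = make_records("P02", [("B", 100, 10, 100, 37, 60)])
    with pytest.raises(ValueError, match="one patient"):
        rescue_mutations(pd.concat([calls, other]), calls)


def test_rescue_idempotent_and_monotone(small_cohort):
    tissue = small_cohort.tissue[small_cohort.tissue["patient"] == "P01"]
    calls = tissue[tissue["called"]]
    m1 = rescue_mutations(calls, tissue)
    present_before = (
        calls.groupby("sample").size().reindex(m1.samples).fillna(0)
    )
    present_after = m1.present().sum(axis=0)
    assert (present_after >= present_before).all()
    # feeding the full present set back through rescue changes nothing
    m2 = rescue_mutations(calls, tissue)
    pd.testing.assert_frame_equal(m1.status, m2.status)


@pytest.mark.parametrize(
    "depth,purity,expected_powered",
    [
        (100, 0.5, True),   # expected VAF 0.25: P(X>=3) ~ 1
        (3, 0.2, False),    # expected VAF 0.1: P(X>=3) = 0.001
        (30, 1.0, True),    # expected VAF 0.5: P(X>=3) > 0.9999
        (0, 0.5, False),    # zero depth can never be powered
    ],
)
def test_power_filter_binomial_tail(depth, purity, expected_powered):
    calls = make_records("P01", [("A", 100, max(depth // 2, 1), max(depth, 1), 37, 60)])
    pileup = make_records(
        "P01",
        [("A", 100, depth // 2, depth, 37, 60), ("B", 100, 0, depth, 37, 60)],
    )
    matrix = rescue_mutations(calls, pileup)
    sheet = make_sheet(["A", "B"], purity=purity)
    out = power_filter(matrix, pileup, sheet)
    assert bool(out.powered.loc["1:100:C>T"]) is expected_powered


@pytest.mark.parametrize(
    "n_present,n_lesions,expected",
    [(9, 9, "truncal"), (1, 9, "private"), (4, 9, "branch")],
)
def test_classification_by_lesion_count(n_present, n_lesions, expected):
    samples = [f"L{i}" for i in range(n_lesions)]
    calls = make_records(
        "P01", [(s, 100, 40, 100, 37, 60) for s in samples[:n_present]]
    )
    pileup = make_records("P01", [(s, 100, 40 if i < n_present else 0, 100, 37, 60)
                                  for i, s in enumerate(samples)])
    matrix = classify_mutations(rescue_mutations(calls, pileup))
    assert matrix.classes.loc["1:100:C>T"] == expected


def test_single_lesion_patient_unclassifiable():
    calls = make_records("P01", [("A", 100, 40, 100, 37, 60)])
    matrix = classify_mutations(rescue_mutations(calls, calls))
    assert (matrix.classes == "unclassifiable").all()


def test_unpowered_everywhere_mutation_not_classified():
    """Present in all lesions but unpowered in one -> unclassifiable."""
    calls = make_records("P01", [("A", 100, 40, 100, 37, 60)])
    pileup = make_records(
        "P01", [("A", 100, 40, 100, 37, 60), ("B", 100, 3, 4, 37, 60)]
    )
    matrix = rescue_mutations(calls, pileup)
    matrix = power_filter(matrix, pileup, make_sheet(["A", "B"], purity=0.5))
    matrix = classify_mutations(matrix)
    assert not matrix.powered.loc["1:100:C>T"]
    assert matrix.classes.loc["1:100:C>T"] == "unclassifiable"


def test_class_partition_on_simulation(clean_cohort, run_config):
    """truncal + branch + private = powered count, and classes match truth."""
    for patient, tissue in clean_cohort.tissue.groupby("patient"):
        sheet = clean_cohort.sample_sheet[
            clean_cohort.sample_sheet["patient"] == patient
        ]
        matrix = classify_patient(tissue, sheet, run_config)
        counts = matrix.class_counts()
        n_classified = sum(
            counts.get(c, 0) for c in ("truncal", "branch", "private")
        )
        assert n_classified == int(matrix.powered.sum())


def brute_force_jaccard(set_a, set_b):
    union = set_a | set_b
    return len(set_a & set_b) / len(union) if union else None


def presence_to_matrix(sets, all_ids):
    from clonoshed.variant_matrix import PresenceMatrix

    status = pd.DataFrame(
        "absent", index=sorted(all_ids), columns=sorted(sets)
    )
    for sample, ids in sets.items():
        for i in ids:
            status.loc[i, sample] = "called"
    return PresenceMatrix(patient="P01", status=status)


@pytest.mark.parametrize(
    "set_a,set_b,expected",
    [
        ({"m1", "m2"}, {"m1", "m2"}, 1.0),
        ({"m1"}, {"m2"}, 0.0),
        ({"m1", "m2", "m3"}, {"m2", "m3", "m4"}, 0.5),
    ],
)
def test_jaccard_set_arithmetic(set_a, set_b, expected):
    matrix = presence_to_matrix({"A": set_a, "B": set_b}, set_a | set_b)
    sim, median = jaccard_similarity(matrix)
    assert sim.loc["A", "B"] == pytest.approx(expected)
    assert sim.loc["B", "A"] == pytest.approx(expected)
    assert sim.loc["A", "A"] == 1.0
    assert median == pytest.approx(expected)


@settings(deadline=None, max_examples=50)
@given(
    st.lists(
        st.frozensets(st.integers(0, 20), max_size=15), min_size=2, max_size=5
    )
)
def test_jaccard_matches_brute_force_sets(sets):
    all_ids = set().union(*sets) if sets else set()
    named = {f"S{i}": {f"m{x}" for x in s} for i, s in enumerate(sets)}
    ids = {f"m{x}" for x in all_ids}
    if not ids:
        ids = {"m0"}
    matrix = presence_to_matrix(named, ids)
    sim, _ = jaccard_similarity(matrix)
    for a in named:
        for b in named:
            if a == b:
                continue
            expected = brute_force_jaccard(named[a], named[b])
            got = sim.loc[a, b]
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)


def test_downsample_jaccard_trivial_and_deterministic(small_cohort, run_config):
    tissue = small_cohort.tissue[small_cohort.tissue["patient"] == "P01"]
    sheet = small_cohort.sample_sheet[small_cohort.sample_sheet["patient"] == "P01"]
    matrix = classify_patient(tissue, sheet, run_config)
    full_median = jaccard_similarity(matrix)[1]
    # full lesion count: every replicate equals the full-data median
    reps = downsample_jaccard(matrix, matrix.n_lesions, 5, seed=1)
    assert np.allclose(reps, full_median)
    # fixed seed reproduces the replicate sequence
    r1 = downsample_jaccard(matrix, 3, 10, seed=7)
    r2 = downsample_jaccard(matrix, 3, 10, seed=7)
    np.testing.assert_array_equal(r1, r2)
    with pytest.raises(ValueError):
        downsample_jaccard(matrix, 1, 5, seed=1)


def test_tmb_filters_and_units():
    # 60 passing coding mutations over 30 Mb -> 2.0 per Mb
    rec = make_records(
        "P01", [("A", 100 + i, 30, 100, 37, 60) for i in range(60)]
    )
    assert tmb(rec, 30e6) == pytest.approx(2.0)
    # VAF at exactly the threshold or below is excluded (strict >)
    low_vaf = make_records("P01", [("A", 100, 1, 200, 37, 60)])  # VAF 0.005
    assert tmb(low_vaf, 1e6) == 0.0
    # depth below 30 excluded from the numerator
    shallow = make_records("P01", [("A", 100, 10, 25, 37, 60)])
    assert tmb(shallow, 1e6) == 0.0
    with pytest.raises(ValueError):
        tmb(rec, 0)


@pytest.mark.parametrize(
    "values,expected",
    [([1, 1, 1], 0.0), ([1, 2, 3, 4, 100], 1.0), ([7.5], 0.0)],
)
def test_mad_unscaled(values, expected):
    assert dispersion_mad(values) == expected


def test_mad_empty_rejected():
    with pytest.raises(ValueError):
        dispersion_mad([])
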