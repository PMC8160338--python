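"""cfDNA detection, power model, and detection/clonality regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonoshed.cfdna import (
    PowerModel,
    branch_vs_private_test,
    ccf_vs_lesions_model,
    detect_in_cfdna,
    detection_model,
    detection_power,
    min_detectable_ccf,
    min_detectable_reads,
)
from clonoshed.variant_matrix import PresenceMatrix, classify_mutations
from conftest import make_records


def brute_force_kstar(depth, error, fpr):
    for k in range(1, depth + 2):
        if stats.binom.sf(k - 1, depth, error) <= fpr:
            return k
    return None


def test_min_reads_at_study_parameters():
    assert min_detectable_reads(1000, PowerModel()) == 10


def test_min_reads_degenerate_bounds():
    assert min_detectable_reads(500, PowerModel(fpr=1.0)) == 1
    assert min_detectable_reads(500, PowerModel(per_base_error=1e-12)) == 1


def test_min_reads_matches_brute_force_scan():
    model_grid = [
        (d, e, f)
        for d in (50, 200, 1000, 1600)
        for e in (1e-4, 1e-3, 5e-3)
        for f in (5e-7, 1e-5, 1e-3)
    ]
    for d, e, f in model_grid:
        model = PowerModel(fpr=f, per_base_error=e)
        assert min_detectable_reads(d, model) == brute_force_kstar(d, e, f)


def test_kstar_monotonicity_over_lattice():
    """k* non-increasing in fpr, non-decreasing in error and depth."""
    depths = [200, 600, 1200]
    errors = [5e-4, 1e-3, 2e-3]
    fprs = [1e-8, 5e-7, 1e-5]
    k = {
        (d, e, f): min_detectable_reads(d, PowerModel(fpr=f, per_base_error=e))
        for d in depths for e in errors for f in fprs
    }
    for d in depths:
        for e in errors:
            ks = [k[(d, e, f)] for f in fprs]
            assert ks == sorted(ks, reverse=True)
        for f in fprs:
            ks = [k[(d, e, f)] for e in errors]
            assert ks == sorted(ks)
    for e in errors:
        for f in fprs:
            ks = [k[(d, e, f)] for d in depths]
            assert ks == sorted(ks)


def test_power_monotone_in_ccf_and_saturates():
    model = PowerModel()
    powers = [
        detection_power(c, 0.3, 1200, model) for c in np.linspace(0.01, 1, 25)
    ]
    assert all(b >= a for a, b in zip(powers, powers[1:]))
    assert detection_power(1.0, 1.0, 1000, model) == pytest.approx(1.0, abs=1e-6)


def test_min_ccf_inversion_consistency():
    model = PowerModel()
    for tf, d in [(0.3, 1200), (0.1, 1600), (0.6, 800)]:
        cmin = min_detectable_ccf(tf, d, model)
        assert detection_power(cmin, tf, d, model) >= model.power_target
        if cmin > 0.011:
            assert detection_power(cmin - 0.01, tf, d, model) < model.power_target


def test_min_ccf_nan_when_unreachable():
    assert np.isnan(min_detectable_ccf(0.001, 100, PowerModel()))


def tissue_matrix(n_lesions=4, present_in=4):
    samples = [f"L{i}" for i in range(n_lesions)]
    status = pd.DataFrame(
        [["called" if i < present_in else "absent" for i in range(n_lesions)]],
        index=["1:100:C>T"],
        columns=samples,
    )
    return classify_mutations(PresenceMatrix(patient="P01", status=status))


def plasma_df(entries):
    return make_records("P01", [("cf", pos, a, d, 37, 60) for pos, a, d in entries])


def test_plasma_rescue_at_three_reads():
    matrix = tissue_matrix()
    detected = detect_in_cfdna(matrix, plasma_df([(100, 3, 1000)]), 0.3)
    assert bool(detected.iloc[0]["detected"])
    undetected = detect_in_cfdna(matrix, plasma_df([(100, 0, 1000)]), 0.3)
    assert not bool(undetected.iloc[0]["detected"])
    below = detect_in_cfdna(matrix, plasma_df([(100, 2, 1000)]), 0.3)
    assert not bool(below.iloc[0]["detected"])


def test_plasma_only_vaf_filter():
    matrix = tissue_matrix()
    # plasma-only variant at VAF 0.004 is filtered, 0.005 retained
    rec = detect_in_cfdna(
        matrix,
        plasma_df([(100, 50, 1000), (200, 4, 1000), (300, 5, 1000)]),
        0.3,
    )
    assert set(rec["mutation"]) == {"1:100:C>T", "1:300:C>T"}
    plasma_only = rec[rec["mutation"] == "1:300:C>T"].iloc[0]
    assert plasma_only["tissue_class"] == "plasma_only"


def test_uncovered_locus_excluded_from_denominator():
    matrix = tissue_matrix()
    rec = detect_in_cfdna(matrix, plasma_df([(999, 10, 1000)]), 0.3)
    row = rec[rec["mutation"] == "1:100:C>T"].iloc[0]
    assert np.isnan(row["detected"])


def simulate_detection(rng, beta0, beta1, n):
    k = rng.integers(1, 12, size=n)
    p = 1 / (1 + np.exp(-(beta0 + beta1 * k)))
    detected = rng.random(n) < p
    return pd.DataFrame(
        {
            "mutation": [f"m{i}" for i in range(n)],
            "tissue_class": "branch",
            "k_lesions": k,
            "detected": detected,
            "ctdna_ccf": np.nan,
        }
    )


def test_detection_model_recovers_generative_or():
    rng = np.random.default_rng(17)
    true_or = 1.6
    rec = simulate_detection(rng, -3.0, np.log(true_or), 600)
    fit = detection_model(rec)
    lo, hi = fit["or_ci"]["k_lesions"]
    assert lo < true_or < hi
    assert not fit["separation_warning"]


def test_detection_model_degenerate_inputs():
    rec = simulate_detection(np.random.default_rng(1), 0.0, 0.1, 100)
    const_k = rec.assign(k_lesions=5)
    with pytest.raises(ValueError, match="constant"):
        detection_model(const_k)
    all_detected = rec.assign(detected=True)
    with pytest.raises(ValueError, match="detected and undetected"):
        detection_model(all_detected)


def test_detection_model_flags_separation():
    rec = simulate_detection(np.random.default_rng(2), 0.0, 0.1, 200)
    rec["detected"] = rec["k_lesions"] > 5  # perfectly separable in k
    fit = detection_model(rec)
    assert fit["separation_warning"]


def detected_records(k, ccf):
    return pd.DataFrame(
        {
            "mutation": [f"m{i}" for i in range(len(k))],
            "tissue_class": "branch",
            "k_lesions": k,
            "detected": True,
            "ctdna_ccf": ccf,
        }
    )


def test_ccf_slope_exact_on_noiseless_mixture():
    n_lesions = 12
    k = np.arange(1, 12)
    rec = detected_records(k, k / n_lesions)
    fit = ccf_vs_lesions_model(rec)
    assert fit["slope"] == pytest.approx(1 / n_lesions)
    flat = detected_records(k, np.full_like(k, 0.4, dtype=float))
    assert ccf_vs_lesions_model(flat)["slope"] == pytest.approx(0.0, abs=1e-12)


def test_ccf_slope_degenerate_design_rejected():
    rec = detected_records(np.array([3, 3, 3]), np.array([0.1, 0.2, 0.3]))
    with pytest.raises(ValueError):
        ccf_vs_lesions_model(rec)


def class_records(branch_det, branch_tot, private_det, private_tot):
    rows = []
    for cls, det, tot in [
        ("branch", branch_det, branch_tot),
        ("private", private_det, private_tot),
    ]:
        for i in range(tot):
            rows.append(
                {
                    "mutation": f"{cls}{i}",
                    "tissue_class": cls,
                    "k_lesions": 2,
                    "detected": i < det,
                    "ctdna_ccf": np.nan,
                }
            )
    return pd.DataFrame(rows)


def test_branch_vs_private_contrast():
    res = branch_vs_private_test(class_records(31, 37, 13, 80))
    assert res["table"] == [[31, 6], [13, 67]]
    assert res["p_value"] < 1e-4
    null = branch_vs_private_test(class_records(5, 10, 5, 10))
    assert null["p_value"] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="private"):
        branch_vs_private_test(class_records(5, 10, 0, 0))
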