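"""Detection of tissue-defined mutations in plasma cell-free DNA.

Tissue mutations are rescued in plasma when supported by at least three
reads; plasma-only variants below VAF 0.005 are filtered.  A power model
gives, for a plasma sample of known tumor fraction and depth, the
probability of detecting a mutation present at a given ctDNA CCF: the
minimum read count ``k*`` that keeps the per-locus false-positive
probability below ``fpr`` at the sequencing error rate is computed from
the binomial error tail, and power is the binomial tail above ``k*`` at
the expected plasma VAF.  Logistic and linear models quantify how the
number of tissue lesions harboring a mutation drives its detection and
its ctDNA CCF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ccf import CCFEstimate, LocalContext, ccf_posterior, expected_vaf
from .variant_matrix import PresenceMatrix, mutation_ids

__all__ = [
    "PowerModel",
    "min_detectable_reads",
    "detection_power",
    "min_detectable_ccf",
    "detect_in_cfdna",
    "detection_model",
    "ccf_vs_lesions_model",
    "branch_vs_private_test",
]


@dataclass(frozen=True)
class PowerModel:
    """Parameters of the cfDNA detection-power calculation.

    fpr
        Per-locus false-positive probability tolerated when setting the
        minimum supporting read count.
    per_base_error
        Per-base sequencing error probability.
    min_reads
        Supporting reads required to rescue a tissue mutation in plasma.
    power_target
        Power level at which the minimum detectable CCF is reported.
    """

    fpr: float = 5e-7
    per_base_error: float = 1e-3
    min_reads: int = 3
    power_target: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.fpr <= 1:
            raise ValueError("fpr must be in (0, 1]")
        if not 0 <= self.per_base_error < 1:
            raise ValueError("per_base_error must be in [0, 1)")


def min_detectable_reads(depth: int, model: PowerModel) -> int:
    """Smallest read count whose error-only tail stays below the FPR.

    Returns the smallest integer k with
    ``P(Binomial(depth, per_base_error) >= k) <= fpr``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    # sf(k-1) = P(X >= k); monotone decreasing in k, so bisect
    lo, hi = 0, depth + 1
    if stats.binom.sf(depth - 1, depth, model.per_base_error) > model.fpr:
        raise ValueError(
            f"depth {depth} too low to control FPR {model.fpr} at error "
            f"rate {model.per_base_error}"
        )
    while lo < hi:
        mid = (lo + hi) // 2
        if stats.binom.sf(mid - 1, depth, model.per_base_error) <= model.fpr:
            hi = mid
        else:
            lo = mid + 1
    return max(lo, 1)


def detection_power(
    ccf: float,
    tumor_fraction: float,
    depth: int,
    model: PowerModel,
    ctx: LocalContext | None = None,
) -> float:
    """Probability of detecting a mutation at ``ccf`` in plasma.

    The expected plasma VAF treats the tumor fraction as purity (with
    the locus copy state from ``ctx``, diploid multiplicity-1 by
    default); detection requires at least ``k*(depth)`` supporting
    reads, the count set by :func:`min_detectable_reads`.
    """
    if ctx is None:
        ctx = LocalContext(purity=tumor_fraction)
    kstar = min_detectable_reads(depth, model)
    vaf = expected_vaf(ctx, ccf)
    return float(stats.binom.sf(kstar - 1, depth, vaf))


def min_detectable_ccf(
    tumor_fraction: float,
    depth: int,
    model: PowerModel,
    ctx: LocalContext | None = None,
    tol: float = 1e-4,
) -> float:
    """Minimum ctDNA CCF detectable at the model's target power.

    Bisection on the power curve, which is monotone non-decreasing in
    CCF.  Returns 1.0-exceeding values as ``nan`` when even a fully
    clonal mutation cannot be detected at target power.
    """
    if detection_power(1.0, tumor_fraction, depth, model, ctx) < model.power_target:
        return float("nan")
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if detection_power(mid, tumor_fraction, depth, model, ctx) >= model.power_target:
            hi = mid
        else:
            lo = mid
    return hi


def detect_in_cfdna(
    matrix: PresenceMatrix,
    plasma: pd.DataFrame,
    tumor_fraction: float,
    min_rescue_reads: int = 3,
    min_denovo_vaf: float = 0.005,
    ccf_from_posterior: bool = True,
) -> pd.DataFrame:
    """Score tissue mutations in a plasma sample.

    ``matrix`` is the classified tissue presence matrix of one patient;
    ``plasma`` the plasma pileup (``chrom, pos, ref, alt, alt_reads,
    depth``) for the same patient.  A tissue mutation is detected when
    supported by >= ``min_rescue_reads`` plasma reads.  Plasma-only
    variants are retained only at VAF >= ``min_denovo_vaf`` and reported
    separately (``tissue_class = plasma_only``).  Loci absent from the
    plasma pileup are excluded from detection denominators
    (``detected = NaN``).

    Returns one row per mutation with the tissue class, harboring-lesion
    count ``k``, detection flag and the ctDNA CCF estimate (posterior
    mode with the tumor fraction as purity).
    """
    plasma = plasma.assign(_id=mutation_ids(plasma)).set_index("_id")
    present = matrix.present()
    rows = []
    for mid in matrix.status.index:
        k = int(present.loc[mid].sum())
        cls = matrix.classes[mid]
        if mid in plasma.index:
            a = int(plasma.loc[mid, "alt_reads"])
            d = int(plasma.loc[mid, "depth"])
            detected: float | bool = a >= min_rescue_reads
            ccf = _plasma_ccf(a, d, tumor_fraction) if ccf_from_posterior else np.nan
        else:
            a = d = 0
            detected = np.nan
            ccf = np.nan
        rows.append(
            {
                "mutation": mid,
                "tissue_class": cls,
                "k_lesions": k,
                "plasma_alt": a,
                "plasma_depth": d,
                "detected": detected,
                "ctdna_ccf": ccf,
            }
        )
    out = pd.DataFrame(rows)

    tissue_ids = set(matrix.status.index)
    denovo = plasma[~plasma.index.isin(tissue_ids)]
    if not denovo.empty:
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = denovo["alt_reads"] / denovo["depth"].replace(0, np.nan)
        keep = denovo[vaf >= min_denovo_vaf]
        extra = pd.DataFrame(
            {
                "mutation": keep.index,
                "tissue_class": "plasma_only",
                "k_lesions": 0,
                "plasma_alt": keep["alt_reads"].astype(int).values,
                "plasma_depth": keep["depth"].astype(int).values,
                "detected": True,
                "ctdna_ccf": [
                    _plasma_ccf(int(a), int(d), tumor_fraction)
                    for a, d in zip(keep["alt_reads"], keep["depth"])
                ],
            }
        )
        out = pd.concat([out, extra], ignore_index=True)
    return out


def _plasma_ccf(a: int, d: int, tumor_fraction: float) -> float:
    if d == 0:
        return np.nan
    est = ccf_posterior(a, d, LocalContext(purity=tumor_fraction))
    return est.point


def detection_model(records: pd.DataFrame):
    """Logistic model of cfDNA detection on lesion count and max CCF.

    Fits ``detected ~ k_lesions + max_tissue_ccf`` (the latter only when
    present in ``records``) by maximum likelihood with Wald intervals.
    Returns a dict with the statsmodels result, per-covariate odds
    ratios and their 95% CIs.  Perfect separation falls back to an
    L2-regularized fit with a warning flag.
    """
    rec = records.dropna(subset=["detected"])
    y = rec["detected"].astype(float)
    if y.nunique() < 2:
        raise ValueError("need both detected and undetected records")
    covs = ["k_lesions"]
    if "max_tissue_ccf" in rec.columns:
        covs.append("max_tissue_ccf")
    for c in covs:
        if rec[c].nunique() < 2:
            raise ValueError(f"covariate {c} is constant; coefficient undefined")
    X = sm.add_constant(rec[covs].astype(float))
    separated = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0)
        if not np.isfinite(fit.bse).all() or (np.abs(fit.params) > 50).any():
            raise np.linalg.LinAlgError("separation")
    except Exception:
        separated = True
        fit = sm.Logit(y, X).fit_regularized(alpha=1.0, disp=0)
    ci = fit.conf_int()
    return {
        "fit": fit,
        "odds_ratios": {c: float(np.exp(fit.params[c])) for c in covs},
        "or_ci": {
            c: (float(np.exp(ci.loc[c, 0])), float(np.exp(ci.loc[c, 1])))
            for c in covs
        },
        "separation_warning": separated,
    }


def ccf_vs_lesions_model(records: pd.DataFrame):
    """OLS of ctDNA CCF on harboring-lesion count, detected sSNVs only.

    Returns the slope (CCF per additional lesion) with its 95% Wald CI
    and the statsmodels result.
    """
    rec = records[(records["detected"] == True) & records["ctdna_ccf"].notna()]  # noqa: E712
    if len(rec) < 3 or rec["k_lesions"].nunique() < 2:
        raise ValueError("need >= 3 detected records with varying lesion count")
    X = sm.add_constant(rec[["k_lesions"]].astype(float))
    fit = sm.OLS(rec["ctdna_ccf"].astype(float), X).fit()
    ci = fit.conf_int().loc["k_lesions"]
    return {
        "fit": fit,
        "slope": float(fit.params["k_lesions"]),
        "slope_ci": (float(ci[0]), float(ci[1])),
    }


def branch_vs_private_test(records: pd.DataFrame) -> dict:
    """Fisher exact test of cfDNA detection, branch vs private mutations."""
    rec = records.dropna(subset=["detected"])
    table = []
    props = {}
    for cls in ("branch", "private"):
        sub = rec[rec["tissue_class"] == cls]
        if sub.empty:
            raise ValueError(f"no {cls} mutations in records")
        det = int(sub["detected"].sum())
        tot = len(sub)
        table.append([det, tot - det])
        props[cls] = det / tot
    res = stats.fisher_exact(table, alternative="two-sided")
    return {"table": table, "p_value": float(res.pvalue), "proportions": props}
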