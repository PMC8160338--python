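"""Biopsy-subset sampling statistics and ROC truncality thresholds.

How many driver alterations would have been found, and how often would
non-truncal drivers have looked truncal, had only ``s`` of a patient's
``N`` lesions been sampled?  All C(N, s) subsets are enumerated exactly
(a seeded Monte-Carlo fallback covers combinatorially large cases).  A
driver counts as detected when present in at least one sampled lesion
and as "truncal" when present in every sampled lesion.

The cfDNA alternative: ctDNA CCFs score mutations, tissue truth labels
them, and the ROC operating point nearest the top-left corner yields a
CCF threshold for calling truncal mutations from a single plasma draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "SubsetSummary",
    "RocResult",
    "subset_statistics",
    "roc_truncal_threshold",
    "classify_truncal_from_cfdna",
]


@dataclass
class SubsetSummary:
    """Statistics over all (or sampled) s-lesion subsets of one patient."""

    subset_size: int
    n_subsets: int
    mean_detected: float
    sd_detected: float
    fraction_complete: float
    mean_misclassified_truncal: float
    misclassified_counts: dict
    exhaustive: bool = True


def subset_statistics(
    presence: pd.DataFrame,
    subset_size: int,
    truncal: pd.Series | None = None,
    max_exhaustive: int = 10**6,
    seed: int = 0,
) -> SubsetSummary:
    """Enumerate driver detection over all s-lesion subsets.

    Parameters
    ----------
    presence : DataFrame of bool
        Driver (rows) x lesion (columns) presence flags for one patient.
    subset_size : int
        Number of lesions sampled, 1..N.
    truncal : Series of bool, optional
        True truncality per driver; derived from the presence flags
        (present in all lesions) when omitted.
    max_exhaustive : int
        Subset-count cap above which seeded Monte-Carlo sampling of
        ``max_exhaustive`` subsets replaces exact enumeration.

    Each subset contributes its count of detected drivers (present in
    >= 1 sampled lesion) and of non-truncal drivers misclassified as
    truncal (present in *every* sampled lesion).  Summaries use the
    sample (n-1) standard deviation.
    """
    lesions = list(presence.columns)
    n = len(lesions)
    if not 1 <= subset_size <= n:
        raise ValueError(f"subset size {subset_size} outside 1..{n}")
    pres = presence.astype(bool)
    if truncal is None:
        truncal = pres.all(axis=1)
    truncal = truncal.astype(bool)

    mat = pres.values  # drivers x lesions
    nontruncal = ~truncal.values

    n_subsets = comb(n, subset_size)
    exhaustive = n_subsets <= max_exhaustive
    if exhaustive:
        subsets = combinations(range(n), subset_size)
        total = n_subsets
    else:
        rng = np.random.default_rng(seed)
        subsets = (
            tuple(rng.choice(n, size=subset_size, replace=False))
            for _ in range(max_exhaustive)
        )
        total = max_exhaustive

    detected_counts = np.empty(total, dtype=int)
    mis_counts = np.empty(total, dtype=int)
    n_drivers = mat.shape[0]
    for i, idx in enumerate(subsets):
        sub = mat[:, list(idx)]
        detected_counts[i] = int(sub.any(axis=1).sum())
        mis_counts[i] = int((sub.all(axis=1) & nontruncal).sum())

    uniq, cnt = np.unique(mis_counts, return_counts=True)
    return SubsetSummary(
        subset_size=subset_size,
        n_subsets=n_subsets,
        mean_detected=float(detected_counts.mean()),
        sd_detected=float(detected_counts.std(ddof=1)) if total > 1 else 0.0,
        fraction_complete=float((detected_counts == n_drivers).mean()),
        mean_misclassified_truncal=float(mis_counts.mean()),
        misclassified_counts={int(u): int(c) for u, c in zip(uniq, cnt)},
        exhaustive=exhaustive,
    )


@dataclass
class RocResult:
    """ROC curve with the closest-to-corner operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_threshold: float
    sens_at_opt: float
    spec_at_opt: float


def roc_truncal_threshold(ccf_values, labels) -> RocResult:
    """ROC analysis of truncal classification by a CCF cutoff.

    ``ccf_values`` score each mutation (e.g. ctDNA CCF); ``labels`` are
    the tissue-truth truncal flags.  Candidate thresholds are midpoints
    between consecutive distinct scores plus sentinels below and above
    the observed range; a mutation is called truncal when its score is
    >= the threshold.  AUC is computed by the trapezoid rule over the
    (FPR, TPR) curve.  The optimal threshold minimizes the Euclidean
    distance to the (FPR 0, TPR 1) corner; ties break toward the higher
    threshold.
    """
    scores = np.asarray(ccf_values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must align")
    if y.all() or not y.any():
        raise ValueError("need both truncal and non-truncal labels")

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2
    thresholds = np.concatenate(
        ([distinct[0] - 1e-9], mids, [distinct[-1] + 1e-9])
    )

    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    sens = np.array([(scores[y] >= t).sum() / n_pos for t in thresholds])
    spec = np.array([(scores[~y] < t).sum() / n_neg for t in thresholds])

    fpr = 1 - spec
    # traverse the staircase with TPR ascending within tied FPR values
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))

    dist = np.hypot(fpr, 1 - sens)
    best = np.flatnonzero(dist == dist.min())
    # thresholds ascend; take the last (highest) minimizer
    i = int(best[np.argmax(thresholds[best])])
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_threshold=float(thresholds[i]),
        sens_at_opt=float(sens[i]),
        spec_at_opt=float(spec[i]),
    )


def classify_truncal_from_cfdna(ccf: float, threshold: float) -> str:
    """Call a plasma mutation truncal when its ctDNA CCF >= threshold."""
    if not 0 <= ccf <= 1:
        raise ValueError("CCF must be in [0, 1]")
    return "truncal" if ccf >= threshold else "non_truncal"
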