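"""Cancer cell fraction (CCF) estimation from read counts.

The fraction of cancer cells carrying a somatic SNV is inferred from the
variant allele fraction (VAF) observed in sequencing reads, corrected for
tumor purity and the local copy-number state.  The expected VAF of a
mutation present at CCF ``c`` with multiplicity ``m`` (number of mutated
chromosomal copies) in a sample of purity ``alpha`` is

    f(c) = alpha * c * m / (alpha * q_t + (1 - alpha) * q_n)

with ``q_t`` the tumor total copy number at the locus and ``q_n = 2`` the
normal copy number.  A posterior over a grid of 100 CCF values in (0, 1]
is built from the binomial likelihood of the observed alt/total read
counts at each grid point, under a uniform prior.

The same machinery estimates ctDNA CCFs from plasma read counts by
treating the plasma tumor fraction as the purity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CCF_GRID",
    "LocalContext",
    "CCFEstimate",
    "expected_vaf",
    "ccf_posterior",
    "classify_clonal",
    "estimate_multiplicity",
    "multiplicity_timing",
    "call_wgd",
]

#: 100 equally spaced CCF values on (0, 1]; c = 0 is not a somatic state.
CCF_GRID: np.ndarray = np.linspace(0.01, 1.0, 100)

#: Minimum depth of coverage for a CCF estimate to be reported.
MIN_REPORT_DEPTH = 30

#: Point-estimate cutoff at and above which a mutation is called clonal.
CLONAL_CCF = 0.9

NORMAL_COPIES = 2


@dataclass(frozen=True)
class LocalContext:
    """Purity and local copy-number state at a mutated locus.

    Parameters
    ----------
    purity : float
        Tumor cell fraction of the sample, in (0, 1].  For plasma this is
        the ctDNA tumor fraction.
    major, minor : int
        Allele-specific copy numbers of the segment containing the locus.
    multiplicity : int
        Number of tumor chromosomal copies carrying the mutation; at most
        ``major``.
    """

    purity: float
    major: int = 1
    minor: int = 1
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.major < 0 or self.minor < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.major < self.minor:
            raise ValueError("major copy number must be >= minor")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.multiplicity > self.major and self.total > 0:
            raise ValueError(
                f"multiplicity {self.multiplicity} exceeds major copy "
                f"number {self.major}"
            )

    @property
    def total(self) -> int:
        """Total tumor copy number (major + minor)."""
        return self.major + self.minor


@dataclass
class CCFEstimate:
    """Grid posterior over CCF with point estimate and credible interval."""

    grid: np.ndarray
    posterior: np.ndarray
    point: float
    ci_low: float
    ci_high: float
    clonal: bool
    depth_ok: bool
    alt_reads: int = 0
    depth: int = 0


def expected_vaf(ctx: LocalContext, ccf: float) -> float:
    """Expected variant allele fraction at CCF ``ccf`` under ``ctx``.

    Returns ``alpha*c*m / (alpha*q_t + (1-alpha)*2)``; 0 when ``ccf`` is 0.

    Raises
    ------
    ValueError
        If the locus contributes no DNA (purity 1 with homozygous
        deletion), or ``ccf`` is outside [0, 1].
    """
    if not 0.0 <= ccf <= 1.0:
        raise ValueError(f"CCF must be in [0, 1], got {ccf}")
    denom = ctx.purity * ctx.total + (1.0 - ctx.purity) * NORMAL_COPIES
    if denom <= 0:
        raise ValueError("no tumor DNA at locus (purity 1, total copies 0)")
    if ccf == 0.0:
        return 0.0
    return ctx.purity * ccf * ctx.multiplicity / denom


def ccf_posterior(
    alt_reads: int,
    depth: int,
    ctx: LocalContext,
    grid: np.ndarray | None = None,
    min_depth: int = MIN_REPORT_DEPTH,
) -> CCFEstimate:
    """Posterior over the CCF grid from binomial read counts.

    The posterior at each grid value ``c`` is proportional to
    ``Binom(alt_reads | depth, expected_vaf(ctx, c))`` under a uniform
    prior.  The point estimate is the posterior mode; the credible
    interval is the central 95% interval of the cumulative posterior.
    Estimates at depth below ``min_depth`` carry ``depth_ok=False`` and
    should not be reported.
    """
    if alt_reads < 0 or depth < 0:
        raise ValueError("read counts must be non-negative")
    if alt_reads > depth:
        raise ValueError(f"alt reads {alt_reads} exceed depth {depth}")
    g = CCF_GRID if grid is None else np.asarray(grid, dtype=float)
    vafs = np.array([expected_vaf(ctx, c) for c in g])
    # clip away p=1 edge cases that make logpmf degenerate
    vafs = np.clip(vafs, 1e-12, 1.0 - 1e-12)
    loglik = stats.binom.logpmf(alt_reads, depth, vafs)
    loglik -= loglik.max()
    post = np.exp(loglik)
    post /= post.sum()
    cum = np.cumsum(post)
    point = float(g[int(np.argmax(post))])
    ci_low = float(g[int(np.searchsorted(cum, 0.025))])
    ci_high = float(g[min(int(np.searchsorted(cum, 0.975)), len(g) - 1)])
    return CCFEstimate(
        grid=g,
        posterior=post,
        point=point,
        ci_low=ci_low,
        ci_high=ci_high,
        clonal=point >= CLONAL_CCF,
        depth_ok=depth >= min_depth,
        alt_reads=alt_reads,
        depth=depth,
    )


def classify_clonal(est: CCFEstimate, threshold: float = CLONAL_CCF) -> str:
    """Call a mutation clonal (point CCF >= threshold) or subclonal.

    Refuses to classify estimates whose depth is below the reporting
    cutoff, mirroring the rule that CCFs are only reported at >= 30x.
    """
    if not est.depth_ok:
        raise ValueError("CCF not reported at depth < 30; cannot classify")
    return "clonal" if est.point >= threshold else "subclonal"


def estimate_multiplicity(alt_reads: int, depth: int, ctx: LocalContext) -> int:
    """Estimate mutation multiplicity by inverting the VAF model.

    m = round(f * (alpha*q_t + (1-alpha)*2) / alpha), clipped to
    [1, major].  Used when multiplicity is not known a priori.
    """
    if depth == 0:
        return 1
    f = alt_reads / depth
    denom = ctx.purity * ctx.total + (1.0 - ctx.purity) * NORMAL_COPIES
    m = round(f * denom / ctx.purity)
    return int(min(max(m, 1), max(ctx.major, 1)))


def multiplicity_timing(multiplicity: int, major: int) -> str:
    """Time a mutation relative to a copy-number gain at its locus.

    In regions with major copy number >= 2, a mutation carried on more
    than one copy (multiplicity > 1) must have preceded the gain;
    multiplicity 1 leaves the order unresolved.  Regions without a gain
    (major < 2) are uninformative.

    Returns one of ``before_scna``, ``after_or_unknown``,
    ``not_applicable``.
    """
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    if multiplicity > major:
        raise ValueError(
            f"multiplicity {multiplicity} exceeds major copy number {major}"
        )
    if major < 2:
        return "not_applicable"
    return "before_scna" if multiplicity > 1 else "after_or_unknown"


def call_wgd(segments: pd.DataFrame, genome_size: int) -> bool:
    """Call whole-genome duplication from allele-specific segments.

    WGD is called when segments with an even major copy number (2, 4, ...)
    cover strictly more than half of ``genome_size``.  Segment coordinates
    are 1-based inclusive; segments must not overlap within a sample.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    _check_non_overlapping(segments)
    lengths = segments["end"] - segments["start"] + 1
    even = segments["major"] % 2 == 0
    covered = int(lengths[even & (segments["major"] > 0)].sum())
    return covered > 0.5 * genome_size


def _check_non_overlapping(segments: pd.DataFrame) -> None:
    cols = ["chrom", "start", "end"]
    group_cols = ["sample", "chrom"] if "sample" in segments.columns else ["chrom"]
    for _, grp in segments[group_cols[:-1] + cols].groupby(group_cols):
        s = grp.sort_values("start")
        if (s["start"].values[1:] <= s["end"].values[:-1]).any():
            raise ValueError("overlapping segments within a sample")
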