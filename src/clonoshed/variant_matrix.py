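"""Power-aware mutation presence matrices across multi-lesion patients.

Multi-region comparisons overestimate heterogeneity when a mutation is
genuinely present in a lesion but missed by the caller.  Two safeguards
are applied before classifying mutations as truncal / branch / private:

* **Rescue** — a mutation called with high confidence in any lesion of a
  patient is scored present in every other lesion where it is supported
  by at least three reads passing base- and mapping-quality gates.
* **Power filter** — only loci with >= 90% power to detect a clonal
  variant in at least three reads in *every* lesion (given local depth
  and sample purity) are retained for heterogeneity analyses.

Mutation classes over the powered set: truncal = present in all lesions,
private = present in exactly one, branch = a strict subset of >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ccf import LocalContext, expected_vaf

__all__ = [
    "MUTATION_KEY",
    "PresenceMatrix",
    "mutation_ids",
    "rescue_mutations",
    "power_filter",
    "classify_mutations",
    "jaccard_similarity",
    "downsample_jaccard",
    "tmb",
    "dispersion_mad",
]

#: Columns identifying one variant locus/allele.
MUTATION_KEY = ["chrom", "pos", "ref", "alt"]

CALLED = "called"
RESCUED = "rescued"
ABSENT = "absent"
UNPOWERED = "unpowered"

PRESENT_STATUSES = frozenset({CALLED, RESCUED})


def mutation_ids(records: pd.DataFrame) -> pd.Series:
    """Stable string identifier ``chrom:pos:ref>alt`` per record."""
    return (
        records["chrom"].astype(str)
        + ":"
        + records["pos"].astype(str)
        + ":"
        + records["ref"].astype(str)
        + ">"
        + records["alt"].astype(str)
    )


@dataclass
class PresenceMatrix:
    """Mutation x lesion status matrix for one patient.

    Attributes
    ----------
    status : DataFrame
        Rows indexed by mutation id, columns by sample id; cells one of
        ``called``, ``rescued``, ``absent``, ``unpowered``.
    powered : Series of bool
        True when the locus is adequately powered in *all* lesions.
    classes : Series of str
        ``truncal`` / ``branch`` / ``private`` / ``unclassifiable``;
        assigned only after :func:`classify_mutations`.
    meta : DataFrame
        Per-mutation annotation (gene, coding flag, driver flag, ...),
        aligned with ``status``.
    """

    patient: str
    status: pd.DataFrame
    powered: pd.Series = None
    classes: pd.Series = None
    meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.powered is None:
            self.powered = pd.Series(True, index=self.status.index)
        if self.classes is None:
            self.classes = pd.Series("unclassifiable", index=self.status.index)

    @property
    def samples(self) -> list[str]:
        return list(self.status.columns)

    @property
    def n_lesions(self) -> int:
        return self.status.shape[1]

    def present(self) -> pd.DataFrame:
        """Boolean presence (called or rescued) per mutation per lesion."""
        return self.status.isin(PRESENT_STATUSES)

    def class_counts(self) -> dict[str, int]:
        return self.classes[self.powered].value_counts().to_dict()


def rescue_mutations(
    calls: pd.DataFrame,
    pileup: pd.DataFrame,
    min_reads: int = 3,
    min_bq: float = 30,
    min_mq: float = 60,
) -> PresenceMatrix:
    """Score per-lesion presence with the read-support rescue rule.

    ``calls`` holds the high-confidence per-lesion calls; ``pileup``
    holds alt/total read counts and median qualities at every called
    locus in every lesion of the patient.  A locus called in >= 1 lesion
    is *rescued* in any other lesion with ``alt_reads >= min_reads``,
    ``base_quality >= min_bq`` and ``map_quality >= min_mq``; otherwise
    it is *absent* there.  Original calls are never downgraded.  A locus
    missing from a lesion's pileup is marked *unpowered* in that lesion.
    """
    patients = set(calls["patient"]) | set(pileup["patient"])
    if len(patients) != 1:
        raise ValueError(f"records must share one patient, got {sorted(patients)}")
    patient = patients.pop()

    samples = sorted(set(pileup["sample"]) | set(calls["sample"]))
    muts = calls.assign(_id=mutation_ids(calls))
    ids = sorted(muts["_id"].unique())

    status = pd.DataFrame(UNPOWERED, index=ids, columns=samples)
    pu = pileup.assign(_id=mutation_ids(pileup))
    pu = pu[pu["_id"].isin(ids)]
    supported = (
        (pu["alt_reads"] >= min_reads)
        & (pu["base_quality"] >= min_bq)
        & (pu["map_quality"] >= min_mq)
    )
    for (_id, sample), ok in zip(
        zip(pu["_id"], pu["sample"]), supported, strict=True
    ):
        status.loc[_id, sample] = RESCUED if ok else ABSENT
    for _id, sample in zip(muts["_id"], muts["sample"]):
        status.loc[_id, sample] = CALLED

    meta_cols = [c for c in ("gene", "coding", "driver") if c in calls.columns]
    meta = (
        muts.drop_duplicates("_id").set_index("_id")[MUTATION_KEY + meta_cols].loc[ids]
    )
    return PresenceMatrix(patient=patient, status=status, meta=meta)


def power_filter(
    matrix: PresenceMatrix,
    pileup: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    power_target: float = 0.90,
    min_reads: int = 3,
) -> PresenceMatrix:
    """Flag mutations powered for detection in every lesion.

    For each mutation and lesion, detection power is the binomial tail
    ``P(X >= min_reads)`` at the lesion's local depth with success
    probability equal to the expected VAF of a clonal (CCF 1),
    multiplicity-1 variant given the lesion's purity.  The per-mutation
    powered flag requires power >= ``power_target`` in *all* lesions;
    loci with depth 0 or missing pileup anywhere are unpowered.
    Cell statuses of unpowered lesions are set to ``unpowered``.
    """
    purity = sample_sheet.set_index("sample")["purity"]
    pu = pileup.assign(_id=mutation_ids(pileup)).set_index(["_id", "sample"])
    depth = pu["depth"]

    powered = pd.Series(True, index=matrix.status.index)
    status = matrix.status.copy()
    for sample in matrix.samples:
        vaf = expected_vaf(LocalContext(purity=float(purity[sample])), 1.0)
        for _id in matrix.status.index:
            d = int(depth.get((_id, sample), 0))
            if d <= 0 or stats.binom.sf(min_reads - 1, d, vaf) < power_target:
                powered[_id] = False
                status.loc[_id, sample] = UNPOWERED
    return PresenceMatrix(
        patient=matrix.patient,
        status=status,
        powered=powered,
        classes=matrix.classes,
        meta=matrix.meta,
    )


def classify_mutations(matrix: PresenceMatrix) -> PresenceMatrix:
    """Assign truncal / branch / private classes to powered mutations.

    A patient with a single lesion cannot distinguish truncal from
    private; all mutations are left unclassifiable.
    """
    classes = pd.Series("unclassifiable", index=matrix.status.index)
    if matrix.n_lesions >= 2:
        present = matrix.present()
        n_present = present.sum(axis=1)
        n = matrix.n_lesions
        classes[matrix.powered & (n_present == n)] = "truncal"
        classes[matrix.powered & (n_present == 1)] = "private"
        classes[matrix.powered & (n_present > 1) & (n_present < n)] = "branch"
        classes[matrix.powered & (n_present == 0)] = "unclassifiable"
    return PresenceMatrix(
        patient=matrix.patient,
        status=matrix.status,
        powered=matrix.powered,
        classes=classes,
        meta=matrix.meta,
    )


def jaccard_similarity(matrix: PresenceMatrix) -> tuple[pd.DataFrame, float]:
    """Pairwise lesion similarity over powered mutations.

    The Jaccard index of two lesions is the number of (called or
    rescued) mutations shared by both divided by the number present in
    either.  Returns the symmetric similarity matrix (unit diagonal,
    NaN where the union is empty) and the median off-diagonal value.
    """
    if matrix.n_lesions < 2:
        raise ValueError("need >= 2 lesions for pairwise similarity")
    present = matrix.present().loc[matrix.powered]
    samples = matrix.samples
    sim = pd.DataFrame(np.nan, index=samples, columns=samples, dtype=float)
    offdiag = []
    for i, a in enumerate(samples):
        sim.loc[a, a] = 1.0
        for b in samples[i + 1 :]:
            inter = int((present[a] & present[b]).sum())
            union = int((present[a] | present[b]).sum())
            val = np.nan if union == 0 else inter / union
            sim.loc[a, b] = sim.loc[b, a] = val
            offdiag.append(val)
    median = float(np.nanmedian(offdiag)) if offdiag else np.nan
    return sim, median


def downsample_jaccard(
    matrix: PresenceMatrix,
    n_lesions: int,
    n_reps: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Median pairwise Jaccard after repeated lesion downsampling.

    Each replicate samples ``n_lesions`` lesions without replacement and
    recomputes the median pairwise Jaccard, giving a distribution
    comparable across patients with different lesion counts.
    """
    if n_lesions < 2:
        raise ValueError("n_lesions must be >= 2")
    if n_lesions > matrix.n_lesions:
        raise ValueError("cannot downsample beyond the available lesions")
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for r in range(n_reps):
        chosen = list(rng.choice(matrix.samples, size=n_lesions, replace=False))
        sub = PresenceMatrix(
            patient=matrix.patient,
            status=matrix.status[chosen],
            powered=matrix.powered,
            meta=matrix.meta,
        )
        out[r] = jaccard_similarity(sub)[1]
    return out


def tmb(
    records: pd.DataFrame,
    powered_coding_bases: float,
    min_depth: int = 30,
    min_vaf: float = 0.01,
) -> float:
    """Tumor mutation burden in mutations per megabase.

    Counts coding point mutations and indels with depth >= ``min_depth``
    and VAF > ``min_vaf``, divided by the megabases of coding territory
    covered by at least ``min_depth`` reads (``powered_coding_bases``).
    """
    if powered_coding_bases <= 0:
        raise ValueError("powered_coding_bases must be positive")
    rec = records
    if "coding" in rec.columns:
        rec = rec[rec["coding"].astype(bool)]
    depth_ok = rec["depth"] >= min_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = rec["alt_reads"] / rec["depth"].replace(0, np.nan)
    n = int((depth_ok & (vaf > min_vaf)).sum())
    return n / (powered_coding_bases / 1e6)


def dispersion_mad(values) -> float:
    """Median absolute deviation from the median, unscaled.

    Raw descriptive dispersion — no 1.4826 normal-consistency factor.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    return float(np.median(np.abs(arr - np.median(arr))))
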