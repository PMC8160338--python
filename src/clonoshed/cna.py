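"""Somatic copy-number event classification and instability metrics.

Events are classified relative to the sample's estimated ploidy psi:
high-level amplification (total >= 3*psi), gain (2*psi <= total < 3*psi),
partial deletion (0 < total < psi/2), homozygous deletion (total = 0).
Loss of heterozygosity (minor copy number 0 with residual copies,
including copy-neutral LOH) is tracked as a separate flag.  Copy-number
instability (CIN) is the fraction of the genome altered by any event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ccf import _check_non_overlapping
from .variant_matrix import PresenceMatrix, mutation_ids

__all__ = [
    "classify_cna",
    "classify_segments",
    "cin",
    "scna_jaccard",
    "detect_mutation_loss",
]

HIGH_AMP = "high_amp"
GAIN = "gain"
PARTIAL_DEL = "partial_del"
HOMOZYGOUS_DEL = "homozygous_del"
NEUTRAL = "neutral"


def classify_cna(total: int, minor: int, ploidy: float) -> tuple[str, bool]:
    """Classify one segment's copy state relative to ploidy.

    Returns ``(event_class, loh_flag)``.  The LOH flag is independent of
    the dosage class: a copy-neutral LOH segment is ``(neutral, True)``.
    """
    if total < 0 or minor < 0:
        raise ValueError("copy numbers must be non-negative")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    loh = minor == 0 and total > 0
    if total == 0:
        cls = HOMOZYGOUS_DEL
    elif total >= 3 * ploidy:
        cls = HIGH_AMP
    elif total >= 2 * ploidy:
        cls = GAIN
    elif total < ploidy / 2:
        cls = PARTIAL_DEL
    else:
        cls = NEUTRAL
    return cls, loh


def classify_segments(segments: pd.DataFrame, ploidy: float) -> pd.DataFrame:
    """Vectorised :func:`classify_cna` over a SEG table.

    Adds ``total``, ``event_class`` and ``loh`` columns.
    """
    seg = segments.copy()
    seg["total"] = seg["major"] + seg["minor"]
    out = [classify_cna(t, m, ploidy) for t, m in zip(seg["total"], seg["minor"])]
    seg["event_class"] = [c for c, _ in out]
    seg["loh"] = [l for _, l in out]
    return seg


def _altered(seg: pd.DataFrame, ploidy: float) -> pd.Series:
    # any deviation of total copies from the rounded ploidy, or LOH
    return (seg["total"] != round(ploidy)) | seg["loh"]


def cin(segments: pd.DataFrame, ploidy: float, genome_size: int) -> float:
    """Fraction of the genome altered by any copy-number event.

    A segment counts as altered when its total copy number deviates from
    the rounded ploidy or it shows LOH.  Unsegmented territory counts as
    unaltered.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    _check_non_overlapping(segments)
    seg = classify_segments(segments, ploidy)
    lengths = seg["end"] - seg["start"] + 1
    altered = int(lengths[_altered(seg, ploidy)].sum())
    return altered / genome_size


def scna_jaccard(
    segments_a: pd.DataFrame,
    segments_b: pd.DataFrame,
    ploidy_a: float,
    ploidy_b: float,
) -> float:
    """Base-level Jaccard similarity of two samples' altered genome.

    Intersection counts bases altered in both samples with the *same*
    event class (dosage class plus LOH flag); union counts bases altered
    in either.  Returns NaN when neither sample is altered anywhere.
    """
    a = classify_segments(segments_a, ploidy_a)
    b = classify_segments(segments_b, ploidy_b)
    a = a[_altered(a, ploidy_a)]
    b = b[_altered(b, ploidy_b)]
    inter = 0
    union = 0
    chroms = set(a["chrom"]) | set(b["chrom"])
    for chrom in chroms:
        ca = a[a["chrom"] == chrom]
        cb = b[b["chrom"] == chrom]
        # piecewise sweep over breakpoints of both samples
        points = sorted(
            set(ca["start"]).union(ca["end"] + 1, cb["start"], cb["end"] + 1)
        )
        for lo, hi in zip(points[:-1], points[1:]):
            length = hi - lo
            la = _label_at(ca, lo)
            lb = _label_at(cb, lo)
            if la is not None or lb is not None:
                union += length
                if la is not None and la == lb:
                    inter += length
    return np.nan if union == 0 else inter / union


def _label_at(seg: pd.DataFrame, pos: int):
    hit = seg[(seg["start"] <= pos) & (seg["end"] >= pos)]
    if hit.empty:
        return None
    row = hit.iloc[0]
    return (row["event_class"], bool(row["loh"]))


def detect_mutation_loss(
    matrix: PresenceMatrix, loh_status: pd.DataFrame
) -> pd.DataFrame:
    """Find branch/private mutations explained by loss of the mutant copy.

    ``loh_status`` is a boolean mutation x lesion table (same shape as
    the presence matrix) marking lesions with loss of the minor allele
    at each locus.  A non-truncal mutation is a loss event when

    1. at least one lesion carries the mutation without LOH (rules out
       calling loss where the *wild-type* copy may have been lost),
    2. at least one lesion lacks the mutation and shows LOH, and
    3. no lesion lacks both — such loci are removed from consideration.

    Returns the loss-event rows of the matrix metadata with supporting
    lesion lists.
    """
    present = matrix.present()
    loh = loh_status.loc[present.index, present.columns].astype(bool)
    rows = []
    for mid in matrix.status.index:
        if matrix.classes[mid] not in ("branch", "private"):
            continue
        p = present.loc[mid]
        l = loh.loc[mid]
        if (~p & ~l).any():  # ambiguous lesion: locus removed
            continue
        if not (p & ~l).any():  # mutation only ever seen with LOH
            continue
        if not (~p & l).any():  # no lesion actually lost it
            continue
        rows.append(
            {
                "mutation": mid,
                "class": matrix.classes[mid],
                "lesions_with_mutation": ",".join(p.index[p]),
                "lesions_with_loss": ",".join(l.index[~p & l]),
            }
        )
    return pd.DataFrame(rows, columns=[
        "mutation", "class", "lesions_with_mutation", "lesions_with_loss"
    ])
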