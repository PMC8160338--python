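"""Synthetic multi-lesion cohort generator with known ground truth.

Emulates the statistical structure of a rapid-autopsy cohort: each
patient contributes several metastatic lesions (default 4-17), somatic
SNVs are placed on a random bifurcating clone tree so that truncal
mutations occupy every lesion, branch mutations a nested strict subset,
and private mutations exactly one lesion.  Read counts are binomial at
the expected VAF given lesion purity, local copy number and depth
(Poisson around the configured mean).  A plasma sample mixes lesion
contributions with per-lesion shedding weights: the ctDNA CCF of a
mutation is the shed-weighted sum of its per-lesion CCFs, and plasma
read counts are binomial at the corresponding VAF with the ctDNA tumor
fraction acting as purity.

Everything the generator draws is recorded in a truth table so every
downstream stage can be scored against known labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ccf import LocalContext, expected_vaf

__all__ = ["SimConfig", "Cohort", "simulate_cohort"]

#: Gene pool used to label synthetic mutations; driver genes first
#: (illustrative subset of a targeted cancer panel).
DRIVER_GENES = ["PIK3CA", "AKT1", "ESR1", "FGFR2", "ARID1B", "SPEN", "NSD1", "MYC"]
PASSENGER_GENES = [f"GENE{i:03d}" for i in range(1, 201)]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the plasma-profiled autopsy cohort: nine patients
    with 4-17 lesions each, tissue depth averaging 117x, plasma depth
    1200x with tumor fraction 0.3, per-base error 1e-3, and purities
    drawn from Beta(6, 4) (mean 0.6).
    """

    n_patients: int = 9
    lesions_per_patient: int | tuple[int, int] = (4, 17)
    n_truncal: int = 40
    n_branch: int = 30
    n_private: int = 30
    n_drivers: int = 5
    driver_classes: tuple[str, ...] = (
        "truncal", "truncal", "truncal", "branch", "private",
    )
    purity_beta: tuple[float, float] = (6.0, 4.0)
    min_purity: float = 0.2
    tissue_depth_mean: float = 117.0
    cfdna_depth_mean: float = 1200.0
    ctdna_tumor_fraction: float = 0.3
    shed_weights: str = "equal"  # or "dirichlet"
    per_base_error: float = 1e-3
    panel_fraction: float = 0.3
    subclonal_fraction: float = 0.0
    subclonal_ccf_range: tuple[float, float] = (0.2, 0.8)
    fixed_class_counts: bool = False
    #: place non-truncal mutations on uniform-size random lesion subsets
    #: (k ~ Uniform(1, N-1)) instead of clone-tree edges; useful when the
    #: harboring-lesion count must sweep its full range evenly
    uniform_k_nontruncal: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.lesion_range
        if lo < 2:
            raise ValueError("patients need at least two lesions")
        for name in ("n_truncal", "n_branch", "n_private", "n_drivers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.ctdna_tumor_fraction <= 1.0:
            raise ValueError("ctdna_tumor_fraction must be in (0, 1]")
        if not 0.0 < self.min_purity <= 1.0:
            raise ValueError("purity bounds must lie in (0, 1]")
        if len(self.driver_classes) != self.n_drivers:
            raise ValueError("driver_classes length must equal n_drivers")

    @property
    def lesion_range(self) -> tuple[int, int]:
        if isinstance(self.lesions_per_patient, int):
            return (self.lesions_per_patient, self.lesions_per_patient)
        lo, hi = self.lesions_per_patient
        return int(lo), int(hi)


@dataclass
class Cohort:
    """Simulated cohort: truth plus observable tables.

    ``tissue`` holds one row per mutation per lesion (the full pileup);
    rows where the caller fired carry ``called = True``.  ``plasma``
    holds one row per on-panel mutation per patient.
    """

    config: SimConfig
    truth: pd.DataFrame
    tissue: pd.DataFrame
    plasma: pd.DataFrame
    segments: pd.DataFrame
    sample_sheet: pd.DataFrame

    def patient_ids(self) -> list[str]:
        return list(self.sample_sheet["patient"].unique())


def _random_clone_tree(n_lesions: int, rng: np.random.Generator) -> list[tuple[int, ...]]:
    """Internal-edge lesion sets of a random bifurcating tree.

    Recursively bipartitions the lesion set; every internal edge below
    the root defines a nested subset with 2 <= size < n_lesions.
    """
    edges: list[tuple[int, ...]] = []

    def split(members: list[int], is_root: bool) -> None:
        if len(members) < 2:
            return
        if not is_root and len(members) < n_lesions:
            edges.append(tuple(sorted(members)))
        cut = int(rng.integers(1, len(members)))
        perm = list(rng.permutation(members))
        split(perm[:cut], False)
        split(perm[cut:], False)

    split(list(range(n_lesions)), True)
    return edges


def simulate_cohort(config: SimConfig, seed: int) -> Cohort:
    """Draw a full cohort; identical config + seed gives identical output."""
    rng = np.random.default_rng(seed)
    truth_rows, tissue_rows, plasma_rows = [], [], []
    seg_rows, sheet_rows = [], []
    pos_counter = 1000

    for p in range(config.n_patients):
        patient = f"P{p + 1:02d}"
        lo, hi = config.lesion_range
        n_lesions = int(rng.integers(lo, hi + 1))
        lesions = [f"{patient}-L{i + 1:02d}" for i in range(n_lesions)]

        a, b = config.purity_beta
        purities = np.maximum(rng.beta(a, b, size=n_lesions), config.min_purity)
        if config.shed_weights == "equal":
            weights = np.full(n_lesions, 1.0 / n_lesions)
        else:
            weights = rng.dirichlet(np.ones(n_lesions))

        for lesion, purity in zip(lesions, purities):
            sheet_rows.append(
                {
                    "sample": lesion,
                    "patient": patient,
                    "lesion": lesion.split("-")[-1],
                    "site": "liver",
                    "purity": round(float(purity), 4),
                    "ploidy": 2.0,
                    "mean_depth": config.tissue_depth_mean,
                }
            )
            # diploid background segment per lesion (chrom "1" spans the
            # synthetic genome); CNA tests inject their own segments
            seg_rows.append(
                {
                    "sample": lesion,
                    "chrom": "1",
                    "start": 1,
                    "end": 100_000_000,
                    "major": 1,
                    "minor": 1,
                }
            )

        internal_edges = _random_clone_tree(n_lesions, rng)

        def n_of(mean: int) -> int:
            if config.fixed_class_counts:
                return int(mean)
            return int(rng.poisson(mean))

        class_plan = (
            [("truncal", None)] * n_of(config.n_truncal)
            + [("branch", None)] * (
                n_of(config.n_branch)
                if internal_edges or config.uniform_k_nontruncal
                else 0
            )
            + [("private", None)] * n_of(config.n_private)
        )
        driver_plan = [(cls, gene) for cls, gene in zip(
            config.driver_classes, DRIVER_GENES
        )]

        for j, (cls, driver_gene) in enumerate(driver_plan + class_plan):
            is_driver = driver_gene is not None
            if cls == "truncal":
                harboring = tuple(range(n_lesions))
            elif config.uniform_k_nontruncal and cls in ("branch", "private"):
                k = int(rng.integers(1, n_lesions))  # uniform on 1..N-1
                harboring = tuple(
                    sorted(rng.choice(n_lesions, size=k, replace=False))
                )
                cls = "private" if k == 1 else "branch"
            elif cls == "branch" and internal_edges:
                harboring = internal_edges[int(rng.integers(len(internal_edges)))]
            elif cls == "branch":
                continue  # two-lesion patients have no internal edges
            else:
                harboring = (int(rng.integers(n_lesions)),)
            pos_counter += int(rng.integers(50, 500))
            pos = pos_counter
            ref, alt = "C", "T"
            gene = driver_gene if is_driver else (
                PASSENGER_GENES[int(rng.integers(len(PASSENGER_GENES)))]
            )
            on_panel = is_driver or rng.random() < config.panel_fraction
            if config.subclonal_fraction and rng.random() < config.subclonal_fraction:
                lo_c, hi_c = config.subclonal_ccf_range
                ccf_in_lesion = float(rng.uniform(lo_c, hi_c))
            else:
                ccf_in_lesion = 1.0

            # weight sums can exceed 1 by a ULP when all lesions harbor
            ctdna_ccf = float(
                min(sum(weights[i] for i in harboring), 1.0) * ccf_in_lesion
            )
            truth_rows.append(
                {
                    "patient": patient,
                    "chrom": "1",
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": gene,
                    "coding": True,
                    "class": cls,
                    "harboring_lesions": ",".join(lesions[i] for i in harboring),
                    "k_lesions": len(harboring),
                    "ccf_in_lesion": ccf_in_lesion,
                    "multiplicity": 1,
                    "driver": is_driver,
                    "on_panel": on_panel,
                    "ctdna_ccf": ctdna_ccf,
                    "tumor_fraction": config.ctdna_tumor_fraction,
                }
            )

            harb = set(harboring)
            for i, (lesion, purity) in enumerate(zip(lesions, purities)):
                depth = int(rng.poisson(config.tissue_depth_mean))
                if i in harb:
                    vaf = expected_vaf(
                        LocalContext(purity=float(purity)), ccf_in_lesion
                    )
                else:
                    vaf = config.per_base_error
                alt_reads = int(rng.binomial(depth, vaf)) if depth > 0 else 0
                called = bool(i in harb and alt_reads >= 3 and depth > 0)
                tissue_rows.append(
                    {
                        "patient": patient,
                        "sample": lesion,
                        "chrom": "1",
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "gene": gene,
                        "coding": True,
                        "alt_reads": alt_reads,
                        "depth": depth,
                        "base_quality": 37.0,
                        "map_quality": 60.0,
                        "called": called,
                    }
                )

            if on_panel:
                pd_depth = int(rng.poisson(config.cfdna_depth_mean))
                plasma_vaf = expected_vaf(
                    LocalContext(purity=config.ctdna_tumor_fraction), ctdna_ccf
                )
                # sequencing error adds background on top of signal
                p_eff = min(
                    plasma_vaf + (1 - plasma_vaf) * config.per_base_error, 1.0
                )
                plasma_alt = int(rng.binomial(pd_depth, p_eff)) if pd_depth else 0
                plasma_rows.append(
                    {
                        "patient": patient,
                        "sample": f"{patient}-cfDNA",
                        "chrom": "1",
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "gene": gene,
                        "coding": True,
                        "alt_reads": plasma_alt,
                        "depth": pd_depth,
                        "base_quality": 37.0,
                        "map_quality": 60.0,
                    }
                )

    return Cohort(
        config=config,
        truth=pd.DataFrame(truth_rows),
        tissue=pd.DataFrame(tissue_rows),
        plasma=pd.DataFrame(plasma_rows),
        segments=pd.DataFrame(seg_rows),
        sample_sheet=pd.DataFrame(sheet_rows),
    )
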