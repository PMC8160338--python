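# clonoshed

Multi-lesion tumor heterogeneity and cell-free DNA (cfDNA) analysis for
multi-region cancer sequencing studies.

When several metastatic lesions of one patient are sequenced, somatic
mutations split into **truncal** (present in every lesion), **branch**
(a strict subset of ≥ 2) and **private** (a single lesion) classes.
Getting those classes right requires guarding against caller dropout:
`clonoshed` implements the *rescue* rule (a mutation called in any
lesion is scored present in another lesion when supported by ≥ 3 reads
at base quality ≥ 30 and mapping quality ≥ 60) and a *power filter*
that keeps only loci with ≥ 90% power to detect a clonal variant in
≥ 3 reads in every lesion, given local depth and sample purity.

On top of the presence matrix the package provides:

- **Cancer cell fraction (CCF) estimation** — a posterior over a grid of
  100 CCF values c ∈ (0, 1], with the binomial likelihood of the
  observed alt/total read counts at the expected VAF
  f(c) = αcm / (αq_t + (1 − α)·2), where α is purity (or plasma tumor
  fraction), q_t the local tumor copy number and m the multiplicity.
  Mutations with point CCF ≥ 0.9 are clonal; estimates need ≥ 30×.
- **Copy-number event classes** relative to ploidy ψ (high-level
  amplification ≥ 3ψ, gain ≥ 2ψ, partial deletion < ψ/2, homozygous
  deletion, LOH), copy-number instability (fraction of genome altered),
  whole-genome duplication (> 50% of the genome at even major copy
  number) and mutation-loss detection via LOH.
- **Driver annotation** from a targeted panel, per-cancer-type
  oncogene/TSG lists with recurrent sites, and a census fallback,
  including the low-level-gain rescue for amplified oncogenes.
- **cfDNA detection power** — the minimum supporting read count k* that
  holds the per-locus false-positive probability below 5 × 10⁻⁷ at a
  per-base error of 10⁻³, the power to detect a mutation at a given
  ctDNA CCF, and the minimum CCF detectable at 90% power.
- **Biopsy-subset sampling** — exhaustive enumeration of all C(N, s)
  subsets of s ≤ 5 lesions, reporting mean/sd of detected drivers,
  the fraction of subsets recovering the complete driver set, and how
  often non-truncal drivers masquerade as truncal.
- **ROC truncality thresholds** — the ctDNA CCF threshold nearest the
  (FPR 0, TPR 1) corner for calling truncal mutations from plasma.
- A **synthetic cohort generator** that places mutations on a random
  clone tree across 4–17 lesions per patient, draws binomial read
  counts from purity/copy-number/depth, and mixes lesions into a plasma
  sample with per-lesion shedding weights — so the whole pipeline runs
  with known ground truth and no external data.

## Worked example

```python
import pandas as pd
from clonoshed import SimConfig, simulate_cohort, RunConfig
from clonoshed.pipeline import classify_patient
from clonoshed.cfdna import detect_in_cfdna, ccf_vs_lesions_model
from clonoshed.sampling import roc_truncal_threshold
from clonoshed.variant_matrix import jaccard_similarity

cohort = simulate_cohort(SimConfig(n_patients=3), seed=42)
cfg = RunConfig()
records = []
for patient, tissue in cohort.tissue.groupby("patient"):
    sheet = cohort.sample_sheet[cohort.sample_sheet["patient"] == patient]
    m = classify_patient(tissue, sheet, cfg)
    _, med = jaccard_similarity(m)
    print(patient, m.n_lesions, "lesions", m.class_counts(),
          "median Jaccard %.2f" % med)
    plasma = cohort.plasma[cohort.plasma["patient"] == patient]
    records.append(detect_in_cfdna(m, plasma, 0.3))
rec = pd.concat(records, ignore_index=True)
fit = ccf_vs_lesions_model(rec)
print("slope %.3f CI (%.3f, %.3f)" % (fit["slope"], *fit["slope_ci"]))
usable = rec[rec["tissue_class"].isin(["truncal", "branch", "private"])]
usable = usable.dropna(subset=["ctdna_ccf"])
roc = roc_truncal_threshold(usable["ctdna_ccf"],
                            usable["tissue_class"] == "truncal")
print("AUC %.2f threshold %.2f sens %.2f spec %.2f"
      % (roc.auc, roc.optimal_threshold, roc.sens_at_opt, roc.spec_at_opt))
```

prints

```
P01 5 lesions {'branch': 47, 'truncal': 46, 'private': 29} median Jaccard 0.63
P02 17 lesions {'truncal': 37, 'private': 30, 'branch': 25} median Jaccard 0.77
P03 8 lesions {'truncal': 41, 'private': 36, 'branch': 33} median Jaccard 0.61
slope 0.059 CI (0.048, 0.069)
AUC 0.99 threshold 0.88 sens 0.97 spec 0.99
```

Each patient's powered mutations partition into the three classes; the
median pairwise Jaccard index summarizes how much of a patient's
mutation profile a single lesion would reveal.  Pooling plasma
detection records across patients, the ctDNA CCF of a non-truncal
mutation rises with the number of lesions harboring it (here ~0.06 CCF
per lesion — patients have 5–17 lesions, so the per-lesion increment
varies), and a ctDNA CCF threshold separates truncal from non-truncal
mutations with high specificity on this equally shedding simulation.

The same stages are exposed on the command line:

```sh
clonoshed simulate --seed 1 --outdir cohort/
clonoshed classify --variants cohort/tissue_variants.tsv \
    --samples cohort/sample_sheet.tsv --out classified/
clonoshed run --seed 1 --outdir results/   # full pipeline + manifest
```

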