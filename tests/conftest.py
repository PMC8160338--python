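import numpy as np
import pandas as pd
import pytest

from clonoshed.drivers import DriverRules
from clonoshed.io import RunConfig
from clonoshed.synthetic import SimConfig, simulate_cohort


def make_records(patient, entries):
    """Build a variant-record table from (sample, pos, alt, depth, bq, mq)."""
    rows = []
    for sample, pos, alt_reads, depth, bq, mq in entries:
        rows.append(
            {
                "patient": patient,
                "sample": sample,
                "chrom": "1",
                "pos": pos,
                "ref": "C",
                "alt": "T",
                "gene": f"G{pos}",
                "coding": True,
                "alt_reads": alt_reads,
                "depth": depth,
                "base_quality": bq,
                "map_quality": mq,
            }
        )
    return pd.DataFrame(rows)


def make_sheet(samples, purity=0.6, patient="P01"):
    return pd.DataFrame(
        {
            "sample": samples,
            "patient": patient,
            "lesion": samples,
            "site": "liver",
            "purity": purity,
            "ploidy": 2.0,
            "mean_depth": 117.0,
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Three-patient cohort at study-default noise and depth."""
    return simulate_cohort(SimConfig(n_patients=3), seed=11)


@pytest.fixture(scope="session")
def clean_cohort():
    """Error-free, saturating-depth cohort: classes recoverable exactly."""
    cfg = SimConfig(
        n_patients=3,
        lesions_per_patient=(5, 9),
        per_base_error=0.0,
        tissue_depth_mean=1000.0,
        cfdna_depth_mean=2000.0,
        min_purity=0.4,
    )
    return simulate_cohort(cfg, seed=5)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture()
def toy_rules():
    return DriverRules(
        panel_genes={"PIK3CA", "AKT1", "ESR1", "TP53", "ARID1B", "MYC", "SPEN"},
        roles={
            ("breast", "PIK3CA"): "oncogene",
            ("breast", "AKT1"): "oncogene",
            ("breast", "MYC"): "oncogene",
            ("breast", "TP53"): "tsg",
            ("breast", "ARID1B"): "tsg",
            ("breast", "SPEN"): "tsg",
        },
        recurrent_sites={
            ("breast", "PIK3CA"): {545, 1047},
            ("breast", "AKT1"): {17},
        },
        census_tier1={"ESR1": {"breast"}},
        blacklist={"KMT2C"},
    )
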