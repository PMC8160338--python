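"""File-format adapters: variant tables (VCF 4.2 / TSV), SEG segments,
sample sheets, truth tables and run configuration.

Coordinates are 1-based inclusive throughout (VCF and SEG convention).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "RunConfig",
    "read_variants",
    "write_variants_tsv",
    "write_vcf",
    "read_segments",
    "write_segments",
    "read_sample_sheet",
    "write_sample_sheet",
]

VARIANT_COLUMNS = [
    "patient", "sample", "chrom", "pos", "ref", "alt", "gene", "coding",
    "alt_reads", "depth", "base_quality", "map_quality",
]


@dataclasses.dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with study defaults."""

    seed: int = 0
    outdir: str = "results"
    min_rescue_reads: int = 3
    min_base_quality: float = 30.0
    min_map_quality: float = 60.0
    power_target: float = 0.90
    clonal_ccf: float = 0.9
    tmb_min_depth: int = 30
    tmb_min_vaf: float = 0.01
    cfdna_min_vaf: float = 0.005
    cfdna_fpr: float = 5e-7
    per_base_error: float = 1e-3
    max_subset_size: int = 5
    genome_size: int = 100_000_000
    log_level: str = "INFO"
    simulate: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def read_variants(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a variant table from VCF 4.2 or the flat TSV dialect.

    The dialect is inferred from the extension when not given.  VCF
    records must carry per-sample AD and DP; INFO keys GENE, CODING,
    BQ, MQ and PATIENT populate the annotation columns.
    """
    path = Path(path)
    if dialect is None:
        dialect = "vcf" if path.suffix == ".vcf" else "tsv"
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = set(VARIANT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return df
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf(path: Path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    rows = []
    for i, var in enumerate(vcf, start=1):
        ad = var.format("AD")
        dp = var.format("DP")
        if ad is None or dp is None:
            raise ValueError(
                f"{path}: record {var.CHROM}:{var.POS} lacks AD/DP"
            )
        info = dict(var.INFO)
        for s_idx, sample in enumerate(samples):
            ad_row = ad[s_idx]
            alt_reads = int(ad_row[-1])
            depth = int(dp[s_idx].item() if hasattr(dp[s_idx], "item") else dp[s_idx])
            rows.append(
                {
                    "patient": info.get("PATIENT", ""),
                    "sample": sample,
                    "chrom": var.CHROM,
                    "pos": int(var.POS),
                    "ref": var.REF,
                    "alt": var.ALT[0] if var.ALT else ".",
                    "gene": info.get("GENE", ""),
                    "coding": bool(int(info.get("CODING", 0))),
                    "alt_reads": alt_reads,
                    "depth": depth,
                    "base_quality": float(info.get("BQ", 0.0)),
                    "map_quality": float(info.get("MQ", 0.0)),
                }
            )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_variants_tsv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def write_vcf(records: pd.DataFrame, path: str | Path) -> None:
    """Write one sample's records as minimal VCF 4.2 (FORMAT AD:DP)."""
    samples = records["sample"].unique()
    if len(samples) != 1:
        raise ValueError("write_vcf expects records of a single sample")
    sample = samples[0]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=PATIENT,Number=1,Type=String,Description="Patient id">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CODING,Number=1,Type=Integer,Description="Coding flag">\n')
        fh.write('##INFO=<ID=BQ,Number=1,Type=Float,Description="Median base quality">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Median mapping quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for _, r in records.sort_values(["chrom", "pos"]).iterrows():
            ref_reads = int(r["depth"]) - int(r["alt_reads"])
            info = (
                f"PATIENT={r['patient']};GENE={r['gene']};"
                f"CODING={int(bool(r['coding']))};"
                f"BQ={float(r['base_quality']):g};MQ={float(r['map_quality']):g}"
            )
            fh.write(
                f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t"
                f".\tPASS\t{info}\tAD:DP\t"
                f"{ref_reads},{int(r['alt_reads'])}:{int(r['depth'])}\n"
            )


def read_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "chrom", "start", "end", "major", "minor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_segments(segments: pd.DataFrame, path: str | Path) -> None:
    segments.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "patient", "purity", "ploidy", "mean_depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)


def _jsonify(x):
    import numpy as np

    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
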