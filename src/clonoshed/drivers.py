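"""Functional (driver / resistance) alteration annotation.

A rules engine over three inputs: the targeted-panel gene set, a
cancer-type-specific driver list with gene roles (oncogene vs tumor
suppressor) and known recurrent sites, and a census of established
cancer genes with cancer-type mapping.  A point mutation is functional
when it falls in a panel gene and is either an inactivating mutation in
a listed tumor suppressor, a recurrent-site mutation in a listed
oncogene, or any mutation in a census gene observed in the matching
cancer type.  Genes on a blacklist (alignment-artifact-prone homologs)
are excluded.  Copy-number drivers are high-level amplifications of
oncogenes and homozygous deletions of tumor suppressors, with low-level
oncogene gains promoted to drivers when another lesion of the same
patient carries a high-level amplification of the gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .cna import GAIN, HIGH_AMP, HOMOZYGOUS_DEL

__all__ = [
    "DriverRules",
    "annotate_functional_mutations",
    "annotate_driver_cna",
    "driver_clonality_association",
]

INACTIVATING = frozenset({"nonsense", "frameshift", "splice"})


@dataclass
class DriverRules:
    """Gene lists and per-cancer-type roles driving annotation.

    ``roles`` maps ``(cancer_type, gene) -> 'oncogene' | 'tsg'``;
    ``recurrent_sites`` maps ``(cancer_type, gene)`` to a set of protein
    positions; ``census_tier1`` maps gene -> set of cancer types in
    which it has been observed.
    """

    panel_genes: frozenset
    roles: dict
    recurrent_sites: dict = field(default_factory=dict)
    census_tier1: dict = field(default_factory=dict)
    blacklist: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.panel_genes = frozenset(self.panel_genes)
        self.blacklist = frozenset(self.blacklist)

    @property
    def cancer_types(self) -> set[str]:
        types = {ct for ct, _ in self.roles}
        for cts in self.census_tier1.values():
            types |= set(cts)
        return types

    @classmethod
    def bundled(cls) -> "DriverRules":
        """Small illustrative rules fixture shipped with the package.

        Real analyses should supply their own panel and driver lists;
        this fixture exists so examples and the demo pipeline run out
        of the box.
        """
        data = Path(__file__).parent / "data"
        return cls.from_tsv(
            data / "driver_rules.tsv", blacklist_path=data / "blacklist.tsv"
        )

    @classmethod
    def from_tsv(
        cls,
        rules_path: str | Path,
        panel_path: str | Path | None = None,
        blacklist_path: str | Path | None = None,
    ) -> "DriverRules":
        """Load rules from TSV files.

        The rules file has columns ``gene``, ``cancer_type``, ``role``
        (oncogene/tsg/census), ``recurrent_sites`` (comma-separated
        protein positions, may be empty).  The optional panel file is a
        one-column gene list (default: all rule genes); the optional
        blacklist file likewise.
        """
        df = pd.read_csv(rules_path, sep="\t", dtype=str).fillna("")
        roles: dict = {}
        sites: dict = {}
        census: dict = {}
        for _, row in df.iterrows():
            key = (row["cancer_type"], row["gene"])
            if row["role"] == "census":
                census.setdefault(row["gene"], set()).add(row["cancer_type"])
            else:
                if key in roles and roles[key] != row["role"]:
                    raise ValueError(f"conflicting roles for {key}")
                roles[key] = row["role"]
            if row.get("recurrent_sites"):
                sites.setdefault(key, set()).update(
                    int(p) for p in row["recurrent_sites"].split(",") if p
                )
        if panel_path is not None:
            panel = frozenset(
                pd.read_csv(panel_path, sep="\t", header=None)[0].astype(str)
            )
        else:
            panel = frozenset(g for _, g in roles) | frozenset(census)
        blacklist = frozenset()
        if blacklist_path is not None:
            blacklist = frozenset(
                pd.read_csv(blacklist_path, sep="\t", header=None)[0].astype(str)
            )
        return cls(
            panel_genes=panel,
            roles=roles,
            recurrent_sites=sites,
            census_tier1=census,
            blacklist=blacklist,
        )


def annotate_functional_mutations(
    mutations: pd.DataFrame, rules: DriverRules, cancer_type: str
) -> pd.DataFrame:
    """Flag functional point mutations under the panel-and-list rules.

    ``mutations`` must carry ``gene``, ``consequence`` (missense /
    nonsense / frameshift / splice / silent) and ``protein_pos``
    columns.  Returns the input restricted to functional rows with a
    ``functional_reason`` column.  Annotation is deterministic and
    order-independent.
    """
    if cancer_type not in rules.cancer_types:
        raise ValueError(
            f"unknown cancer type {cancer_type!r}; available: "
            f"{sorted(rules.cancer_types)}"
        )
    reasons = []
    keep = []
    for idx, row in mutations.iterrows():
        gene = row["gene"]
        if gene not in rules.panel_genes or gene in rules.blacklist:
            continue
        role = rules.roles.get((cancer_type, gene))
        reason = None
        if role == "tsg" and row["consequence"] in INACTIVATING:
            reason = "inactivating_in_tsg"
        elif role == "oncogene":
            sites = rules.recurrent_sites.get((cancer_type, gene), set())
            if row.get("protein_pos") in sites:
                reason = "recurrent_site_in_oncogene"
        if reason is None and cancer_type in rules.census_tier1.get(gene, set()):
            if row["consequence"] != "silent":
                reason = "census_tier1"
        if reason is not None:
            keep.append(idx)
            reasons.append(reason)
    out = mutations.loc[keep].copy()
    out["functional_reason"] = reasons
    return out


def annotate_driver_cna(
    events: pd.DataFrame, rules: DriverRules, cancer_type: str
) -> pd.DataFrame:
    """Flag driver copy-number events, with the low-level-gain rescue.

    ``events`` must carry ``patient``, ``sample``, ``gene`` and
    ``event_class`` columns.  High-level amplifications of oncogenes and
    homozygous deletions of tumor suppressors are drivers; an oncogene
    *gain* is promoted to a driver in a lesion when any other lesion of
    the same patient harbors a high-level amplification of that gene.
    """
    rows = []
    for (patient, gene), grp in events.groupby(["patient", "gene"]):
        role = rules.roles.get((cancer_type, gene))
        has_high_amp = (grp["event_class"] == HIGH_AMP).any()
        for _, ev in grp.iterrows():
            reason = None
            if role == "oncogene" and ev["event_class"] == HIGH_AMP:
                reason = "oncogene_high_amp"
            elif role == "tsg" and ev["event_class"] == HOMOZYGOUS_DEL:
                reason = "tsg_homozygous_del"
            elif (
                role == "oncogene"
                and ev["event_class"] == GAIN
                and has_high_amp
            ):
                reason = "oncogene_gain_rescued"
            if reason is not None:
                rows.append({**ev.to_dict(), "functional_reason": reason})
    return pd.DataFrame(
        rows, columns=list(events.columns) + ["functional_reason"]
    )


def driver_clonality_association(
    driver_clonal: pd.Series, nondriver_clonal: pd.Series
) -> dict:
    """Association between driver status and clonality of sSNVs.

    Builds the 2x2 driver x clonal contingency table and returns the
    sample odds ratio (inf when a cell is empty but the association is
    perfect, NaN when undefined), the two-sided Fisher exact p-value and
    the per-group clonal proportions.
    """
    a = int(driver_clonal.sum())
    b = int((~driver_clonal.astype(bool)).sum())
    c = int(nondriver_clonal.sum())
    d = int((~nondriver_clonal.astype(bool)).sum())
    table = [[a, b], [c, d]]
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError("both driver and non-driver groups must be non-empty")
    res = stats.fisher_exact(table, alternative="two-sided")
    if b == 0 or c == 0:
        odds = float("inf") if a > 0 and d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return {
        "table": table,
        "odds_ratio": odds,
        "p_value": float(res.pvalue),
        "prop_driver_clonal": a / (a + b),
        "prop_nondriver_clonal": c / (c + d),
    }
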