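"""Construction of the BDNF prefrontal-cortex gene co-expression network.

The network that anchors the expression-weighted polygenic score is built in
four steps: (1) select mouse genes whose PFC expression correlates with Bdnf
at |r| >= 0.5, (2) map them to human homologs, (3) keep genes whose early-life
(prenatal to early childhood) PFC expression exceeds adult expression by at
least 1.5-fold, and (4) attach genomic intervals extended by a flank so SNPs
can be assigned to network genes.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "GeneNetwork",
    "load_packaged_coexpression",
    "select_coexpressed",
    "map_to_homologs",
    "filter_stage_enrichment",
    "annotate_intervals",
]

DEFAULT_RMIN = 0.5
DEFAULT_FOLD = 1.5
DEFAULT_FLANK = 500


@dataclasses.dataclass(frozen=True)
class GeneNetwork:
    """Per-gene human symbol, co-expression sign and flanked genomic interval.

    ``table`` columns: gene, coexpr_sign (+1/-1), chrom, start, end (1-based,
    inclusive, already extended by ``flank`` and clipped at 1).
    """

    table: pd.DataFrame
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        t = self.table
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if (t["coexpr_sign"] == 0).any():
            raise ValueError("coexpr_sign must be -1 or +1")
        if (t["start"] > t["end"]).any():
            raise ValueError("interval start > end")

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def load_packaged_coexpression() -> pd.DataFrame:
    """Load the packaged mouse-PFC Bdnf co-expression snapshot.

    Columns: gene (symbol as printed in the source table, which includes a
    literal ``NA`` symbol), ensembl, r.
    """
    ref = resources.files("bdnfnet.data") / "coexpression_pfc_bdnf.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False,
                           dtype={"gene": str, "ensembl": str, "r": float})


def select_coexpressed(table: pd.DataFrame, rmin: float = DEFAULT_RMIN) -> pd.DataFrame:
    """Keep genes with |co-expression r| >= ``rmin`` (boundary inclusive).

    Returns a frame with columns gene, r, coexpr_sign ordered by |r|
    descending (ties keep input order).
    """
    if not 0 < rmin <= 1:
        raise ValueError("rmin must be in (0, 1]")
    if table.empty:
        raise ValueError("empty co-expression table")
    if table["r"].abs().gt(1).any():
        raise ValueError("|r| must be <= 1")
    kept = table.loc[table["r"].abs() >= rmin, [c for c in table.columns]].copy()
    kept["coexpr_sign"] = np.sign(kept["r"]).astype(int)
    order = (-kept["r"].abs()).argsort(kind="stable")
    return kept.iloc[order].reset_index(drop=True)


def map_to_homologs(
    genes: pd.DataFrame, homolog_map: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Replace mouse symbols by human homologs; never invent a mapping.

    ``homolog_map`` columns: mouse, human (optionally gene_id).  A mouse gene
    absent from the map is dropped and listed in the report; a mouse gene with
    several human homologs keeps all of them (flagged) — downstream SNP
    assignment guarantees each SNP contributes once.

    Returns (mapped frame with columns gene, coexpr_sign [, r], report dict
    with keys ``unmapped`` and ``multi_mapped``).
    """
    if homolog_map.empty:
        raise ValueError("empty homolog map")
    merged = genes.merge(homolog_map, left_on="gene", right_on="mouse", how="left")
    unmapped = sorted(merged.loc[merged["human"].isna(), "gene"].unique())
    mapped = merged.dropna(subset=["human"]).copy()
    counts = mapped.groupby("gene")["human"].nunique()
    multi = sorted(counts[counts > 1].index)
    out_cols = {"gene": mapped["human"], "coexpr_sign": mapped["coexpr_sign"]}
    if "r" in mapped.columns:
        out_cols["r"] = mapped["r"]
    if "gene_id" in mapped.columns:
        out_cols["gene_id"] = mapped["gene_id"]
    out = pd.DataFrame(out_cols).reset_index(drop=True)
    report = {"unmapped": unmapped, "multi_mapped": multi,
              "n_in": int(len(genes)), "n_out": int(len(out))}
    return out, report


def filter_stage_enrichment(
    genes: pd.DataFrame,
    stage_table: pd.DataFrame,
    early_stages: set[str] | None = None,
    adult_stage: str = "adult",
    fold: float = DEFAULT_FOLD,
) -> tuple[pd.DataFrame, dict]:
    """Keep genes enriched in early development relative to adult samples.

    A gene is retained iff mean(expression over ``early_stages``) divided by
    its adult expression is >= ``fold`` (boundary inclusive).  ``stage_table``
    columns: gene, stage, value.  When ``early_stages`` is None every stage
    except ``adult_stage`` counts as early.  A gene with adult expression 0 is
    retained and flagged as infinite fold.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    stages = set(stage_table["stage"])
    if adult_stage not in stages:
        raise ValueError(f"stage table lacks the {adult_stage!r} stage")
    if early_stages is None:
        early_stages = stages - {adult_stage}
    early = (
        stage_table[stage_table["stage"].isin(early_stages)]
        .groupby("gene")["value"].mean()
    )
    adult = stage_table[stage_table["stage"] == adult_stage].set_index("gene")["value"]
    keep, infinite = [], []
    for g in genes["gene"]:
        if g not in early.index or g not in adult.index:
            continue
        if adult[g] == 0:
            keep.append(g)
            infinite.append(g)
        elif early[g] / adult[g] >= fold:
            keep.append(g)
    out = genes[genes["gene"].isin(keep)].reset_index(drop=True)
    report = {"n_in": int(len(genes)), "n_out": int(len(out)),
              "infinite_fold": infinite}
    return out, report


def annotate_intervals(
    genes: pd.DataFrame, annotation: pd.DataFrame, flank: int = DEFAULT_FLANK
) -> GeneNetwork:
    """Attach [start - flank, end + flank] intervals (1-based, clipped at 1).

    ``annotation`` columns: gene, chrom, start, end.  A network gene missing
    from the annotation is an error.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    ann = annotation.set_index("gene")
    missing = [g for g in genes["gene"] if g not in ann.index]
    if missing:
        raise KeyError(f"genes missing coordinates: {missing}")
    rows = []
    for _, rec in genes.iterrows():
        a = ann.loc[rec["gene"]]
        rows.append({
            "gene": rec["gene"],
            "coexpr_sign": int(rec["coexpr_sign"]),
            "chrom": str(a["chrom"]),
            "start": max(1, int(a["start"]) - flank),
            "end": int(a["end"]) + flank,
        })
    return GeneNetwork(table=pd.DataFrame(rows), flank=flank)
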