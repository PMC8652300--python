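"""Expression-weighted polygenic scoring (ePRS) over a gene network.

The score for a sample is the sum over retained SNPs of

    dosage x eQTL slope x sign(co-expression with BDNF)

so that higher scores proxy higher predicted expression of the network genes.
This module provides the genotype QC filters (call rate, minor allele
frequency, Hardy-Weinberg exact test), SNP-to-network assignment with a
+/- 500 bp gene flank, greedy LD clumping, the scoring itself, and the
population-stratification PCA used to derive ancestry covariates.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix
from .network import GeneNetwork

__all__ = [
    "QCReport",
    "PCResult",
    "hwe_exact_test",
    "qc_genotypes",
    "assign_snps",
    "ld_clump",
    "compute_eprs",
    "stratification_pca",
]

WEIGHT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele",
                  "gene", "slope", "assoc_p", "coexpr_sign"]


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test (heterozygote enumeration).

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts that are no more probable than the observed one.
    Monomorphic sites return 1.0 by convention.  Uses the stable probability
    recurrence over possible heterozygote counts.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("need at least one genotype")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # het counts share the parity of the rare-allele count
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downward recurrence: P(h-2)/P(h) = h(h-1) / ((r-h+2)/2 * (c-h+2)/2) ... inverted
    h, common = mid, 2 * n - n_rare
    while h >= 2:
        rare_hom = (n_rare - h) // 2
        common_hom = (common - h) // 2
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (rare_hom + 1) * (common_hom + 1))
        h -= 2
    h = mid
    while h + 2 <= min(n_rare, common):
        rare_hom = (n_rare - h) // 2
        common_hom = (common - h) // 2
        probs[h + 2] = probs[h] * 4.0 * rare_hom * common_hom / ((h + 2) * (h + 1))
        h += 2
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Genotype QC
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class QCReport:
    n_samples_in: int
    n_variants_in: int
    samples_removed_call_rate: int = 0
    variants_removed_call_rate: int = 0
    variants_removed_maf: int = 0
    variants_removed_hwe: int = 0
    thresholds: dict = dataclasses.field(default_factory=dict)

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.samples_removed_call_rate

    @property
    def n_variants_out(self) -> int:
        return (self.n_variants_in - self.variants_removed_call_rate
                - self.variants_removed_maf - self.variants_removed_hwe)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_samples_out"] = self.n_samples_out
        d["n_variants_out"] = self.n_variants_out
        return d


def qc_genotypes(
    G: GenotypeMatrix,
    snp_call_rate: float = 0.95,
    hwe_floor: float = 1e-40,
    maf_min: float = 0.05,
    sample_call_rate: float = 0.90,
) -> tuple[GenotypeMatrix, QCReport]:
    """Standard genotype QC in the order samples -> SNP call rate -> MAF -> HWE.

    Removal rules (boundaries follow the thresholds' phrasing): samples with
    call rate < ``sample_call_rate``; variants with call rate <
    ``snp_call_rate``; variants with MAF < ``maf_min`` (MAF exactly at the
    threshold is kept); variants with HWE exact p < ``hwe_floor``.
    """
    if G.n_variants == 0 or G.n_samples == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(
        G.n_samples, G.n_variants,
        thresholds={"snp_call_rate": snp_call_rate, "hwe_floor": hwe_floor,
                    "maf_min": maf_min, "sample_call_rate": sample_call_rate},
    )
    obs = G.dosage != MISSING

    keep_s = obs.mean(axis=1) >= sample_call_rate
    report.samples_removed_call_rate = int((~keep_s).sum())
    G = G.subset(sample_idx=np.flatnonzero(keep_s))
    obs = G.dosage != MISSING

    keep_v = obs.mean(axis=0) >= snp_call_rate
    report.variants_removed_call_rate = int((~keep_v).sum())
    G = G.subset(variant_idx=np.flatnonzero(keep_v))

    p = G.effect_allele_freq()
    maf = np.minimum(p, 1 - p)
    keep_v = maf >= maf_min
    report.variants_removed_maf = int((~keep_v).sum())
    G = G.subset(variant_idx=np.flatnonzero(keep_v))

    keep = []
    for j in range(G.n_variants):
        col = G.dosage[:, j]
        col = col[col != MISSING]
        pval = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                              int((col == 2).sum()))
        keep.append(pval >= hwe_floor)
    keep = np.asarray(keep, dtype=bool)
    report.variants_removed_hwe = int((~keep).sum())
    G = G.subset(variant_idx=np.flatnonzero(keep))

    if G.n_variants == 0:
        raise ValueError("empty after QC")
    return G, report


# ---------------------------------------------------------------------------
# SNP-to-network assignment
# ---------------------------------------------------------------------------

def assign_snps(
    G: GenotypeMatrix, network: GeneNetwork, weights_ref: pd.DataFrame
) -> pd.DataFrame:
    """Build the weight table for SNPs falling inside flanked network genes.

    ``weights_ref`` has one row per (SNP, gene): id, gene, effect_allele,
    slope, assoc_p.  A SNP inside several (overlapping) gene intervals is
    attached to the gene with the smallest assoc_p among its reference rows,
    so each SNP appears exactly once.  SNPs outside every interval, or with
    no reference weight for any overlapping gene, are excluded.
    """
    net = network.table
    ref = weights_ref.set_index(["id", "gene"])
    sign_of = dict(zip(net["gene"], net["coexpr_sign"]))
    rows = []
    for v in G.variants:
        hits = net[(net["chrom"] == v.chrom)
                   & (net["start"] <= v.pos) & (v.pos <= net["end"])]
        candidates = []
        for g in hits["gene"]:
            if (v.id, g) in ref.index:
                w = ref.loc[(v.id, g)]
                candidates.append((float(w["assoc_p"]), g, w))
        if not candidates:
            continue
        candidates.sort(key=lambda t: (t[0], t[1]))
        assoc_p, gene, w = candidates[0]
        rows.append({
            "id": v.id, "chrom": v.chrom, "pos": v.pos,
            "effect_allele": w.get("effect_allele", v.effect_allele),
            "other_allele": v.other_allele, "gene": gene,
            "slope": float(w["slope"]), "assoc_p": assoc_p,
            "coexpr_sign": int(sign_of[gene]),
        })
    return pd.DataFrame(rows, columns=WEIGHT_COLUMNS)


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation over samples with both calls present."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok].astype(float), b[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def ld_clump(
    G: GenotypeMatrix,
    table: pd.DataFrame,
    r2_max: float = 0.2,
    window: int = 500_000,
) -> pd.DataFrame:
    """Greedy LD clumping keeping the most-associated independent SNPs.

    Rank rows by assoc_p ascending (ties: position, then id); repeatedly take
    the best remaining SNP as index and discard remaining SNPs on the same
    chromosome within ``window`` bp whose dosage r-squared with the index
    exceeds ``r2_max``.  The result is independent of input row order.
    """
    if table.empty:
        return table.copy()
    col = {v.id: j for j, v in enumerate(G.variants)}
    missing_ids = [i for i in table["id"] if i not in col]
    if missing_ids:
        raise KeyError(f"weight-table SNPs absent from genotypes: {missing_ids}")
    ranked = table.sort_values(["assoc_p", "pos", "id"], kind="stable").reset_index(drop=True)
    alive = np.ones(len(ranked), dtype=bool)
    kept_idx = []
    for i in range(len(ranked)):
        if not alive[i]:
            continue
        kept_idx.append(i)
        idx = ranked.iloc[i]
        gi = G.dosage[:, col[idx["id"]]]
        for j in range(i + 1, len(ranked)):
            if not alive[j]:
                continue
            row = ranked.iloc[j]
            if row["chrom"] != idx["chrom"] or abs(int(row["pos"]) - int(idx["pos"])) > window:
                continue
            if _dosage_r2(gi, G.dosage[:, col[row["id"]]]) > r2_max:
                alive[j] = False
    return ranked.iloc[kept_idx].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def compute_eprs(
    G: GenotypeMatrix, table: pd.DataFrame, standardize: bool = True
) -> pd.DataFrame:
    """Weighted allele sum: score = sum(dosage * slope * coexpr_sign).

    Effect alleles are harmonized against the weight table: when the table's
    effect allele is the genotype matrix's other allele the dosage is flipped
    (2 - d); any other mismatch is an error.  Missing dosages are mean-imputed
    as twice the effect-allele frequency.  Returns a frame with sample_id,
    eprs and (optionally) the within-dataset z-standardized eprs_z.
    """
    by_id = {v.id: j for j, v in enumerate(G.variants)}
    absent = [i for i in table["id"] if i not in by_id]
    if absent:
        raise KeyError(f"weight-table SNPs absent from genotypes: {absent}")
    afreq = G.effect_allele_freq()
    score = np.zeros(G.n_samples)
    for row in table.itertuples():
        j = by_id[row.id]
        v = G.variants[j]
        d = G.dosage[:, j].astype(float)
        f = afreq[j]
        if row.effect_allele == v.effect_allele:
            pass
        elif row.effect_allele == v.other_allele:
            obs = d != MISSING
            d[obs] = 2 - d[obs]
            f = 1 - f
        else:
            raise ValueError(f"{row.id}: weight-table alleles do not match genotypes")
        d[d == MISSING] = 2 * f
        score += d * row.slope * row.coexpr_sign
    out = pd.DataFrame({"sample_id": G.sample_ids, "eprs": score})
    if standardize:
        sd = score.std(ddof=1)
        out["eprs_z"] = (score - score.mean()) / sd if sd > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# Population-stratification PCA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PCResult:
    scores: np.ndarray       # (n_samples, k)
    eigenvalues: np.ndarray  # (k,)
    kept_variants: list[str]
    params: dict


def _prune_ld(G: GenotypeMatrix, r2: float, window_bp: int, step: int) -> np.ndarray:
    """PLINK-style sliding-window pairwise pruning; returns kept column indices."""
    keep = np.ones(G.n_variants, dtype=bool)
    order = np.lexsort(([v.pos for v in G.variants], [v.chrom for v in G.variants]))
    by_chrom: dict[str, list[int]] = {}
    for j in order:
        by_chrom.setdefault(G.variants[j].chrom, []).append(j)
    for cols in by_chrom.values():
        start = 0
        while start < len(cols):
            base_pos = G.variants[cols[start]].pos
            win = [j for j in cols[start:]
                   if G.variants[j].pos - base_pos <= window_bp]
            for a in range(len(win)):
                if not keep[win[a]]:
                    continue
                for b in range(a + 1, len(win)):
                    if not keep[win[b]]:
                        continue
                    if _dosage_r2(G.dosage[:, win[a]], G.dosage[:, win[b]]) >= r2:
                        keep[win[b]] = False
            start += step
    return np.flatnonzero(keep)


def stratification_pca(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    prune_r2: float = 0.20,
    window_kb: int = 50,
    step: int = 5,
    k: int = 3,
) -> PCResult:
    """Ancestry PCA on LD-pruned common variants.

    Keeps variants with MAF > ``maf_min``, prunes pairs with r2 >=
    ``prune_r2`` in a sliding window (``window_kb`` kb, increment ``step``
    SNPs), then runs PCA on dosages centered by 2p and scaled by
    sqrt(2p(1-p)); missing dosages contribute 0 after centering.
    """
    if G.n_samples < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} components")
    p = G.effect_allele_freq()
    maf = np.minimum(p, 1 - p)
    common = np.flatnonzero(maf > maf_min)
    Gc = G.subset(variant_idx=common)
    kept = _prune_ld(Gc, prune_r2, window_kb * 1000, step)
    Gp = Gc.subset(variant_idx=kept)

    p = Gp.effect_allele_freq()
    denom = np.sqrt(2 * p * (1 - p))
    denom[denom == 0] = 1.0
    X = Gp.dosage.astype(float)
    X[X == MISSING] = np.nan
    X = (X - 2 * p) / denom
    X = np.nan_to_num(X, nan=0.0)

    U, S, _ = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    eigvals = (S ** 2) / (Gp.n_samples - 1)
    return PCResult(
        scores=U[:, :k] * S[:k],
        eigenvalues=eigvals[:k],
        kept_variants=Gp.variant_ids(),
        params={"maf_min": maf_min, "prune_r2": prune_r2,
                "window_kb": window_kb, "step": step, "k": k},
    )
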