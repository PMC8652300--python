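"""Synthetic cohort generators with stored ground truth.

Every pipeline input can be generated with the statistical structure the
analyses assume: LD-structured diploid genotypes, reference tables for the
co-expression network (correlations straddling the 0.5 cut, fold-changes
straddling 1.5, eQTL slopes and association p-values), Rasch item responses
over an overlapping common-item form design, longitudinal cognitive
trajectories from the published fixed-effect column with per-child random
age terms and AR(1) residuals, prenatal adversity indicators, and
two-modality fusion matrices with a planted linked loading pair.

All generators are pure functions of (spec, seed); each returns its ground
truth so recovery tests never re-derive it from the generated data.  Default
sizes mirror the study design: 157 children at 6/12/18/36 months with a
47-child imaging subsample splitting 23/24 on adversity.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .genio import GenotypeMatrix, SNPRecord, VoxelMatrix
from .irt import ResponseMatrix

__all__ = [
    "TABLE_BETA", "GenotypeSpec", "NetworkSpec", "GrowthSpec", "IRTSpec",
    "AdversitySpec", "FusionSpec", "SimulationSpec",
    "gen_genotypes", "gen_reference_tables", "gen_bayley_responses",
    "gen_cohort", "gen_adversity_records", "gen_fusion_data",
]

# Generating fixed effects for the growth model (published coefficient column).
TABLE_BETA = {
    "intercept": -12.65,
    "eprs": -3.19,
    "adversity": 0.31,
    "eprs_x_adversity": 1.73,
    "age": 10.60,
    "eprs_x_age": 0.17,
    "adversity_x_age": -0.14,
    "eprs_x_adversity_x_age": -0.12,
    "age_sq": -0.07,
    "sex_female": 1.87,
    "pc1": -34.50,
    "pc2": 21.31,
    "pc3": -8.11,
}


@dataclasses.dataclass
class GenotypeSpec:
    n_snps: int = 300
    block_size: int = 10
    rho: float = 0.85               # latent AR(1) correlation within LD blocks
    maf_range: tuple = (0.05, 0.5)


@dataclasses.dataclass
class NetworkSpec:
    n_genes: int = 60
    n_coexpressed: int = 46         # planted genes with |r| >= 0.5
    r_pass_range: tuple = (0.5, 0.85)
    r_fail_range: tuple = (0.1, 0.49)
    neg_fraction: float = 0.25
    n_enriched: int = 46            # planted genes with early/adult fold >= 1.5
    fold_pass_range: tuple = (1.5, 4.0)
    fold_fail_range: tuple = (0.5, 1.45)
    gene_length: int = 20_000
    flank: int = 500
    snps_per_gene: int = 4
    n_decoy_snps: int = 60
    slope_sd: float = 0.3


@dataclasses.dataclass
class GrowthSpec:
    beta: dict = dataclasses.field(default_factory=lambda: dict(TABLE_BETA))
    sd_age: float = 0.5             # per-child random age-slope SD (points/month)
    sd_age2: float = 0.012          # per-child random age^2-slope SD
    re_corr: float = -0.2
    phi: float = 0.3                # AR(1) residual correlation across visits
    sigma: float = 8.0              # residual SD (scaled-score points)
    pc_sd: float = 0.01


@dataclasses.dataclass
class IRTSpec:
    items_per_form: int = 12
    n_common: int = 3               # items shared between adjacent forms
    b_spread: float = 1.2           # within-form difficulty spread (logits)
    form_step: float = 1.5          # difficulty shift between adjacent forms


@dataclasses.dataclass
class AdversitySpec:
    # per-indicator prevalences; the implied total has mean ~1.3 like the cohort
    prevalences: dict = dataclasses.field(default_factory=lambda: {
        "money": 0.10, "depression": 0.12, "anxiety": 0.15, "abuse": 0.05,
        "marital_strain": 0.15, "health": 0.25, "smoking": 0.11,
        "gestational_age": 0.08, "birth_size": 0.12, "income": 0.17,
    })


@dataclasses.dataclass
class FusionSpec:
    n_subjects: int = 47
    k1: int = 2
    k2: int = 2
    n_features1: int = 200
    vol_shape: tuple = (8, 8, 8)
    active_per_component: int = 10
    rho: float = 0.6                # planted linked-pair loading correlation
    snr: float = 5.0                # signal variance / noise variance


@dataclasses.dataclass
class SimulationSpec:
    seed: int = 0
    n_children: int = 157
    visit_ages: tuple = (6, 12, 18, 36)
    n_imaging: int = 47
    genotype: GenotypeSpec = dataclasses.field(default_factory=GenotypeSpec)
    network: NetworkSpec = dataclasses.field(default_factory=NetworkSpec)
    growth: GrowthSpec = dataclasses.field(default_factory=GrowthSpec)
    irt: IRTSpec = dataclasses.field(default_factory=IRTSpec)
    adversity: AdversitySpec = dataclasses.field(default_factory=AdversitySpec)
    fusion: FusionSpec = dataclasses.field(default_factory=FusionSpec)


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *tags])


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def gen_genotypes(
    spec: GenotypeSpec,
    n_samples: int,
    seed: int,
    variants: list[SNPRecord] | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """LD-structured diploid genotypes via a thresholded latent AR(1) process.

    Haplotypes within a block come from a stationary AR(1) Gaussian
    (correlation ``rho`` between adjacent SNPs) dichotomized at the
    allele-frequency quantile, so dosage r^2 decays with index distance.
    Returns the matrix and the target effect-allele frequencies.
    """
    rng = _rng(seed, 11)
    if variants is None:
        variants = [
            SNPRecord(f"rs{j:05d}", str(1 + j // 1000), 1000 + 2000 * (j % 1000),
                      "A", "G")
            for j in range(spec.n_snps)
        ]
    m = len(variants)
    freqs = rng.uniform(*spec.maf_range, size=m)
    thresholds = norm.ppf(freqs)
    haps = np.empty((2, n_samples, m))
    for h in range(2):
        z = np.empty((n_samples, m))
        for j in range(m):
            if j % spec.block_size == 0:
                z[:, j] = rng.standard_normal(n_samples)
            else:
                z[:, j] = (spec.rho * z[:, j - 1]
                           + np.sqrt(1 - spec.rho ** 2) * rng.standard_normal(n_samples))
        haps[h] = z < thresholds
    dosage = (haps[0] + haps[1]).astype(np.int8)
    G = GenotypeMatrix([f"S{i:04d}" for i in range(n_samples)], list(variants), dosage)
    return G, {"target_freq": freqs, "block_size": spec.block_size, "rho": spec.rho}


# ---------------------------------------------------------------------------
# Reference tables for the network and score
# ---------------------------------------------------------------------------

def gen_reference_tables(spec: NetworkSpec, seed: int) -> dict:
    """Co-expression, homolog, stage-expression, annotation and eQTL-weight
    tables, plus the variant plan placing SNPs inside gene flanks or decoys.

    Planted structure (recorded in ``truth``): exactly ``n_coexpressed``
    genes pass the |r| >= 0.5 filter, ``n_enriched`` of those pass the
    1.5-fold early-enrichment filter, and ``n_decoy_snps`` variants lie
    outside every flanked interval.
    """
    rng = _rng(seed, 23)
    n = spec.n_genes
    mouse = [f"Gm{i:03d}" for i in range(n)]
    human = [f"GENE{i:03d}" for i in range(n)]
    pass_idx = np.arange(spec.n_coexpressed)
    r = np.empty(n)
    r[pass_idx] = rng.uniform(*spec.r_pass_range, size=len(pass_idx))
    r[spec.n_coexpressed:] = rng.uniform(*spec.r_fail_range,
                                         size=n - spec.n_coexpressed)
    neg = rng.random(n) < spec.neg_fraction
    r = np.where(neg, -r, r)
    coexpr = pd.DataFrame({"gene": mouse, "r": np.round(r, 3)})
    homolog = pd.DataFrame({"mouse": mouse, "human": human,
                            "gene_id": [f"ENSG{i:05d}" for i in range(n)]})

    # stage expression: enriched genes pass the early/adult fold cut
    enr_idx = set(rng.choice(pass_idx, size=spec.n_enriched, replace=False)
                  if spec.n_enriched < spec.n_coexpressed else pass_idx)
    rows = []
    folds = np.empty(n)
    for i in range(n):
        adult = rng.uniform(1.0, 5.0)
        fold = (rng.uniform(*spec.fold_pass_range) if i in enr_idx
                else rng.uniform(*spec.fold_fail_range))
        folds[i] = fold
        early = adult * fold
        rows += [{"gene": human[i], "stage": "early_prenatal", "value": early * rng.uniform(0.9, 1.1)},
                 {"gene": human[i], "stage": "early_childhood", "value": early * rng.uniform(0.9, 1.1)},
                 {"gene": human[i], "stage": "adult", "value": adult}]
    stage = pd.DataFrame(rows)
    # regenerate so the mean over the two early stages hits the planted fold
    piv = stage.pivot(index="gene", columns="stage", values="value")
    scale = folds[[human.index(g) for g in piv.index]] * piv["adult"] \
        / piv[["early_prenatal", "early_childhood"]].mean(axis=1)
    piv["early_prenatal"] *= scale
    piv["early_childhood"] *= scale
    stage = piv.reset_index().melt(id_vars="gene", var_name="stage", value_name="value")

    # non-overlapping gene intervals, round-robin over chromosomes
    ann_rows, variant_plan, weight_rows = [], [], []
    snp_no = 0
    for i in range(n):
        chrom = str(1 + i % 4)
        start = 1_000_000 + (i // 4) * 3_000_000
        end = start + spec.gene_length
        ann_rows.append({"gene": human[i], "chrom": chrom, "start": start, "end": end})
        offsets = np.linspace(-spec.flank, spec.gene_length + spec.flank,
                              spec.snps_per_gene).astype(int)
        for off in offsets:
            vid = f"rs{snp_no:05d}"
            snp_no += 1
            variant_plan.append(SNPRecord(vid, chrom, start + int(off), "A", "G"))
            weight_rows.append({
                "id": vid, "gene": human[i], "effect_allele": "A",
                "slope": float(rng.normal(0, spec.slope_sd)),
                "assoc_p": float(10 ** -rng.uniform(0.3, 8)
                                 if rng.random() < 0.3 else rng.uniform(0.05, 1.0)),
            })
    decoys = []
    for d in range(spec.n_decoy_snps):
        vid = f"rs{snp_no:05d}"
        snp_no += 1
        chrom = str(1 + d % 4)
        pos = 500_000_000 + d * 10_000
        decoys.append(vid)
        variant_plan.append(SNPRecord(vid, chrom, pos, "A", "G"))
    annotation = pd.DataFrame(ann_rows)
    weights_ref = pd.DataFrame(weight_rows)
    truth = {
        "n_coexpressed": int(spec.n_coexpressed),
        "coexpressed_mouse": [mouse[i] for i in pass_idx],
        "coexpr_signs": {mouse[i]: int(np.sign(r[i])) for i in range(n)},
        "n_enriched": int(len(enr_idx)),
        "enriched_human": sorted(human[i] for i in enr_idx),
        "decoy_snps": decoys,
        "folds": {human[i]: float(folds[i]) for i in range(n)},
    }
    return {"coexpression": coexpr, "homolog": homolog, "stage_expression": stage,
            "annotation": annotation, "weights_ref": weights_ref,
            "variant_plan": variant_plan, "truth": truth}


# ---------------------------------------------------------------------------
# Item responses
# ---------------------------------------------------------------------------

def gen_bayley_responses(
    spec: IRTSpec,
    abilities: np.ndarray,
    person_forms: Sequence[int],
    seed: int,
) -> tuple[ResponseMatrix, dict]:
    """Bernoulli Rasch responses over linked age forms.

    Form f spans items [f * (items_per_form - n_common),
    ... + items_per_form); consecutive forms therefore share ``n_common``
    items with a single shared difficulty, which is what permits concurrent
    vertical scaling.  ``abilities`` is theta per person (one row per
    person-visit); ``person_forms`` maps each person to a form index.
    """
    if spec.n_common < 1:
        raise ValueError("adjacent forms must share at least one item")
    rng = _rng(seed, 31)
    person_forms = np.asarray(person_forms)
    n_forms = int(person_forms.max()) + 1
    step = spec.items_per_form - spec.n_common
    n_items = n_forms * step + spec.n_common
    centers = (np.arange(n_forms) - (n_forms - 1) / 2) * spec.form_step
    b = np.empty(n_items)
    item_forms: dict[str, set] = {}
    for f in range(n_forms):
        sl = slice(f * step, f * step + spec.items_per_form)
        idx = np.arange(n_items)[sl]
        for j in idx:
            item_forms.setdefault(f"I{j:03d}", set()).add(f)
    # one difficulty per item, spread around the mean of the form centers it serves
    for j in range(n_items):
        forms_j = sorted(item_forms[f"I{j:03d}"])
        b[j] = np.mean(centers[forms_j]) + spec.b_spread * ((j % 7) / 3.0 - 1.0)
    b -= b.mean()

    theta = np.asarray(abilities, dtype=float)
    resp = np.full((len(theta), n_items), np.nan)
    for p, f in enumerate(person_forms):
        idx = np.arange(f * step, f * step + spec.items_per_form)
        pr = expit(theta[p] - b[idx])
        resp[p, idx] = (rng.random(len(idx)) < pr).astype(float)
    R = ResponseMatrix(
        person_ids=[f"P{p:04d}" for p in range(len(theta))],
        item_ids=[f"I{j:03d}" for j in range(n_items)],
        responses=resp,
        person_form=list(person_forms),
        item_forms=item_forms,
    )
    truth = {"b": b, "theta": theta,
             "common_items": sorted(i for i, fs in item_forms.items() if len(fs) > 1)}
    return R, truth


# ---------------------------------------------------------------------------
# Longitudinal cohort
# ---------------------------------------------------------------------------

def gen_cohort(spec: SimulationSpec, seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Longitudinal outcomes from the published fixed effects.

    Per child: standardized ePRS and adversity draws, balanced sex,
    small-variance PCs; outcome = fixed-effect linear predictor + correlated
    random age/age^2 slopes + AR(1) residuals over the ordered visits.  The
    ground truth records the generating coefficients, the per-child random
    effects, and a 47-child imaging subsample whose continuous adversity
    latent splits 23 high / 24 low at the median.
    """
    from .growth import FIXED_TERMS, design_matrix

    seed = spec.seed if seed is None else seed
    g = spec.growth
    rng = _rng(seed, 41)
    n, ages = spec.n_children, np.asarray(spec.visit_ages, float)
    eprs = rng.standard_normal(n)
    adversity = rng.standard_normal(n)
    sex = np.array(["female", "male"] * ((n + 1) // 2))[:n]
    rng.shuffle(sex)
    pcs = rng.normal(0, g.pc_sd, size=(n, 3))

    cov = np.array([
        [g.sd_age ** 2, g.re_corr * g.sd_age * g.sd_age2],
        [g.re_corr * g.sd_age * g.sd_age2, g.sd_age2 ** 2],
    ])
    u = rng.multivariate_normal(np.zeros(2), cov, size=n)

    nv = len(ages)
    eps = np.empty((n, nv))
    eps[:, 0] = rng.standard_normal(n)
    for t in range(1, nv):
        eps[:, t] = g.phi * eps[:, t - 1] + np.sqrt(1 - g.phi ** 2) * rng.standard_normal(n)
    eps *= g.sigma

    rows = []
    for i in range(n):
        for t, a in enumerate(ages):
            rows.append({"child_id": f"C{i:04d}", "age": a, "eprs_z": eprs[i],
                         "adversity_z": adversity[i], "sex": sex[i],
                         "pc1": pcs[i, 0], "pc2": pcs[i, 1], "pc3": pcs[i, 2]})
    data = pd.DataFrame(rows)
    beta = np.array([g.beta[t] for t in FIXED_TERMS])
    mu = design_matrix(data) @ beta
    re = np.repeat(u[:, 0], nv) * data["age"].to_numpy() \
        + np.repeat(u[:, 1], nv) * data["age"].to_numpy() ** 2
    data["cognition"] = mu + re + eps.ravel()

    img_idx = np.sort(rng.choice(n, size=min(spec.n_imaging, n), replace=False))
    truth = {
        "beta": dict(g.beta), "random_effects": u,
        "sd_age": g.sd_age, "sd_age2": g.sd_age2, "phi": g.phi, "sigma": g.sigma,
        "imaging_children": [f"C{i:04d}" for i in img_idx],
        "imaging_adversity": adversity[img_idx],
    }
    return data, truth


def gen_adversity_records(spec: AdversitySpec, n: int, seed: int) -> tuple[pd.DataFrame, dict]:
    """Raw prenatal indicator fields whose rubric totals match planted draws.

    Each indicator is an independent Bernoulli draw; field values are then
    placed on the met/unmet side of the rubric threshold accordingly.
    """
    rng = _rng(seed, 43)
    prev = spec.prevalences
    flags = {k: rng.random(n) < p for k, p in prev.items()}
    tab = pd.DataFrame({
        "subject_id": [f"C{i:04d}" for i in range(n)],
        "money_hassles": np.where(flags["money"], rng.uniform(10, 20, n), rng.uniform(0, 9, n)),
        "cesd": np.where(flags["depression"], rng.uniform(23, 50, n), rng.uniform(0, 22, n)),
        "stai": np.where(flags["anxiety"], rng.uniform(2.0, 4.0, n), rng.uniform(1.0, 1.95, n)),
        "abuse_present": flags["abuse"].astype(int),
        "marital_strain": np.where(flags["marital_strain"], rng.uniform(1.0, 2.89, n),
                                   rng.uniform(2.9, 4.0, n)),
        "diabetes": (flags["health"] & (rng.random(n) < 0.5)).astype(int),
        "hypertension": (flags["health"] & (rng.random(n) < 0.5)).astype(int),
        "smoking": flags["smoking"].astype(int),
        "gestational_age": np.where(flags["gestational_age"], rng.uniform(30, 37, n),
                                    rng.uniform(37.5, 42, n)),
        "birth_percentile": np.where(flags["birth_size"],
                                     np.where(rng.random(n) < 0.5,
                                              rng.uniform(0, 9.9, n), rng.uniform(90.1, 100, n)),
                                     rng.uniform(15, 85, n)),
        "income": np.where(flags["income"], rng.uniform(5_000, 29_999, n),
                           rng.uniform(30_000, 120_000, n)),
    })
    # health flag may miss when both sampled conditions came up false
    tab.loc[flags["health"] & (tab["diabetes"] + tab["hypertension"] == 0), "diabetes"] = 1
    totals = np.sum([v.astype(int) for v in flags.values()], axis=0)
    return tab, {"indicator_draws": flags, "totals": totals}


# ---------------------------------------------------------------------------
# Fusion data
# ---------------------------------------------------------------------------

def gen_fusion_data(spec: FusionSpec, seed: int) -> tuple[np.ndarray, VoxelMatrix, dict]:
    """Two subject-aligned modalities with one planted linked loading pair.

    Sources are sparse spike patterns (a handful of large-weight features per
    component over a small Gaussian background); loadings are Gaussian with
    component 0 of modality 2 correlated at ``rho`` with component 0 of
    modality 1.  Noise is scaled so var(signal)/var(noise) = ``snr``.  The
    voxel modality is laid out in a 3-D mask.
    """
    rng = _rng(seed, 53)
    n = spec.n_subjects
    vol_shape = tuple(spec.vol_shape)
    mask = np.zeros(vol_shape, dtype=bool)
    mask[1:-1, 1:-1, 1:-1] = True
    m2 = int(mask.sum())
    m1 = spec.n_features1

    def sources(k, m):
        S = rng.normal(0, 0.25, size=(k, m))
        active = []
        for c in range(k):
            idx = rng.choice(m, size=spec.active_per_component, replace=False)
            S[c, idx] += rng.choice([-1, 1], size=len(idx)) * rng.uniform(3.5, 5.0, len(idx))
            active.append(np.sort(idx))
        return S, active

    S1, act1 = sources(spec.k1, m1)
    S2, act2 = sources(spec.k2, m2)
    A1 = rng.standard_normal((n, spec.k1))
    A2 = rng.standard_normal((n, spec.k2))
    # plant the linked pair at *exactly* the requested sample correlation:
    # residualize the noise against the linked column before mixing
    a1 = (A1[:, 0] - A1[:, 0].mean()) / A1[:, 0].std()
    e = rng.standard_normal(n)
    e -= e.mean()
    e -= a1 * (e @ a1) / (a1 @ a1)
    e /= e.std()
    A2[:, 0] = spec.rho * a1 + np.sqrt(1 - spec.rho ** 2) * e

    def assemble(A, S):
        sig = A @ S
        noise_sd = np.sqrt(sig.var() / spec.snr)
        return sig + rng.normal(0, noise_sd, size=sig.shape)

    X1 = assemble(A1, S1)
    X2 = assemble(A2, S2)
    V = VoxelMatrix([f"S{i:04d}" for i in range(n)], mask, X2, np.eye(4))
    truth = {"A1": A1, "A2": A2, "S1": S1, "S2": S2,
             "active1": act1, "active2": act2,
             "rho": spec.rho, "linked_pair": (0, 0)}
    return X1, V, truth
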