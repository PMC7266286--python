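"""Synthetic MPM cohort generator with planted ground truth.

Emulates the statistical structure the downstream stages assume: per-gene
damaging-mutation frequencies with log-linear pairwise co-occurrence
(TERT-promoter/NF2 enrichment, BAP1/TERT-promoter exclusivity), histology
drawn from the cohort's clinico-pathological distribution, molecular
subtype conditional on histology, class-structured qRT-PCR expression for
the 9 predictor genes, mixture-structured expression for the 55 signature
genes, TERT expression shifted by promoter status, and exponential
proportional-hazards survival with administrative censoring.

Mutation vectors are drawn from a log-linear pairwise (Ising-type) model:
independent Bernoulli baselines multiplied by pairwise odds factors.  The
interaction graph is tiny (two pairs by default), so each connected
component's joint distribution is enumerated exactly and the main-effect
terms are calibrated by iterative proportional fitting, which makes the
configured marginal frequencies hold exactly in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .ladder import M1_CONSEQUENCES, NONCODING_CONSEQUENCES
from .panel import (
    DEFAULT_HOTSPOT_WEIGHTS,
    DEFAULT_TERT_HOTSPOTS,
    GENE_REGIONS,
    HISTOLOGIES,
    HOUSEKEEPING_GENES,
    PANEL_GENES,
    PANEL_LOCI,
    PREDICTOR_GENES,
    SIGNATURE_GENES,
    SUBTYPES_LEVEL2,
    TASK_GENES,
    TERT_PROM,
)


class CohortConfigError(ValueError):
    """Raised when a cohort configuration value is out of range."""


# Cohort-level damaging-mutation probabilities.  BAP1/NF2/TERT_prom are the
# series' printed frequencies; the remaining genes are package defaults in
# the range reported across MPM sequencing series.
DEFAULT_GENE_FREQS: dict[str, float] = {
    "BAP1": 0.245, "NF2": 0.192, TERT_PROM: 0.120, "TP53": 0.060,
    "SETD2": 0.050, "LATS2": 0.035, "ARID2": 0.025, "SMARCA4": 0.012,
    "KMT2D": 0.010, "ARID1A": 0.010, "CDKN2A": 0.008, "PBRM1": 0.008,
    "SETDB1": 0.008, "SF3B1": 0.006, "DDX3X": 0.006, "TRAF7": 0.005,
    "RB1": 0.005, "PTCH1": 0.004, "PIK3CA": 0.004, "KRAS": 0.004,
    "NRAS": 0.004, "CUL1": 0.003,
}

#: Pairwise odds multipliers of the log-linear co-occurrence model.
DEFAULT_COOCCURRENCE_ODDS: dict[frozenset, float] = {
    frozenset({TERT_PROM, "NF2"}): 4.0,
    frozenset({"BAP1", TERT_PROM}): 0.25,
}

_RAW_HIST = {"MME": 0.78, "MMB": 0.12, "MMS": 0.08, "MMD": 0.02,
             "lympho": 0.01}
DEFAULT_HISTOLOGY_PROBS: dict[str, float] = {
    k: v / sum(_RAW_HIST.values()) for k, v in _RAW_HIST.items()
}

#: Expected number of planted non-retained variants per sample, per class.
DEFAULT_NOISE_MIX: dict[str, float] = {
    "low_quality": 1.0, "frequent_polymorphism": 1.0,
    "rare_polymorphism": 1.0, "artifact": 1.0, "silent": 1.0,
    "noncoding": 1.0,
}

# P(level-2 subtype | histology): C1A is epithelioid-enriched, C2B
# sarcomatoid-enriched, mirroring the published subtype/histology link.
SUBTYPE_GIVEN_HISTOLOGY: dict[str, tuple[float, ...]] = {
    # order: C1A, C1B, C2A, C2B
    "MME": (0.55, 0.30, 0.12, 0.03),
    "MMB": (0.10, 0.25, 0.40, 0.25),
    "MMS": (0.02, 0.08, 0.25, 0.65),
    "MMD": (0.02, 0.08, 0.25, 0.65),
    "lympho": (0.25, 0.25, 0.25, 0.25),
}

# Dirichlet concentration of the true (E, S, non-tumor) weights by histology.
WEIGHT_ALPHAS: dict[str, tuple[float, float, float]] = {
    "MME": (12.0, 1.5, 4.0),
    "MMB": (6.0, 5.0, 4.0),
    "MMS": (1.5, 12.0, 4.0),
    "MMD": (1.5, 12.0, 4.0),
    "lympho": (4.0, 4.0, 6.0),
}

#: Share of M1 / M2 / M3 tags among planted damaging coding mutations.
TAG_MIX = (0.70, 0.20, 0.10)


@dataclass(frozen=True)
class ExprParams:
    """qRT-PCR simulation parameters (cycles, dCt scale: lower = higher expression)."""

    effect_size: float = 2.0       # class-mean separation of predictor genes, in sd units
    sd: float = 1.0                # within-class sd of predictor-gene dCt
    base_delta_ct: float = 5.0     # midpoint dCt of predictor genes
    sig_noise_sd: float = 0.1      # multiplicative noise of signature genes (linear scale)
    tert_base: float = 8.0         # TERT dCt in promoter-wild-type tumors
    tert_shift: float = -2.0       # dCt shift in promoter-mutant tumors (more expressed)
    tert_sd: float = 1.0
    hk_baseline_mean: float = 20.0  # per-sample mean housekeeping Ct
    hk_baseline_sd: float = 1.0
    hk_noise_sd: float = 0.1


@dataclass(frozen=True)
class SurvivalParams:
    """Exponential proportional-hazards model with administrative censoring."""

    baseline_hazard: float = float(np.log(2) / 19.8)  # per month; median OS 19.8 mo
    log_hazards: Mapping[str, float] = field(
        default_factory=lambda: {TERT_PROM: 0.7, "NF2": 0.5, "TP53": 0.6})
    horizon_months: float = 120.0
    accrual_months: float = 96.0   # censoring uniform on [horizon-accrual, horizon]


@dataclass
class CohortConfig:
    n_samples: int = 266
    gene_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_FREQS))
    cooccurrence_odds: dict[frozenset, float] = field(
        default_factory=lambda: dict(DEFAULT_COOCCURRENCE_ODDS))
    histology_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HISTOLOGY_PROBS))
    noise_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_MIX))
    expr_params: ExprParams = field(default_factory=ExprParams)
    survival_params: SurvivalParams = field(default_factory=SurvivalParams)
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_samples, (int, np.integer))
                and self.n_samples > 0):
            raise CohortConfigError(f"n_samples must be a positive integer, "
                                    f"got {self.n_samples!r}")
        for locus, p in self.gene_freqs.items():
            if locus not in PANEL_LOCI:
                raise CohortConfigError(f"unknown panel locus {locus!r}")
            if not np.isfinite(p) or not (0.0 <= p <= 1.0):
                raise CohortConfigError(
                    f"mutation probability for {locus} out of [0,1]: {p!r}")
        for pair, odds in self.cooccurrence_odds.items():
            if len(set(pair)) != 2:
                raise CohortConfigError(f"odds key must be a pair: {pair!r}")
            if not np.isfinite(odds) or odds <= 0:
                raise CohortConfigError(
                    f"odds multiplier for {set(pair)} must be positive finite")
            for locus in pair:
                if locus not in self.gene_freqs:
                    raise CohortConfigError(
                        f"odds pair references unknown locus {locus!r}")
        for h, p in self.histology_probs.items():
            if h not in HISTOLOGIES:
                raise CohortConfigError(f"unknown histology {h!r}")
            if not np.isfinite(p) or not (0.0 <= p <= 1.0):
                raise CohortConfigError(f"histology probability out of "
                                        f"[0,1]: {h}={p!r}")
        if abs(sum(self.histology_probs.values()) - 1.0) > 1e-6:
            raise CohortConfigError("histology_probs must sum to 1")
        for cls, lam in self.noise_mix.items():
            if cls not in DEFAULT_NOISE_MIX:
                raise CohortConfigError(f"unknown noise class {cls!r}")
            if not np.isfinite(lam) or lam < 0:
                raise CohortConfigError(f"noise rate must be >= 0: {cls}={lam!r}")
        if self.survival_params.baseline_hazard <= 0:
            raise CohortConfigError("baseline hazard must be positive")


@dataclass
class GroundTruth:
    """Planted truth for every generated sample and variant."""

    mutations: pd.DataFrame          # all samples x loci, {WT,M1,M2,M3}
    subtype: pd.Series               # level-2 label per sample
    weights: pd.DataFrame            # columns E, S, non_tumor; rows sum to 1
    variant_categories: pd.DataFrame  # variant_id, sample_id, true_category
    survival_log_hazards: dict[str, float]


@dataclass
class SyntheticCohort:
    clinical: pd.DataFrame
    variants: pd.DataFrame
    ct: pd.DataFrame                 # genes x samples Ct matrix
    truth: GroundTruth
    blacklist: pd.DataFrame          # chrom, pos, ref, alt


# ---------------------------------------------------------------------------
# mutation model


def _components(loci: list[str],
                pairs: Mapping[frozenset, float]) -> list[list[str]]:
    parent = {g: g for g in loci}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pair in pairs:
        a, b = sorted(pair)
        parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for g in loci:
        groups.setdefault(find(g), []).append(g)
    return sorted(groups.values(), key=lambda c: c[0])


def _component_distribution(
    members: list[str],
    targets: np.ndarray,
    pairs: Mapping[frozenset, float],
    max_iter: int = 500,
    tol: float = 1e-12,
) -> np.ndarray:
    """Exact state distribution of one component, marginals calibrated by IPF."""
    k = len(members)
    if k > 16:
        raise CohortConfigError(
            "co-occurrence component too large to enumerate (>16 loci)")
    states = np.array([[(s >> i) & 1 for i in range(k)]
                       for s in range(2 ** k)], dtype=float)
    log_inter = np.zeros(2 ** k)
    idx = {g: i for i, g in enumerate(members)}
    for pair, odds in pairs.items():
        a, b = sorted(pair)
        if a in idx and b in idx:
            log_inter += np.log(odds) * states[:, idx[a]] * states[:, idx[b]]
    theta = np.log(targets) - np.log1p(-targets)
    for _ in range(max_iter):
        logp = states @ theta + log_inter
        logp -= logp.max()
        p = np.exp(logp)
        p /= p.sum()
        marg = states.T @ p
        err = np.abs(marg - targets).max()
        if err < tol:
            break
        theta += (np.log(targets) - np.log1p(-targets)
                  - np.log(marg) + np.log1p(-marg))
    return p


def sample_mutation_status(config: CohortConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Draw true mutation indicators (samples x loci) from the pairwise model."""
    loci = list(config.gene_freqs)
    n = config.n_samples
    out = np.zeros((n, len(loci)), dtype=bool)
    col = {g: i for i, g in enumerate(loci)}
    for members in _components(loci, config.cooccurrence_odds):
        targets = np.array([config.gene_freqs[g] for g in members])
        if len(members) == 1 or np.all(targets == 0):
            for g in members:
                out[:, col[g]] = rng.random(n) < config.gene_freqs[g]
            continue
        # degenerate marginals cannot be calibrated; clamp away from 0/1
        safe = np.clip(targets, 1e-9, 1 - 1e-9)
        p = _component_distribution(members, safe, config.cooccurrence_odds)
        draws = rng.choice(len(p), size=n, p=p)
        k = len(members)
        states = ((draws[:, None] >> np.arange(k)[None, :]) & 1).astype(bool)
        for j, g in enumerate(members):
            out[:, col[g]] = states[:, j]
    return pd.DataFrame(out, columns=loci)


# ---------------------------------------------------------------------------
# reference centroids for the deconvolution signature


def default_component_centroids(seed: int = 123456) -> pd.DataFrame:
    """Synthetic reference centroids (linear expression scale).

    Signature genes x {E, S, non_tumor}, generated deterministically and
    shared between this generator and the deconvolution defaults.  A real
    centroid table with matching row names may be supplied instead.
    """
    rng = np.random.default_rng(seed)
    dct = rng.uniform(2.0, 10.0, size=(len(SIGNATURE_GENES), 3))
    return pd.DataFrame(2.0 ** (-dct), index=list(SIGNATURE_GENES),
                        columns=["E", "S", "non_tumor"])


# ---------------------------------------------------------------------------
# variant emission


_REF_ALT = (("G", "A"), ("C", "T"), ("A", "G"), ("T", "C"),
            ("G", "T"), ("C", "A"))


def _passing_metrics(rng: np.random.Generator) -> dict:
    return {
        "qual": float(np.round(rng.uniform(150.0, 2000.0), 1)),
        "alt_depth": int(rng.integers(10, 200)),
        "gq": 99.0,
        "vaf": float(np.round(rng.uniform(0.15, 0.6), 3)),
        "pop_freq": None,
        "is_blacklisted": False,
    }


def _base_record(sample_id: str, gene: str, rng: np.random.Generator) -> dict:
    chrom, start = GENE_REGIONS[gene]
    ref, alt = _REF_ALT[int(rng.integers(len(_REF_ALT)))]
    return {
        "sample_id": sample_id, "chrom": chrom,
        "pos": int(start + rng.integers(0, 5000)), "ref": ref, "alt": alt,
        "gene": gene, "pred1": "missing", "pred2": "missing",
        "pred3": "missing", "cadd": None,
        **_passing_metrics(rng),
    }


def _damaging_record(sample_id: str, locus: str, tag: str,
                     rng: np.random.Generator) -> dict:
    rec = _base_record(sample_id, locus, rng)
    if locus == TERT_PROM:
        site = int(rng.choice(len(DEFAULT_TERT_HOTSPOTS),
                              p=np.asarray(DEFAULT_HOTSPOT_WEIGHTS)
                              / sum(DEFAULT_HOTSPOT_WEIGHTS)))
        chrom, pos = DEFAULT_TERT_HOTSPOTS[site]
        rec.update(chrom=chrom, pos=pos, consequence="promoter",
                   ref="G", alt="A")
        return rec
    if tag == "M1":
        rec["consequence"] = str(rng.choice(sorted(M1_CONSEQUENCES)))
    else:
        rec["consequence"] = "missense"
        rec["cadd"] = float(np.round(rng.uniform(21.0, 45.0), 1))
        verdicts = ["damaging", "damaging", "damaging"]
        if tag == "M3":
            verdicts[int(rng.integers(3))] = "benign"
        rec.update(pred1=verdicts[0], pred2=verdicts[1], pred3=verdicts[2])
    return rec


def _noise_record(sample_id: str, cls: str, rng: np.random.Generator,
                  blacklist: list[dict]) -> dict:
    """A planted non-retained variant violating exactly one ladder criterion."""
    gene = str(rng.choice(PANEL_GENES))
    rec = _base_record(sample_id, gene, rng)
    rec["consequence"] = "nonsense"  # would be retained but for the violation
    if cls == "low_quality":
        which = int(rng.integers(4))
        if which == 0:
            rec["qual"] = float(np.round(rng.uniform(10.0, 99.0), 1))
        elif which == 1:
            rec["alt_depth"] = int(rng.integers(1, 6))
        elif which == 2:
            rec["gq"] = float(rng.integers(10, 99))
        else:
            rec["vaf"] = float(np.round(rng.uniform(0.01, 0.099), 3))
    elif cls == "frequent_polymorphism":
        rec["pop_freq"] = float(np.round(rng.uniform(0.002, 0.05), 5))
    elif cls == "rare_polymorphism":
        rec["pop_freq"] = float(np.round(rng.uniform(1e-5, 9e-4), 6))
    elif cls == "artifact":
        rec["is_blacklisted"] = True
        blacklist.append({k: rec[k] for k in ("chrom", "pos", "ref", "alt")})
    elif cls == "silent":
        rec["consequence"] = "silent"
    elif cls == "noncoding":
        if rng.random() < 0.2:  # off-hotspot promoter position
            chrom, start = GENE_REGIONS[TERT_PROM]
            rec.update(gene=TERT_PROM, chrom=chrom,
                       pos=int(start + 400 + rng.integers(0, 50)),
                       consequence="promoter")
        else:
            rec["consequence"] = str(
                rng.choice(sorted(NONCODING_CONSEQUENCES)))
    else:  # pragma: no cover
        raise CohortConfigError(f"unknown noise class {cls!r}")
    return rec


def generate_raw_variants(sample_id: str, truth_tags: Mapping[str, str],
                          noise_mix: Mapping[str, float],
                          rng: np.random.Generator,
                          blacklist: list[dict]) -> tuple[list[dict], list[dict]]:
    """Variant records for one sample: (records, truth rows).

    Every truly damaging mutation is emitted with metrics that pass all
    ladder thresholds; each planted noise variant violates exactly one
    criterion and its true category is recorded.
    """
    records, truth_rows = [], []
    for locus in truth_tags:
        tag = truth_tags[locus]
        if tag == "WT":
            continue
        rec = _damaging_record(sample_id, locus, tag, rng)
        records.append(rec)
        truth_rows.append({"sample_id": sample_id, "true_category": "retained",
                           "true_tag": tag})
    for cls in DEFAULT_NOISE_MIX:
        lam = noise_mix.get(cls, 0.0)
        for _ in range(int(rng.poisson(lam))):
            records.append(_noise_record(sample_id, cls, rng, blacklist))
            truth_rows.append({"sample_id": sample_id, "true_category": cls,
                               "true_tag": "none"})
    return records, truth_rows


# ---------------------------------------------------------------------------
# cohort assembly


_HK_OFFSETS = {"18S": -8.0, "ACTB": 1.0, "CLTC": 3.0, "GAPDH": 1.0, "TBP": 3.0}

_STAGE_PROBS = {"I": 0.02, "II": 0.14, "III": 0.45, "IV": 0.39}


def _predictor_gene_means(subtype: str, params: ExprParams) -> dict[str, float]:
    half = params.effect_size * params.sd / 2.0
    base = params.base_delta_ct
    means = {}
    for g in TASK_GENES["C1_vs_C2"]:
        means[g] = base - half if subtype.startswith("C1") else base + half
    for g in TASK_GENES["C1A_vs_C1B"]:
        means[g] = base + {"C1A": -half, "C1B": half}.get(subtype, 0.0)
    for g in TASK_GENES["C2A_vs_C2B"]:
        means[g] = base + {"C2A": -half, "C2B": half}.get(subtype, 0.0)
    return means


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; byte-identical for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]
    loci = list(config.gene_freqs)

    status = sample_mutation_status(config, rng)
    tags = pd.DataFrame("WT", index=pd.Index(samples, name="sample_id"),
                        columns=loci)
    tag_choices = np.array(["M1", "M2", "M3"])
    for g in loci:
        hit = status[g].to_numpy()
        if g == TERT_PROM:
            tags.loc[hit, g] = "M1"
        else:
            tags.loc[hit, g] = rng.choice(tag_choices, size=int(hit.sum()),
                                          p=TAG_MIX)
    # loci not in the panel frame get WT columns so the matrix shape is stable
    for locus in PANEL_LOCI:
        if locus not in tags.columns:
            tags[locus] = "WT"
    tags = tags[[c for c in PANEL_LOCI]]

    histology = rng.choice(list(config.histology_probs),
                           size=n, p=list(config.histology_probs.values()))
    subtype = np.array([
        rng.choice(SUBTYPES_LEVEL2, p=SUBTYPE_GIVEN_HISTOLOGY[h])
        for h in histology
    ])
    weights = np.vstack([rng.dirichlet(WEIGHT_ALPHAS[h]) for h in histology])

    tumor_content = np.clip(np.round(rng.normal(65.0, 22.0, size=n)), 5, 98)
    asbestos = np.where(rng.random(n) < 0.13, "NA",
                        np.where(rng.random(n) < 0.81, "exposed",
                                 "nonexposed"))
    stage = rng.choice(list(_STAGE_PROBS), size=n,
                       p=list(_STAGE_PROBS.values()))

    sp = config.survival_params
    log_hr = np.zeros(n)
    for locus, beta in sp.log_hazards.items():
        if locus in tags.columns:
            log_hr += beta * (tags[locus].to_numpy() != "WT")
    hazard = sp.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    censor = rng.uniform(max(sp.horizon_months - sp.accrual_months, 0.0),
                         sp.horizon_months, size=n)
    os_event = (t_event <= censor).astype(int)
    os_months = np.round(np.minimum(t_event, censor), 2)

    clinical = pd.DataFrame({
        "sample_id": samples,
        "histology": histology,
        "tumor_content_pct": tumor_content.astype(int),
        "asbestos": asbestos,
        "stage": stage,
        "os_months": os_months,
        "os_event": os_event,
    })

    # --- variants (only tumors with >= 10% content were sequenced) ---
    blacklist_rows: list[dict] = []
    records: list[dict] = []
    truth_rows: list[dict] = []
    for i, s in enumerate(samples):
        if tumor_content[i] < 10:
            continue
        recs, trows = generate_raw_variants(
            s, tags.loc[s].to_dict(), config.noise_mix, rng, blacklist_rows)
        records.extend(recs)
        truth_rows.extend(trows)
    for j, rec in enumerate(records):
        rec["variant_id"] = f"V{j + 1:06d}"
        truth_rows[j]["variant_id"] = rec["variant_id"]
    variant_cols = ["variant_id", "sample_id", "chrom", "pos", "ref", "alt",
                    "qual", "alt_depth", "gq", "vaf", "pop_freq",
                    "is_blacklisted", "consequence", "gene",
                    "pred1", "pred2", "pred3", "cadd"]
    variants = pd.DataFrame(records, columns=variant_cols)
    variant_truth = pd.DataFrame(
        truth_rows, columns=["variant_id", "sample_id", "true_category",
                             "true_tag"])
    blacklist = pd.DataFrame(blacklist_rows,
                             columns=["chrom", "pos", "ref", "alt"])
    blacklist = blacklist.drop_duplicates().reset_index(drop=True)

    # --- qRT-PCR Ct matrix ---
    ep = config.expr_params
    genes = (list(PREDICTOR_GENES) + list(SIGNATURE_GENES) + ["TERT"]
             + list(HOUSEKEEPING_GENES))
    centroids = default_component_centroids()
    baseline = rng.normal(ep.hk_baseline_mean, ep.hk_baseline_sd, size=n)
    ct = np.empty((len(genes), n))
    gene_index = {g: i for i, g in enumerate(genes)}
    for i, s in enumerate(samples):
        means = _predictor_gene_means(subtype[i], ep)
        for g in PREDICTOR_GENES:
            dct = rng.normal(means[g], ep.sd)
            ct[gene_index[g], i] = dct + baseline[i]
        linear = centroids.to_numpy() @ weights[i]
        noisy = np.maximum(linear * (1.0 + rng.normal(0.0, ep.sig_noise_sd,
                                                      size=len(linear))),
                           1e-12)
        dct_sig = -np.log2(noisy)
        for k, g in enumerate(SIGNATURE_GENES):
            ct[gene_index[g], i] = dct_sig[k] + baseline[i]
        tert_mean = ep.tert_base + (
            ep.tert_shift if tags.at[s, TERT_PROM] != "WT" else 0.0)
        ct[gene_index["TERT"], i] = rng.normal(tert_mean, ep.tert_sd) + baseline[i]
        for g in HOUSEKEEPING_GENES:
            ct[gene_index[g], i] = (baseline[i] + _HK_OFFSETS[g]
                                    + rng.normal(0.0, ep.hk_noise_sd))
    ct_frame = pd.DataFrame(np.round(ct, 4), index=pd.Index(genes, name="gene"),
                            columns=samples)

    truth = GroundTruth(
        mutations=tags,
        subtype=pd.Series(subtype, index=samples, name="subtype"),
        weights=pd.DataFrame(weights, index=samples,
                             columns=["E", "S", "non_tumor"]),
        variant_categories=variant_truth,
        survival_log_hazards=dict(sp.log_hazards),
    )
    return SyntheticCohort(clinical=clinical, variants=variants, ct=ct_frame,
                           truth=truth, blacklist=blacklist)
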