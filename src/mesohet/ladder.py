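"""Ordered variant-triage ladder and damaging-mutation tagging.

Tumor-only variant calls are triaged into exclusion categories in a fixed
order; only variants with a structural consequence (or a TERT-promoter
hotspot) survive.  Retained variants are tagged by damaging class:

* ``M1`` — truncating/structural events: nonsense, splice site, inframe and
  frameshift indels, de novo start inframe, and TERT-promoter hotspots;
* ``M2`` — missense with CADD > 20 called damaging by all three in-silico
  predictors;
* ``M3`` — missense with CADD > 20 called damaging by two of the three.

Missense variants with CADD <= 20 are not conserved: they keep category
``retained`` but carry tag ``none`` and are excluded from every damaging
summary and from the mutation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .panel import DEFAULT_TERT_HOTSPOTS, PANEL_LOCI, TERT_PROM

logger = logging.getLogger(__name__)

STRUCTURAL_CONSEQUENCES = frozenset({
    "nonsense", "missense", "splice_site", "inframe_del", "inframe_ins",
    "frameshift_del", "frameshift_ins", "de_novo_start_inframe",
})
M1_CONSEQUENCES = STRUCTURAL_CONSEQUENCES - {"missense"}
NONCODING_CONSEQUENCES = frozenset({
    "intron", "IGR", "3'UTR", "5'UTR", "5'flank", "3'flank",
})
CONSEQUENCES = STRUCTURAL_CONSEQUENCES | NONCODING_CONSEQUENCES | {
    "silent", "promoter",
}

#: Triage categories in ladder order; the first matching one wins.
CATEGORIES = (
    "low_quality", "frequent_polymorphism", "rare_polymorphism",
    "artifact", "silent", "noncoding", "retained",
)

DAMAGING_TAGS = ("M1", "M2", "M3", "none")


class VariantValidationError(ValueError):
    """Raised for malformed variant records (unknown consequence, bad VAF...)."""


@dataclass(frozen=True)
class AnnotatedVariant:
    """One called variant with quality, frequency and consequence annotation.

    ``pop_freq`` is the maximum allele frequency across the referenced
    population databases, or ``None`` when the variant is absent from all of
    them.  ``pred_damaging`` holds the three in-silico predictor verdicts,
    each ``"damaging"``, ``"benign"`` or ``"missing"``.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    alt_depth: int
    gq: float
    vaf: float
    pop_freq: Optional[float]
    is_blacklisted: bool
    consequence: str
    gene: str
    pred_damaging: tuple[str, str, str] = ("missing", "missing", "missing")
    cadd: Optional[float] = None
    variant_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0) or not np.isfinite(self.vaf):
            raise VariantValidationError(f"VAF out of [0,1]: {self.vaf!r}")
        if self.pop_freq is not None and not (0.0 <= self.pop_freq <= 1.0):
            raise VariantValidationError(
                f"population frequency out of [0,1]: {self.pop_freq!r}")
        if self.consequence not in CONSEQUENCES:
            raise VariantValidationError(
                f"unknown consequence label: {self.consequence!r}")


@dataclass(frozen=True)
class LadderThresholds:
    """Printed triage thresholds; defaults are the assay's published values."""

    min_qual: float = 100.0
    min_alt_depth: int = 6
    min_gq: float = 99.0
    min_vaf: float = 0.1
    polymorphism_freq_cutoff: float = 0.001
    cadd_cutoff: float = 20.0

    def __post_init__(self) -> None:
        for name in ("min_qual", "min_alt_depth", "min_gq", "min_vaf",
                     "polymorphism_freq_cutoff", "cadd_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ClassifiedVariant:
    variant: AnnotatedVariant
    category: str
    damaging_tag: str = "none"
    confirmed: bool = False  # manual-review placeholder

    def __post_init__(self) -> None:
        if self.damaging_tag != "none" and self.category != "retained":
            raise ValueError("damaging tag on a non-retained variant")


def _is_hotspot(v: AnnotatedVariant,
                hotspots: Iterable[tuple[str, int]]) -> bool:
    return (v.chrom, v.pos) in set(hotspots)


def assign_filter_category(
    v: AnnotatedVariant,
    thresholds: LadderThresholds = LadderThresholds(),
    hotspots: Sequence[tuple[str, int]] = DEFAULT_TERT_HOTSPOTS,
) -> str:
    """Return the first matching triage category, in ladder order.

    Order: (a) low quality (QUAL, alt depth, GQ or VAF below threshold);
    (b) frequent polymorphism (database frequency above the 0.1% cutoff);
    (c) rare polymorphism (referenced in a database at or below the cutoff);
    (d) artifact (blacklist membership); (e) silent; (f) noncoding (intron/
    IGR/UTR/flank, and promoter positions off the hotspot list); (g) retained.
    """
    t = thresholds
    if (v.qual < t.min_qual or v.alt_depth < t.min_alt_depth
            or v.gq < t.min_gq or v.vaf < t.min_vaf):
        return "low_quality"
    if v.pop_freq is not None and v.pop_freq > t.polymorphism_freq_cutoff:
        return "frequent_polymorphism"
    if v.pop_freq is not None:
        return "rare_polymorphism"
    if v.is_blacklisted:
        return "artifact"
    if v.consequence == "silent":
        return "silent"
    if v.consequence in NONCODING_CONSEQUENCES:
        return "noncoding"
    if v.consequence == "promoter":
        return "retained" if _is_hotspot(v, hotspots) else "noncoding"
    if v.consequence in STRUCTURAL_CONSEQUENCES:
        return "retained"
    raise VariantValidationError(
        f"unknown consequence label: {v.consequence!r}")  # pragma: no cover


def tag_damaging(
    v: AnnotatedVariant,
    thresholds: LadderThresholds = LadderThresholds(),
    hotspots: Sequence[tuple[str, int]] = DEFAULT_TERT_HOTSPOTS,
) -> str:
    """Damaging tag for a *retained* variant.

    Missense variants need CADD > cutoff to be conserved at all; among those,
    3/3 damaging predictor verdicts give M2 and 2/3 give M3.  Missing
    verdicts count as non-damaging (logged).  TERT-promoter hotspots behave
    as M1-class events of the ``TERT_prom`` locus.
    """
    if v.consequence == "promoter":
        return "M1" if _is_hotspot(v, hotspots) else "none"
    if v.consequence in M1_CONSEQUENCES:
        return "M1"
    if v.consequence == "missense":
        if v.cadd is None or v.cadd <= thresholds.cadd_cutoff:
            return "none"
        if "missing" in v.pred_damaging:
            logger.warning(
                "missing in-silico prediction(s) for %s:%s %s>%s counted as "
                "non-damaging", v.chrom, v.pos, v.ref, v.alt)
        n_damaging = sum(p == "damaging" for p in v.pred_damaging)
        if n_damaging == 3:
            return "M2"
        if n_damaging == 2:
            return "M3"
        return "none"
    return "none"


def apply_filter_ladder(
    variants: Iterable[AnnotatedVariant],
    thresholds: LadderThresholds = LadderThresholds(),
    hotspots: Sequence[tuple[str, int]] = DEFAULT_TERT_HOTSPOTS,
) -> list[ClassifiedVariant]:
    """Classify every variant; the categories partition the input."""
    out = []
    for v in variants:
        category = assign_filter_category(v, thresholds, hotspots)
        tag = (tag_damaging(v, thresholds, hotspots)
               if category == "retained" else "none")
        out.append(ClassifiedVariant(variant=v, category=category,
                                     damaging_tag=tag))
    return out


_TAG_PRIORITY = {"M1": 3, "M2": 2, "M3": 1, "none": 0, "WT": 0}


def build_mutation_matrix(
    classified: Sequence[ClassifiedVariant],
    clinical: pd.DataFrame,
    loci: Sequence[str] = PANEL_LOCI,
    min_tumor_content: float = 10.0,
) -> pd.DataFrame:
    """Sample x locus matrix of {WT, M1, M2, M3}.

    Every clinical sample with tumor content >= ``min_tumor_content`` gets a
    row (all-WT when it carries no damaging variant); each cell holds the
    highest-priority tag (M1 > M2 > M3) among that sample's variants at that
    locus.  A variant referencing a sample absent from the clinical table
    raises.
    """
    samples = clinical.loc[
        clinical["tumor_content_pct"] >= min_tumor_content, "sample_id"
    ].tolist()
    known = set(clinical["sample_id"])
    matrix = pd.DataFrame("WT", index=pd.Index(samples, name="sample_id"),
                          columns=list(loci))
    included = set(samples)
    for cv in classified:
        v = cv.variant
        if v.sample_id not in known:
            raise KeyError(f"variant references unknown sample {v.sample_id!r}")
        if cv.damaging_tag == "none" or v.sample_id not in included:
            continue
        locus = TERT_PROM if v.consequence == "promoter" else v.gene
        if locus not in matrix.columns:
            raise KeyError(f"variant references unknown locus {locus!r}")
        if _TAG_PRIORITY[cv.damaging_tag] > _TAG_PRIORITY[matrix.at[v.sample_id, locus]]:
            matrix.at[v.sample_id, locus] = cv.damaging_tag
    return matrix


@dataclass
class FrequencySummary:
    per_locus: pd.Series
    frac_mutated_genes_only: float
    frac_mutated_with_tert_prom: float
    n_samples: int = field(default=0)


def mutation_frequencies(matrix: pd.DataFrame) -> FrequencySummary:
    """Per-locus mutated fractions and cohort mutated-sample fractions.

    The cohort fraction is reported both over the coding genes alone and
    with the TERT promoter included.
    """
    if matrix.empty:
        raise ValueError("mutation matrix is empty")
    mutated = matrix != "WT"
    gene_cols = [c for c in matrix.columns if c != TERT_PROM]
    return FrequencySummary(
        per_locus=mutated.mean(axis=0),
        frac_mutated_genes_only=float(mutated[gene_cols].any(axis=1).mean()),
        frac_mutated_with_tert_prom=float(mutated.any(axis=1).mean()),
        n_samples=len(matrix),
    )


def tert_hotspot_summary(
    classified: Sequence[ClassifiedVariant],
    hotspots: Sequence[tuple[str, int]] = DEFAULT_TERT_HOTSPOTS,
) -> pd.DataFrame:
    """Counts and proportions of retained promoter variants per hotspot site."""
    counts = {hs: 0 for hs in hotspots}
    for cv in classified:
        v = cv.variant
        if cv.category == "retained" and v.consequence == "promoter":
            key = (v.chrom, v.pos)
            if key in counts:
                counts[key] += 1
    total = sum(counts.values())
    rows = [
        {"chrom": c, "pos": p, "count": n,
         "proportion": (n / total) if total else 0.0}
        for (c, p), n in counts.items()
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "count", "proportion"])
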