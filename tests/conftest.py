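"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mesohet.ladder import (AnnotatedVariant, LadderThresholds,
                            M1_CONSEQUENCES, NONCODING_CONSEQUENCES,
                            STRUCTURAL_CONSEQUENCES)
from mesohet.panel import DEFAULT_TERT_HOTSPOTS, PANEL_GENES, TERT_PROM
from mesohet.synth import CohortConfig, generate_cohort

HOTSPOT = DEFAULT_TERT_HOTSPOTS[0]


def make_variant(**kw) -> AnnotatedVariant:
    """A variant passing every ladder threshold unless overridden."""
    defaults = dict(
        sample_id="S0001", chrom="chr22", pos=30_000_000, ref="C", alt="T",
        qual=500.0, alt_depth=50, gq=99.0, vaf=0.4, pop_freq=None,
        is_blacklisted=False, consequence="nonsense", gene="NF2",
        pred_damaging=("missing", "missing", "missing"), cadd=None,
    )
    defaults.update(kw)
    return AnnotatedVariant(**defaults)


def random_variant(rng: np.random.Generator) -> AnnotatedVariant:
    """Adversarial random variant hitting every threshold boundary."""
    consequence = str(rng.choice(sorted(
        STRUCTURAL_CONSEQUENCES | NONCODING_CONSEQUENCES
        | {"silent", "promoter"})))
    if consequence == "promoter":
        gene = TERT_PROM
        chrom, pos = (HOTSPOT if rng.random() < 0.5
                      else ("chr5", 1_295_000 + int(rng.integers(0, 500))))
    else:
        gene = str(rng.choice(PANEL_GENES))
        chrom, pos = "chr1", int(rng.integers(1, 10_000_000))
    return make_variant(
        chrom=chrom, pos=pos, gene=gene, consequence=consequence,
        qual=float(rng.choice([50.0, 99.9, 100.0, 100.1, 800.0])),
        alt_depth=int(rng.choice([2, 5, 6, 7, 80])),
        gq=float(rng.choice([50.0, 98.0, 99.0])),
        vaf=float(rng.choice([0.05, 0.099, 0.1, 0.101, 0.45])),
        pop_freq=(None if rng.random() < 0.5 else
                  float(rng.choice([1e-5, 0.0005, 0.001, 0.0011, 0.02, 0.3]))),
        is_blacklisted=bool(rng.random() < 0.3),
        pred_damaging=tuple(rng.choice(["damaging", "benign", "missing"],
                                       size=3)),
        cadd=(None if rng.random() < 0.3 else
              float(rng.choice([5.0, 19.9, 20.0, 20.1, 35.0]))),
    )


def oracle_category(v: AnnotatedVariant,
                    t: LadderThresholds = LadderThresholds(),
                    hotspots=DEFAULT_TERT_HOTSPOTS) -> str:
    """Brute force: evaluate every criterion, return the minimal-index match."""
    is_hot = (v.chrom, v.pos) in set(hotspots)
    checks = [
        ("low_quality", v.qual < t.min_qual or v.alt_depth < t.min_alt_depth
         or v.gq < t.min_gq or v.vaf < t.min_vaf),
        ("frequent_polymorphism", v.pop_freq is not None
         and v.pop_freq > t.polymorphism_freq_cutoff),
        ("rare_polymorphism", v.pop_freq is not None
         and v.pop_freq <= t.polymorphism_freq_cutoff),
        ("artifact", v.is_blacklisted),
        ("silent", v.consequence == "silent"),
        ("noncoding", v.consequence in NONCODING_CONSEQUENCES
         or (v.consequence == "promoter" and not is_hot)),
        ("retained", v.consequence in STRUCTURAL_CONSEQUENCES
         or (v.consequence == "promoter" and is_hot)),
    ]
    return next(name for name, hit in checks if hit)


def oracle_tag(v: AnnotatedVariant,
               t: LadderThresholds = LadderThresholds(),
               hotspots=DEFAULT_TERT_HOTSPOTS) -> str:
    """Independent restatement of the damaging-tag rules for retained variants."""
    if v.consequence == "promoter":
        return "M1" if (v.chrom, v.pos) in set(hotspots) else "none"
    if v.consequence in M1_CONSEQUENCES:
        return "M1"
    if v.consequence == "missense" and v.cadd is not None \
            and v.cadd > t.cadd_cutoff:
        n = list(v.pred_damaging).count("damaging")
        return {3: "M2", 2: "M3"}.get(n, "none")
    return "none"


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_samples=120, seed=5))


@pytest.fixture(scope="session")
def medium_cohort():
    return generate_cohort(CohortConfig(n_samples=266, seed=7))
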