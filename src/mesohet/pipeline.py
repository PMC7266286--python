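"""End-to-end orchestration: simulate -> filter -> classify -> deconvolve
-> associate -> report.

Every output table carries a provenance header (package version, seed,
configuration hash) and the whole run is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deconv import MixtureDeconvolver
from .expression import delta_ct_normalize
from .io import classified_to_frame, variants_from_frame, write_table
from .ladder import (LadderThresholds, apply_filter_ladder,
                     build_mutation_matrix, mutation_frequencies,
                     tert_hotspot_summary)
from .panel import DEFAULT_TERT_HOTSPOTS, TERT_PROM
from .predictor import SubtypePredictor, calls_to_frame
from .stats import (build_survival_frame, cox_regression, km_logrank,
                    pairwise_cooccurrence, score_association_ttest,
                    tert_expression_test)
from .synth import CohortConfig, generate_cohort

FOCUS_GENES = ("BAP1", "NF2", "TP53", "SETD2", "LATS2", "ARID2")


class PipelineConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    n_samples: int = 266
    seed: int = 0
    n_train: int = 63              # samples used to train the subtype predictor
    outdir: Optional[str] = None
    thresholds: LadderThresholds = field(default_factory=LadderThresholds)
    cohort_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise PipelineConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        thresholds = LadderThresholds(**raw.pop("thresholds", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise PipelineConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(thresholds=thresholds, **raw)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(n_samples=self.n_samples, seed=self.seed,
                            **self.cohort_overrides)

    def config_hash(self) -> str:
        def _default(o):
            if isinstance(o, frozenset):
                return sorted(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(str(type(o)))
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # analysis parameters only, not paths
        blob = json.dumps(payload, sort_keys=True, default=_default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a synthetic cohort; returns the report dict."""
    meta = {"version": __version__, "seed": config.seed,
            "config_hash": config.config_hash()}
    report: dict = {"provenance": dict(meta)}

    try:
        cohort = generate_cohort(config.cohort_config())
    except Exception as exc:
        raise StageError(f"simulate: {exc}") from exc

    try:
        variants = variants_from_frame(cohort.variants)
        classified = apply_filter_ladder(variants, config.thresholds,
                                         DEFAULT_TERT_HOTSPOTS)
        matrix = build_mutation_matrix(classified, cohort.clinical)
        freqs = mutation_frequencies(matrix)
        hotspots = tert_hotspot_summary(classified)
        cat_counts = (classified_to_frame(classified)["category"]
                      .value_counts().sort_index())
        report["variants"] = {
            "n_total": len(classified),
            "category_counts": cat_counts.to_dict(),
            "per_locus_frequency": freqs.per_locus.round(6).to_dict(),
            "frac_mutated_genes_only": freqs.frac_mutated_genes_only,
            "frac_mutated_with_tert_prom": freqs.frac_mutated_with_tert_prom,
            "n_matrix_samples": freqs.n_samples,
            "tert_hotspots": hotspots.to_dict("records"),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"filter: {exc}") from exc

    try:
        norm = delta_ct_normalize(cohort.ct)
        dct = norm.dct
        clinical = cohort.clinical.set_index("sample_id")
        content = clinical["tumor_content_pct"]
        eligible = [s for s in dct.columns if content[s] >= 30]
        train = eligible[:config.n_train]
        predictor = SubtypePredictor(random_state=config.seed).fit(
            dct[train], cohort.truth.subtype.loc[train])
        test = [s for s in dct.columns if s not in set(train)]
        calls = predictor.predict(dct[test], content.loc[test])
        call_frame = calls_to_frame(calls)
        gated = call_frame[call_frame["score_ok"]
                           & call_frame["tumor_content_ok"]]
        truth2 = cohort.truth.subtype
        agree = float(np.mean([
            truth2[s] == l2 for s, l2 in
            zip(gated["sample_id"], gated["level2"])])) if len(gated) else float("nan")
        report["subtypes"] = {
            "n_train": len(train), "n_predicted": len(call_frame),
            "n_gated": int(len(gated)),
            "level1_counts": call_frame["level1"].value_counts().to_dict(),
            "level2_counts": call_frame["level2"].value_counts().to_dict(),
            "gated_truth_agreement": agree,
        }
    except Exception as exc:
        raise StageError(f"classify: {exc}") from exc

    try:
        deconv = MixtureDeconvolver().fit()
        scores = deconv.transform(dct)
        gate_frac = float(scores["gate_passed"].fillna(False).mean())
        mae = float(np.nanmean(np.abs(
            scores[["w_E", "w_S", "w_NT"]].to_numpy(float)
            - cohort.truth.weights.loc[scores.index].to_numpy())))
        report["deconvolution"] = {
            "n_samples": int(len(scores)),
            "frac_gate_passed": gate_frac,
            "weight_mae_vs_truth": mae,
            "mean_s_score": float(scores["S_score"].dropna().mean()),
        }
    except Exception as exc:
        raise StageError(f"deconvolve: {exc}") from exc

    try:
        cooc = pairwise_cooccurrence(matrix, loci=list(FOCUS_GENES),
                                     focal=TERT_PROM)
        ttests = {}
        for locus in list(FOCUS_GENES) + [TERT_PROM]:
            try:
                r = score_association_ttest(matrix, scores["S_score"], locus)
                ttests[locus] = {"p_value": r.p_value,
                                 "mean_mutated": r.mean_mutated,
                                 "mean_wildtype": r.mean_wildtype}
            except ValueError as exc:
                ttests[locus] = {"skipped": str(exc)}
        km = {}
        surv = clinical.loc[matrix.index]
        for locus in ("TERT_prom", "NF2", "TP53"):
            res = km_logrank(surv["os_months"], surv["os_event"],
                             (matrix[locus] != "WT").map({True: "M",
                                                          False: "WT"}))
            km[locus] = {"chi2": res.chi2, "p_value": res.p_value}
        frame = build_survival_frame(cohort.clinical, matrix, scores)
        cox = cox_regression(frame)
        tert = tert_expression_test(dct.loc["TERT"],
                                    matrix[TERT_PROM] != "WT")
        report["associations"] = {
            "cooccurrence_vs_tert_prom": cooc.round(6).to_dict("records"),
            "s_score_ttests": ttests,
            "km_logrank": km,
            "cox": {
                kind: {c: {"hr": f.hazard_ratio, "ci": [f.ci_low, f.ci_high],
                           "p": f.p_value, "flagged": f.flagged}
                       for c, f in fits.items()}
                for kind, fits in cox.items()
            },
            "tert_expression": {"p_value": tert.p_value,
                                "direction": tert.direction},
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"associate: {exc}") from exc

    report = _round_floats(report)

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(cohort.clinical, out / "clinical.tsv", meta)
        write_table(cohort.variants, out / "variants.tsv", meta)
        write_table(cohort.blacklist, out / "blacklist.tsv", meta)
        write_table(classified_to_frame(classified),
                    out / "classified_variants.tsv", meta)
        write_table(matrix, out / "mutation_matrix.tsv", meta, index=True)
        write_table(dct.round(4), out / "delta_ct.tsv", meta, index=True)
        write_table(call_frame, out / "subtype_calls.tsv", meta)
        write_table(scores.round(6), out / "scores.tsv", meta, index=True)
        write_table(cooc.round(6), out / "cooccurrence.tsv", meta)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
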