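"""Readers and writers for the package's tabular formats.

All tables are plain TSV with optional ``# key: value`` provenance header
lines.  Variant input is either the annotated-variant TSV dialect (one
column per AnnotatedVariant field) or a VCF 4.x file read through pysam
(CHROM/POS/REF/ALT/QUAL plus AD/GQ genotype fields and the INFO keys
GENE, CSQ, POP_FREQ, CADD, PRED, BLACKLIST).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .ladder import AnnotatedVariant, ClassifiedVariant


def write_table(df: pd.DataFrame, path, meta: Optional[Mapping] = None,
                index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def _opt_float(x) -> Optional[float]:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    return float(x)


def variants_from_frame(df: pd.DataFrame) -> list[AnnotatedVariant]:
    out = []
    for row in df.itertuples(index=False):
        out.append(AnnotatedVariant(
            sample_id=str(row.sample_id), chrom=str(row.chrom),
            pos=int(row.pos), ref=str(row.ref), alt=str(row.alt),
            qual=float(row.qual), alt_depth=int(row.alt_depth),
            gq=float(row.gq), vaf=float(row.vaf),
            pop_freq=_opt_float(row.pop_freq),
            is_blacklisted=bool(row.is_blacklisted),
            consequence=str(row.consequence), gene=str(row.gene),
            pred_damaging=(str(row.pred1), str(row.pred2), str(row.pred3)),
            cadd=_opt_float(row.cadd),
            variant_id=(str(row.variant_id)
                        if hasattr(row, "variant_id") else None),
        ))
    return out


def classified_to_frame(classified: Sequence[ClassifiedVariant]) -> pd.DataFrame:
    rows = []
    for cv in classified:
        v = cv.variant
        rows.append({
            "variant_id": v.variant_id, "sample_id": v.sample_id,
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "qual": v.qual, "alt_depth": v.alt_depth, "gq": v.gq,
            "vaf": v.vaf, "pop_freq": v.pop_freq,
            "is_blacklisted": v.is_blacklisted, "consequence": v.consequence,
            "gene": v.gene, "pred1": v.pred_damaging[0],
            "pred2": v.pred_damaging[1], "pred3": v.pred_damaging[2],
            "cadd": v.cadd, "category": cv.category,
            "damaging_tag": cv.damaging_tag,
        })
    return pd.DataFrame(rows)


def apply_blacklist(df: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    """Set ``is_blacklisted`` from an artifact-panel (chrom,pos,ref,alt) table."""
    keys = set(zip(blacklist["chrom"], blacklist["pos"],
                   blacklist["ref"], blacklist["alt"]))
    df = df.copy()
    df["is_blacklisted"] = [
        (c, p, r, a) in keys
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    return df


def read_vcf(path) -> list[AnnotatedVariant]:
    """Minimal VCF reader; one AnnotatedVariant per non-reference genotype."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            raw = info.get("PRED")
            if raw is None:
                parts = []
            elif isinstance(raw, (tuple, list)):
                parts = [str(x) for x in raw]
            else:
                parts = str(raw).split(",")
            pred = tuple((parts + ["missing"] * 3)[:3])
            for sample_id, call in rec.samples.items():
                ad = call.get("AD")
                if ad is None or len(ad) < 2 or not ad[1]:
                    continue
                depth = sum(x for x in ad if x is not None)
                out.append(AnnotatedVariant(
                    sample_id=sample_id, chrom=str(rec.chrom),
                    pos=int(rec.pos), ref=str(rec.ref),
                    alt=str(rec.alts[0]),
                    qual=float(rec.qual if rec.qual is not None else 0.0),
                    alt_depth=int(ad[1]),
                    gq=float(call.get("GQ", 0) or 0),
                    vaf=float(ad[1]) / depth if depth else 0.0,
                    pop_freq=(float(info["POP_FREQ"])
                              if "POP_FREQ" in info else None),
                    is_blacklisted=bool(info.get("BLACKLIST", False)),
                    consequence=str(info.get("CSQ", "missense")),
                    gene=str(info.get("GENE", "")),
                    pred_damaging=pred,
                    cadd=float(info["CADD"]) if "CADD" in info else None,
                ))
    return out


def read_ct_matrix(path) -> pd.DataFrame:
    return read_table(path, index_col=0)


def read_clinical(path) -> pd.DataFrame:
    return read_table(path)
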