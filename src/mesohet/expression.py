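"""qRT-PCR Ct normalization.

Expression is measured in PCR cycles (Ct); the housekeeping-normalized
measure is dCt = Ct_gene - mean(Ct over the housekeeping set) per sample,
so lower dCt means higher expression and dCt is invariant to adding a
constant to every Ct of a sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .panel import HOUSEKEEPING_GENES


class NormalizationError(ValueError):
    pass


@dataclass
class DeltaCtResult:
    dct: pd.DataFrame               # genes (housekeeping removed) x samples
    excluded_samples: list[str]     # samples missing a housekeeping value


def delta_ct_normalize(
    ct: pd.DataFrame,
    housekeeping: Sequence[str] = HOUSEKEEPING_GENES,
) -> DeltaCtResult:
    """Normalize a genes x samples Ct matrix to dCt.

    Samples missing any housekeeping measurement are flagged and excluded.
    The housekeeping rows themselves are dropped from the output.
    """
    missing = [g for g in housekeeping if g not in ct.index]
    if missing:
        raise NormalizationError(
            f"housekeeping genes absent from Ct matrix: {missing}")
    hk = ct.loc[list(housekeeping)]
    bad = hk.columns[hk.isna().any(axis=0)].tolist()
    keep = [c for c in ct.columns if c not in bad]
    dct = ct.loc[[g for g in ct.index if g not in set(housekeeping)], keep]
    dct = dct.sub(hk[keep].mean(axis=0), axis=1)
    return DeltaCtResult(dct=dct, excluded_samples=bad)


def dct_to_linear(dct: pd.DataFrame) -> pd.DataFrame:
    """Linear-scale expression 2**(-dCt)."""
    return 2.0 ** (-dct)
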