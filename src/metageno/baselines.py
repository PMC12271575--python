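"""Classic weighted-sum polygenic risk score baseline."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genodata import MISSING, GenotypeMatrix, VariantPanel


@dataclass
class PRSResult:
    score: np.ndarray          # weighted effect-allele count per sample
    standardized: np.ndarray   # z-scored against the reference cohort


def prs_score(G: GenotypeMatrix, panel: Optional[VariantPanel] = None,
              missing_policy: str = "mean",
              reference_scores: Optional[np.ndarray] = None) -> PRSResult:
    """score_i = sum_v weight_v * dosage_iv.

    MISSING dosages contribute ``weight_v * 2*maf_v`` (policy ``mean``, with
    maf estimated from observed calls) or 0 (policy ``zero``). Standardized
    scores are z-scored against ``reference_scores`` when given, else
    against the cohort itself.
    """
    panel = panel or G.panel
    w = panel.weights
    dos = G.dosages.astype(float)
    miss = G.dosages == MISSING
    if miss.all(axis=1).any():
        warnings.warn("samples with all genotypes missing; scores use the "
                      "non-missing subset only")
    if missing_policy == "mean":
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(np.where(miss, np.nan, dos), axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        dos = np.where(miss, col_mean, dos)
    elif missing_policy == "zero":
        dos = np.where(miss, 0.0, dos)
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    score = dos @ w
    ref = np.asarray(reference_scores) if reference_scores is not None else score
    sd = ref.std()
    standardized = (score - ref.mean()) / (sd if sd > 0 else 1.0)
    return PRSResult(score=score, standardized=standardized)
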