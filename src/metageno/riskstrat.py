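"""Downstream risk evaluation: percentile stratification, bin-wise Cox
hazard ratios, Harrell's C-index, Kaplan-Meier cumulative incidence and
chromosome attention reports.

Risk scores are normalized against the validation (reference) population's
empirical distribution with mid-rank tie handling. Hazard ratios come from
Cox proportional-hazards fits on the age axis with a bin indicator as the
only covariate; cumulative incidence is one minus the Kaplan-Meier
survival function with Greenwood confidence bands (both via lifelines).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

logger = logging.getLogger(__name__)

#: tertile scheme: label -> [lo, hi) percentile interval (hi inclusive at 100)
TERTILES = {"0-33": (0.0, 33.0), "33-67": (33.0, 67.0), "67-100": (67.0, 100.0)}

#: percentile scheme of overlapping high-risk bins, each compared to the
#: 45-55 reference band
PERCENTILE_BINS = {
    "low 0-45": (0.0, 45.0),
    "reference 45-55": (45.0, 55.0),
    "55-100": (55.0, 100.0),
    "80-100": (80.0, 100.0),
    "90-100": (90.0, 100.0),
    "95-100": (95.0, 100.0),
    "99-100": (99.0, 100.0),
}


@dataclass
class RiskStrata:
    percentile: np.ndarray           # [0, 100] per sample
    tertile: np.ndarray              # label per sample
    scheme_bins: Dict[str, tuple] = field(default_factory=dict)

    def in_bin(self, label: str) -> np.ndarray:
        lo, hi = self.scheme_bins[label]
        if hi >= 100.0:
            return (self.percentile >= lo) & (self.percentile <= 100.0)
        return (self.percentile >= lo) & (self.percentile < hi)


@dataclass
class SurvivalEstimate:
    group: str
    times: np.ndarray
    cumulative_incidence: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


@dataclass
class AttentionReport:
    raw: np.ndarray         # per-chromosome attention mass, length 22
    normalized: np.ndarray  # min-max normalized to [0, 1]
    degenerate: bool        # all chromosomes equal (e.g. untrained model)


def to_percentiles(scores: np.ndarray,
                   reference_scores: np.ndarray) -> RiskStrata:
    """Percentile of each score in the reference empirical distribution.

    percentile = 100 * (count_below + 0.5 * count_equal) / n_reference
    (mid-rank tie handling), so the map is monotone in the score.
    """
    ref = np.sort(np.asarray(reference_scores, dtype=float))
    if ref.size == 0:
        raise ValueError("reference distribution must be non-empty")
    s = np.asarray(scores, dtype=float)
    below = np.searchsorted(ref, s, side="left")
    upto = np.searchsorted(ref, s, side="right")
    pct = 100.0 * (below + 0.5 * (upto - below)) / ref.size
    tert = np.empty(len(s), dtype=object)
    for label, (lo, hi) in TERTILES.items():
        mask = (pct >= lo) & ((pct < hi) if hi < 100 else (pct <= 100))
        tert[mask] = label
    return RiskStrata(percentile=pct, tertile=tert,
                      scheme_bins=dict(PERCENTILE_BINS))


def bin_hazard_ratios(strata: RiskStrata, survival: pd.DataFrame,
                      scheme: str = "tertiles",
                      reference_bin: Optional[str] = None) -> pd.DataFrame:
    """HR with Wald 95% CI for each bin against the reference bin.

    ``survival`` needs columns age_end and event_is. Each comparison is a
    Cox fit on the union of the reference and comparison bins with the bin
    indicator as the only covariate and age as the time axis.
    """
    if scheme == "tertiles":
        bins = {label: strata.tertile == label for label in TERTILES}
        reference_bin = reference_bin or "0-33"
    elif scheme == "percentiles":
        bins = {label: strata.in_bin(label) for label in PERCENTILE_BINS}
        reference_bin = reference_bin or "reference 45-55"
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    ref_mask = bins.pop(reference_bin)
    if survival.loc[ref_mask, "event_is"].sum() == 0:
        warnings.warn("no events in the reference bin; HRs undefined")
    rows = []
    for label, mask in bins.items():
        n_events = int(survival.loc[mask, "event_is"].sum())
        if n_events == 0:
            warnings.warn(f"no events in bin {label}; HR undefined")
            rows.append({"bin": label, "hr": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "n": int(mask.sum()),
                         "events": 0})
            continue
        sub = survival.loc[mask | ref_mask, ["age_end", "event_is"]].copy()
        sub["in_bin"] = mask[mask | ref_mask].astype(float)
        cph = CoxPHFitter()
        cph.fit(sub, duration_col="age_end", event_col="event_is")
        s = cph.summary.loc["in_bin"]
        rows.append({"bin": label, "hr": float(s["exp(coef)"]),
                     "ci_low": float(s["exp(coef) lower 95%"]),
                     "ci_high": float(s["exp(coef) upper 95%"]),
                     "n": int(mask.sum()), "events": n_events})
    return pd.DataFrame(rows)


def c_index(scores: np.ndarray, age: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance on the age timeline.

    Permissible pairs: an event at time t_i against any sample surviving
    (or censored) strictly beyond t_i. Concordant when the earlier-event
    sample has the higher score; score ties count 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    age = np.asarray(age, dtype=float)
    event = np.asarray(event).astype(bool)
    cases = np.where(event)[0]
    num = den = 0.0
    for i in cases:
        later = age > age[i]
        n_pairs = int(later.sum())
        if n_pairs == 0:
            continue
        den += n_pairs
        num += (scores[i] > scores[later]).sum()
        num += 0.5 * (scores[i] == scores[later]).sum()
    if den == 0:
        raise ValueError("no permissible pairs for the C-index")
    return float(num / den)


def c_index_by_task_combination(train_and_score: Callable,
                                combinations: Sequence,
                                survival: pd.DataFrame) -> pd.DataFrame:
    """C-index per task combination.

    ``train_and_score(combination) -> scores`` must train (or look up) a
    model restricted to that task subset and return IS risk scores aligned
    with ``survival``; one row per requested combination.
    """
    rows = []
    for combo in combinations:
        scores = train_and_score(combo)
        rows.append({
            "combination": "+".join(combo) if not isinstance(combo, str) else combo,
            "c_index": c_index(scores, survival["age_end"].to_numpy(),
                               survival["event_is"].to_numpy()),
        })
    return pd.DataFrame(rows)


def cumulative_incidence(survival: pd.DataFrame,
                         groups: Dict[str, np.ndarray]) -> list:
    """1 - Kaplan-Meier survival per group, with Greenwood 95% bands.

    ``groups`` maps a label to a boolean mask over ``survival`` rows; empty
    groups are skipped with a warning. Subgroups crossing risk deciles with
    covariate flags are expressed by the caller as combined masks.
    """
    out = []
    for label, mask in groups.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            warnings.warn(f"empty group {label!r}; skipped")
            continue
        km = KaplanMeierFitter()
        km.fit(survival.loc[mask, "age_end"], survival.loc[mask, "event_is"],
               label=label)
        surv = km.survival_function_[label].to_numpy()
        ci = km.confidence_interval_
        out.append(SurvivalEstimate(
            group=label,
            times=km.survival_function_.index.to_numpy(dtype=float),
            cumulative_incidence=1.0 - surv,
            ci_low=1.0 - ci.iloc[:, 1].to_numpy(),
            ci_high=1.0 - ci.iloc[:, 0].to_numpy(),
        ))
    return out


def risk_decile_mask(percentile: np.ndarray, top: bool = True,
                     frac: float = 10.0) -> np.ndarray:
    """Boolean mask for the top (or bottom) ``frac`` percent of risk."""
    pct = np.asarray(percentile, dtype=float)
    return pct >= 100.0 - frac if top else pct <= frac


def chromosome_attention_report(model, states: np.ndarray,
                                source: str = "backbone",
                                batch_size: int = 512) -> AttentionReport:
    """Aggregate the model's attention into a 22-entry chromosome report.

    ``source`` selects where the attention mass is read:

    - ``backbone`` (default): incoming multi-head attention mass per
      chromosome token in the sequence backbone, summed over heads and
      queries and averaged over samples. Within the chromosome-wise layer
      every attention matrix row sums to one, so a per-chromosome sum of
      SNP-level attention is the SNP count by construction; the token-level
      attention the backbone pays to each chromosome is the quantity that
      actually varies with learned importance.
    - ``chromembed``: SNP-level incoming attention mass in the chromosome
      layer weighted by each SNP's value-vector norm, summed per
      chromosome (kept for diagnostics; degenerate reports are flagged).

    The 22 raw masses are min-max normalized to [0, 1].
    """
    from .autodiff import no_grad

    if model.mode != "chromosome_wise":
        raise ValueError("attention report requires a chromosome_wise model")
    if source not in ("backbone", "chromembed"):
        raise ValueError(f"unknown source {source!r}")
    if source == "backbone" and not getattr(model.backbone, "blocks", None):
        raise ValueError("backbone attention requires a transformer backbone "
                         "with depth >= 1; use source='chromembed'")
    raw = np.zeros(22)
    denom = 0.0
    for lo in range(0, len(states), batch_size):
        batch = states[lo:lo + batch_size]
        with no_grad():
            model.forward_logits(batch, keep_attention=(source == "chromembed"))
        if source == "backbone":
            for blk in model.backbone.blocks:
                a = blk.last_alpha                     # (B, heads, 22, 22)
                raw += a.sum(axis=(0, 1, 2))           # incoming per token
                denom += a.shape[0] * a.shape[1]
        else:
            for gi, alpha, v in model.embedding.last_attention:
                incoming = alpha.sum(axis=-2)          # (B, m) column sums
                raw[gi] += (incoming * np.linalg.norm(v, axis=-1)).sum()
            denom += len(batch)
    raw /= max(denom, 1.0)
    span = raw.max() - raw.min()
    degenerate = bool(span < 1e-9)
    if degenerate:
        logger.warning("attention report is degenerate (all chromosomes equal)")
        normalized = np.zeros(22)
    else:
        normalized = (raw - raw.min()) / span
    return AttentionReport(raw=raw, normalized=normalized, degenerate=degenerate)
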