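"""Synthetic genotype and multi-disease phenotype generation.

Genotypes are sums of two haplotypes. Within an LD block the haplotype
alleles come from a Gaussian copula (a correlated multivariate normal
thresholded at the MAF quantile) whose latent correlation is calibrated
numerically so the realized allele correlation matches the requested r.
Disease labels follow a liability-threshold model with optional additive
effects, within-chromosome epistatic pairs (products of centred dosages)
and a single shared latent factor that induces cross-disease comorbidity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import (DISEASES, ChromosomeGroup, GenotypeMatrix, Variant,
                       VariantPanel)

__all__ = [
    "ArchitectureSpec", "CohortTable", "simulate_genotypes",
    "simulate_multitask_phenotypes", "simulate_ages_and_events",
    "make_panel", "make_epistasis_spec", "make_shared_factor_spec",
    "make_causal_chrom_spec", "make_null_spec",
]


@dataclass
class LDBlock:
    chrom: int
    start: int  # first within-chromosome variant index (inclusive)
    stop: int   # last index (exclusive)
    r: float    # target pairwise dosage correlation

    def __post_init__(self):
        if not (0.0 <= self.r < 1.0):
            raise ValueError("LD target r must lie in [0, 1)")


@dataclass
class EpistaticPair:
    variant_a: int  # global column index
    variant_b: int
    effect: float
    disease: str


@dataclass
class ArchitectureSpec:
    """Full description of a synthetic cohort's genetic architecture."""

    n_variants_per_chrom: Sequence
    maf: np.ndarray                      # per-variant, in (0, 0.5]
    ld_blocks: list = field(default_factory=list)
    additive_effects: dict = field(default_factory=dict)   # disease -> per-variant array
    epistatic_pairs: list = field(default_factory=list)
    shared_factor_loading: dict = field(default_factory=dict)  # disease -> float
    prevalence: dict = field(default_factory=dict)             # disease -> (0,1)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.n_variants_per_chrom = list(self.n_variants_per_chrom)
        if len(self.n_variants_per_chrom) != 22:
            raise ValueError("n_variants_per_chrom must list all 22 autosomes")
        self.maf = np.asarray(self.maf, dtype=float)
        if self.maf.shape != (self.n_variants,):
            raise ValueError("maf must have one entry per variant")
        if np.any((self.maf < 0) | (self.maf > 0.5)):
            raise ValueError("maf must lie in [0, 0.5]")
        chrom_of = self.chrom_of_variant
        for p in self.epistatic_pairs:
            if chrom_of[p.variant_a] != chrom_of[p.variant_b]:
                raise ValueError("epistatic pair members must share a chromosome")
        for d, prev in self.prevalence.items():
            if not (0.0 < prev < 1.0):
                raise ValueError(f"prevalence for {d} must be in (0,1)")

    @property
    def n_variants(self) -> int:
        return int(sum(self.n_variants_per_chrom))

    @property
    def chrom_of_variant(self) -> np.ndarray:
        return np.repeat(np.arange(1, 23), self.n_variants_per_chrom)

    @property
    def chrom_offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.n_variants_per_chrom)])


@dataclass
class CohortTable:
    """Per-sample labels, survival covariates and (for oracle tests) liabilities."""

    sample_ids: list
    labels: np.ndarray                  # n x 6 binary, DISEASES order
    liability: np.ndarray               # n x 6 real
    age_end: Optional[np.ndarray] = None
    event_is: Optional[np.ndarray] = None
    family_history: Optional[np.ndarray] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.event_is is not None:
            if np.any((self.event_is == 1) & (self.labels[:, 0] == 0)):
                raise ValueError("event_is = 1 requires an IS case label")
        if self.age_end is not None and np.any(self.age_end <= 0):
            raise ValueError("age_end must be positive")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids})
        for i, d in enumerate(DISEASES):
            df[d] = self.labels[:, i]
        if self.age_end is not None:
            df["age_end"] = self.age_end
        if self.event_is is not None:
            df["event_is"] = self.event_is
        if self.family_history is not None:
            df["family_history"] = self.family_history
        return df


def make_panel(spec: ArchitectureSpec) -> VariantPanel:
    """Build a synthetic VariantPanel matching the spec's variant layout."""
    variants = []
    j = 0
    is_effects = spec.additive_effects.get("IS")
    for chrom, m in zip(range(1, 23), spec.n_variants_per_chrom):
        for i in range(m):
            w = float(is_effects[j]) if is_effects is not None else 0.0
            variants.append(Variant(rsid=f"rs{j + 1}", chrom=chrom,
                                    pos=1000 * (i + 1), effect_allele="T",
                                    other_allele="A", effect_weight=w,
                                    trait_tags=frozenset(DISEASES)))
            j += 1
    return VariantPanel(variants)


def _latent_rho(maf_a: float, maf_b: float, target_r: float) -> float:
    """Latent MVN correlation whose thresholded indicators correlate target_r.

    Solved by bisection on the bivariate-normal orthant probability.
    """
    if target_r == 0.0:
        return 0.0
    ta, tb = stats.norm.ppf(maf_a), stats.norm.ppf(maf_b)
    sa = np.sqrt(maf_a * (1 - maf_a))
    sb = np.sqrt(maf_b * (1 - maf_b))

    def point_corr(rho):
        p11 = stats.multivariate_normal.cdf([ta, tb], mean=[0, 0],
                                            cov=[[1, rho], [rho, 1]])
        return (p11 - maf_a * maf_b) / (sa * sb)

    lo, hi = 0.0, 0.999999
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if point_corr(mid) < target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_genotypes(n: int, spec: ArchitectureSpec) -> GenotypeMatrix:
    """Draw n diploid genotypes: independent Binomial(2, maf) outside LD
    blocks, Gaussian-copula-correlated haplotypes inside them."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    nv = spec.n_variants
    haplos = np.empty((2, n, nv), dtype=np.int8)
    for h in range(2):
        u = rng.random((n, nv))
        haplos[h] = (u < spec.maf).astype(np.int8)

    offsets = spec.chrom_offsets
    for block in spec.ld_blocks:
        lo = offsets[block.chrom - 1] + block.start
        hi = offsets[block.chrom - 1] + block.stop
        size = hi - lo
        if size < 2:
            continue
        mafs = spec.maf[lo:hi]
        # equicorrelated latent normals; calibrate rho against the mean MAF
        rho = _latent_rho(float(mafs.mean()), float(mafs.mean()), block.r)
        cov = np.full((size, size), rho)
        np.fill_diagonal(cov, 1.0)
        chol = np.linalg.cholesky(cov)
        thresholds = stats.norm.ppf(mafs)
        for h in range(2):
            z = rng.standard_normal((n, size)) @ chol.T
            haplos[h][:, lo:hi] = (z < thresholds).astype(np.int8)

    dosages = haplos[0] + haplos[1]
    panel = make_panel(spec)
    sample_ids = [f"S{i:06d}" for i in range(n)]
    return GenotypeMatrix(dosages, sample_ids, panel)


def liabilities(G: GenotypeMatrix, spec: ArchitectureSpec,
                rng: np.random.Generator) -> np.ndarray:
    """n x 6 liability matrix: additive + epistatic + shared factor + noise."""
    n = G.n_samples
    centred = G.dosages.astype(float) - 2.0 * spec.maf  # MISSING never simulated
    u = rng.standard_normal(n)
    liab = np.zeros((n, len(DISEASES)))
    for i, d in enumerate(DISEASES):
        ell = np.zeros(n)
        w = spec.additive_effects.get(d)
        if w is not None:
            ell += centred @ np.asarray(w, dtype=float)
        for pair in spec.epistatic_pairs:
            if pair.disease == d:
                ell += pair.effect * centred[:, pair.variant_a] * centred[:, pair.variant_b]
        ell += spec.shared_factor_loading.get(d, 0.0) * u
        ell += spec.noise_sd * rng.standard_normal(n)
        liab[:, i] = ell
    return liab


def simulate_multitask_phenotypes(G: GenotypeMatrix,
                                  spec: ArchitectureSpec) -> CohortTable:
    """Threshold liabilities at empirical (1 - prevalence) quantiles to get
    the six binary labels; the empirical quantile gives exact prevalence
    control even when epistasis makes liabilities non-normal."""
    rng = np.random.default_rng(spec.seed + 1)
    liab = liabilities(G, spec, rng)
    labels = np.zeros_like(liab, dtype=np.int8)
    for i, d in enumerate(DISEASES):
        prev = spec.prevalence.get(d, 0.5)
        thr = np.quantile(liab[:, i], 1.0 - prev)
        labels[:, i] = (liab[:, i] > thr).astype(np.int8)
    return CohortTable(list(G.sample_ids), labels, liab)


def simulate_ages_and_events(cohort: CohortTable, base_age: float = 40.0,
                             scale: float = 30.0, seed: int = 0,
                             fh_slope: float = 1.0) -> CohortTable:
    """Attach event/censoring ages and a family-history flag.

    IS cases get event ages from an exponential whose hazard is multiplied
    by exp(standardized IS liability), so higher liability means earlier
    events; controls get censoring ages from the baseline hazard. The
    family-history flag is Bernoulli with log-odds increasing in liability.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort.sample_ids)
    ell = cohort.liability[:, 0]
    z = (ell - ell.mean()) / (ell.std() + 1e-12)
    hazard = np.exp(z) / scale
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.exponential(scale, size=n)
    is_case = cohort.labels[:, 0] == 1
    age_end = np.where(is_case, base_age + event_time, base_age + censor_time)
    age_end = np.clip(age_end, base_age + 0.1, 100.0)
    event_is = is_case.astype(np.int8)
    p_fh = 1.0 / (1.0 + np.exp(-(fh_slope * z - 1.0)))
    family_history = (rng.random(n) < p_fh).astype(np.int8)
    return CohortTable(cohort.sample_ids, cohort.labels, cohort.liability,
                       age_end=age_end, event_is=event_is,
                       family_history=family_history)


# ---------------------------------------------------------------------------
# canonical cohort architectures used by the evaluation suite


def _uniform_layout(n_variants: int) -> list:
    base, extra = divmod(n_variants, 22)
    return [base + (1 if c < extra else 0) for c in range(22)]


def make_null_spec(n_variants: int = 110, prevalence: float = 0.2,
                   seed: int = 0) -> ArchitectureSpec:
    """No-signal cohort: labels are thresholded pure noise."""
    layout = _uniform_layout(n_variants)
    return ArchitectureSpec(
        n_variants_per_chrom=layout,
        maf=np.full(n_variants, 0.3),
        prevalence={d: prevalence for d in DISEASES},
        seed=seed,
    )


def make_epistasis_spec(n_variants: int = 200, causal_chroms: Sequence = (2, 9),
                        pairs_per_chrom: int = 4, effect: float = 3.0,
                        additive_effect: float = 0.0,
                        prevalence: float = 0.3, seed: int = 0) -> ArchitectureSpec:
    """Within-chromosome epistasis on the given chromosomes.

    With ``additive_effect = 0`` (the default) there are no marginal effects
    anywhere: products of centred dosages keep each member's marginal
    association with the label near zero, so a linear PRS has nothing to
    work with while an interaction-capable model does. A nonzero
    ``additive_effect`` additionally puts that per-allele weight on every
    causal-chromosome SNP (used by the representation-ablation fixture).
    """
    layout = _uniform_layout(n_variants)
    offsets = np.concatenate([[0], np.cumsum(layout)])
    pairs = []
    additive = np.zeros(n_variants)
    for chrom in causal_chroms:
        lo, m = offsets[chrom - 1], layout[chrom - 1]
        if 2 * pairs_per_chrom > m:
            raise ValueError("not enough variants on chromosome for the pairs")
        for p in range(pairs_per_chrom):
            pairs.append(EpistaticPair(int(lo + 2 * p), int(lo + 2 * p + 1),
                                       effect, "IS"))
        additive[lo:lo + m] = additive_effect
    effects = {"IS": additive} if additive_effect else {}
    return ArchitectureSpec(
        n_variants_per_chrom=layout,
        maf=np.full(n_variants, 0.5),
        additive_effects=effects,
        epistatic_pairs=pairs,
        prevalence={d: prevalence for d in DISEASES},
        seed=seed,
    )


def make_causal_chrom_spec(n_variants: int = 200, chroms: Sequence = (2, 9),
                           weight: float = 0.35, maf: float = 0.3,
                           prevalence: float = 0.3,
                           seed: int = 0) -> ArchitectureSpec:
    """Additive IS effects confined to the given chromosomes.

    The attention-recovery fixture: every SNP on a causal chromosome gets
    the same per-allele weight, all other chromosomes are pure noise.
    """
    layout = _uniform_layout(n_variants)
    offsets = np.concatenate([[0], np.cumsum(layout)])
    w = np.zeros(n_variants)
    for c in chroms:
        w[offsets[c - 1]:offsets[c - 1] + layout[c - 1]] = weight
    return ArchitectureSpec(
        n_variants_per_chrom=layout,
        maf=np.full(n_variants, maf),
        additive_effects={"IS": w},
        prevalence={d: prevalence for d in DISEASES},
        seed=seed,
    )


def make_shared_factor_spec(n_variants: int = 200, n_causal: int = 40,
                            effect_sd: float = 0.22, loading: float = 1.0,
                            prevalence: float = 0.3, noise_sd: float = 1.0,
                            seed: int = 0) -> ArchitectureSpec:
    """Shared-architecture cohort: all six diseases load on the same causal
    SNPs (per-disease effects are correlated draws around a common vector)
    plus one shared latent factor, so auxiliary labels carry information
    about the genotype-to-IS mapping."""
    rng = np.random.default_rng(seed + 777)
    layout = _uniform_layout(n_variants)
    causal = rng.choice(n_variants, size=n_causal, replace=False)
    base = rng.normal(0.0, effect_sd, size=n_causal)
    effects = {}
    for d in DISEASES:
        w = np.zeros(n_variants)
        w[causal] = base + rng.normal(0.0, 0.25 * effect_sd, size=n_causal)
        effects[d] = w
    return ArchitectureSpec(
        n_variants_per_chrom=layout,
        maf=np.full(n_variants, 0.3),
        additive_effects=effects,
        shared_factor_loading={d: loading for d in DISEASES},
        prevalence={d: prevalence for d in DISEASES},
        noise_sd=noise_sd,
        seed=seed,
    )
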