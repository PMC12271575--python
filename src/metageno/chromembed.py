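"""Chromosome-wise SNP embedding layer.

Each SNP's allele state (0/1/2, optionally a dedicated missing state) is
one-hot encoded and mapped through a single embedding matrix ``E`` shared
across all SNPs and diseases, plus a learned per-SNP identity embedding
``P`` (without it, every SNP with the same allele state would collapse to
the same vector). SNPs on the same chromosome then exchange information
through single-head scaled dot-product self-attention; mean pooling gives
one summary vector per chromosome, and the 22 summaries are stacked into
the representation ``Z`` (22 x d) consumed by the sequence backbone.

Alternative representation modes (for ablations) skip the per-chromosome
attention + pooling and hand the backbone one token per SNP, so the same
sequence model sees the whole panel at once (global attention scope):

- ``chromosome_wise``: E + P, attention within each chromosome (default);
  output is the 22 x d chromosome-aware representation
- ``global_snp``:      E only, SNP tokens for panel-wide attention
- ``independent_snp``: a separate V x d table per SNP, SNP tokens
- ``one_hot``:         raw one-hot states padded to width d, no learned
  parameters, SNP tokens
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .autodiff import Parameter, Tensor, stack
from .genodata import MISSING, ChromosomeGroup

MODES = ("chromosome_wise", "global_snp", "independent_snp", "one_hot")


def encode_allele_state(dosage: int, V: int) -> np.ndarray:
    """One-hot encode a single allele state over V possible states."""
    if V not in (3, 4):
        raise ValueError("V must be 3 or 4")
    if dosage == MISSING:
        if V == 3:
            raise ValueError("MISSING state requires V = 4")
        idx = 3
    elif dosage in (0, 1, 2):
        idx = int(dosage)
    else:
        raise ValueError(f"invalid dosage {dosage}")
    x = np.zeros(V)
    x[idx] = 1.0
    return x


@dataclass
class EmbeddingParams:
    """Learnable parameters of the embedding layer.

    E is shared across all SNPs and diseases; P carries per-SNP identity;
    W_Q/W_K/W_V are shared across all 22 chromosomes. ``null_tokens`` holds
    one learned d-vector per chromosome, returned for chromosomes with no
    panel SNPs so that Z always has 22 rows.
    """

    E: Parameter
    P: Parameter
    W_Q: Parameter
    W_K: Parameter
    W_V: Parameter
    null_tokens: Parameter
    d: int
    V: int
    snp_table: Optional[Parameter] = None  # independent_snp mode only

    @classmethod
    def init(cls, n_variants: int, d: int, V: int = 4, seed: int = 0,
             mode: str = "chromosome_wise") -> "EmbeddingParams":
        if d < 1:
            raise ValueError("embedding dimension d must be >= 1")
        rng = np.random.default_rng(seed)
        s = 1.0 / np.sqrt(d)
        params = cls(
            E=Parameter(rng.normal(0, s, size=(V, d))),
            P=Parameter(rng.normal(0, s, size=(n_variants, d))),
            W_Q=Parameter(rng.normal(0, s, size=(d, d))),
            W_K=Parameter(rng.normal(0, s, size=(d, d))),
            W_V=Parameter(rng.normal(0, s, size=(d, d))),
            null_tokens=Parameter(np.zeros((22, d))),
            d=d,
            V=V,
        )
        if mode == "independent_snp":
            params.snp_table = Parameter(rng.normal(0, s, size=(n_variants * V, d)))
        return params

    def trainable(self, mode: str = "chromosome_wise") -> list:
        if mode == "chromosome_wise":
            return [self.E, self.P, self.W_Q, self.W_K, self.W_V, self.null_tokens]
        if mode == "global_snp":
            return [self.E, self.W_Q, self.W_K, self.W_V, self.null_tokens]
        if mode == "independent_snp":
            return [self.snp_table, self.null_tokens]
        if mode == "one_hot":
            return []
        raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ChromosomeAttentionOutput:
    alpha: Tensor  # (..., m, m) attention weights, rows sum to 1
    H: Tensor      # (..., m, d) contextualized embeddings
    v: Optional[Tensor] = None  # (..., m, d) value vectors


def embed_snps(encodings, params: EmbeddingParams, mode: str = "chromosome_wise",
               snp_cols: Optional[np.ndarray] = None) -> Tensor:
    """Map one-hot allele encodings of one chromosome's SNPs to (m, d).

    ``snp_cols`` gives the global panel column index of each SNP (needed by
    the modes with per-SNP parameters).
    """
    x = np.asarray(encodings, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    states = np.argmax(x, axis=-1)
    if mode == "chromosome_wise":
        e = params.E.take0(states)
        if snp_cols is None:
            raise ValueError("chromosome_wise mode needs snp_cols for P")
        return e + params.P.take0(np.asarray(snp_cols))
    if mode == "global_snp":
        return params.E.take0(states)
    if mode == "independent_snp":
        if params.snp_table is None or snp_cols is None:
            raise ValueError("independent_snp mode needs snp_table and snp_cols")
        flat = np.asarray(snp_cols) * params.V + states
        return params.snp_table.take0(flat)
    if mode == "one_hot":
        m, V = x.shape
        out = np.zeros((m, params.d))
        out[:, : min(V, params.d)] = x[:, : min(V, params.d)]
        return Tensor(out)
    raise ValueError(f"unknown mode {mode!r}")


def chromosome_self_attention(Ej: Tensor, params: EmbeddingParams
                              ) -> ChromosomeAttentionOutput:
    """Single-head scaled dot-product self-attention over one chromosome.

    alpha[k, l] = softmax_l(q_k . k_l / sqrt(d)); h_k = sum_l alpha[k, l] v_l.
    Accepts (m, d) or batched (B, m, d) input.
    """
    if not np.isfinite(Ej.data).all():
        raise FloatingPointError("non-finite embedding input to attention")
    q = Ej @ params.W_Q
    k = Ej @ params.W_K
    v = Ej @ params.W_V
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(params.d))
    alpha = scores.softmax(axis=-1)
    H = alpha @ v
    return ChromosomeAttentionOutput(alpha=alpha, H=H, v=v)


def pool_chromosome(H: Tensor, null_token: Tensor) -> Tensor:
    """Mean over the SNP axis; an empty chromosome yields the null token."""
    if H.data.shape[-2] == 0:
        return null_token
    return H.mean(axis=-2)


def assemble_representation(summaries: Sequence[Tensor]) -> Tensor:
    """Stack the 22 chromosome summaries into Z (..., 22, d)."""
    summaries = list(summaries)
    if len(summaries) != 22:
        raise ValueError(f"expected 22 chromosome summaries, got {len(summaries)}")
    return stack(summaries, axis=-2)


class ChromosomeEmbedding:
    """Batched embedding layer: allele-state matrix -> Z of shape (B, 22, d)."""

    def __init__(self, groups: Sequence[ChromosomeGroup], d: int, V: int = 4,
                 mode: str = "chromosome_wise", seed: int = 0,
                 params: Optional[EmbeddingParams] = None,
                 positional: bool = True):
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        self.groups = list(groups)
        if len(self.groups) != 22:
            raise ValueError("expected 22 chromosome groups")
        self.mode = mode
        self.positional = positional and mode == "chromosome_wise"
        n_variants = int(sum(g.m for g in self.groups))
        self.params = params or EmbeddingParams.init(n_variants, d, V,
                                                     seed=seed, mode=mode)
        # column order concatenated per chromosome (position-sorted already)
        self.col_order = np.concatenate(
            [np.asarray(g.column_indices, dtype=int) for g in self.groups if g.m]
        ) if n_variants else np.zeros(0, dtype=int)
        self.last_attention: list = []
        # padded layout: all chromosomes aligned to the max SNP count, so one
        # masked attention call covers all 22 (identical math, ~15x fewer ops)
        self._m = np.array([g.m for g in self.groups])
        mmax = max(int(self._m.max()), 1)
        self._pad_cols = np.zeros((22, mmax), dtype=int)
        self._valid = np.zeros((22, mmax), dtype=bool)
        for gi, g in enumerate(self.groups):
            self._pad_cols[gi, :g.m] = g.column_indices
            self._valid[gi, :g.m] = True
        self._key_bias = np.where(self._valid, 0.0, -1e9)[:, None, :]  # (22,1,mmax)

    def trainable(self) -> list:
        ps = self.params.trainable(self.mode)
        if self.mode == "chromosome_wise" and not self.positional:
            ps = [p for p in ps if p is not self.params.P]
        return ps

    def _embed_all(self, states: np.ndarray) -> Optional[Tensor]:
        """(B, nv) state indices (already in col_order) -> (B, nv, d)."""
        p = self.params
        if self.mode in ("chromosome_wise", "global_snp"):
            e = p.E.take0(states)
            if self.positional:
                e = e + p.P.take0(self.col_order)
            return e
        if self.mode == "independent_snp":
            flat = self.col_order[None, :] * p.V + states
            return p.snp_table.take0(flat)
        if self.mode == "one_hot":
            B, nv = states.shape
            out = np.zeros((B, nv, p.d))
            width = min(p.V, p.d)
            onehot = np.eye(p.V)[states][..., :width]
            out[..., :width] = onehot
            return Tensor(out)
        raise AssertionError

    def _embed_padded(self, padded: np.ndarray) -> Tensor:
        """(B, 22, mmax) state indices -> (B, 22, mmax, d)."""
        p = self.params
        if self.mode == "chromosome_wise":
            e = p.E.take0(padded)
            if self.positional:
                e = e + p.P.take0(self._pad_cols)
            return e
        if self.mode == "independent_snp":
            flat = self._pad_cols[None] * p.V + padded
            return p.snp_table.take0(flat)
        if self.mode == "one_hot":
            out = np.zeros(padded.shape + (p.d,))
            width = min(p.V, p.d)
            out[..., :width] = np.eye(p.V)[padded][..., :width]
            return Tensor(out)
        raise AssertionError

    def forward(self, states: np.ndarray, keep_attention: bool = False) -> Tensor:
        """states: (B, n_variants) integer allele states in panel column order.

        The chromosome_wise / independent_snp / one_hot modes run on the
        padded layout (one masked attention over all 22 chromosomes at
        once); global_snp attends over the whole panel as one sequence. All
        paths realize the same per-chromosome equations.
        """
        states = np.asarray(states)
        if states.ndim == 1:
            states = states[None, :]
        B = states.shape[0]
        self.last_attention = []
        p = self.params

        if self.mode != "chromosome_wise":
            # ablation modes keep SNP-level tokens: the backbone consumes the
            # whole panel as one sequence, so no per-chromosome pooling
            # happens here; global_snp additionally contextualizes the
            # tokens with one panel-wide self-attention pass (same W_Q/K/V,
            # scope widened from chromosome to panel)
            seq = states[:, self.col_order] if self.col_order.size else states[:, :0]
            e = self._embed_all(seq)
            if self.mode == "global_snp" and seq.shape[1] > 0:
                att = chromosome_self_attention(e, p)
                if keep_attention:
                    self.last_attention.append(
                        ("global", att.alpha.data, att.v.data))
                return att.H
            return e

        # padded layout (B, 22, mmax): one masked attention over all 22 groups
        padded = states[:, self._pad_cols]
        e = self._embed_padded(padded)
        q = e @ p.W_Q
        k = e @ p.W_K
        v = e @ p.W_V
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(p.d))
        alpha = (scores + Tensor(self._key_bias)).softmax(axis=-1)
        H = alpha @ v
        if keep_attention:
            for gi, g in enumerate(self.groups):
                if g.m:
                    self.last_attention.append(
                        (gi, alpha.data[:, gi, :g.m, :g.m],
                         v.data[:, gi, :g.m, :]))
        vmask = Tensor(self._valid[:, :, None].astype(float))
        inv_m = Tensor(np.where(self._m > 0, 1.0 / np.maximum(self._m, 1), 0.0)
                       [:, None])
        pooled = (H * vmask).sum(axis=-2) * inv_m            # (B, 22, d)
        has = Tensor((self._m > 0).astype(float)[:, None])    # (22, 1)
        return pooled * has + p.null_tokens * (1.0 - has.data)
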