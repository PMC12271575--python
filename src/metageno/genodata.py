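"""Variant panels, VCF genotype extraction and chromosome grouping.

Scoring panels follow the PGS-Catalog tab-separated dialect (rsID,
chr_name, chr_position, effect_allele, other_allele, effect_weight;
``#``-prefixed metadata lines ignored). Genotypes are read from VCF with
cyvcf2 and stored as effect-allele dosages in {0, 1, 2} with ``MISSING``
(-1) for no-calls.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel dosage for a missing genotype call
MISSING: int = -1

#: the six disease identifiers, in canonical column order
DISEASES: tuple = ("IS", "AF", "CAD", "T2D", "HT", "HCL")

_PANEL_COLUMNS = {"chrom": "chr_name", "pos": "chr_position",
                  "effect_allele": "effect_allele", "effect_weight": "effect_weight"}


@dataclass(frozen=True)
class Variant:
    rsid: str
    chrom: int
    pos: int
    effect_allele: str
    other_allele: str
    effect_weight: float
    trait_tags: frozenset

    @property
    def key(self):
        return (self.chrom, self.pos, self.effect_allele, self.other_allele)


@dataclass
class VariantPanel:
    """Deduplicated union of per-disease variant lists, sorted by (chrom, pos).

    Column order of any GenotypeMatrix built against this panel equals the
    order of ``variants``, so chromosome groups are contiguous slices.
    """

    variants: list

    def __post_init__(self):
        seen = set()
        for v in self.variants:
            if not (1 <= v.chrom <= 22):
                raise ValueError(f"non-autosomal chromosome {v.chrom} in panel")
            if v.key in seen:
                raise ValueError(f"duplicate variant {v.key} in panel")
            seen.add(v.key)

    def __len__(self):
        return len(self.variants)

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.effect_weight for v in self.variants], dtype=float)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants], dtype=int)


@dataclass
class GenotypeMatrix:
    """n_samples x n_variants effect-allele dosages; MISSING (-1) = no call."""

    dosages: np.ndarray
    sample_ids: list
    panel: VariantPanel

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape[1] != len(self.panel):
            raise ValueError("column count must equal panel variant count")
        ok = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or MISSING")

    @property
    def n_samples(self):
        return self.dosages.shape[0]

    @property
    def n_variants(self):
        return self.dosages.shape[1]


@dataclass
class ChromosomeGroup:
    chrom: int
    column_indices: list
    m: int = field(init=False)

    def __post_init__(self):
        self.m = len(self.column_indices)


class PanelFormatError(ValueError):
    pass


def _chrom_to_int(value) -> int | None:
    s = str(value).removeprefix("chr")
    try:
        return int(s)
    except ValueError:
        return None  # X, Y, MT, ...


def read_scoring_panel(paths: Sequence, trait_tags: Sequence) -> VariantPanel:
    """Read PGS-Catalog-style scoring files and return their deduplicated union.

    One trait tag per file. Variants present in several files keep the first
    file's effect weight and the union of trait tags. Non-autosomal rows are
    dropped (logged). The resulting panel is sorted by (chrom, pos).
    """
    if len(paths) != len(trait_tags):
        raise ValueError("one trait tag per scoring file is required")
    merged: dict = {}
    order: list = []
    n_dropped = 0
    for path, tag in zip(paths, trait_tags):
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        for internal, col in _PANEL_COLUMNS.items():
            if col not in df.columns:
                raise PanelFormatError(f"{path}: missing mandatory column '{col}'")
        for _, row in df.iterrows():
            chrom = _chrom_to_int(row["chr_name"])
            if chrom is None or not (1 <= chrom <= 22):
                n_dropped += 1
                continue
            v = Variant(
                rsid=str(row.get("rsID", "")),
                chrom=chrom,
                pos=int(row["chr_position"]),
                effect_allele=str(row["effect_allele"]),
                other_allele=str(row.get("other_allele", "")),
                effect_weight=float(row["effect_weight"]),
                trait_tags=frozenset([tag]),
            )
            if v.key in merged:
                old = merged[v.key]
                if old.effect_weight != v.effect_weight:
                    logger.warning("weight conflict at %s: keeping %s",
                                   v.key, old.effect_weight)
                merged[v.key] = Variant(old.rsid, old.chrom, old.pos,
                                        old.effect_allele, old.other_allele,
                                        old.effect_weight,
                                        old.trait_tags | v.trait_tags)
            else:
                merged[v.key] = v
                order.append(v.key)
    if n_dropped:
        logger.info("dropped %d non-autosomal panel rows", n_dropped)
    if not merged:
        raise PanelFormatError("empty panel after merging scoring files")
    variants = sorted(merged.values(), key=lambda v: (v.chrom, v.pos))
    return VariantPanel(variants)


def align_effect_allele(raw_dosage: int, effect_is_ref: bool) -> int:
    """Convert an ALT-allele count into an effect-allele count."""
    return 2 - raw_dosage if effect_is_ref else raw_dosage


def read_genotypes_vcf(path, panel: VariantPanel) -> GenotypeMatrix:
    """Extract panel variants from a VCF as effect-allele dosage columns.

    Matching is by (chrom, pos) with allele verification; panel variants
    absent from the VCF (or with mismatching alleles, or multi-allelic)
    become fully-MISSING columns with a warning. Half-calls and ``./.``
    are MISSING; phase is ignored.
    """
    from cyvcf2 import VCF

    by_site = {}
    for j, v in enumerate(panel.variants):
        by_site.setdefault((v.chrom, v.pos), []).append(j)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    dosages = np.full((n, len(panel)), MISSING, dtype=np.int8)
    filled = np.zeros(len(panel), dtype=bool)

    for rec in vcf:
        chrom = _chrom_to_int(rec.CHROM)
        if chrom is None:
            continue
        cols = by_site.get((chrom, rec.POS))
        if not cols:
            continue
        if len(rec.ALT) > 1:
            logger.warning("multi-allelic site %s:%d skipped", rec.CHROM, rec.POS)
            continue
        alt = rec.ALT[0] if rec.ALT else ""
        for j in cols:
            var = panel.variants[j]
            if var.effect_allele == alt and var.other_allele == rec.REF:
                effect_is_ref = False
            elif var.effect_allele == rec.REF and var.other_allele == alt:
                effect_is_ref = True
            else:
                logger.warning("allele mismatch for %s at %s:%d", var.rsid,
                               rec.CHROM, rec.POS)
                continue
            # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt; half-calls -> unknown
            raw = rec.gt_types.astype(int)
            col = np.full(n, MISSING, dtype=np.int8)
            col[raw == 0] = align_effect_allele(0, effect_is_ref)
            col[raw == 1] = align_effect_allele(1, effect_is_ref)
            col[raw == 3] = align_effect_allele(2, effect_is_ref)
            dosages[:, j] = col
            filled[j] = True
    vcf.close()

    n_absent = int((~filled).sum())
    if n_absent:
        logger.warning("%d panel variants absent from VCF; columns set MISSING",
                       n_absent)
    return GenotypeMatrix(dosages, samples, panel)


def group_by_chromosome(panel: VariantPanel) -> list:
    """Partition panel columns into 22 position-sorted chromosome groups."""
    groups = []
    for chrom in range(1, 23):
        cols = [j for j, v in enumerate(panel.variants) if v.chrom == chrom]
        cols.sort(key=lambda j: panel.variants[j].pos)
        groups.append(ChromosomeGroup(chrom, cols))
    return groups


def encode_states(dosages: np.ndarray, missing_policy: str = "state") -> tuple:
    """Map dosage values to allele-state indices for the embedding layer.

    Returns (states, V): under ``state`` MISSING becomes index 3 and V=4;
    under ``zero`` MISSING collapses to 0 and V=3.
    """
    states = np.asarray(dosages).copy()
    if missing_policy == "state":
        states[states == MISSING] = 3
        return states.astype(np.int64), 4
    if missing_policy == "zero":
        states[states == MISSING] = 0
        return states.astype(np.int64), 3
    raise ValueError(f"unknown missing_policy {missing_policy!r}")


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write dosages back out as a minimal biallelic VCF 4.2 text file.

    Dosage counts the effect allele, which is emitted as ALT so that a
    round-trip through :func:`read_genotypes_vcf` is exact.
    """
    gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in range(1, 23):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        for j, v in enumerate(geno.panel.variants):
            ref = v.other_allele or "A"
            calls = "\t".join(gt[int(d)] for d in geno.dosages[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.rsid or '.'}\t{ref}\t"
                     f"{v.effect_allele}\t.\tPASS\t.\tGT\t{calls}\n")


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype/covariate table (TSV or CSV, sniffed from the header)."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise ValueError("phenotype table must contain a sample_id column")
    return df
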