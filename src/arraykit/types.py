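"""Core domain containers shared across the array pipeline.

Conventions
-----------
* Coordinates are 1-based inclusive everywhere in memory; BED export is the
  only 0-based surface.
* Genotypes are alt-allele dosage codes: 0 = AA (hom ref), 1 = AB (het),
  2 = BB (hom alt), -1 = missing, matching Axiom calls-file conventions.
* Read depths use -1 for "unknown" (DP absent in the source VCF).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

MISSING = -1

GENOTYPE_LABELS = {0: "AA", 1: "AB", 2: "BB", MISSING: "NoCall"}
GENOTYPE_CODES = {v: k for k, v in GENOTYPE_LABELS.items()}

_NAT_SPLIT = re.compile(r"(\d+)")


def natural_key(name: str) -> tuple:
    """Sort key putting chr2 before chr10 (natural/chromosome order)."""
    return tuple(int(tok) if tok.isdigit() else tok
                 for tok in _NAT_SPLIT.split(str(name)))


@dataclass(frozen=True)
class GenomicInterval:
    """A pair of breakpoint coordinates on one scaffold.

    ``length`` is ``end - start``: the insertion occupies the gap between
    the two junction coordinates (breakpoint-flanking convention).
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class VariantRecord:
    """Single-site view of a :class:`VariantTable` row."""

    chrom: str
    pos: int
    ref: str
    alt: tuple[str, ...]
    af: float
    genotypes: np.ndarray
    depths: np.ndarray
    multiallelic: bool = False


@dataclass
class VariantTable:
    """Site-major container of multi-sample small-variant calls."""

    sample_ids: list[str]
    chrom: np.ndarray          # (n_sites,) str
    pos: np.ndarray            # (n_sites,) int64, 1-based
    ref: list[str]
    alt: list[tuple[str, ...]]
    af: np.ndarray             # (n_sites,) float64
    genotypes: np.ndarray      # (n_sites, n_samples) int8 dosage, -1 missing
    depths: np.ndarray         # (n_sites, n_samples) int32, -1 unknown
    multiallelic: np.ndarray   # (n_sites,) bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.pos)
        if not (len(self.chrom) == len(self.ref) == len(self.alt)
                == len(self.af) == len(self.multiallelic) == n):
            raise ValueError("inconsistent site-axis lengths")
        if self.genotypes.shape != (n, len(self.sample_ids)):
            raise ValueError("genotype matrix shape mismatch")
        if self.depths.shape != self.genotypes.shape:
            raise ValueError("depth matrix shape mismatch")
        if n and self.pos.min() < 1:
            raise ValueError("positions are 1-based and must be >= 1")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def record(self, i: int) -> VariantRecord:
        return VariantRecord(
            chrom=str(self.chrom[i]), pos=int(self.pos[i]), ref=self.ref[i],
            alt=tuple(self.alt[i]), af=float(self.af[i]),
            genotypes=self.genotypes[i], depths=self.depths[i],
            multiallelic=bool(self.multiallelic[i]))

    def __iter__(self) -> Iterator[VariantRecord]:
        return (self.record(i) for i in range(self.n_sites))

    def take(self, idx) -> "VariantTable":
        """Subset sites by integer or boolean index, preserving order."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return VariantTable(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
            af=self.af[idx],
            genotypes=self.genotypes[idx],
            depths=self.depths[idx],
            multiallelic=self.multiallelic[idx],
            meta=dict(self.meta))

    def sorted(self) -> "VariantTable":
        order = sorted(range(self.n_sites),
                       key=lambda i: (natural_key(self.chrom[i]), self.pos[i]))
        return self.take(np.asarray(order, dtype=np.intp))

    def is_snp(self) -> np.ndarray:
        """Boolean mask of sites where ref and every alt are single bases."""
        return np.array(
            [len(r) == 1 and all(len(a) == 1 for a in alts)
             for r, alts in zip(self.ref, self.alt)], dtype=bool)


@dataclass
class GenotypeMatrix:
    """Samples x markers array-style genotype calls."""

    sample_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray          # (n_samples, n_markers) int8
    marker_chrom: np.ndarray   # (n_markers,) str
    marker_pos: np.ndarray     # (n_markers,) int64, 1-based
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError("calls shape does not match id lists")
        if len(self.marker_chrom) != len(self.marker_ids):
            raise ValueError("marker_coords length mismatch")
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1,0,1,2}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def marker_indexer(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.marker_ids)}

    def take_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in ids]
        return GenotypeMatrix(
            sample_ids=list(ids), marker_ids=list(self.marker_ids),
            calls=self.calls[idx], marker_chrom=self.marker_chrom,
            marker_pos=self.marker_pos, meta=dict(self.meta))

    def take_markers(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lut = self.marker_indexer()
        idx = np.array([lut[m] for m in ids], dtype=np.intp)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids), marker_ids=list(ids),
            calls=self.calls[:, idx], marker_chrom=self.marker_chrom[idx],
            marker_pos=self.marker_pos[idx], meta=dict(self.meta))

    def sample_call_rates(self) -> np.ndarray:
        """Per-sample percentage of non-missing calls."""
        if self.n_markers == 0:
            return np.full(self.n_samples, np.nan)
        return 100.0 * (self.calls != MISSING).mean(axis=1)

    def marker_call_rates(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.full(self.n_markers, np.nan)
        return 100.0 * (self.calls != MISSING).mean(axis=0)


@dataclass
class IntensityTable:
    """Samples x probes signal intensities (single summarised channel)."""

    sample_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray         # (n_samples, n_probes) float64, >= 0
    probe_chrom: np.ndarray
    probe_pos: np.ndarray      # interrogated junction, 1-based
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sample_ids), len(self.probe_ids)):
            raise ValueError("values shape does not match id lists")
        if np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def take_probes(self, ids: Sequence[str]) -> "IntensityTable":
        lut = {p: i for i, p in enumerate(self.probe_ids)}
        idx = np.array([lut[p] for p in ids], dtype=np.intp)
        return IntensityTable(
            sample_ids=list(self.sample_ids), probe_ids=list(ids),
            values=self.values[:, idx], probe_chrom=self.probe_chrom[idx],
            probe_pos=self.probe_pos[idx], meta=dict(self.meta))


PANEL_CATEGORIES = (
    "genome_wide", "gsdf_region_snp", "sex_segregating_snp",
    "te_breakpoint_probe")

PANEL_COLUMNS = ["marker_id", "chrom", "pos", "ref", "alt", "maf", "category"]


@dataclass
class MarkerPanel:
    """Ordered selected loci with category annotations.

    Backed by a DataFrame with columns ``marker_id, chrom, pos, ref, alt,
    maf, category``; TE breakpoint probes carry '.' alleles and NaN MAF.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"panel missing columns {missing}")
        bad = set(self.df["category"]) - set(PANEL_CATEGORIES)
        if bad:
            raise ValueError(f"unknown panel categories {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self) -> "MarkerPanel":
        key = self.df["chrom"].map(natural_key)
        out = self.df.assign(_k=key).sort_values(
            ["_k", "pos"], kind="mergesort").drop(columns="_k")
        return MarkerPanel(out.reset_index(drop=True))

    def category_counts(self) -> dict[str, int]:
        counts = self.df["category"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in PANEL_CATEGORIES}

    def sex_subtotal(self) -> int:
        """Loci potentially informative for genetic sex (categories a+b+c)."""
        c = self.category_counts()
        return (c["gsdf_region_snp"] + c["sex_segregating_snp"]
                + c["te_breakpoint_probe"])

    def subset(self, categories: Sequence[str]) -> "MarkerPanel":
        return MarkerPanel(
            self.df[self.df["category"].isin(categories)].reset_index(drop=True))


SAMPLESHEET_COLUMNS = [
    "sample_id", "phenotypic_sex", "true_genetic_sex", "duplicate_of",
    "dish_qc"]

PHENOTYPE_LABELS = ("female", "male", "neomale", "unknown")
GENETIC_SEXES = ("female", "male")
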