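"""Readers and writers for the formats the pipeline touches.

VCF is read through :mod:`cyvcf2`. Tabular surfaces (calls matrix,
intensity matrix, sample sheet, marker panel) are plain TSV with markers
or probes as rows and samples as columns. All writers emit deterministic
ordering: natural chromosome sort, then position.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (GENOTYPE_CODES, GENOTYPE_LABELS, MISSING, PANEL_COLUMNS,
                    SAMPLESHEET_COLUMNS, GenomicInterval, GenotypeMatrix,
                    IntensityTable, MarkerPanel, VariantTable, natural_key)

log = logging.getLogger(__name__)


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a breakpoint-flanked interval: ``end - start``.

    The two coordinates are the junctions flanking an insertion, so the
    inserted sequence occupies the gap between them.
    """
    return iv.length


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, sample_subset: Optional[Sequence[str]] = None) -> VariantTable:
    """Read a (possibly bgzipped) VCF with GT and DP FORMAT fields.

    Half-calls and phased separators are normalised to unphased dosage;
    any allele index > 1 (at a flagged multi-allelic site) becomes missing
    for array-style analyses, with a logged count. ``af`` is taken from
    INFO/AF when present, otherwise computed from the genotypes. Missing
    DP is recorded as -1 (unknown) and counted.
    """
    vcf = VCF(str(path))
    try:
        vcf.get_header_type("GT")
    except KeyError:
        raise ValueError(f"{path}: VCF has no GT FORMAT field") from None
    try:
        vcf.get_header_type("DP")
        has_dp_header = True
    except KeyError:
        has_dp_header = False

    if sample_subset is not None:
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)
    n = len(samples)

    chroms, poss, refs, alts, afs, multi = [], [], [], [], [], []
    gts, dps = [], []
    n_alt2_to_missing = 0
    n_missing_dp = 0

    for var in vcf:
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alt = tuple(var.ALT)
        alts.append(alt)
        multi.append(len(alt) > 1)

        g = np.full(n, MISSING, dtype=np.int8)
        for i, call in enumerate(var.genotypes):
            a, b = call[0], call[1]
            if a < 0 or b < 0:
                continue  # missing or half-call -> missing
            if a > 1 or b > 1:
                n_alt2_to_missing += 1
                continue
            g[i] = a + b
        gts.append(g)

        dp = var.format("DP") if has_dp_header else None
        if dp is None:
            d = np.full(n, -1, dtype=np.int32)
            n_missing_dp += 1
        else:
            d = dp.reshape(-1).astype(np.int32, copy=False).copy()
            d[d < 0] = -1
        dps.append(d)

        info_af = var.INFO.get("AF")
        if info_af is not None:
            af = float(info_af[0] if isinstance(info_af, tuple) else info_af)
        else:
            ok = g >= 0
            af = float(g[ok].sum() / (2.0 * ok.sum())) if ok.any() else np.nan
        afs.append(af)

    if n_alt2_to_missing:
        log.info("read_vcf: %d genotype(s) with allele index > 1 set missing",
                 n_alt2_to_missing)
    if n_missing_dp:
        log.info("read_vcf: %d site(s) lack DP; depths recorded as unknown",
                 n_missing_dp)

    n_sites = len(poss)
    return VariantTable(
        sample_ids=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=refs,
        alt=alts,
        af=np.array(afs, dtype=np.float64),
        genotypes=(np.vstack(gts) if n_sites else
                   np.empty((0, n), dtype=np.int8)),
        depths=(np.vstack(dps) if n_sites else
                np.empty((0, n), dtype=np.int32)),
        multiallelic=np.array(multi, dtype=bool),
        meta={"n_alt2_to_missing": n_alt2_to_missing,
              "n_missing_dp": n_missing_dp})


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(vt: VariantTable, path) -> None:
    """Write a minimal VCF 4.2 with INFO/AF and GT:DP genotypes."""
    vt = vt.sorted()
    contigs = sorted(set(map(str, vt.chrom)), key=natural_key)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,'
                 'Description="Alternate allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vt.sample_ids) + "\n")
        for i in range(vt.n_sites):
            alt = ",".join(vt.alt[i]) if vt.alt[i] else "."
            af = vt.af[i]
            info = f"AF={af:.6g}" if np.isfinite(af) else "."
            cells = []
            for g, d in zip(vt.genotypes[i], vt.depths[i]):
                dp = "." if d < 0 else str(int(d))
                cells.append(f"{_GT_STR[int(g)]}:{dp}")
            fh.write(f"{vt.chrom[i]}\t{vt.pos[i]}\t.\t{vt.ref[i]}\t{alt}\t.\t"
                     f"PASS\t{info}\tGT:DP\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# calls / intensity matrices (markers as rows, samples as columns)
# ---------------------------------------------------------------------------

def write_calls_tsv(gm: GenotypeMatrix, path) -> None:
    labels = np.array([GENOTYPE_LABELS[c] for c in (-1, 0, 1, 2)])
    coded = labels[gm.calls + 1]  # shift -1..2 -> 0..3
    df = pd.concat(
        [pd.DataFrame({"marker_id": gm.marker_ids,
                       "chrom": gm.marker_chrom,
                       "pos": gm.marker_pos}),
         pd.DataFrame(coded.T, columns=gm.sample_ids)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["marker_id", "chrom", "pos"]
    samples = [c for c in df.columns if c not in meta_cols]
    calls = np.empty((len(samples), len(df)), dtype=np.int8)
    for j, s in enumerate(samples):
        calls[j] = df[s].map(GENOTYPE_CODES).to_numpy(dtype=np.int8)
    return GenotypeMatrix(
        sample_ids=samples, marker_ids=df["marker_id"].astype(str).tolist(),
        calls=calls, marker_chrom=df["chrom"].to_numpy(dtype=object),
        marker_pos=df["pos"].to_numpy(dtype=np.int64))


def write_intensity_tsv(it: IntensityTable, path) -> None:
    df = pd.concat(
        [pd.DataFrame({"probe_id": it.probe_ids,
                       "chrom": it.probe_chrom,
                       "pos": it.probe_pos}),
         pd.DataFrame(it.values.T, columns=it.sample_ids)], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_intensity_tsv(path) -> IntensityTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["probe_id", "chrom", "pos"]
    samples = [c for c in df.columns if c not in meta_cols]
    values = df[samples].to_numpy(dtype=np.float64).T
    return IntensityTable(
        sample_ids=samples, probe_ids=df["probe_id"].astype(str).tolist(),
        values=values, probe_chrom=df["chrom"].to_numpy(dtype=object),
        probe_pos=df["pos"].to_numpy(dtype=np.int64))


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    missing = [c for c in SAMPLESHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns {missing}")
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in SAMPLESHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns {missing}")
    sheet["duplicate_of"] = sheet["duplicate_of"].fillna("").astype(str)
    return sheet


# ---------------------------------------------------------------------------
# marker panel (TSV + BED)
# ---------------------------------------------------------------------------

def write_panel(panel: MarkerPanel, path) -> tuple[Path, Path]:
    """Write a panel as TSV and BED.

    The TSV keeps 1-based positions; the BED is 0-based half-open, so BED
    start = pos - 1 and BED end = pos for point loci.
    Returns (tsv_path, bed_path).
    """
    if len(panel) == 0:
        raise ValueError("refusing to write an empty panel")
    panel = panel.sorted()
    tsv_path = Path(path)
    bed_path = tsv_path.with_suffix(".bed")
    df = panel.df.copy()
    df["alleles"] = df["ref"].astype(str) + "/" + df["alt"].astype(str)
    df[["marker_id", "chrom", "pos", "alleles", "maf", "category"]].to_csv(
        tsv_path, sep="\t", index=False, float_format="%.6g")
    bed = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["pos"].astype(np.int64) - 1,
        "end": df["pos"].astype(np.int64),
        "name": df["marker_id"]})
    bed.to_csv(bed_path, sep="\t", index=False, header=False)
    return tsv_path, bed_path


def read_panel(path) -> MarkerPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    ra = df["alleles"].astype(str).str.split("/", n=1, expand=True)
    df["ref"], df["alt"] = ra[0], ra[1]
    return MarkerPanel(df[PANEL_COLUMNS].copy())
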