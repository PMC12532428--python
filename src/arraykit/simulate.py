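"""Synthetic cohort generator.

Emulates the statistical structure the downstream analyses assume: a
24-chromosome genome plus unplaced scaffolds, a uniform MAF spectrum,
Hardy-Weinberg genotypes with optional inbreeding, male-heterozygous
sex-linked SNPs on one chromosome (a *gsdf*-linked XX/XY-like locus),
two male-only TE insertions whose breakpoint probes lose signal in
females, array genotyping error and missingness, phenotype mislabels
(including neomales: genetic females with male phenotype), and
re-genotyped duplicate samples.

Sites are drawn independently (no haplotype structure); every random
draw flows from a single seed so identical configs give byte-identical
outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (MISSING, GenomicInterval, GenotypeMatrix, IntensityTable,
                    VariantTable)

# Real coordinates of the sex locus on chromosome 13: the gsdf gene region
# and the two male-specific Gypsy-like TE insertions flanking/within it.
GSDF_REGION = GenomicInterval("chr13", 8_506_700, 8_510_213)
TE_INSERTIONS = (GenomicInterval("chr13", 8_503_901, 8_505_128),
                 GenomicInterval("chr13", 8_509_688, 8_509_767))


@dataclass
class SimConfig:
    """Study-condition parameters for :func:`simulate_cohort`.

    Defaults mirror the study design: 40 sequenced broodstock (20 of each
    sex), a validation cohort phenotyped as 114 females / 22 males / 18
    neomales, 6 sex-reversed phenotypic males and 1 masculinised neomale
    planted as mislabels, a 59-SNP sex-segregating panel, 245 gsdf-region
    SNPs (42 of them sex-linked) and 334 TE-breakpoint probes. The genome
    is scaled to 24 x 9 Mb chromosomes (chr13 keeps the real sex-locus
    coordinates) at ~1 site / 3 kb.
    """

    # genome
    n_chrom: int = 24
    chrom_length: int = 9_000_000
    n_unplaced: int = 6
    unplaced_length: int = 200_000
    site_density: float = 1.0 / 3000.0
    # cohort
    n_wgs: int = 40
    n_validation: int = 154
    phenotype_counts: Optional[tuple[int, int, int]] = (114, 22, 18)
    n_sexrev_males: int = 6        # phenotypic males that are genetic females
    n_masc_neomales: int = 1       # neomale labels that are genetic males
    # allele frequencies / genotypes
    maf_min: float = 0.01
    inbreeding_f: float = 0.0
    genotype_error: float = 0.005
    missing_rate: float = 0.0036   # array no-call rate (mean call rate 99.64%)
    n_lowqual_samples: int = 0
    lowqual_missing_rate: float = 0.15
    # sequencing depth (negative binomial)
    depth_mean: float = 20.0
    depth_size: float = 100.0      # NB size parameter; larger = less dispersed
    # sex system
    sex_chrom: str = "chr13"
    gsdf_region: GenomicInterval = GSDF_REGION
    te_intervals: tuple[GenomicInterval, ...] = TE_INSERTIONS
    n_sex_snps: int = 59
    n_gsdf_sites: int = 245
    n_gsdf_sexlinked: int = 42
    # TE breakpoint probes and intensity model
    n_te_probes: int = 334
    te_flank: int = 100
    probe_len: int = 35
    mu_present: float = 1500.0
    mu_absent: float = 700.0
    intensity_sd: float = 150.0
    # sample-level QC attribute
    dish_qc_mean: float = 0.95
    dish_qc_sd: float = 0.02
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("maf_min", "inbreeding_f", "genotype_error",
                     "missing_rate", "lowqual_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mu_present <= self.mu_absent:
            raise ValueError("mu_present must exceed mu_absent")
        if self.n_wgs + self.n_validation < 2:
            raise ValueError("need at least 2 samples")
        if self.n_wgs % 2:
            raise ValueError("n_wgs must be even (balanced sexes)")


@dataclass
class SimulatedCohort:
    """Bundle of simulated data plus the generating truth.

    Iterating yields ``(variants, genotypes, intensities, sheet)`` so the
    cohort unpacks as the four primary outputs.
    """

    variants: VariantTable
    genotypes: GenotypeMatrix
    intensities: IntensityTable
    sheet: pd.DataFrame
    sites: pd.DataFrame            # chrom, pos, alt_af, sexlinked, in_gsdf
    truth: np.ndarray              # (n_samples, n_sites) error-free calls
    informative_probes: list[str]  # probes whose 35-mer spans a breakpoint
    config: SimConfig = field(repr=False, default=None)

    def __iter__(self) -> Iterator:
        return iter((self.variants, self.genotypes, self.intensities,
                     self.sheet))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _draw_positions(rng, length: int, n: int,
                    forbidden: Sequence[tuple[int, int]] = ()) -> np.ndarray:
    """Draw n distinct 1-based positions avoiding forbidden [lo, hi] zones."""
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    taken = np.empty(0, dtype=np.int64)
    want = n
    for _ in range(100):
        cand = rng.choice(length, size=min(length, int(want * 1.3) + 16),
                          replace=False).astype(np.int64) + 1
        ok = np.ones(len(cand), dtype=bool)
        for lo, hi in forbidden:
            ok &= (cand < lo) | (cand > hi)
        cand = cand[ok]
        taken = np.unique(np.concatenate([taken, cand]))
        if len(taken) >= n:
            break
        want = n - len(taken)
    if len(taken) < n:
        raise ValueError("cannot place sites: genome too constrained")
    return np.sort(rng.choice(taken, size=n, replace=False))


def _apportion(total: int, k: int) -> list[int]:
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _phenotype_counts(cfg: SimConfig) -> tuple[int, int, int]:
    if cfg.phenotype_counts is not None and \
            sum(cfg.phenotype_counts) == cfg.n_validation:
        return tuple(cfg.phenotype_counts)
    # largest-remainder apportionment of the default 114:22:18 ratio
    fracs = np.array([114, 22, 18], dtype=float) / 154.0
    raw = fracs * cfg.n_validation
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: cfg.n_validation - counts.sum()]:
        counts[i] += 1
    return tuple(int(c) for c in counts)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate a synthetic cohort under the configured study conditions."""
    rng = np.random.default_rng(cfg.seed)
    flank_zone = cfg.te_flank + cfg.probe_len // 2
    breakpoints = [bp for te in cfg.te_intervals for bp in (te.start, te.end)]
    bp_zones = [(bp - flank_zone, bp + flank_zone) for bp in breakpoints]

    # --- samples -----------------------------------------------------------
    n_f, n_m, n_n = _phenotype_counts(cfg)
    brood_ids = [f"BRD{i + 1:04d}" for i in range(cfg.n_wgs)]
    val_ids = [f"VAL{i + 1:04d}" for i in range(cfg.n_validation)]
    sample_ids = brood_ids + val_ids

    brood_sex = np.array(["female", "male"] * (cfg.n_wgs // 2), dtype=object)
    pheno_val = np.array(["female"] * n_f + ["male"] * n_m
                         + ["neomale"] * n_n, dtype=object)
    pheno_val = rng.permutation(pheno_val)
    true_val = np.where(pheno_val == "male", "male", "female").astype(object)
    # planted phenotype mislabels
    male_idx = np.flatnonzero(pheno_val == "male")
    neo_idx = np.flatnonzero(pheno_val == "neomale")
    for idx_pool, n_flip, new_truth in (
            (male_idx, cfg.n_sexrev_males, "female"),
            (neo_idx, cfg.n_masc_neomales, "male")):
        n_flip = min(n_flip, len(idx_pool))
        if n_flip:
            flip = rng.choice(idx_pool, size=n_flip, replace=False)
            true_val[flip] = new_truth

    phenotypic_sex = np.concatenate([brood_sex, pheno_val])
    true_sex = np.concatenate([brood_sex.copy(), true_val])
    is_male = true_sex == "male"
    n_samples = len(sample_ids)

    dish_qc = np.clip(rng.normal(cfg.dish_qc_mean, cfg.dish_qc_sd, n_samples),
                      0.0, 1.0)

    # --- sites -------------------------------------------------------------
    chrom_lengths = {f"chr{i + 1}": cfg.chrom_length
                     for i in range(cfg.n_chrom)}
    chrom_lengths.update({f"scaffold_{i + 1}": cfg.unplaced_length
                          for i in range(cfg.n_unplaced)})
    if cfg.sex_chrom not in chrom_lengths:
        raise ValueError(f"sex chromosome {cfg.sex_chrom} not in genome")

    chroms, poss, sexlinked, in_gsdf = [], [], [], []
    gsdf = cfg.gsdf_region
    for chrom, length in chrom_lengths.items():
        n_sites = int(round(length * cfg.site_density))
        if chrom == cfg.sex_chrom:
            # planted sex-segregating panel (outside gsdf, off breakpoints)
            forb = bp_zones + [(gsdf.start, gsdf.end)]
            sex_pos = _draw_positions(rng, length, cfg.n_sex_snps, forb)
            # planted gsdf-region sites (off the TE2 breakpoints)
            gsdf_pos = gsdf.start + _draw_positions(
                rng, gsdf.end - gsdf.start + 1, cfg.n_gsdf_sites,
                [(lo - gsdf.start + 1, hi - gsdf.start + 1)
                 for lo, hi in bp_zones]) - 1
            gsdf_linked = np.zeros(cfg.n_gsdf_sites, dtype=bool)
            if cfg.n_gsdf_sexlinked:
                pick = rng.choice(cfg.n_gsdf_sites,
                                  size=min(cfg.n_gsdf_sexlinked,
                                           cfg.n_gsdf_sites), replace=False)
                gsdf_linked[pick] = True
            taken = [(p, p) for p in np.concatenate([sex_pos, gsdf_pos])]
            rand_pos = _draw_positions(rng, length, n_sites,
                                       forb + taken)
            pos = np.concatenate([rand_pos, sex_pos, gsdf_pos])
            link = np.concatenate([
                np.zeros(len(rand_pos), dtype=bool),
                np.ones(len(sex_pos), dtype=bool),
                gsdf_linked])
            ing = np.concatenate([
                np.zeros(len(rand_pos) + len(sex_pos), dtype=bool),
                np.ones(len(gsdf_pos), dtype=bool)])
            order = np.argsort(pos)
            pos, link, ing = pos[order], link[order], ing[order]
        else:
            pos = _draw_positions(rng, length, n_sites)
            link = np.zeros(len(pos), dtype=bool)
            ing = np.zeros(len(pos), dtype=bool)
        chroms.append(np.full(len(pos), chrom, dtype=object))
        poss.append(pos)
        sexlinked.append(link)
        in_gsdf.append(ing)

    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(poss)
    sexlinked = np.concatenate(sexlinked)
    in_gsdf = np.concatenate(in_gsdf)
    n_sites = len(pos_arr)

    # alleles: random ordered base pairs (W/S pairs arise naturally)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4
    ref = bases[ref_idx]
    alt = bases[alt_idx]

    maf = rng.uniform(cfg.maf_min, 0.5, n_sites)
    alt_is_minor = rng.random(n_sites) < 0.5
    alt_af = np.where(alt_is_minor, maf, 1.0 - maf)
    # sex-linked sites: which allele is fixed in females is random per site
    female_hom = np.where(rng.random(n_sites) < 0.5, 0, 2).astype(np.int8)

    # --- truth genotypes (samples x sites) ---------------------------------
    F = cfg.inbreeding_f
    p = alt_af
    q = 1.0 - p
    p_hom_ref = q * q + F * p * q
    p_het = 2.0 * p * q * (1.0 - F)
    t1 = p_hom_ref
    t2 = p_hom_ref + p_het
    truth = np.empty((n_samples, n_sites), dtype=np.int8)
    block = max(1024, 16_000_000 // n_samples)  # cap transient memory
    for lo in range(0, n_sites, block):
        hi = min(lo + block, n_sites)
        u = rng.random((n_samples, hi - lo))
        g = (u >= t1[lo:hi]).astype(np.int8)
        g += (u >= t2[lo:hi]).astype(np.int8)
        truth[:, lo:hi] = g
    # overwrite sex-linked sites: males het, females fixed-homozygous
    sl = np.flatnonzero(sexlinked)
    truth[np.ix_(is_male, sl)] = 1
    truth[np.ix_(~is_male, sl)] = np.broadcast_to(
        female_hom[sl], ((~is_male).sum(), len(sl)))

    # --- variant table (WGS broodstock subset, error-free) -----------------
    wgs_idx = np.arange(cfg.n_wgs)
    wgs_gt = truth[wgs_idx].T.copy()                       # sites x wgs
    af_emp = wgs_gt.mean(axis=1) / 2.0
    depths = rng.negative_binomial(
        cfg.depth_size, cfg.depth_size / (cfg.depth_size + cfg.depth_mean),
        size=wgs_gt.shape).astype(np.int32)
    variants = VariantTable(
        sample_ids=brood_ids,
        chrom=chrom_arr, pos=pos_arr,
        ref=list(ref), alt=[(a,) for a in alt],
        af=af_emp,
        genotypes=wgs_gt, depths=depths,
        multiallelic=np.zeros(n_sites, dtype=bool),
        meta={"drawn_alt_af": alt_af})

    # --- array calls: error then missingness, after truth is recorded ------
    calls = truth.copy()
    if cfg.genotype_error > 0:
        err = rng.random(calls.shape) < cfg.genotype_error
        shift = rng.integers(1, 3, size=calls.shape).astype(np.int8)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    miss_rate = np.full(n_samples, cfg.missing_rate)
    lowqual_ids: list[str] = []
    if cfg.n_lowqual_samples:
        low = rng.choice(np.arange(cfg.n_wgs, n_samples),
                         size=cfg.n_lowqual_samples, replace=False)
        miss_rate[low] = cfg.lowqual_missing_rate
        lowqual_ids = [sample_ids[i] for i in sorted(low)]
    if miss_rate.any():
        miss = rng.random(calls.shape) < miss_rate[:, None]
        calls = np.where(miss, MISSING, calls).astype(np.int8)

    marker_ids = [f"{c}_{p}" for c, p in zip(chrom_arr, pos_arr)]
    genotypes = GenotypeMatrix(
        sample_ids=list(sample_ids), marker_ids=marker_ids, calls=calls,
        marker_chrom=chrom_arr.copy(), marker_pos=pos_arr.copy(),
        meta={"lowqual_samples": lowqual_ids})

    # --- TE breakpoint probe intensities -----------------------------------
    probe_pos, probe_bp = [], []
    for bp, count in zip(breakpoints, _apportion(cfg.n_te_probes,
                                                 len(breakpoints))):
        grid = np.linspace(bp - cfg.te_flank, bp + cfg.te_flank,
                           count).round().astype(np.int64)
        probe_pos.append(grid)
        probe_bp.append(np.full(count, bp, dtype=np.int64))
    probe_pos = np.concatenate(probe_pos)
    probe_bp = np.concatenate(probe_bp)
    informative = np.abs(probe_pos - probe_bp) <= cfg.probe_len // 2
    probe_ids = [f"TE_{cfg.sex_chrom}_{p}_{i}"
                 for i, p in enumerate(probe_pos)]
    mu = np.where(informative[None, :] & ~is_male[:, None],
                  cfg.mu_absent, cfg.mu_present)
    values = np.clip(rng.normal(mu, cfg.intensity_sd), 0.0, None)
    intensities = IntensityTable(
        sample_ids=list(sample_ids), probe_ids=probe_ids, values=values,
        probe_chrom=np.full(len(probe_ids), cfg.sex_chrom, dtype=object),
        probe_pos=probe_pos,
        meta={"breakpoint": probe_bp, "informative": informative})

    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "phenotypic_sex": phenotypic_sex,
        "true_genetic_sex": true_sex,
        "duplicate_of": [""] * n_samples,
        "dish_qc": np.round(dish_qc, 4),
        "group": ["broodstock"] * cfg.n_wgs + ["validation"] * cfg.n_validation,
    })

    sites = pd.DataFrame({
        "chrom": chrom_arr, "pos": pos_arr, "ref": ref, "alt": alt,
        "alt_af": alt_af, "sexlinked": sexlinked, "in_gsdf": in_gsdf})

    return SimulatedCohort(
        variants=variants, genotypes=genotypes, intensities=intensities,
        sheet=sheet, sites=sites, truth=truth,
        informative_probes=[p for p, i in zip(probe_ids, informative) if i],
        config=cfg)


# ---------------------------------------------------------------------------
# duplicate samples
# ---------------------------------------------------------------------------

def inject_duplicates(gm: GenotypeMatrix, sheet: pd.DataFrame, n_pairs: int,
                      miss_rate: float = 0.02, disc_rate: float = 0.004,
                      seed: int = 0) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Append re-genotyped copies of ``n_pairs`` samples.

    The copy equals the original except for independent missingness
    (``miss_rate``) and genotype flips (``disc_rate``); the provenance is
    recorded in the sheet's ``duplicate_of`` column, and the exact planted
    per-pair difference counts go to ``gm.meta['duplicate_truth']``.
    """
    for name, r in (("miss_rate", miss_rate), ("disc_rate", disc_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [0, 1]")
    if n_pairs > gm.n_samples:
        raise ValueError("n_pairs exceeds number of samples")
    rng = np.random.default_rng(seed)
    originals = [s for s in gm.sample_ids
                 if not s.endswith("_rep")]
    src = sorted(rng.choice(len(originals), size=n_pairs, replace=False))
    src_ids = [originals[i] for i in src]

    new_rows, new_ids, truth_counts = [], [], []
    for sid in src_ids:
        orig = gm.calls[gm.sample_index(sid)].copy()
        rep = orig.copy()
        called = rep != MISSING
        flip = (rng.random(rep.shape) < disc_rate) & called
        shift = rng.integers(1, 3, size=rep.shape).astype(np.int8)
        rep = np.where(flip, (rep + shift) % 3, rep).astype(np.int8)
        drop = rng.random(rep.shape) < miss_rate
        rep = np.where(drop, MISSING, rep).astype(np.int8)
        differs = orig != rep
        one_missing = differs & ((orig == MISSING) ^ (rep == MISSING))
        both_called = differs & (orig != MISSING) & (rep != MISSING)
        truth_counts.append({
            "sample_id": sid, "replicate_id": f"{sid}_rep",
            "n_inconsistencies": int(differs.sum()),
            "n_missing_type": int(one_missing.sum()),
            "n_discordant_type": int(both_called.sum())})
        new_rows.append(rep)
        new_ids.append(f"{sid}_rep")

    out = GenotypeMatrix(
        sample_ids=list(gm.sample_ids) + new_ids,
        marker_ids=list(gm.marker_ids),
        calls=np.vstack([gm.calls] + [r[None, :] for r in new_rows]),
        marker_chrom=gm.marker_chrom, marker_pos=gm.marker_pos,
        meta={**gm.meta, "duplicate_truth": truth_counts})

    extra = sheet[sheet["sample_id"].isin(src_ids)].copy()
    extra = extra.set_index("sample_id").loc[src_ids].reset_index()
    extra["duplicate_of"] = extra["sample_id"]
    extra["sample_id"] = new_ids
    out_sheet = pd.concat([sheet, extra], ignore_index=True)
    return out, out_sheet


def scaled_config(seed: int = 17, **overrides) -> SimConfig:
    """A desk-scale config: 4 chromosomes, small cohort, same rates.

    Keeps every rate and the sex-system layout at study defaults but
    shrinks the genome and cohort so end-to-end runs finish in seconds.
    """
    base = dict(
        n_chrom=4, chrom_length=1_000_000, n_unplaced=2,
        unplaced_length=100_000, site_density=1 / 2000,
        n_wgs=20, n_validation=77, phenotype_counts=(57, 11, 9),
        n_sexrev_males=3, n_masc_neomales=1,
        n_sex_snps=30, n_gsdf_sites=60, n_gsdf_sexlinked=20,
        n_te_probes=80,
        sex_chrom="chr4",
        gsdf_region=GenomicInterval("chr4", 650_000, 653_513),
        te_intervals=(GenomicInterval("chr4", 647_201, 648_428),
                      GenomicInterval("chr4", 652_988, 653_067)),
        seed=seed)
    base.update(overrides)
    return SimConfig(**base)
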