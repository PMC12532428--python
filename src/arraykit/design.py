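"""Array-content design: candidate filtering, interval spacing, trimming
and sex-locus enrichment.

The genome-wide track filters multi-sample variant calls (bi-allelic SNPs,
no strand-ambiguous A/T / C/G pairs, 0.1 < AF < 0.9, every sample's depth
strictly between 5 and 30), then greedily selects loci spaced at a 3 kb
target and trims any locus closer than 3150 bp to its retained
predecessor, plus loci with MAF exactly 0.5. Three sex-locus categories
are added separately: (a) SNPs inside the gsdf gene region, (b) SNPs
homozygous in every labelled female and heterozygous in every labelled
male, and (c) non-polymorphic probe targets tiled +/-100 bp around the
four TE insertion breakpoints.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (MISSING, GenomicInterval, MarkerPanel, VariantTable,
                    natural_key)

log = logging.getLogger(__name__)

WS_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})


@dataclass
class DesignParams:
    """Thresholds of the array-content pipeline (defaults as published)."""

    af_window: tuple[float, float] = (0.1, 0.9)   # exclusive bounds
    dp_window: tuple[int, int] = (6, 29)          # inclusive; DP>5 and DP<30
    exclude_ws: bool = True
    spacing_target: int = 3000
    min_gap: int = 3150
    drop_maf_half: bool = True
    breakpoint_flank: int = 100
    probe_len: int = 35
    te_probe_budget: Optional[int] = 334

    def __post_init__(self) -> None:
        lo, hi = self.af_window
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("AF window must satisfy 0 < lo < hi < 1")
        if self.dp_window[0] >= self.dp_window[1]:
            raise ValueError("DP window lo must be < hi")
        if self.spacing_target <= 0:
            raise ValueError("spacing_target must be positive")
        if self.min_gap < self.spacing_target:
            raise ValueError("min_gap must be >= spacing_target")


# ---------------------------------------------------------------------------
# variant filtering
# ---------------------------------------------------------------------------

def filter_variants(vt: VariantTable, p: DesignParams) -> VariantTable:
    """Keep bi-allelic, strand-unambiguous SNPs inside the AF/DP windows.

    Each site is charged to the first rule that rejects it; the attrition
    table is logged and stored in ``result.meta['attrition']``.
    """
    if vt.n_sites == 0:
        raise ValueError("empty variant table")
    n = vt.n_sites
    keep = np.ones(n, dtype=bool)
    attrition: dict[str, int] = {"input": n}

    def charge(rule: str, rejected: np.ndarray) -> None:
        newly = rejected & keep
        attrition[rule] = int(newly.sum())
        keep[newly] = False

    charge("not_snp", ~vt.is_snp())
    charge("multiallelic",
           vt.multiallelic | np.array([len(a) != 1 for a in vt.alt]))
    if p.exclude_ws:
        ws = np.array(
            [len(alts) == 1 and frozenset((r, alts[0])) in WS_PAIRS
             for r, alts in zip(vt.ref, vt.alt)])
        charge("ws_ambiguous", ws)
    lo, hi = p.af_window
    charge("af_window", ~((vt.af > lo) & (vt.af < hi)))
    dp_lo, dp_hi = p.dp_window
    dp_known = vt.depths >= 0
    charge("dp_unknown", ~dp_known.all(axis=1))
    in_window = (vt.depths >= dp_lo) & (vt.depths <= dp_hi)
    charge("dp_window", ~in_window.all(axis=1))

    attrition["output"] = int(keep.sum())
    log.info("filter_variants attrition: %s", attrition)
    out = vt.take(keep)
    out.meta["attrition"] = attrition
    return out


# ---------------------------------------------------------------------------
# spacing selection and trimming
# ---------------------------------------------------------------------------

def _panel_df(chrom, pos, ref, alt, maf, category) -> pd.DataFrame:
    return pd.DataFrame({
        "marker_id": [f"{c}_{p}" for c, p in zip(chrom, pos)],
        "chrom": np.asarray(chrom, dtype=object),
        "pos": np.asarray(pos, dtype=np.int64),
        "ref": ref, "alt": alt,
        "maf": maf, "category": category})


def select_spaced(vt: VariantTable, p: DesignParams) -> MarkerPanel:
    """Greedy per-scaffold selection of loci spaced at the 3 kb target.

    The first site on each scaffold is accepted; thereafter, among sites
    at distance >= ``spacing_target`` from the last accepted site, the one
    closest to ``last + spacing_target`` is accepted (with sites sorted by
    position this is the first such site; a coordinate tie would resolve
    to the smaller position).
    """
    vt = vt.sorted()
    rows = []
    for chrom in sorted(set(map(str, vt.chrom)), key=natural_key):
        idx = np.flatnonzero(vt.chrom == chrom)
        pos = vt.pos[idx]
        i = 0
        while i < len(idx):
            rows.append(idx[i])
            nxt = np.searchsorted(pos, pos[i] + p.spacing_target, side="left")
            i = nxt
    rows = np.asarray(rows, dtype=np.intp)
    maf = np.minimum(vt.af[rows], 1.0 - vt.af[rows])
    df = _panel_df(vt.chrom[rows], vt.pos[rows],
                   [vt.ref[i] for i in rows],
                   [vt.alt[i][0] if vt.alt[i] else "." for i in rows],
                   maf, "genome_wide")
    return MarkerPanel(df)


def trim_panel(panel: MarkerPanel, p: DesignParams) -> MarkerPanel:
    """Drop MAF = 0.5 loci, then loci too close to a retained predecessor.

    The gap pass is a single left-to-right scan per scaffold: a locus is
    dropped when its distance to the nearest *retained* preceding locus on
    the same scaffold is < ``min_gap``. Only genome-wide loci are subject
    to trimming; sex-locus categories pass through untouched.
    """
    if len(panel) == 0:
        return panel
    df = panel.sorted().df
    gw = df["category"] == "genome_wide"
    keep = np.ones(len(df), dtype=bool)
    if p.drop_maf_half:
        keep &= ~(gw & np.isclose(df["maf"].to_numpy(dtype=float), 0.5,
                                  rtol=0.0, atol=1e-9))
    last_pos: dict[str, int] = {}
    for i in range(len(df)):
        if not keep[i] or not gw.iloc[i]:
            continue
        chrom, pos = df["chrom"].iloc[i], int(df["pos"].iloc[i])
        prev = last_pos.get(chrom)
        if prev is not None and pos - prev < p.min_gap:
            keep[i] = False
        else:
            last_pos[chrom] = pos
    return MarkerPanel(df[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# sex-locus enrichment
# ---------------------------------------------------------------------------

def pick_sex_loci(vt: VariantTable, sex_labels: Mapping[str, str],
                  gsdf: GenomicInterval,
                  te: Sequence[GenomicInterval],
                  p: DesignParams) -> MarkerPanel:
    """Select the three sex-locus categories.

    (a) every bi-allelic SNP inside the gsdf region;
    (b) SNPs homozygous in every labelled female AND heterozygous in every
        labelled male (missing calls ignored), excluding (a) so the
        categories partition;
    (c) probe target positions tiled over [breakpoint - flank,
        breakpoint + flank] for each TE breakpoint, at positions whose
        35-mer footprint contains no variant site; when a
        ``te_probe_budget`` is set, eligible candidates are evenly
        down-sampled to that count.
    """
    vt = vt.sorted()
    f_idx = [i for i, s in enumerate(vt.sample_ids)
             if sex_labels.get(s) == "female"]
    m_idx = [i for i, s in enumerate(vt.sample_ids)
             if sex_labels.get(s) == "male"]
    if not f_idx or not m_idx:
        raise ValueError("sex-segregating selection needs labelled samples "
                         "of both sexes")

    snp = vt.is_snp() & ~vt.multiallelic
    in_gsdf = np.array([gsdf.contains(str(c), int(q))
                        for c, q in zip(vt.chrom, vt.pos)])
    cat_a = snp & in_gsdf

    G = vt.genotypes
    Fg, Mg = G[:, f_idx], G[:, m_idx]
    f_miss, m_miss = Fg == MISSING, Mg == MISSING
    f_hom = ((Fg == 0) | (Fg == 2)) | f_miss
    m_het = (Mg == 1) | m_miss
    cat_b = (snp & f_hom.all(axis=1) & m_het.all(axis=1)
             & (~f_miss).any(axis=1) & (~m_miss).any(axis=1) & ~cat_a)

    parts = []
    for mask, category in ((cat_a, "gsdf_region_snp"),
                           (cat_b, "sex_segregating_snp")):
        idx = np.flatnonzero(mask)
        maf = np.minimum(vt.af[idx], 1.0 - vt.af[idx])
        parts.append(_panel_df(
            vt.chrom[idx], vt.pos[idx], [vt.ref[i] for i in idx],
            [vt.alt[i][0] for i in idx], maf, category))

    # category (c): tiled non-polymorphic breakpoint probes
    half = p.probe_len // 2
    cand_chrom, cand_pos = [], []
    for iv in te:
        site_pos = np.sort(vt.pos[vt.chrom == iv.chrom])
        for bp in (iv.start, iv.end):
            cand = np.arange(bp - p.breakpoint_flank,
                             bp + p.breakpoint_flank + 1, dtype=np.int64)
            lo = np.searchsorted(site_pos, cand - half, side="left")
            hi = np.searchsorted(site_pos, cand + half, side="right")
            eligible = cand[lo == hi]   # no variant within the footprint
            cand_chrom.extend([iv.chrom] * len(eligible))
            cand_pos.extend(eligible.tolist())
    cand_pos = np.asarray(cand_pos, dtype=np.int64)
    cand_chrom = np.asarray(cand_chrom, dtype=object)
    if p.te_probe_budget is not None and len(cand_pos) > p.te_probe_budget:
        take = np.linspace(0, len(cand_pos) - 1,
                           p.te_probe_budget).round().astype(np.intp)
        take = np.unique(take)
        cand_pos, cand_chrom = cand_pos[take], cand_chrom[take]
    te_df = _panel_df(cand_chrom, cand_pos, ["."] * len(cand_pos),
                      ["."] * len(cand_pos), np.nan, "te_breakpoint_probe")
    te_df["marker_id"] = ["TE_" + m for m in te_df["marker_id"]]
    parts.append(te_df)

    panel = MarkerPanel(pd.concat(parts, ignore_index=True)).sorted()
    counts = panel.category_counts()
    log.info("sex-locus categories: %s (subtotal %d)", counts,
             panel.sex_subtotal())
    return panel


# ---------------------------------------------------------------------------
# pluggable conversion scoring (vendor step stand-in)
# ---------------------------------------------------------------------------

Scorer = Callable[[pd.Series], str]


def accept_all_scorer(row: pd.Series) -> str:
    return "recommended"


def periodic_scorer(k: int) -> Scorer:
    """Reject every k-th locus (demo scorer for attrition bookkeeping)."""
    state = {"i": 0}

    def score(row: pd.Series) -> str:
        state["i"] += 1
        return "not_recommended" if state["i"] % k == 0 else "recommended"
    return score


def hashed_scorer(seed: int, reject_frac: float = 0.1) -> Scorer:
    """Deterministic pseudo-random scorer keyed on marker id."""
    import hashlib

    def score(row: pd.Series) -> str:
        digest = hashlib.md5(
            f"{seed}:{row['marker_id']}".encode()).hexdigest()
        h = int(digest[:8], 16) % 10_000
        return "not_recommended" if h < reject_frac * 10_000 else "recommended"
    return score


def mock_pconvert(panel: MarkerPanel,
                  scorer: Optional[Scorer] = None) -> MarkerPanel:
    """Drop loci a conversion scorer marks not_recommended.

    The vendor's thermodynamic conversion-probability model is proprietary;
    any callable mapping a panel row to one of {recommended, neutral,
    not_recommended} can stand in. Default accepts everything.
    """
    if scorer is None:
        scorer = accept_all_scorer
    verdicts = panel.df.apply(scorer, axis=1)
    bad = set(verdicts) - {"recommended", "neutral", "not_recommended"}
    if bad:
        raise ValueError(f"scorer returned unknown verdicts {sorted(bad)}")
    keep = verdicts != "not_recommended"
    log.info("mock_pconvert: removed %d of %d loci",
             int((~keep).sum()), len(panel))
    return MarkerPanel(panel.df[keep.to_numpy()].reset_index(drop=True))
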