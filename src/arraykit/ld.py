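"""Pairwise linkage disequilibrium (r^2) and decay summaries.

r^2 is the squared Pearson correlation of alt-allele dosage vectors
(composite LD, as computed by PLINK's ``--r2`` on unphased genotypes),
over pairwise-complete samples, within one chromosome at a time. A
haplotype-frequency backend (EM under random mating, the Hill-Robertson
formulation) is provided as an independent cross-check. Decay summaries
average r^2 in left-closed distance bins.
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


def pairwise_r2(gm: GenotypeMatrix, chrom: str,
                max_dist: Optional[int] = None,
                min_samples: int = 2) -> pd.DataFrame:
    """All within-chromosome marker pairs with their dosage r^2.

    Pairs with fewer than ``min_samples`` pairwise-complete samples, or
    monomorphic in the complete subset, are dropped (count logged and kept
    in ``df.attrs['n_dropped']``).
    """
    idx = np.flatnonzero(gm.marker_chrom == chrom)
    if len(idx) < 2:
        raise ValueError(f"need >= 2 markers on {chrom}")
    order = idx[np.argsort(gm.marker_pos[idx], kind="mergesort")]
    pos = gm.marker_pos[order].astype(np.int64)
    X = gm.calls[:, order].astype(np.float64)
    M = (X != MISSING).astype(np.float64)
    X0 = np.where(M > 0, X, 0.0)

    # pairwise-complete moment matrices
    N = M.T @ M
    Sx = X0.T @ M          # Sx[i,j] = sum of x_i over samples complete for (i,j)
    Sxx = (X0 * X0).T @ M
    Sxy = X0.T @ X0
    Sy, Syy = Sx.T, Sxx.T

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = N * Sxy - Sx * Sy
        var_x = N * Sxx - Sx * Sx
        var_y = N * Syy - Sy * Sy
        r2 = (cov * cov) / (var_x * var_y)

    iu, ju = np.triu_indices(len(order), k=1)
    dist = pos[ju] - pos[iu]
    vals = r2[iu, ju]
    n_pair = N[iu, ju]
    ok = (n_pair >= min_samples) & np.isfinite(vals)
    if max_dist is not None:
        ok &= dist < max_dist
    n_dropped = int(((n_pair < min_samples) | ~np.isfinite(vals)).sum())
    if n_dropped:
        log.info("pairwise_r2(%s): dropped %d undefined pair(s)", chrom,
                 n_dropped)
    out = pd.DataFrame({
        "chrom": chrom,
        "pos_i": pos[iu][ok],
        "pos_j": pos[ju][ok],
        "distance": dist[ok],
        "r2": np.clip(vals[ok], 0.0, 1.0)})
    out.attrs["n_dropped"] = n_dropped
    return out


# ---------------------------------------------------------------------------
# haplotype-frequency backend (independent cross-check)
# ---------------------------------------------------------------------------

def r2_haplotype(x, y, max_iter: int = 200, tol: float = 1e-10) -> float:
    """Hill-Robertson r^2 from EM-estimated haplotype frequencies.

    Dosage vectors over the same samples; missing codes are excluded
    pairwise. The only phase-ambiguous cell is the double heterozygote,
    resolved by EM under random mating: r^2 = D^2 / (pA pa pB pb).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise ValueError("need >= 2 complete samples")
    n9 = np.zeros((3, 3))
    for gx, gy in zip(x.astype(int), y.astype(int)):
        n9[gx, gy] += 1
    n_hap = 2.0 * len(x)
    # haplotypes indexed (allele at locus 1, allele at locus 2); allele 1 = alt
    f = np.full(4, 0.25)  # f00, f01, f10, f11
    fixed = np.array([
        2 * n9[0, 0] + n9[0, 1] + n9[1, 0],   # 00
        2 * n9[0, 2] + n9[0, 1] + n9[1, 2],   # 01
        2 * n9[2, 0] + n9[2, 1] + n9[1, 0],   # 10
        2 * n9[2, 2] + n9[2, 1] + n9[1, 2],   # 11
    ])
    n_dh = n9[1, 1]
    for _ in range(max_iter):
        denom = f[0] * f[3] + f[1] * f[2]
        w = 0.5 if denom == 0 else f[0] * f[3] / denom
        counts = fixed + n_dh * np.array([w, 1 - w, 1 - w, w])
        new = counts / n_hap
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    p_a = f[2] + f[3]   # alt frequency at locus 1
    p_b = f[1] + f[3]   # alt frequency at locus 2
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0:
        return np.nan
    d = f[3] - p_a * p_b
    return float(d * d / denom)


# ---------------------------------------------------------------------------
# decay summaries
# ---------------------------------------------------------------------------

def bin_decay(pairs: pd.DataFrame, bin_width: int = 100_000,
              max_dist: int = 10_000_000) -> pd.DataFrame:
    """Mean r^2 in contiguous left-closed distance bins up to ``max_dist``.

    A pair at distance d lands in bin floor(d / bin_width); only populated
    bins are returned.
    """
    if pairs.empty:
        raise ValueError("no pairs to bin")
    sub = pairs[pairs["distance"] < max_dist]
    bins = (sub["distance"] // bin_width).astype(int)
    grouped = sub.groupby(bins)["r2"].agg(["size", "mean"])
    return pd.DataFrame({
        "bin_lo": grouped.index * bin_width,
        "bin_hi": (grouped.index + 1) * bin_width,
        "n_pairs": grouped["size"].astype(int),
        "mean_r2": grouped["mean"]}).reset_index(drop=True)


def per_chrom_decay(pairs: pd.DataFrame, bin_width: int = 1_000_000,
                    n_bins: int = 10) -> pd.DataFrame:
    """Per-chromosome mean r^2 in ``n_bins`` contiguous bins.

    Defaults follow the 10 x 1 Mb layout (0-0.99 Mb ... 9-10 Mb). Bins a
    chromosome cannot populate are absent from the output.
    """
    out = []
    for chrom, sub in pairs.groupby("chrom", sort=False):
        binned = bin_decay(sub, bin_width=bin_width,
                           max_dist=bin_width * n_bins)
        binned.insert(0, "chrom", chrom)
        binned.insert(1, "bin_index", (binned["bin_lo"] // bin_width))
        out.append(binned)
    if not out:
        raise ValueError("no pairs to bin")
    return pd.concat(out, ignore_index=True)


def genome_decay(gm: GenotypeMatrix, bin_width: int = 100_000,
                 max_dist: int = 10_000_000,
                 pool_chromosomes: bool = True) -> pd.DataFrame:
    """Genome-wide LD decay: r^2 for every within-chromosome pair, binned.

    With ``pool_chromosomes`` the bin means pool pairs from all
    chromosomes; otherwise per-chromosome bin means are averaged with
    equal chromosome weight (both conventions are in circulation).
    """
    frames = []
    for chrom in pd.unique(gm.marker_chrom):
        if (gm.marker_chrom == chrom).sum() < 2:
            continue
        frames.append(pairwise_r2(gm, str(chrom), max_dist=max_dist))
    if not frames:
        raise ValueError("no chromosome has >= 2 markers")
    pairs = pd.concat(frames, ignore_index=True)
    if pool_chromosomes:
        return bin_decay(pairs, bin_width=bin_width, max_dist=max_dist)
    per = per_chrom_decay(pairs, bin_width=bin_width,
                          n_bins=max_dist // bin_width)
    agg = per.groupby("bin_index").agg(
        n_pairs=("n_pairs", "sum"), mean_r2=("mean_r2", "mean"))
    return pd.DataFrame({
        "bin_lo": agg.index * bin_width,
        "bin_hi": (agg.index + 1) * bin_width,
        "n_pairs": agg["n_pairs"].astype(int),
        "mean_r2": agg["mean_r2"]}).reset_index(drop=True)
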