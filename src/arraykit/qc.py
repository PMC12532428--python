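"""Sample- and SNP-level genotyping QC and simplified SNP classification.

Sample gating follows the array's Best Practices defaults: Dish QC >= 0.82
and call rate >= 97%. Markers are summarised by call rate, MAF and a
1-df chi-square Hardy-Weinberg test, and assigned one of six quality
classes (PHR, NMH, MHR, CRbT, OTV, Other). The vendor's 2-D cluster
metrics are approximated by a one-dimensional separation statistic with
the published FLD default threshold of 3.6.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import MISSING, GenotypeMatrix

SNP_CATEGORIES = ("PHR", "NMH", "MHR", "CRbT", "OTV", "Other")


@dataclass
class SampleQCReport:
    sample_id: str
    dish_qc: float
    call_rate: float            # percent
    passed: bool


@dataclass
class SNPMetrics:
    marker_id: str
    call_rate: float            # percent
    maf: float
    hwe_p: float
    category: str


@dataclass
class SnpClassThresholds:
    """Knobs of the simplified six-class SNP classifier."""

    call_rate_min: float = 97.0
    otv_low_signal: float = 500.0   # absolute signal under which a sample
                                    # counts toward an off-target sub-cluster
    otv_min_fraction: float = 0.05
    separation_min: float = 3.6     # FLD-like cluster separation
    min_minor_hom: int = 2


# ---------------------------------------------------------------------------
# sample QC
# ---------------------------------------------------------------------------

def sample_qc(gm: GenotypeMatrix, dish_qc_values: Mapping[str, float],
              cr_threshold: float = 97.0,
              dish_threshold: float = 0.82) -> list[SampleQCReport]:
    """Gate samples on Dish QC and genotype call rate.

    ``dish_qc_values`` must cover exactly the samples in the matrix; Dish
    QC is a raw-signal attribute that cannot be derived from calls, so it
    arrives as an input.
    """
    if gm.n_markers == 0:
        raise ValueError("empty genotype matrix")
    unknown = set(dish_qc_values) - set(gm.sample_ids)
    if unknown:
        raise ValueError(f"dish_qc_values has unknown samples {sorted(unknown)}")
    missing = set(gm.sample_ids) - set(dish_qc_values)
    if missing:
        raise ValueError(f"dish_qc_values missing samples {sorted(missing)}")
    rates = gm.sample_call_rates()
    out = []
    for sid, cr in zip(gm.sample_ids, rates):
        dq = float(dish_qc_values[sid])
        out.append(SampleQCReport(
            sample_id=sid, dish_qc=dq, call_rate=float(cr),
            passed=bool(dq >= dish_threshold and cr >= cr_threshold)))
    return out


def passing_samples(reports: Sequence[SampleQCReport]) -> list[str]:
    return [r.sample_id for r in reports if r.passed]


# ---------------------------------------------------------------------------
# marker metrics
# ---------------------------------------------------------------------------

def genotype_counts(calls: np.ndarray) -> tuple[int, int, int]:
    """(nAA, nAB, nBB) over non-missing calls of one marker."""
    calls = np.asarray(calls)
    return (int((calls == 0).sum()), int((calls == 1).sum()),
            int((calls == 2).sum()))


def snp_call_rate_maf(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker call rate (%) and MAF over non-missing calls.

    Monomorphic markers get MAF 0; all-missing markers get call rate 0 and
    NaN MAF (flagged downstream rather than erroring).
    """
    called = gm.calls != MISSING
    n_called = called.sum(axis=0)
    call_rate = np.where(gm.n_samples > 0,
                         100.0 * n_called / gm.n_samples, np.nan)
    dose = np.where(called, gm.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_called > 0, dose / (2.0 * n_called), np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    return pd.DataFrame({
        "marker_id": gm.marker_ids,
        "call_rate": call_rate,
        "maf": maf})


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square goodness-of-fit p-value against HWE proportions.

    Expectations come from the observed allele frequency; no continuity
    correction. Monomorphic input returns p = 1 by convention.
    """
    return float(hwe_test_many(np.array([[n_aa, n_ab, n_bb]]))[0])


def hwe_test_many(counts: np.ndarray) -> np.ndarray:
    """Vectorised :func:`hwe_test` over rows of (nAA, nAB, nBB)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=1)
    if (n < 1).any():
        raise ValueError("HWE test needs at least one genotype")
    p = (counts[:, 2] * 2 + counts[:, 1]) / (2 * n)
    q = 1.0 - p
    expected = np.column_stack([n * q * q, 2 * n * p * q, n * p * p])
    poly = (p > 0) & (p < 1)
    chi2 = np.zeros(len(counts))
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (counts - expected) ** 2 / expected
    chi2[poly] = terms[poly].sum(axis=1)
    out = np.ones(len(counts))
    out[poly] = stats.chi2.sf(chi2[poly], df=1)
    return out


# ---------------------------------------------------------------------------
# six-class SNP classification
# ---------------------------------------------------------------------------

def _separation_statistic(calls: np.ndarray, signal: np.ndarray) -> float:
    """Minimum adjacent-class separation of per-sample signals.

    For each adjacent genotype-class pair (AA-AB, AB-BB) present, the
    absolute difference of class mean signals divided by the pooled
    within-class SD; returns the minimum over pairs, or +inf when fewer
    than two classes are present or the pooled SD is zero.
    """
    stats_by_class = {}
    for g in (0, 1, 2):
        vals = signal[calls == g]
        if len(vals):
            stats_by_class[g] = (vals.mean(),
                                 vals.var(ddof=0) * len(vals), len(vals))
    best = np.inf
    for a, b in ((0, 1), (1, 2)):
        if a in stats_by_class and b in stats_by_class:
            ma, ssa, na = stats_by_class[a]
            mb, ssb, nb = stats_by_class[b]
            pooled = np.sqrt((ssa + ssb) / (na + nb))
            sep = np.inf if pooled == 0 else abs(ma - mb) / pooled
            best = min(best, sep)
    return best


def classify_snp(calls: np.ndarray,
                 intensities: Optional[np.ndarray] = None,
                 thresholds: Optional[SnpClassThresholds] = None) -> str:
    """Assign one of the six quality classes to a marker.

    Rule order: call rate below threshold -> CRbT; a low-signal
    sub-cluster among called samples -> OTV; poor cluster separation ->
    Other; a single genotype class -> MHR; heterozygotes but no minor
    homozygote -> NMH; all three classes with enough minor homozygotes ->
    PHR. Residual shapes (two homozygote classes with no het, or a lone
    minor homozygote) land in Other.
    """
    t = thresholds or SnpClassThresholds()
    calls = np.asarray(calls)
    if calls.size == 0:
        raise ValueError("classify_snp needs at least one call")
    called = calls != MISSING
    call_rate = 100.0 * called.mean()
    if call_rate < t.call_rate_min:
        return "CRbT"
    if intensities is not None:
        sig = np.asarray(intensities, dtype=float)[called]
        if len(sig) and (sig < t.otv_low_signal).mean() >= t.otv_min_fraction:
            return "OTV"
        if _separation_statistic(calls[called], sig) < t.separation_min:
            return "Other"
    n_aa, n_ab, n_bb = genotype_counts(calls)
    n_classes = int(n_aa > 0) + int(n_ab > 0) + int(n_bb > 0)
    if n_classes <= 1:
        return "MHR"
    n = n_aa + n_ab + n_bb
    p_b = (2 * n_bb + n_ab) / (2 * n)
    minor_hom = n_bb if p_b <= 0.5 else n_aa
    if n_ab > 0 and minor_hom == 0:
        return "NMH"
    if n_classes == 3 and minor_hom >= t.min_minor_hom:
        return "PHR"
    return "Other"


def classify_markers(gm: GenotypeMatrix,
                     intensities: Optional[np.ndarray] = None,
                     thresholds: Optional[SnpClassThresholds] = None
                     ) -> pd.DataFrame:
    """Per-marker metrics table: call rate, MAF, HWE p, quality class.

    ``intensities``, when given, is a samples x markers signal array
    aligned with the genotype matrix.
    """
    base = snp_call_rate_maf(gm)
    counts = np.column_stack([(gm.calls == g).sum(axis=0) for g in (0, 1, 2)])
    any_called = counts.sum(axis=1) > 0
    hwe = np.ones(gm.n_markers)
    if any_called.any():
        hwe[any_called] = hwe_test_many(counts[any_called])
    cats = []
    for j in range(gm.n_markers):
        col_int = intensities[:, j] if intensities is not None else None
        cats.append(classify_snp(gm.calls[:, j], col_int, thresholds))
    base["hwe_p"] = hwe
    base["category"] = cats
    return base


def qc_summary(metrics: pd.DataFrame,
               hwe_alpha: float = 0.01,
               maf_floor: float = 0.05) -> dict:
    """Cohort-level summary: class counts and threshold fractions.

    Returns category counts, the fraction of markers departing from HWE at
    ``hwe_alpha``, the fraction with MAF above ``maf_floor``, and simple
    call-rate/MAF/HWE histograms.
    """
    if metrics.empty:
        raise ValueError("empty metrics table")
    counts = metrics["category"].value_counts().to_dict()
    maf = metrics["maf"].dropna()
    return {
        "n_markers": int(len(metrics)),
        "category_counts": {c: int(counts.get(c, 0)) for c in SNP_CATEGORIES},
        "frac_hwe_depart": float((metrics["hwe_p"] < hwe_alpha).mean()),
        "frac_maf_above_floor": float((maf > maf_floor).mean()),
        "mean_call_rate": float(metrics["call_rate"].mean()),
        "call_rate_hist": _hist(metrics["call_rate"], [0, 90, 95, 97, 99, 100.001]),
        "maf_hist": _hist(maf, [0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5001]),
        "hwe_p_hist": _hist(metrics["hwe_p"], [0, 0.001, 0.01, 0.05, 0.5, 1.0001]),
    }


def _hist(values: pd.Series, edges: list[float]) -> dict[str, int]:
    counts, _ = np.histogram(values.dropna().to_numpy(), bins=edges)
    return {f"[{edges[i]:g},{edges[i+1]:g})": int(c)
            for i, c in enumerate(counts)}
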