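"""Array-vs-sequencing genotype concordance and duplicate reproducibility.

Concordance compares dosage calls marker-by-marker over samples genotyped
on both platforms, counting only comparisons where both calls are
non-missing. The per-category summary reports, for each SNP quality
class, how many markers agreed at every sample, how many showed any
discordance, the mean number of discordant samples among the latter, and
an overall percent concordance defined as
``100 * (1 - discordant genotypes / (markers * samples))``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix


@dataclass
class ConcordanceRow:
    category: str
    n_on_array: int
    pct_on_array: float
    n_fully_concordant: int
    n_discordant: int
    mean_discordant_samples_per_snp: float
    overall_pct_concordance: float

    @classmethod
    def from_counts(cls, category: str, n_on_array: int, n_samples: int,
                    n_discordant: int, mean_discordant_samples: float,
                    n_fully_concordant: Optional[int] = None,
                    pct_on_array: float = float("nan")) -> "ConcordanceRow":
        """Build a row from aggregate counts.

        ``overall_pct_concordance`` = 100 * (1 - total discordant genotypes
        / (n_on_array * n_samples)), with the discordant genotype total
        taken as ``n_discordant * mean_discordant_samples``.
        """
        if n_on_array <= 0 or n_samples <= 0:
            raise ValueError("marker and sample counts must be positive")
        discordant_genotypes = n_discordant * mean_discordant_samples
        overall = 100.0 * (1.0 - discordant_genotypes
                           / (n_on_array * n_samples))
        if n_fully_concordant is None:
            n_fully_concordant = n_on_array - n_discordant
        return cls(category=category, n_on_array=n_on_array,
                   pct_on_array=pct_on_array,
                   n_fully_concordant=n_fully_concordant,
                   n_discordant=n_discordant,
                   mean_discordant_samples_per_snp=mean_discordant_samples,
                   overall_pct_concordance=overall)


@dataclass
class DuplicatePairReport:
    sample_id: str
    replicate_id: str
    n_inconsistencies: int
    n_missing_type: int         # exactly one of the pair is missing
    n_discordant_type: int      # both called, unequal


# ---------------------------------------------------------------------------
# array vs sequencing
# ---------------------------------------------------------------------------

def genotype_concordance(gm_array: GenotypeMatrix, gm_wgs: GenotypeMatrix,
                         sample_map: Mapping[str, str],
                         min_sample_cr: float = 80.0) -> pd.DataFrame:
    """Per-marker agreement counts between two genotype matrices.

    ``sample_map`` pairs array sample ids with sequencing sample ids.
    Array samples whose overall call rate falls below ``min_sample_cr``
    are excluded before comparison. Markers are matched by (chrom, pos);
    a comparison is counted only where both calls are non-missing.

    Returns a DataFrame (marker_id, chrom, pos, n_compared, n_agree,
    n_disagree) with the number of compared samples in ``df.attrs``.
    """
    rates = dict(zip(gm_array.sample_ids, gm_array.sample_call_rates()))
    pairs = [(a, w) for a, w in sample_map.items()
             if rates.get(a, 0.0) >= min_sample_cr]
    excluded = sorted(set(sample_map) - {a for a, _ in pairs})
    if not pairs:
        raise ValueError("no samples left after the call-rate gate")

    coords_wgs = {(c, p): j for j, (c, p) in
                  enumerate(zip(gm_wgs.marker_chrom, gm_wgs.marker_pos))}
    shared = [(i, coords_wgs[(c, p)]) for i, (c, p) in
              enumerate(zip(gm_array.marker_chrom, gm_array.marker_pos))
              if (c, p) in coords_wgs]
    if not shared:
        raise ValueError("no markers shared between the two matrices")
    ai = np.array([i for i, _ in shared], dtype=np.intp)
    wi = np.array([j for _, j in shared], dtype=np.intp)

    a_rows = [gm_array.sample_index(a) for a, _ in pairs]
    w_rows = [gm_wgs.sample_index(w) for _, w in pairs]
    A = gm_array.calls[np.ix_(a_rows, ai)]
    W = gm_wgs.calls[np.ix_(w_rows, wi)]
    both = (A != MISSING) & (W != MISSING)
    agree = both & (A == W)
    out = pd.DataFrame({
        "marker_id": [gm_array.marker_ids[i] for i in ai],
        "chrom": gm_array.marker_chrom[ai],
        "pos": gm_array.marker_pos[ai],
        "n_compared": both.sum(axis=0),
        "n_agree": agree.sum(axis=0),
        "n_disagree": (both & ~agree).sum(axis=0)})
    out.attrs["n_samples_compared"] = len(pairs)
    out.attrs["excluded_samples"] = excluded
    return out


def category_summary(per_marker: pd.DataFrame,
                     categories: Mapping[str, str],
                     n_samples: int) -> list[ConcordanceRow]:
    """Summarise per-marker concordance by SNP quality class.

    Every marker must be categorised. A Total row (aggregating all
    categories) is appended; its counts are the column sums of the
    category rows.
    """
    missing = [m for m in per_marker["marker_id"] if m not in categories]
    if missing:
        raise ValueError(f"{len(missing)} marker(s) lack a category, "
                         f"e.g. {missing[:3]}")
    df = per_marker.assign(
        category=[categories[m] for m in per_marker["marker_id"]])
    total_markers = len(df)
    rows = []
    for cat, sub in df.groupby("category", sort=True):
        disc = sub["n_disagree"] > 0
        n_disc = int(disc.sum())
        mean_disc = float(sub.loc[disc, "n_disagree"].mean()) if n_disc else 0.0
        rows.append(ConcordanceRow.from_counts(
            category=str(cat), n_on_array=len(sub), n_samples=n_samples,
            n_discordant=n_disc, mean_discordant_samples=mean_disc,
            n_fully_concordant=int((~disc).sum()),
            pct_on_array=100.0 * len(sub) / total_markers))
    disc = df["n_disagree"] > 0
    n_disc = int(disc.sum())
    rows.append(ConcordanceRow.from_counts(
        category="Total", n_on_array=total_markers, n_samples=n_samples,
        n_discordant=n_disc,
        mean_discordant_samples=(float(df.loc[disc, "n_disagree"].mean())
                                 if n_disc else 0.0),
        n_fully_concordant=int((~disc).sum()),
        pct_on_array=100.0))
    return rows


def summary_frame(rows: Sequence[ConcordanceRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# duplicate samples
# ---------------------------------------------------------------------------

def duplicate_reproducibility(gm: GenotypeMatrix,
                              pairs: Sequence[tuple[str, str]],
                              marker_subset: Optional[Sequence[str]] = None
                              ) -> tuple[list[DuplicatePairReport], float]:
    """Count inconsistencies between re-genotyped sample pairs.

    An inconsistency is a marker where the two calls differ; it is
    missing-type when exactly one call is missing and discordant-type when
    both are called but unequal. Both-missing counts as consistent.
    Returns the per-pair reports and the mean inconsistency count.
    """
    sub = gm if marker_subset is None else gm.take_markers(list(marker_subset))
    reports = []
    for a, b in pairs:
        va = sub.calls[sub.sample_index(a)]
        vb = sub.calls[sub.sample_index(b)]
        differs = va != vb
        one_missing = differs & ((va == MISSING) ^ (vb == MISSING))
        both_called = differs & (va != MISSING) & (vb != MISSING)
        reports.append(DuplicatePairReport(
            sample_id=a, replicate_id=b,
            n_inconsistencies=int(differs.sum()),
            n_missing_type=int(one_missing.sum()),
            n_discordant_type=int(both_called.sum())))
    mean = float(np.mean([r.n_inconsistencies for r in reports])) \
        if reports else 0.0
    return reports, mean
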