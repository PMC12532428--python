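"""Genetic-sex assignment from three evidence classes.

The sex locus is gsdf-linked: genetic males are heterozygous at
sex-segregating SNPs where genetic females are homozygous, and only males
carry the two TE insertions whose breakpoint probes therefore lose signal
in females. Each sample collects three votes — homozygosity over the
RNA-seq-derived SNP panel, homozygosity over the gsdf-region
discriminating panel, and mean TE-breakpoint probe intensity — and the
majority of informative votes is the genetic-sex call, reconciled against
the phenotype label (neomales are genetic females with a male phenotype,
so a female call for them is the expected, consistent outcome).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, IntensityTable

UNINFORMATIVE = "uninformative"


@dataclass
class SexEvidence:
    sample_id: str
    hom_prop_panel_a: float     # RNA-seq-derived sex-segregating panel
    hom_prop_panel_b: float     # gsdf-region discriminating panel
    te_mean_intensity: float
    vote_a: str
    vote_b: str
    vote_te: str


@dataclass
class SexCall:
    sample_id: str
    genetic_sex: str            # female / male / ambiguous
    votes: tuple[str, str, str]
    phenotype: str
    reconciliation: str         # concordant / candidate_misassignment /
                                # neomale_consistent / unresolved


# ---------------------------------------------------------------------------
# evidence primitives
# ---------------------------------------------------------------------------

def homozygosity_proportions(gm: GenotypeMatrix,
                             marker_ids: Sequence[str]) -> pd.Series:
    """Per-sample proportion of homozygous calls over a marker panel.

    Missing calls are excluded from the denominator; a sample with no
    non-missing call in the panel gets NaN (uninformative).
    """
    sub = gm.take_markers(list(marker_ids))
    called = sub.calls != MISSING
    hom = (sub.calls == 0) | (sub.calls == 2)
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore"):
        prop = np.where(n_called > 0, hom.sum(axis=1) / n_called, np.nan)
    return pd.Series(prop, index=sub.sample_ids, name="hom_prop")


def homozygosity_proportion(gm: GenotypeMatrix, marker_ids: Sequence[str],
                            sample_id: str) -> float:
    """Single-sample convenience wrapper; NaN when all calls are missing."""
    return float(homozygosity_proportions(gm, marker_ids)[sample_id])


def select_discriminating_snps(gm: GenotypeMatrix,
                               sex_labels: Mapping[str, str],
                               delta: float = 0.5) -> pd.DataFrame:
    """SNPs whose homozygosity rate differs between the sexes by >= delta.

    For every marker the homozygosity rate (homozygous / non-missing) is
    computed separately in labelled females and males; markers with
    |female rate - male rate| >= delta are retained. Returns a DataFrame
    (marker_id, hom_rate_female, hom_rate_male, contrast, selected).
    """
    f_ids = [s for s in gm.sample_ids if sex_labels.get(s) == "female"]
    m_ids = [s for s in gm.sample_ids if sex_labels.get(s) == "male"]
    if not f_ids or not m_ids:
        raise ValueError("need labelled samples of both sexes")

    def rates(ids: list[str]) -> np.ndarray:
        calls = gm.take_samples(ids).calls
        called = calls != MISSING
        hom = (calls == 0) | (calls == 2)
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, hom.sum(axis=0) / n, np.nan)

    rf, rm = rates(f_ids), rates(m_ids)
    contrast = np.abs(rf - rm)
    return pd.DataFrame({
        "marker_id": gm.marker_ids,
        "hom_rate_female": rf,
        "hom_rate_male": rm,
        "contrast": contrast,
        "selected": contrast >= delta})


def te_probe_differential(intensities: IntensityTable,
                          sex_labels: Mapping[str, str],
                          threshold: float = 400.0) -> pd.DataFrame:
    """Female-minus-male mean signal per probe; select strong negatives.

    A probe interrogating a male-only insertion junction loses template in
    females, so its differential (mean female - mean male) is strongly
    negative; probes with differential <= -threshold are selected. Probes
    with an *elevated* female signal (positive differential) are never
    selected, whatever the magnitude.
    """
    f_rows = [i for i, s in enumerate(intensities.sample_ids)
              if sex_labels.get(s) == "female"]
    m_rows = [i for i, s in enumerate(intensities.sample_ids)
              if sex_labels.get(s) == "male"]
    if not f_rows or not m_rows:
        raise ValueError("need labelled samples of both sexes")
    mean_f = intensities.values[f_rows].mean(axis=0)
    mean_m = intensities.values[m_rows].mean(axis=0)
    diff = mean_f - mean_m
    return pd.DataFrame({
        "probe_id": intensities.probe_ids,
        "chrom": intensities.probe_chrom,
        "pos": intensities.probe_pos,
        "mean_female": mean_f,
        "mean_male": mean_m,
        "differential": diff,
        "selected": diff <= -threshold})


def te_sample_score(intensities: IntensityTable,
                    selected_probes: Sequence[str],
                    train_labels: Mapping[str, str],
                    ambiguity_band: float = 0.10) -> pd.DataFrame:
    """Mean intensity over selected probes, voted against training means.

    The vote midpoint is halfway between the labelled-male and
    labelled-female training means; scores within ``ambiguity_band`` of
    the male-female gap around the midpoint are uninformative. Training
    labels should exclude neomales (genetic females that would bias the
    male mean). With no selected probes every vote is uninformative.
    """
    if not selected_probes:
        return pd.DataFrame({
            "sample_id": intensities.sample_ids,
            "te_mean": np.nan,
            "vote": UNINFORMATIVE})
    sub = intensities.take_probes(list(selected_probes))
    score = sub.values.mean(axis=1)
    by_id = dict(zip(sub.sample_ids, score))
    f_scores = [by_id[s] for s in sub.sample_ids
                if train_labels.get(s) == "female"]
    m_scores = [by_id[s] for s in sub.sample_ids
                if train_labels.get(s) == "male"]
    if not f_scores or not m_scores:
        raise ValueError("need labelled training samples of both sexes")
    mid = (np.mean(f_scores) + np.mean(m_scores)) / 2.0
    band = ambiguity_band * abs(np.mean(m_scores) - np.mean(f_scores))
    votes = np.where(score > mid + band, "male",
                     np.where(score < mid - band, "female", UNINFORMATIVE))
    return pd.DataFrame({
        "sample_id": sub.sample_ids, "te_mean": score, "vote": votes})


# ---------------------------------------------------------------------------
# assembly and the final call
# ---------------------------------------------------------------------------

def _hom_vote(prop: float, female_min: float, male_max: float) -> str:
    if np.isnan(prop):
        return UNINFORMATIVE
    if prop >= female_min:
        return "female"
    if prop <= male_max:
        return "male"
    return UNINFORMATIVE


def assemble_evidence(gm: GenotypeMatrix,
                      panel_a: Sequence[str],
                      panel_b: Sequence[str],
                      intensities: Optional[IntensityTable],
                      selected_probes: Sequence[str],
                      train_labels: Mapping[str, str],
                      hom_thresholds: tuple[float, float] = (0.85, 0.65),
                      ambiguity_band: float = 0.10) -> list[SexEvidence]:
    """Collect the three per-sample evidence values and votes."""
    female_min, male_max = hom_thresholds
    hom_a = homozygosity_proportions(gm, panel_a) if panel_a else None
    hom_b = homozygosity_proportions(gm, panel_b) if panel_b else None
    if intensities is not None and selected_probes:
        te = te_sample_score(intensities, selected_probes, train_labels,
                             ambiguity_band).set_index("sample_id")
    else:
        te = None
    out = []
    for sid in gm.sample_ids:
        pa = float(hom_a[sid]) if hom_a is not None else np.nan
        pb = float(hom_b[sid]) if hom_b is not None else np.nan
        if te is not None and sid in te.index:
            tm = float(te.loc[sid, "te_mean"])
            tv = str(te.loc[sid, "vote"])
        else:
            tm, tv = np.nan, UNINFORMATIVE
        out.append(SexEvidence(
            sample_id=sid,
            hom_prop_panel_a=pa, hom_prop_panel_b=pb, te_mean_intensity=tm,
            vote_a=_hom_vote(pa, female_min, male_max),
            vote_b=_hom_vote(pb, female_min, male_max),
            vote_te=tv))
    return out


def _reconcile(genetic: str, phenotype: str) -> str:
    if genetic == "ambiguous" or phenotype not in ("female", "male", "neomale"):
        return "unresolved"
    if phenotype == "neomale":
        return "neomale_consistent" if genetic == "female" \
            else "candidate_misassignment"
    return "concordant" if genetic == phenotype else "candidate_misassignment"


def call_genetic_sex(evidence: Sequence[SexEvidence],
                     phenotype_labels: Mapping[str, str]) -> list[SexCall]:
    """Majority vote over informative evidence, reconciled with phenotype.

    The call is female/male when the informative votes have a strict
    majority, ambiguous on a tie or when no evidence is informative.
    Phenotypic males called female (outside the neomale label) are flagged
    candidate_misassignment; neomales called female are neomale_consistent.
    """
    out = []
    for ev in evidence:
        votes = (ev.vote_a, ev.vote_b, ev.vote_te)
        n_f = votes.count("female")
        n_m = votes.count("male")
        if n_f > n_m:
            genetic = "female"
        elif n_m > n_f:
            genetic = "male"
        else:
            genetic = "ambiguous"
        pheno = phenotype_labels.get(ev.sample_id, "unknown")
        out.append(SexCall(
            sample_id=ev.sample_id, genetic_sex=genetic, votes=votes,
            phenotype=pheno, reconciliation=_reconcile(genetic, pheno)))
    return out


def calls_frame(calls: Sequence[SexCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": c.sample_id,
        "genetic_sex": c.genetic_sex,
        "vote_panel_a": c.votes[0],
        "vote_panel_b": c.votes[1],
        "vote_te": c.votes[2],
        "phenotype": c.phenotype,
        "reconciliation": c.reconciliation} for c in calls])
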