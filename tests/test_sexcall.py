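import numpy as np
import pandas as pd
import pytest

from arraykit import design, sexcall
from arraykit.simulate import scaled_config, simulate_cohort
from arraykit.types import MISSING, IntensityTable

from conftest import make_gm


class TestHomozygosityProportion:
    def test_all_het_is_zero(self):
        gm = make_gm(np.ones((1, 10)))
        assert sexcall.homozygosity_proportion(gm, gm.marker_ids, "S1") == 0.0

    def test_missing_excluded_from_denominator(self):
        gm = make_gm(np.array([[0, 1, 2, MISSING]]))
        prop = sexcall.homozygosity_proportion(gm, gm.marker_ids, "S1")
        assert prop == pytest.approx(2 / 3)

    def test_all_missing_uninformative(self):
        gm = make_gm(np.full((1, 5), MISSING))
        assert np.isnan(
            sexcall.homozygosity_proportion(gm, gm.marker_ids, "S1"))


LABELS4 = {"F1": "female", "F2": "female", "M1": "male", "M2": "male"}


class TestSelectDiscriminatingSnps:
    def _gm(self, *cols):
        calls = np.array(cols).T.astype(np.int8)
        return make_gm(calls, sample_ids=["F1", "F2", "M1", "M2"])

    def test_full_contrast_retained(self):
        gm = self._gm([0, 2, 1, 1])
        out = sexcall.select_discriminating_snps(gm, LABELS4)
        assert out["contrast"].iloc[0] == pytest.approx(1.0)
        assert out["selected"].iloc[0]

    def test_no_contrast_dropped(self):
        gm = self._gm([0, 1, 0, 1])
        out = sexcall.select_discriminating_snps(gm, LABELS4)
        assert out["contrast"].iloc[0] == pytest.approx(0.0)
        assert not out["selected"].iloc[0]

    def test_single_sex_rejected(self):
        gm = self._gm([0, 2, 1, 1])
        with pytest.raises(ValueError):
            sexcall.select_discriminating_snps(
                gm, {"F1": "female", "F2": "female"})

    def test_delta_one_matches_strict_design_rule(self, clean_cohort):
        """At delta = 1.0 the data-driven scan recovers exactly the strict
        female-hom / male-het loci that the design stage selects."""
        c = clean_cohort
        cfg = c.config
        labels = dict(zip(c.sheet["sample_id"],
                          c.sheet["true_genetic_sex"]))
        # outside gsdf so design's category precedence does not interfere
        panel = design.pick_sex_loci(
            c.variants, {s: labels[s] for s in c.variants.sample_ids},
            cfg.gsdf_region, list(cfg.te_intervals), design.DesignParams())
        strict_b = set(panel.df.loc[
            panel.df["category"] == "sex_segregating_snp", "marker_id"])
        wgs = c.genotypes.take_samples(list(c.variants.sample_ids))
        off_gsdf = [m for m, ch, po in zip(wgs.marker_ids, wgs.marker_chrom,
                                           wgs.marker_pos)
                    if not cfg.gsdf_region.contains(str(ch), int(po))]
        scan = sexcall.select_discriminating_snps(
            wgs.take_markers(off_gsdf), labels, delta=1.0)
        got = set(scan.loc[scan["selected"], "marker_id"])
        assert got == strict_b


def _intensity(values, sample_ids):
    values = np.asarray(values, dtype=float)
    n_probes = values.shape[1]
    return IntensityTable(
        sample_ids=sample_ids,
        probe_ids=[f"P{j+1}" for j in range(n_probes)],
        values=values,
        probe_chrom=np.full(n_probes, "chr13", dtype=object),
        probe_pos=np.arange(1, n_probes + 1) * 10 + 8_503_900)


class TestTeProbeDifferential:
    def test_equal_means_not_selected(self):
        it = _intensity([[1000.0], [1000.0], [1000.0], [1000.0]],
                        ["F1", "F2", "M1", "M2"])
        out = sexcall.te_probe_differential(it, LABELS4)
        assert out["differential"].iloc[0] == 0.0
        assert not out["selected"].iloc[0]

    def test_strong_negative_differential_selected(self):
        it = _intensity([[700.0], [700.0], [1500.0], [1500.0]],
                        ["F1", "F2", "M1", "M2"])
        out = sexcall.te_probe_differential(it, LABELS4)
        assert out["differential"].iloc[0] == pytest.approx(-800.0)
        assert out["selected"].iloc[0]

    def test_elevated_female_signal_not_selected(self):
        it = _intensity([[1800.0], [1800.0], [1500.0], [1500.0]],
                        ["F1", "F2", "M1", "M2"])
        out = sexcall.te_probe_differential(it, LABELS4)
        assert out["differential"].iloc[0] == pytest.approx(300.0)
        assert not out["selected"].iloc[0]

    def test_threshold_is_inclusive_at_minus_400(self):
        it = _intensity([[1100.0], [1100.0], [1500.0], [1500.0]],
                        ["F1", "F2", "M1", "M2"])
        out = sexcall.te_probe_differential(it, LABELS4)
        assert out["selected"].iloc[0]


class TestTeSampleScore:
    def _it(self):
        return _intensity(
            [[700.0, 720.0], [680.0, 700.0],
             [1500.0, 1480.0], [1520.0, 1500.0], [1100.0, 1100.0]],
            ["F1", "F2", "M1", "M2", "Q1"])

    def test_sample_at_male_mean_votes_male(self):
        out = sexcall.te_sample_score(self._it(), ["P1", "P2"], LABELS4)
        votes = dict(zip(out["sample_id"], out["vote"]))
        assert votes["M1"] == "male" and votes["F1"] == "female"

    def test_midpoint_sample_uninformative(self):
        out = sexcall.te_sample_score(self._it(), ["P1", "P2"], LABELS4)
        votes = dict(zip(out["sample_id"], out["vote"]))
        assert votes["Q1"] == "uninformative"

    def test_no_selected_probes_all_uninformative(self):
        out = sexcall.te_sample_score(self._it(), [], LABELS4)
        assert (out["vote"] == "uninformative").all()


class TestCallGeneticSex:
    def _ev(self, sid, va, vb, vt):
        return sexcall.SexEvidence(sid, np.nan, np.nan, np.nan, va, vb, vt)

    @pytest.mark.parametrize("votes,pheno,sex,recon", [
        (("female", "female", "female"), "female", "female", "concordant"),
        (("female", "female", "female"), "male", "female",
         "candidate_misassignment"),
        (("male", "male", "male"), "neomale", "male",
         "candidate_misassignment"),
        (("female", "female", "male"), "neomale", "female",
         "neomale_consistent"),
        (("female", "male", "uninformative"), "female", "ambiguous",
         "unresolved"),
        (("uninformative",) * 3, "male", "ambiguous", "unresolved"),
    ])
    def test_vote_and_reconciliation_logic(self, votes, pheno, sex, recon):
        calls = sexcall.call_genetic_sex(
            [self._ev("X", *votes)], {"X": pheno})
        assert calls[0].genetic_sex == sex
        assert calls[0].reconciliation == recon

    def test_majority_of_two_informative(self):
        calls = sexcall.call_genetic_sex(
            [self._ev("X", "female", "female", "uninformative")],
            {"X": "female"})
        assert calls[0].genetic_sex == "female"


def _run_caller(cohort):
    c = cohort
    labels = {s: p for s, p in zip(c.sheet["sample_id"],
                                   c.sheet["phenotypic_sex"])
              if p in ("female", "male")}
    panel_a = c.sites.loc[c.sites["sexlinked"] & ~c.sites["in_gsdf"]]
    panel_a = [f"{ch}_{po}" for ch, po in zip(panel_a["chrom"],
                                              panel_a["pos"])]
    gsdf_ids = [f"{ch}_{po}" for ch, po, g in
                zip(c.sites["chrom"], c.sites["pos"], c.sites["in_gsdf"])
                if g]
    disc = sexcall.select_discriminating_snps(
        c.genotypes.take_markers(gsdf_ids), labels, delta=0.5)
    panel_b = disc.loc[disc["selected"], "marker_id"].tolist()
    diff = sexcall.te_probe_differential(c.intensities, labels)
    sel = diff.loc[diff["selected"], "probe_id"].tolist()
    evidence = sexcall.assemble_evidence(
        c.genotypes, panel_a, panel_b, c.intensities, sel, labels)
    phenos = dict(zip(c.sheet["sample_id"], c.sheet["phenotypic_sex"]))
    return sexcall.call_genetic_sex(evidence, phenos)


def test_error_free_simulation_calls_perfectly(clean_cohort):
    calls = _run_caller(clean_cohort)
    truth = dict(zip(clean_cohort.sheet["sample_id"],
                     clean_cohort.sheet["true_genetic_sex"]))
    assert all(c.genetic_sex == truth[c.sample_id] for c in calls)
    neo = [c for c in calls if c.phenotype == "neomale"]
    assert neo and all(c.reconciliation == "neomale_consistent" for c in neo)


def test_planted_mislabels_are_flagged():
    c = simulate_cohort(scaled_config(seed=23, genotype_error=0.0,
                                      missing_rate=0.0))
    calls = _run_caller(c)
    flagged = {x.sample_id for x in calls
               if x.reconciliation == "candidate_misassignment"}
    sheet = c.sheet
    planted = set(sheet.loc[
        ((sheet["phenotypic_sex"] == "male")
         & (sheet["true_genetic_sex"] == "female"))
        | ((sheet["phenotypic_sex"] == "neomale")
           & (sheet["true_genetic_sex"] == "male")), "sample_id"])
    assert flagged == planted


def test_pipeline_invariant_to_sample_and_marker_order(clean_cohort):
    c = clean_cohort
    calls = {x.sample_id: x.genetic_sex for x in _run_caller(c)}
    rng = np.random.default_rng(1)
    perm_s = rng.permutation(c.genotypes.n_samples)
    shuffled = c.genotypes.take_samples(
        [c.genotypes.sample_ids[i] for i in perm_s])
    labels = {s: p for s, p in zip(c.sheet["sample_id"],
                                   c.sheet["phenotypic_sex"])
              if p in ("female", "male")}
    panel_a = [f"{ch}_{po}" for ch, po, sl, g in
               zip(c.sites["chrom"], c.sites["pos"], c.sites["sexlinked"],
                   c.sites["in_gsdf"]) if sl and not g]
    evidence = sexcall.assemble_evidence(
        shuffled, panel_a, [], None, [], labels)
    phenos = dict(zip(c.sheet["sample_id"], c.sheet["phenotypic_sex"]))
    redone = {x.sample_id: x.genetic_sex
              for x in sexcall.call_genetic_sex(evidence, phenos)}
    for sid, sex in redone.items():
        if sex != "ambiguous":
            assert calls[sid] == sex
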