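import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arraykit import design
from arraykit.types import GenomicInterval, MarkerPanel

from conftest import make_variant_table


@pytest.fixture
def params():
    return design.DesignParams()


class TestFilterVariants:
    def _eight_site_fixture(self):
        """1 indel, 1 tri-allelic, 1 A/T, 1 C/G, 1 low-AF, 1 DP=30 sample,
        2 clean sites."""
        depths = np.full((8, 3), 15, dtype=np.int32)
        depths[5, 1] = 30  # one sample at the excluded upper bound
        return make_variant_table(
            chrom=["chr1"] * 8,
            pos=[100, 200, 300, 400, 500, 600, 700, 800],
            ref=["AT", "A", "A", "C", "A", "A", "A", "C"],
            alt=[("A",), ("C", "T"), ("T",), ("G",), ("G",), ("G",),
                 ("G",), ("A",)],
            af=[0.3, 0.3, 0.3, 0.3, 0.05, 0.3, 0.3, 0.4],
            genotypes=np.ones((8, 3)),
            depths=depths)

    def test_manual_enumeration(self, params):
        vt = self._eight_site_fixture()
        out = design.filter_variants(vt, params)
        assert out.n_sites == 2
        assert list(out.pos) == [700, 800]
        attr = out.meta["attrition"]
        assert attr["input"] == 8 and attr["output"] == 2
        assert attr["not_snp"] == 1 and attr["multiallelic"] == 1
        assert attr["ws_ambiguous"] == 2
        assert attr["af_window"] == 1 and attr["dp_window"] == 1

    def test_ws_snp_rejected_regardless_of_af(self, params):
        vt = make_variant_table(["chr1"], [10], ["A"], ["T"], [0.3],
                                np.ones((1, 2)))
        assert design.filter_variants(vt, params).n_sites == 0

    def test_af_window_is_exclusive(self, params):
        vt = make_variant_table(["chr1"] * 2, [10, 20], ["A", "A"],
                                ["G", "G"], [0.1, 0.9], np.ones((2, 2)))
        assert design.filter_variants(vt, params).n_sites == 0

    def test_unknown_depth_rejected_with_count(self, params):
        depths = np.array([[15, -1]], dtype=np.int32)
        vt = make_variant_table(["chr1"], [10], ["A"], ["G"], [0.3],
                                np.ones((1, 2)), depths=depths)
        out = design.filter_variants(vt, params)
        assert out.n_sites == 0
        assert out.meta["attrition"]["dp_unknown"] == 1

    def test_idempotent(self, params):
        vt = self._eight_site_fixture()
        once = design.filter_variants(vt, params)
        twice = design.filter_variants(once, params)
        assert list(twice.pos) == list(once.pos)


class TestSelectSpaced:
    def _vt_at(self, positions, chrom=None):
        n = len(positions)
        chrom = chrom or ["chr1"] * n
        return make_variant_table(chrom, positions, ["A"] * n, ["G"] * n,
                                  [0.3] * n, np.ones((n, 2)))

    def test_greedy_hand_trace(self, params):
        panel = design.select_spaced(
            self._vt_at([1000, 2000, 4100, 6900, 7100]), params)
        assert list(panel.df["pos"]) == [1000, 4100, 7100]

    def test_single_site_selected(self, params):
        panel = design.select_spaced(self._vt_at([1234]), params)
        assert list(panel.df["pos"]) == [1234]

    def test_cluster_within_target_keeps_one(self, params):
        panel = design.select_spaced(
            self._vt_at([100, 900, 1700, 2500]), params)
        assert len(panel) == 1

    def test_scaffolds_independent(self, params):
        vt = self._vt_at([1000, 1500, 1000, 1500],
                         chrom=["chr1", "chr1", "chr2", "chr2"])
        panel = design.select_spaced(vt, params)
        assert list(zip(panel.df["chrom"], panel.df["pos"])) == [
            ("chr1", 1000), ("chr2", 1000)]


def _panel_at(positions, mafs=None, chrom=None, category="genome_wide"):
    n = len(positions)
    mafs = mafs if mafs is not None else [0.3] * n
    chrom = chrom or ["chr1"] * n
    return MarkerPanel(pd.DataFrame({
        "marker_id": [f"{c}_{p}" for c, p in zip(chrom, positions)],
        "chrom": chrom, "pos": positions,
        "ref": ["A"] * n, "alt": ["G"] * n,
        "maf": mafs, "category": [category] * n}))


class TestTrimPanel:
    def test_gap_checked_against_retained_predecessor(self, params):
        panel = _panel_at([1000, 4100, 7400])
        out = design.trim_panel(panel, params)
        # 4100 - 1000 = 3100 < 3150 -> dropped; 7400 - 1000 >= 3150 -> kept
        assert list(out.df["pos"]) == [1000, 7400]

    def test_maf_half_dropped(self, params):
        panel = _panel_at([1000, 10000], mafs=[0.5, 0.3])
        out = design.trim_panel(panel, params)
        assert list(out.df["pos"]) == [10000]

    def test_empty_panel_passthrough(self, params):
        panel = _panel_at([1000]).subset(["gsdf_region_snp"])
        assert len(design.trim_panel(panel, params)) == 0

    def test_sex_categories_untouched(self, params):
        df = pd.concat([_panel_at([1000, 2000]).df,
                        _panel_at([2500, 2600],
                                  category="gsdf_region_snp").df])
        out = design.trim_panel(MarkerPanel(df.reset_index(drop=True)),
                                params)
        kept = out.df.groupby("category")["pos"].apply(list).to_dict()
        assert kept["genome_wide"] == [1000]
        assert kept["gsdf_region_snp"] == [2500, 2600]

    @settings(max_examples=50, deadline=None)
    @given(pos=st.lists(st.integers(min_value=1, max_value=200_000),
                        min_size=1, max_size=60, unique=True),
           mafs=st.lists(st.sampled_from([0.1, 0.3, 0.5]), min_size=60,
                         max_size=60))
    def test_min_gap_invariant(self, pos, mafs):
        pos = sorted(pos)
        panel = _panel_at(pos, mafs=mafs[:len(pos)])
        out = design.trim_panel(panel, design.DesignParams())
        kept = out.df["pos"].to_numpy()
        assert (np.diff(kept) >= 3150).all()
        assert not np.isclose(out.df["maf"], 0.5).any()


class TestPickSexLoci:
    GSDF = GenomicInterval("chr4", 10_000, 13_513)
    TE = [GenomicInterval("chr4", 5_000, 6_227)]

    def _vt(self, genotypes, positions, chrom=None):
        genotypes = np.asarray(genotypes)
        n = genotypes.shape[0]
        return make_variant_table(
            chrom or ["chr4"] * n, positions, ["A"] * n, ["G"] * n,
            [0.5] * n, genotypes,
            sample_ids=[f"F{i}" for i in range(1, 3)]
            + [f"M{i}" for i in range(1, 3)])

    LABELS = {"F1": "female", "F2": "female", "M1": "male", "M2": "male"}

    def test_gsdf_snp_is_category_a(self):
        vt = self._vt([[0, 0, 1, 1]], [11_000])
        panel = design.pick_sex_loci(vt, self.LABELS, self.GSDF, self.TE,
                                     design.DesignParams())
        sub = panel.df[panel.df["pos"] == 11_000]
        assert list(sub["category"]) == ["gsdf_region_snp"]

    def test_strict_dimorphism_required_for_category_b(self):
        strict = self._vt([[0, 2, 1, 1]], [50_000])
        lax = self._vt([[0, 2, 1, 0]], [50_000])  # one male homozygous
        p = design.DesignParams()
        got = design.pick_sex_loci(strict, self.LABELS, self.GSDF, self.TE, p)
        assert got.category_counts()["sex_segregating_snp"] == 1
        got = design.pick_sex_loci(lax, self.LABELS, self.GSDF, self.TE, p)
        assert got.category_counts()["sex_segregating_snp"] == 0

    def test_category_b_symmetric_under_allele_relabelling(self):
        vt = self._vt([[0, 2, 1, 1], [1, 1, 0, 0]], [50_000, 60_000])
        flipped = self._vt(2 - vt.genotypes, [50_000, 60_000])
        flipped.genotypes[vt.genotypes == -1] = -1
        p = design.DesignParams()
        a = design.pick_sex_loci(vt, self.LABELS, self.GSDF, self.TE, p)
        b = design.pick_sex_loci(flipped, self.LABELS, self.GSDF, self.TE, p)
        sel = lambda pn: sorted(pn.df.loc[
            pn.df["category"] == "sex_segregating_snp", "pos"])
        assert sel(a) == sel(b)

    def test_breakpoint_candidates_without_polymorphism(self):
        vt = self._vt([[0, 0, 1, 1]], [50_000])  # far from the breakpoints
        p = design.DesignParams(te_probe_budget=None)
        te = [GenomicInterval("chr4", 5_000, 6_227)]
        panel = design.pick_sex_loci(vt, self.LABELS, self.GSDF, te, p)
        # two breakpoints x (2*100+1) candidate positions
        assert panel.category_counts()["te_breakpoint_probe"] == 402

    def test_polymorphic_footprint_excludes_candidates(self):
        vt = self._vt([[0, 0, 1, 1]], [5_000])  # SNP at the breakpoint
        p = design.DesignParams(te_probe_budget=None)
        panel = design.pick_sex_loci(vt, self.LABELS, self.GSDF, self.TE, p)
        n_te = panel.category_counts()["te_breakpoint_probe"]
        # positions within +/-17 bp of 5000 lose their 35-mer eligibility
        assert n_te == 402 - 35

    def test_budget_downsamples_evenly(self):
        vt = self._vt([[0, 0, 1, 1]], [50_000])
        p = design.DesignParams(te_probe_budget=100)
        panel = design.pick_sex_loci(vt, self.LABELS, self.GSDF, self.TE, p)
        assert panel.category_counts()["te_breakpoint_probe"] == 100

    def test_unlabelled_cohort_rejected(self):
        vt = self._vt([[0, 0, 1, 1]], [50_000])
        with pytest.raises(ValueError):
            design.pick_sex_loci(vt, {}, self.GSDF, self.TE,
                                 design.DesignParams())


class TestMockPconvert:
    def test_accept_all_is_identity(self):
        panel = _panel_at(list(range(1000, 21000, 1000)))
        out = design.mock_pconvert(panel)
        assert len(out) == len(panel)

    def test_periodic_scorer_drops_every_tenth(self):
        panel = _panel_at(list(range(1000, 101000, 1000)))
        out = design.mock_pconvert(panel, design.periodic_scorer(10))
        assert len(out) == 90

    def test_hashed_scorer_deterministic(self):
        panel = _panel_at(list(range(1000, 51000, 1000)))
        a = design.mock_pconvert(panel, design.hashed_scorer(seed=4))
        b = design.mock_pconvert(panel, design.hashed_scorer(seed=4))
        assert list(a.df["marker_id"]) == list(b.df["marker_id"])
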