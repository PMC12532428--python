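"""End-to-end orchestration: simulate -> design -> qc -> concordance ->
ld -> sexcall, driven by one config, with a machine-readable run report.

Every stage writes its tables under the output directory and contributes
attrition counts to the report; the report carries the config hash and
seed so a rerun with the same config is byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import design as design_mod
from . import io_core, ld, qc, sexcall
from .simulate import SimConfig, inject_duplicates, simulate_cohort
from .types import GenomicInterval, GenotypeMatrix, MarkerPanel

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "design", "qc", "concordance", "ld", "sexcall")


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 17
    stages: tuple[str, ...] = ALL_STAGES
    sim: SimConfig = field(default_factory=SimConfig)
    design: design_mod.DesignParams = field(
        default_factory=design_mod.DesignParams)
    # QC thresholds
    cr_threshold: float = 97.0
    dish_threshold: float = 0.82
    hwe_alpha: float = 0.01
    # duplicate injection
    n_duplicate_pairs: int = 9
    dup_miss_rate: float = 0.02
    dup_disc_rate: float = 0.004
    # LD
    ld_bin_width: int = 100_000
    ld_max_dist: int = 10_000_000
    ld_max_markers_per_chrom: int = 400
    # sex calling
    hom_female_min: float = 0.85
    hom_male_max: float = 0.65
    discriminating_delta: float = 0.5
    te_threshold: float = 400.0
    te_ambiguity_band: float = 0.10

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if "simulate" in self.stages and self.seed is None:
            raise ValueError("seed is mandatory when simulation is enabled")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("gsdf_region",):
            if key in sim_raw:
                sim_raw[key] = GenomicInterval(**sim_raw[key])
        if "te_intervals" in sim_raw:
            sim_raw["te_intervals"] = tuple(
                GenomicInterval(**iv) for iv in sim_raw["te_intervals"])
        design_raw = raw.pop("design", {})
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(sim=SimConfig(**sim_raw),
                   design=design_mod.DesignParams(**design_raw), **raw)

    def config_hash(self) -> str:
        payload = _jsonable(self)
        payload.pop("outdir", None)  # a location, not an analysis parameter
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(config.stages),
    }

    cohort = None
    panel: Optional[MarkerPanel] = None
    gm: Optional[GenotypeMatrix] = None
    metrics = None

    if "simulate" in config.stages:
        try:
            sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
            cohort = simulate_cohort(sim_cfg)
            gm, sheet = cohort.genotypes, cohort.sheet
            if config.n_duplicate_pairs:
                gm, sheet = inject_duplicates(
                    gm, sheet, config.n_duplicate_pairs,
                    config.dup_miss_rate, config.dup_disc_rate,
                    seed=config.seed + 1)
            cohort.genotypes, cohort.sheet = gm, sheet
            io_core.write_vcf(cohort.variants, out / "variants.vcf")
            io_core.write_calls_tsv(gm, out / "calls.tsv")
            io_core.write_intensity_tsv(cohort.intensities,
                                        out / "intensities.tsv")
            io_core.write_sample_sheet(sheet, out / "samples.tsv")
            report["simulate"] = {
                "n_sites": cohort.variants.n_sites,
                "n_samples": gm.n_samples,
                "n_duplicate_pairs": config.n_duplicate_pairs,
            }
        except Exception as e:
            raise StageError(f"[simulate] {e}") from e

    downstream = set(config.stages) - {"simulate"}
    if cohort is None:
        if downstream:
            raise StageError("[pipeline] stages beyond simulate need "
                             "simulated inputs; enable the simulate stage")
        with open(out / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    vt, sheet = cohort.variants, cohort.sheet

    if "design" in config.stages:
        try:
            filtered = design_mod.filter_variants(vt, config.design)
            spaced = design_mod.select_spaced(filtered, config.design)
            trimmed = design_mod.trim_panel(spaced, config.design)
            brood = sheet[sheet.get("group", "") == "broodstock"]
            labels = dict(zip(brood["sample_id"], brood["phenotypic_sex"]))
            sex_panel = design_mod.pick_sex_loci(
                vt, labels, config.sim.gsdf_region,
                list(config.sim.te_intervals), config.design)
            combined = MarkerPanel(pd.concat(
                [trimmed.df, sex_panel.df], ignore_index=True)).sorted()
            panel = design_mod.mock_pconvert(combined)
            io_core.write_panel(panel, out / "panel.tsv")
            attr = dict(filtered.meta.get("attrition", {}))
            report["design"] = {
                "attrition": attr,
                "n_spaced": len(spaced),
                "n_trimmed": len(trimmed),
                "category_counts": panel.category_counts(),
                "sex_subtotal": panel.sex_subtotal(),
                "n_panel": len(panel),
            }
        except Exception as e:
            raise StageError(f"[design] {e}") from e

    # markers of the panel that the array genotypes (SNP categories only)
    genotyped_ids = None
    if panel is not None:
        on_array = panel.df["category"] != "te_breakpoint_probe"
        known = set(gm.marker_ids)
        genotyped_ids = [m for m in panel.df.loc[on_array, "marker_id"]
                         if m in known]

    qc_pass_ids = list(gm.sample_ids)
    if "qc" in config.stages:
        try:
            gm_qc = (gm.take_markers(genotyped_ids)
                     if genotyped_ids else gm)
            dish = dict(zip(sheet["sample_id"], sheet["dish_qc"]))
            reports = qc.sample_qc(gm_qc, dish, config.cr_threshold,
                                   config.dish_threshold)
            qc_pass_ids = qc.passing_samples(reports)
            _write_tsv(pd.DataFrame([r.__dict__ for r in reports]),
                       out / "qc_samples.tsv")
            gm_pass = gm_qc.take_samples(qc_pass_ids)
            metrics = qc.classify_markers(gm_pass)
            _write_tsv(metrics, out / "qc_markers.tsv")
            summary = qc.qc_summary(metrics, hwe_alpha=config.hwe_alpha)
            report["qc"] = {
                "n_samples": gm_qc.n_samples,
                "n_samples_pass": len(qc_pass_ids),
                "n_samples_fail": gm_qc.n_samples - len(qc_pass_ids),
                **summary,
            }
        except Exception as e:
            raise StageError(f"[qc] {e}") from e

    if "concordance" in config.stages:
        try:
            dup_rows = sheet[sheet["duplicate_of"].astype(str) != ""]
            pairs = list(zip(dup_rows["duplicate_of"], dup_rows["sample_id"]))
            dup_reports, dup_mean = conc.duplicate_reproducibility(gm, pairs)
            _write_tsv(pd.DataFrame([r.__dict__ for r in dup_reports]),
                       out / "duplicates.tsv")
            # array vs sequencing over the WGS broodstock
            wgs_gm = GenotypeMatrix(
                sample_ids=list(vt.sample_ids),
                marker_ids=[f"{c}_{p}" for c, p in zip(vt.chrom, vt.pos)],
                calls=vt.genotypes.T.copy(),
                marker_chrom=vt.chrom, marker_pos=vt.pos)
            sample_map = {s: s for s in vt.sample_ids}
            gm_cmp = (gm.take_markers(genotyped_ids)
                      if genotyped_ids else gm)
            per_marker = conc.genotype_concordance(gm_cmp, wgs_gm, sample_map)
            if metrics is not None:
                cats = dict(zip(metrics["marker_id"], metrics["category"]))
            else:
                cats = {m: "all" for m in per_marker["marker_id"]}
            rows = conc.category_summary(
                per_marker, cats, per_marker.attrs["n_samples_compared"])
            _write_tsv(conc.summary_frame(rows), out / "concordance.tsv")
            n_markers = int(gm.n_markers)
            report["concordance"] = {
                "duplicate_mean_inconsistencies": dup_mean,
                "duplicate_mean_pct": (100.0 * dup_mean / n_markers
                                       if n_markers else float("nan")),
                "n_samples_compared": per_marker.attrs["n_samples_compared"],
                "overall_by_category": {
                    r.category: r.overall_pct_concordance for r in rows},
            }
        except Exception as e:
            raise StageError(f"[concordance] {e}") from e

    if "ld" in config.stages:
        try:
            if panel is not None:
                gw = panel.subset(["genome_wide"])
                known = set(gm.marker_ids)
                ids = [m for m in gw.df["marker_id"] if m in known]
            else:
                ids = list(gm.marker_ids)
            gm_ld = gm.take_markers(ids).take_samples(qc_pass_ids)
            # cap per-chromosome marker counts to bound the pair matrix
            keep = []
            for chrom in pd.unique(gm_ld.marker_chrom):
                cidx = np.flatnonzero(gm_ld.marker_chrom == chrom)
                if len(cidx) > config.ld_max_markers_per_chrom:
                    take = np.linspace(0, len(cidx) - 1,
                                       config.ld_max_markers_per_chrom
                                       ).round().astype(int)
                    cidx = cidx[np.unique(take)]
                keep.extend(cidx.tolist())
            gm_ld = gm_ld.take_markers([gm_ld.marker_ids[i]
                                        for i in sorted(keep)])
            decay = ld.genome_decay(gm_ld, bin_width=config.ld_bin_width,
                                    max_dist=config.ld_max_dist)
            _write_tsv(decay, out / "ld_decay.tsv")
            frames = []
            for chrom in pd.unique(gm_ld.marker_chrom):
                if (gm_ld.marker_chrom == chrom).sum() >= 2:
                    frames.append(ld.pairwise_r2(
                        gm_ld, str(chrom), max_dist=config.ld_max_dist))
            pairs_df = pd.concat(frames, ignore_index=True)
            per_chrom = ld.per_chrom_decay(pairs_df)
            _write_tsv(per_chrom, out / "ld_per_chrom.tsv")
            report["ld"] = {
                "n_markers": gm_ld.n_markers,
                "n_pairs": int(decay["n_pairs"].sum()),
                "first_bin_mean_r2": float(decay["mean_r2"].iloc[0]),
            }
        except Exception as e:
            raise StageError(f"[ld] {e}") from e

    if "sexcall" in config.stages:
        try:
            known = set(gm.marker_ids)
            if panel is not None:
                panel_a = [m for m in panel.subset(
                    ["sex_segregating_snp"]).df["marker_id"] if m in known]
                gsdf_ids = [m for m in panel.subset(
                    ["gsdf_region_snp"]).df["marker_id"] if m in known]
            else:
                panel_a, gsdf_ids = [], []
            # training labels: phenotyped females/males, neomales excluded
            lab = sheet[(sheet["duplicate_of"].astype(str) == "")
                        & sheet["phenotypic_sex"].isin(["female", "male"])]
            labels = dict(zip(lab["sample_id"], lab["phenotypic_sex"]))
            if gsdf_ids:
                disc = sexcall.select_discriminating_snps(
                    gm.take_markers(gsdf_ids), labels,
                    config.discriminating_delta)
                panel_b = disc.loc[disc["selected"], "marker_id"].tolist()
                _write_tsv(disc, out / "sex_discriminating.tsv")
            else:
                panel_b = []
            diff = sexcall.te_probe_differential(
                cohort.intensities, labels, config.te_threshold)
            _write_tsv(diff, out / "sex_te_probes.tsv")
            sel_probes = diff.loc[diff["selected"], "probe_id"].tolist()
            evidence = sexcall.assemble_evidence(
                gm, panel_a, panel_b, cohort.intensities, sel_probes,
                labels, (config.hom_female_min, config.hom_male_max),
                config.te_ambiguity_band)
            phenos = dict(zip(sheet["sample_id"], sheet["phenotypic_sex"]))
            calls = sexcall.call_genetic_sex(evidence, phenos)
            frame = sexcall.calls_frame(calls)
            _write_tsv(frame, out / "sex_calls.tsv")
            entry = {
                "n_panel_a": len(panel_a),
                "n_panel_b": len(panel_b),
                "n_te_probes_selected": len(sel_probes),
                "n_ambiguous": int((frame["genetic_sex"] == "ambiguous").sum()),
                "n_candidate_misassignment": int(
                    (frame["reconciliation"]
                     == "candidate_misassignment").sum()),
            }
            if "true_genetic_sex" in sheet.columns:
                truth = dict(zip(sheet["sample_id"],
                                 sheet["true_genetic_sex"]))
                correct = [c.genetic_sex == truth[c.sample_id]
                           for c in calls if c.sample_id in truth]
                entry["accuracy_pct"] = 100.0 * float(np.mean(correct))
            report["sexcall"] = entry
        except Exception as e:
            raise StageError(f"[sexcall] {e}") from e

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
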