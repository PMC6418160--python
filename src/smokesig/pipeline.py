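"""End-to-end orchestration: simulate -> preprocess -> EWAS -> enrichment.

`run_pipeline` executes the full chain under a single `RunConfig`, writes
all stage outputs as plain-text tables, and returns a manifest whose
sample/probe counts reconcile stage to stage. Identical config and seeds
give identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrich, ewas, io, preprocess, synthdata
from .synthdata import SimulationConfig


@dataclass
class RunConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    detp_cut: float = 0.01
    sample_fail_frac: float = 0.01
    probe_sample_frac: float = 0.10
    intensity_cut: float = 11.0
    noob_offset: float = 15.0
    beta_offset: float = 100.0
    gap_threshold: float = 0.05
    gap_out_cutoff: float = 0.01
    p_cutoff_a: float = enrich.P_CUTOFF
    p_cutoff_b: float = enrich.P_CUTOFF
    n_perm: int = 10_000
    run_sweep: bool = True
    run_stratified: bool = False
    contrast: str = "current"
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        self.sim.validate()
        for name in ("detp_cut", "sample_fail_frac", "probe_sample_frac",
                     "p_cutoff_a", "p_cutoff_b", "gap_threshold", "gap_out_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**data.pop("sim", {}))
        return cls(sim=sim, **data)


@dataclass
class RunResult:
    manifest: dict
    annotation: pd.DataFrame
    cohort: pd.DataFrame
    effects: pd.DataFrame
    prep: preprocess.PreprocessResult
    ewas_result: ewas.EwasResult
    blood_stats: pd.DataFrame
    enrichment: enrich.EnrichmentResult
    sweep: pd.DataFrame | None
    permutation: enrich.PermutationNull
    concordance: enrich.ConcordanceReport | None
    region: enrich.RegionEnrichment | None
    stratified: dict | None


def _stage_seeds(seed: int) -> dict:
    """Independent per-stage seeds derived from the master seed."""
    ss = np.random.SeedSequence(seed)
    names = ("annotation", "cohort", "effects", "intensities", "blood", "perm")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> RunResult:
    config.validate()
    seeds = _stage_seeds(config.seed)
    sim = config.sim

    annotation = synthdata.simulate_annotation(
        sim.n_probes, cross_reactive_frac=sim.cross_reactive_frac, seed=seeds["annotation"]
    )
    cohort = synthdata.simulate_cohort(
        sim.n_samples, group_props=sim.group_props, n_plates=sim.n_plates, seed=seeds["cohort"]
    )
    effects = synthdata.plant_effects(annotation, sim, seed=seeds["effects"])
    raw = synthdata.simulate_intensities(annotation, cohort, effects, sim, seed=seeds["intensities"])
    blood = synthdata.simulate_summary_stats(
        effects, annotation, meta_n=sim.meta_n, seed=seeds["blood"]
    )

    prep = preprocess.preprocess(
        raw, cohort, annotation,
        detp_cut=config.detp_cut, sample_fail_frac=config.sample_fail_frac,
        probe_sample_frac=config.probe_sample_frac, intensity_cut=config.intensity_cut,
        noob_offset=config.noob_offset, beta_offset=config.beta_offset,
        gap_threshold=config.gap_threshold, gap_out_cutoff=config.gap_out_cutoff,
    )
    ew = ewas.run_ewas(prep.beta, cohort, gap_flags=prep.gap_flags, annotation=annotation)
    lung = ew.tables[config.contrast]

    universe, N, n_b_lost = enrich.harmonize_universe(lung.reset_index(), blood)
    blood_in = blood[blood["probe_id"].isin(universe)]
    set_b = set(blood_in.loc[blood_in["p"] < config.p_cutoff_b, "probe_id"])
    set_a = set(lung.index[lung["p"] < config.p_cutoff_a])
    result = enrich.overlap_enrichment(
        set_a, set_b, N, threshold_a=config.p_cutoff_a, threshold_b=config.p_cutoff_b
    )
    sweep = (
        enrich.threshold_sweep(lung["p"], set_b, N) if config.run_sweep else None
    )
    perm = enrich.permutation_null(
        lung["p"], set_b, N, threshold=config.p_cutoff_a,
        n_perm=config.n_perm, seed=seeds["perm"],
    )
    overlap = set_a & set_b
    concordance = (
        enrich.effect_concordance(lung.reset_index(), blood, overlap) if overlap else None
    )
    region = (
        enrich.region_distribution_test(overlap, annotation) if overlap else None
    )
    stratified = None
    if config.run_stratified:
        strata = {}
        meta = cohort[cohort["sample_id"].isin(prep.beta.columns)]
        for stage, grp in meta.groupby("stage"):
            if grp["smoking"].nunique() < 2 or len(grp) <= ew.design.rank:
                continue
            sub = ewas.run_ewas(prep.beta[list(grp["sample_id"])], grp,
                                gap_flags=prep.gap_flags)
            if config.contrast in sub.tables:
                strata[stage] = sub.tables[config.contrast]["p"]
        stratified = enrich.stratified_enrichment(strata, set_b, threshold=config.p_cutoff_a)

    manifest = dict(prep.manifest)
    manifest.update(
        {
            "seed": config.seed,
            "stage_seeds": seeds,
            "universe_N": int(N),
            "n_blood_probes_lost": int(n_b_lost),
            "n_a": result.n_a,
            "n_b": result.n_b,
            "k_overlap": result.k,
            "expected_overlap": result.expected,
            "p_fisher": result.p_fisher,
            "empirical_p": perm.empirical_p,
            "lambda": ew.lambdas,
            "ebayes_d0": ew.prior.d0,
            "ebayes_s0_sq": ew.prior.s0_sq,
        }
    )
    # reconciliation guard: counts must balance at every stage
    assert manifest["n_samples_in"] - manifest["n_samples_qc_removed"] \
        - manifest["n_samples_duplicate_removed"] == manifest["n_samples_out"]
    assert manifest["n_probes_in"] - manifest["n_probes_cross_reactive_removed"] \
        - manifest["n_probes_low_detection_removed"] == manifest["n_probes_out"]

    run = RunResult(
        manifest=manifest, annotation=annotation, cohort=cohort, effects=effects,
        prep=prep, ewas_result=ew, blood_stats=blood, enrichment=result, sweep=sweep,
        permutation=perm, concordance=concordance, region=region, stratified=stratified,
    )
    if config.outdir:
        write_outputs(run, config)
    return run


def write_outputs(run: RunResult, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_annotation(run.annotation, out / "annotation.tsv")
    io.write_cohort(run.cohort, out / "cohort.csv")
    run.effects.to_csv(out / "effects.tsv", sep="\t", index=False)
    io.write_matrix(run.prep.beta, out / "beta.tsv")
    io.write_summary_stats(run.blood_stats, out / "blood_summary_stats.tsv")
    for name, tab in run.ewas_result.tables.items():
        tab.to_csv(out / f"ewas_{name}.tsv", sep="\t")
    if run.sweep is not None:
        run.sweep.to_csv(out / "sweep.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"overlap": run.permutation.overlaps, "fisher_p": run.permutation.fisher_p}
    ).to_csv(out / "permutation_trace.tsv", sep="\t", index=False)
    enr = dataclasses.asdict(run.enrichment)
    enr["empirical_p"] = run.permutation.empirical_p
    if run.concordance:
        enr["concordance"] = dataclasses.asdict(run.concordance)
    if run.region:
        enr["region"] = dataclasses.asdict(run.region)
    io.write_json(enr, out / "enrichment.json")
    io.write_json(run.manifest, out / "manifest.json")
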