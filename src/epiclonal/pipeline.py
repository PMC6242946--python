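"""End-to-end orchestration of the clonal epigenetics analysis.

``run_full`` chains the stages on CSV inputs: SSR clone identification ->
restriction to clone members -> MS-AFLP scoring (both double-absence
modes) -> diversity and structure statistics -> bud-set CLMM and D50% ->
per-epilocus association tests with FDR control.  All intermediates are
plain CSV/JSON so every stage can be inspected and re-run independently;
``run_synthetic`` generates a synthetic study first and appends
truth-versus-estimate diagnostics.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import association, diversity, msap, phenology, ssr
from .config import RunConfig, SimConfig
from .simulate import simulate_study, write_study

__all__ = ["run_full", "run_synthetic", "RunReport"]

log = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Per-stage summaries of one full pipeline run."""

    version: str = __version__
    config: dict = field(default_factory=dict)
    ssr: dict = field(default_factory=dict)
    msap: dict = field(default_factory=dict)
    diversity: dict = field(default_factory=dict)
    phenology: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)
    truth_comparison: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    errors: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True,
                      default=_jsonify)
            fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def _stage(name: str, t0: float, **counts) -> None:
    info = " ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, info)


# ------------------------------------------------------------------- stages
def stage_ssr(genotypes: pd.DataFrame, config: RunConfig, report: RunReport):
    t0 = time.perf_counter()
    assignment = ssr.identify_mlgs(genotypes)
    assignment = ssr.classify_clonemates(assignment, genotypes,
                                         max_mismatch=config.max_mismatch)
    try:
        err = ssr.genotyping_error_rate(genotypes)
    except ValueError:
        err = np.nan
        report.warnings.append("no SSR replicate pairs; error rate undefined")
    clones = assignment.loc[assignment["is_clone"], "sample_id"].tolist()
    report.ssr = {
        "n_samples": int(assignment.shape[0]),
        "n_mlgs": int(assignment["mlg_id"].nunique()),
        "n_clone_members": len(clones),
        "genotyping_error_rate_pct": None if np.isnan(err) else float(err),
    }
    _stage("ssr", t0, samples=len(assignment), clones=len(clones))
    return assignment, clones


def stage_msap(fragments: pd.DataFrame, clones: list[str], config: RunConfig,
               report: RunReport):
    t0 = time.perf_counter()
    keep = (fragments["sample_id"].isin(clones)
            | fragments["replicate_of"].isin(clones))
    fragments = fragments[keep]
    results = {}
    for mode in msap.MODES:
        epi, rates, mean_rate, removal_log, patterns = msap.score_pipeline(
            fragments, mode, config.min_fragment_size,
            config.max_fragment_size, test=config.susceptibility_test,
            threshold_override=config.threshold_override)
        results[mode] = epi
    combo_of_locus = patterns.columns.to_series().map(
        fragments.groupby("locus_id")["primer_combo_id"].first())
    flags = (results["missing_on_double_absence"].meta[
        "is_methylation_susceptible"].reindex(patterns.columns)
        .astype("boolean").fillna(False).astype(bool))
    summary = msap.marker_summary(patterns, flags,
                                  results["missing_on_double_absence"],
                                  rates, combo_of_locus)
    combined = msap.combine_marker_summary(summary)
    epi_missing = results["missing_on_double_absence"]
    epi_zero = results["absence_as_unmethylated"]
    report.msap = {
        "per_combo": summary.to_dict(orient="records"),
        "combined": combined.to_dict(),
        "mean_error_rate": mean_rate,
        "n_loci_total": int(combined["n_markers"]),
        "n_methylation_susceptible": int(combined["n_methylation_susceptible"]),
        "n_polymorphic_missing_mode": int(
            epi_missing.meta["is_polymorphic"].sum()),
        "n_polymorphic_zero_mode": int(epi_zero.meta["is_polymorphic"].sum()),
        "n_loci_with_missing": int(epi_missing.meta["has_missing"].sum()),
        "n_removed": removal_log.groupby("reason").size().to_dict(),
    }
    _stage("msap", t0, loci=int(combined["n_markers"]),
           susceptible=int(combined["n_methylation_susceptible"]))
    return epi_missing, epi_zero, summary, combined, rates, removal_log


def stage_diversity(epi_missing: msap.EpilocusMatrix, donors: pd.DataFrame,
                    sites: pd.DataFrame, config: RunConfig,
                    report: RunReport):
    t0 = time.perf_counter()
    poly = epi_missing.states[
        epi_missing.meta.index[epi_missing.meta["is_polymorphic"]]]
    complete = poly[[c for c in poly.columns if poly[c].notna().all()]]
    if complete.shape[1] == 0:
        raise ValueError("no complete polymorphic epiloci for diversity")
    per_locus, mean_i, sd_i = diversity.shannon_index(complete)
    groups_all = diversity.match_epigenotypes(poly)
    d_plain = diversity.epi_distance(complete, squared=False)
    d_sq = diversity.epi_distance(complete, squared=True)
    pco = diversity.pcoa(d_plain)

    donor_info = donors.set_index("donor_id").reindex(complete.index)
    site_cols = sites.set_index("site_id")
    coords = donor_info.join(site_cols[["latitude", "longitude"]],
                             on="site_id")
    geo = diversity.geo_distance(coords)
    seeds = _child_seeds(config.seed, 2)
    am = diversity.amova(d_sq, donor_info["country"],
                         n_perm=config.n_permutations, seed=seeds[0])
    mt = diversity.mantel(d_plain, geo, n_perm=config.n_permutations,
                          seed=seeds[1])
    report.diversity = {
        "n_samples": int(complete.shape[0]),
        "n_loci_used": int(complete.shape[1]),
        "shannon_mean": mean_i,
        "shannon_sd": sd_i,
        "n_unique_epigenotypes": int(groups_all.nunique()),
        "pcoa_pct_variance": [float(v) for v in pco.pct_variance[:3]],
        "amova": am.to_dict(),
        "mantel": mt.to_dict(),
    }
    _stage("diversity", t0, samples=complete.shape[0],
           loci=complete.shape[1])
    return per_locus, groups_all, d_plain, d_sq, geo, pco, am, mt


def stage_phenology(budset: pd.DataFrame, clones: list[str],
                    sites: pd.DataFrame, config: RunConfig,
                    report: RunReport, se: bool = False):
    t0 = time.perf_counter()
    obs = budset[budset["donor_id"].isin(clones)]
    model = phenology.BudSetClmm.from_dataframe(obs)
    fit = model.fit(se=se)
    d50_table = fit.d50(cn_ref=config.cn_reference)
    corr = phenology.pearson_climate(d50_table, sites)
    report.warnings.extend(fit.warnings)
    report.phenology = {
        "fit": fit.to_dict(),
        "d50_mean": float(d50_table["d50"].mean()),
        "d50_range": [float(d50_table["d50"].min()),
                      float(d50_table["d50"].max())],
        "climate_correlations": corr.to_dict(orient="records"),
    }
    _stage("phenology", t0, obs=len(obs), donors=d50_table.shape[0])
    return fit, d50_table, corr


def stage_associate(epi_zero: msap.EpilocusMatrix, d50_table: pd.DataFrame,
                    donors: pd.DataFrame, sites: pd.DataFrame,
                    config: RunConfig, report: RunReport):
    t0 = time.perf_counter()
    states = epi_zero.states[
        epi_zero.meta.index[epi_zero.meta["is_polymorphic"]]]
    donor_info = donors.set_index("donor_id").reindex(states.index)
    climate = donor_info.join(
        sites.set_index("site_id")[list(association.CLIMATE_COVARIATES)],
        on="site_id")
    glm = association.epilocus_glm(states, climate)
    glm = association.apply_fdr(glm, q=config.fdr_q)
    welch = association.welch_test(d50_table, states)
    welch = association.apply_fdr(welch, q=config.fdr_q)
    report.association = {
        "n_polymorphic_zero_mode": int(states.shape[1]),
        "glm_tests": int(glm.shape[0]),
        "glm_nonestimable": int((~glm["estimable"]).sum()) if len(glm) else 0,
        "glm_significant_pre_fdr": int((glm["p_value"] < 0.05).sum())
        if len(glm) else 0,
        "glm_loci_significant_pre_fdr": int(
            glm.loc[glm["p_value"] < 0.05, "locus_id"].nunique())
        if len(glm) else 0,
        "glm_significant_post_fdr": int(glm["significant_at_q05"].sum())
        if len(glm) else 0,
        "welch_tests": int(welch.shape[0]),
        "welch_significant_pre_fdr": int((welch["p_value"] < 0.05).sum())
        if len(welch) else 0,
        "welch_significant_post_fdr": int(welch["significant_at_q05"].sum())
        if len(welch) else 0,
    }
    _stage("associate", t0, glm=len(glm), welch=len(welch))
    return glm, welch


# ----------------------------------------------------------------- full runs
def _load_inputs(config: RunConfig):
    read = lambda p: pd.read_csv(p, na_values=["NA"])
    frags = read(config.fragments_csv)
    genotypes = read(config.ssr_csv)
    sites = read(config.climate_csv)
    budset = read(config.budset_csv)
    donors = (budset[["donor_id", "site_id"]].drop_duplicates()
              .reset_index(drop=True))
    donors = donors.merge(sites[["site_id", "country"]], on="site_id",
                          how="left")
    return frags, genotypes, sites, budset, donors


def run_full(config: RunConfig, se: bool = False) -> RunReport:
    """Execute the whole analysis from CSV inputs; writes stage outputs and a
    JSON report under ``config.output_dir`` and returns the report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())
    try:
        frags, genotypes, sites, budset, donors = _load_inputs(config)
        assignment, clones = stage_ssr(genotypes, config, report)
        assignment.to_csv(outdir / "mlg_assignment.csv", index=False)

        epi_missing, epi_zero, summary, combined, rates, removal_log = \
            stage_msap(frags, clones, config, report)
        for mode_tag, epi in (("missing", epi_missing), ("zero", epi_zero)):
            epi.states.to_csv(outdir / f"epigenotypes_{mode_tag}.csv",
                              na_rep="NA")
            epi.meta.to_csv(outdir / f"epilocus_metadata_{mode_tag}.csv")
        pd.concat([summary, combined.to_frame().T], ignore_index=True).to_csv(
            outdir / "marker_summary.csv", index=False)
        removal_log.to_csv(outdir / "removed_loci.csv", index=False)

        per_locus, groups_all, d_plain, d_sq, geo, pco, am, mt = \
            stage_diversity(epi_missing, donors, sites, config, report)
        d_plain.to_csv(outdir / "epi_distance.csv")
        geo.to_csv(outdir / "geo_distance_km.csv")
        pco.coordinates.to_csv(outdir / "pcoa_coordinates.csv")
        with open(outdir / "structure.json", "w") as fh:
            json.dump({"amova": am.to_dict(), "mantel": mt.to_dict()}, fh,
                      indent=2, sort_keys=True, default=_jsonify)

        fit, d50_table, corr = stage_phenology(budset, clones, sites, config,
                                               report, se=se)
        with open(outdir / "clmm_fit.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=2, sort_keys=True,
                      default=_jsonify)
        d50_table.to_csv(outdir / "d50.csv", index=False)
        corr.to_csv(outdir / "climate_correlations.csv", index=False)

        glm, welch = stage_associate(epi_zero, d50_table, donors, sites,
                                     config, report)
        glm.to_csv(outdir / "associations_glm.csv", index=False)
        welch.to_csv(outdir / "associations_welch.csv", index=False)
    except Exception as exc:
        log.exception("pipeline stage failed")
        report.errors.append(f"{type(exc).__name__}: {exc}")
    report.save(outdir / "report.json")
    if report.errors:
        raise RuntimeError("; ".join(report.errors))
    return report


def run_synthetic(sim_config: SimConfig, run_config: RunConfig | None = None,
                  se: bool = False) -> RunReport:
    """Generate a synthetic study, run the full pipeline on its CSV files and
    append truth-versus-estimate diagnostics to the report."""
    run_config = run_config or RunConfig()
    outdir = Path(run_config.output_dir)
    study = simulate_study(sim_config)
    paths = write_study(study, outdir / "inputs")
    run_config.fragments_csv = Path(paths["fragments"])
    run_config.ssr_csv = Path(paths["ssr"])
    run_config.climate_csv = Path(paths["sites"])
    run_config.budset_csv = Path(paths["budset"])
    report = run_full(run_config, se=se)

    # truth comparison: methylation-state recovery on retained loci
    epi = pd.read_csv(outdir / "epigenotypes_missing.csv", index_col=0,
                      na_values=["NA"])
    truth = study.msap.truth.loc[epi.index]
    truth_bin = truth.apply(
        lambda c: c.map({"U": 0.0, "I": 1.0, "H": 1.0, "A": np.nan}))
    common = [c for c in epi.columns if c in truth_bin.columns]
    obs = epi[common].to_numpy(float)
    tru = truth_bin[common].to_numpy(float)
    comparable = ~np.isnan(obs) & ~np.isnan(tru)
    recovery = (float((obs[comparable] == tru[comparable]).mean())
                if comparable.any() else np.nan)

    p = sim_config.clmm_params
    fit = report.phenology["fit"]
    report.truth_comparison = {
        "state_recovery_rate": recovery,
        "n_states_compared": int(comparable.sum()),
        "clmm_truth": {"thresholds": list(p.thresholds),
                       "beta_day": p.beta_day, "beta_cn": p.beta_cn,
                       "sigma_tree": p.sigma_tree,
                       "sigma_ramet": p.sigma_ramet},
        "clmm_estimates": {"thresholds": fit["thresholds"],
                           "beta_day": fit["beta"].get("day"),
                           "beta_cn": fit["beta"].get("cn"),
                           "sigma_tree": fit["sigma_tree"],
                           "sigma_ramet": fit["sigma_ramet"]},
    }
    report.save(outdir / "report.json")
    return report
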