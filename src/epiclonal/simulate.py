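"""Synthetic clonal common-garden study generator.

Generates every input table of the analysis — site climate, dual-enzyme
MS-AFLP fragment profiles, SSR multilocus genotypes and longitudinal ordinal
bud-set observations — with the statistical structure the downstream analysis
assumes, alongside the latent truth needed to validate the scoring stages.

Climate covariates share a single latent "winter harshness" factor so that
January/March temperature, frost-day frequency and potential
evapotranspiration are mutually correlated at r^2 > 0.8, as in the real
sampling range.  Methylation states are drawn per locus and mapped to the
HpaII/MspI presence patterns; per-band technical noise is applied
independently to every scoring, including the replicated samples.  Bud-set
scores are drawn from the cumulative-logit model with donor and ramet random
intercepts, a site effect linear in January temperature, and a
carbon:nitrogen covariate negatively correlated with cutting weight.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import SimConfig
from .phenology import SCORE_LEVELS, cumulative_logit_probs

__all__ = [
    "CLIMATE_RANGES",
    "simulate_sites",
    "simulate_msap",
    "simulate_ssr",
    "simulate_budset",
    "simulate_study",
    "MsapSimulation",
    "SsrSimulation",
    "BudSetSimulation",
    "StudyData",
]

#: Observed ranges of the home-site geography/climate variables (min, max).
CLIMATE_RANGES: dict[str, tuple[float, float]] = {
    "latitude": (40.752, 55.890),
    "longitude": (-4.593, 25.457),
    "t_jan": (-1.400, 8.024),
    "t_mar": (3.87, 10.83),
    "t_jul": (14.93, 26.20),
    "precip": (23.274, 101.065),
    "frost_days": (8.497, 26.436),
    "pet": (22.746, 43.879),
    "cn_topsoil": (6.0, 20.0),
}

# latent-factor loading shared by the winter-harshness variables; 0.97 gives
# pairwise r^2 ~ 0.88 before range clipping
_LOADING = 0.97

#: (mean, sd, sign of loading on the winter factor); sd spans the observed
#: range at ~2.2 sigma so clipping is rare.
_CLIMATE_MODEL = {
    "t_jan": (3.31, 2.1, +1),
    "t_mar": (7.35, 1.55, +1),
    "frost_days": (17.47, 4.0, -1),
    "pet": (33.31, 4.7, +1),
    "t_jul": (20.57, 2.5, 0),
    "precip": (62.17, 17.0, 0),
    "cn_topsoil": (12.0, 2.5, 0),
}

_PATTERN_BANDS = {  # latent state -> (HpaII, MspI) presence
    "U": (1, 1),
    "I": (0, 1),
    "H": (1, 0),
    "A": (0, 0),
}


class MsapSimulation(NamedTuple):
    profiles: pd.DataFrame  # long fragment table, both enzymes
    truth: pd.DataFrame     # sample_id x locus_id latent state (U/I/H/A)


class SsrSimulation(NamedTuple):
    genotypes: pd.DataFrame
    truth: pd.DataFrame  # sample_id -> true class (clone/variant/nonclone)


class BudSetSimulation(NamedTuple):
    observations: pd.DataFrame
    ranef_tree: pd.Series
    ranef_ramet: pd.Series
    site_effects: pd.Series


class StudyData(NamedTuple):
    sites: pd.DataFrame
    donors: pd.DataFrame
    msap: MsapSimulation
    ssr: SsrSimulation
    budset: BudSetSimulation


def _rngs(config: SimConfig, n: int) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(config.seed).spawn(n)
    return [np.random.default_rng(s) for s in seqs]


def simulate_sites(config: SimConfig) -> pd.DataFrame:
    """Draw home sites with geography, climate and a country grouping.

    Returns one row per site.  Winter-related covariates (January and March
    temperature, frost days, PET) load on a shared latent factor with
    loading 0.97, so each pair has squared correlation > 0.8 in expectation;
    July temperature, precipitation and topsoil C:N are independent.  All
    values are clipped to the observed ranges.  Latitude decreases with the
    winter factor (colder winters further north); countries group
    neighbouring sites by latitude.
    """
    if config.n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    rng = _rngs(config, 6)[0]
    n = config.n_sites
    scale = config.climate_sd_scale
    harsh = rng.standard_normal(n)
    cols: dict[str, np.ndarray] = {}
    for name, (mean, sd, sign) in _CLIMATE_MODEL.items():
        if sign == 0:
            raw = mean + sd * scale * rng.standard_normal(n)
        else:
            noise = np.sqrt(1.0 - _LOADING**2) * rng.standard_normal(n)
            raw = mean + sd * scale * sign * (_LOADING * harsh + noise)
        lo, hi = CLIMATE_RANGES[name]
        cols[name] = np.clip(raw, lo, hi)
    lat_lo, lat_hi = CLIMATE_RANGES["latitude"]
    lat = np.clip(48.3 + scale * (-2.8 * harsh + 1.5 * rng.standard_normal(n)),
                  lat_lo, lat_hi)
    lon_lo, lon_hi = CLIMATE_RANGES["longitude"]
    if scale == 0:
        lon = np.full(n, 0.5 * (lon_lo + lon_hi))
    else:
        lon = rng.uniform(lon_lo, lon_hi, n)
    sites = pd.DataFrame(
        {"site_id": [f"S{i+1:02d}" for i in range(n)],
         "latitude": lat, "longitude": lon, **cols}
    )
    # ~2 sites per country, neighbours by latitude share a country
    n_countries = max(2, int(np.ceil(n / 2)))
    order = np.argsort(-sites["latitude"].to_numpy(), kind="stable")
    country = np.empty(n, dtype=object)
    for rank, idx in enumerate(order):
        country[idx] = f"C{rank % n_countries + 1:02d}" if n_countries < n \
            else f"C{rank + 1:02d}"
    # contiguous blocks rather than round-robin
    for rank, idx in enumerate(order):
        country[idx] = f"C{rank // 2 + 1:02d}"
    sites["country"] = country
    return sites


def donor_table(config: SimConfig, sites: pd.DataFrame) -> pd.DataFrame:
    """Assign ``trees_per_site`` donor trees to each site."""
    rows = []
    k = 0
    for _, site in sites.iterrows():
        for _ in range(config.trees_per_site):
            k += 1
            rows.append({"donor_id": f"D{k:03d}", "site_id": site["site_id"],
                         "country": site["country"]})
    return pd.DataFrame(rows)


def simulate_msap(config: SimConfig, sites: pd.DataFrame,
                  donors: pd.DataFrame | None = None) -> MsapSimulation:
    """Simulate dual-enzyme fragment profiles for one ramet per donor.

    Per locus a baseline methylation frequency is drawn uniformly from
    ``meth_freq_range``; per sample the methylation probability may shift on
    the logit scale with site January temperature (``climate_effect`` per
    degree).  Latent states U / I / H / A map to (HpaII, MspI) presence
    (1,1) / (0,1) / (1,0) / (0,0); each band is then flipped independently
    with the combination's per-band error rate.  Replicated samples re-score
    the same latent states with independent flips.
    """
    if donors is None:
        donors = donor_table(config, sites)
    if config.n_replicate_pairs > len(donors):
        raise ValueError("more replicate pairs than samples")
    rng = _rngs(config, 6)[1]
    t_jan = donors.merge(sites[["site_id", "t_jan"]], on="site_id")["t_jan"]
    t_jan = t_jan.to_numpy()
    dt = t_jan - t_jan.mean()
    n_samp = len(donors)
    sample_ids = donors["donor_id"].to_numpy()

    rep_idx = rng.choice(n_samp, size=config.n_replicate_pairs, replace=False)
    frames = []
    truth_frames = []
    for c in range(config.n_primer_combos):
        combo = f"PC{c+1}"
        e = config.error_rate_per_combo[c]
        n_loci = config.loci_per_combo
        lo, hi = config.meth_freq_range
        # U-shaped: most loci nearly never or nearly always methylated, so
        # roughly half the panel clears the technical threshold and a
        # quarter of those is monomorphically methylated, as in real panels
        base = lo + (hi - lo) * rng.beta(0.15, 0.25, n_loci)
        sizes = np.sort(rng.integers(150, 601, n_loci))
        logit = np.log(np.clip(base, 1e-3, 1 - 1e-3)
                       / (1 - np.clip(base, 1e-3, 1 - 1e-3)))
        p_meth = 1.0 / (1.0 + np.exp(-(logit[None, :]
                                       + config.climate_effect * dt[:, None])))
        u = rng.random((n_samp, n_loci))
        state = np.where(u < config.double_absence_rate, "A", "U")
        free = state == "U"
        meth = free & (rng.random((n_samp, n_loci)) < p_meth)
        hemi = meth & (rng.random((n_samp, n_loci)) < config.hemi_fraction)
        state[meth] = "I"
        state[hemi] = "H"

        locus_ids = [f"{combo}_L{j+1:03d}" for j in range(n_loci)]
        truth_frames.append(pd.DataFrame(
            state, index=pd.Index(sample_ids, name="sample_id"),
            columns=locus_ids))

        def score(states: np.ndarray, ids: np.ndarray,
                  replicate_of: np.ndarray) -> pd.DataFrame:
            recs = {}
            for ez, bit in (("HpaII", 0), ("MspI", 1)):
                bands = np.array(
                    [[_PATTERN_BANDS[s][bit] for s in row] for row in states],
                    dtype=int)
                flips = rng.random(bands.shape) < e
                recs[ez] = np.where(flips, 1 - bands, bands)
            long = []
            for ez in ("HpaII", "MspI"):
                df = pd.DataFrame(recs[ez], columns=locus_ids)
                df.insert(0, "sample_id", ids)
                df = df.melt("sample_id", var_name="locus_id",
                             value_name="present")
                df["enzyme"] = ez
                long.append(df)
            out = pd.concat(long, ignore_index=True)
            out["primer_combo_id"] = combo
            out["size"] = out["locus_id"].map(dict(zip(locus_ids, sizes)))
            out["replicate_of"] = out["sample_id"].map(
                dict(zip(ids, replicate_of)))
            return out

        frames.append(score(state, sample_ids, np.full(n_samp, np.nan,
                                                       dtype=object)))
        rep_states = state[rep_idx]
        rep_ids = np.array([f"{sample_ids[i]}_rep" for i in rep_idx])
        frames.append(score(rep_states, rep_ids, sample_ids[rep_idx]))

    profiles = pd.concat(frames, ignore_index=True)[
        ["primer_combo_id", "enzyme", "sample_id", "locus_id", "size",
         "present", "replicate_of"]]
    truth = pd.concat(truth_frames, axis=1)
    return MsapSimulation(profiles, truth)


_SSR_LOCI = [f"SSR{i+1:02d}" for i in range(11)]


def simulate_ssr(config: SimConfig, donors: pd.DataFrame | None = None,
                 sites: pd.DataFrame | None = None,
                 repeat_unit: int = 2) -> SsrSimulation:
    """Simulate SSR genotypes: one dominant clonal multilocus genotype, a few
    single-repeat somatic variants, a few unrelated-but-allele-sharing
    genotypes, and replicated samples with per-locus scoring error.

    ``ssr_error_rate`` is the probability that a replicate's genotype call at
    a locus is discordant with the first analysis (one allele off by one
    repeat unit), so the recovered study-wide error rate equals it in
    expectation.
    """
    if donors is None:
        if sites is None:
            sites = simulate_sites(config)
        donors = donor_table(config, sites)
    rng = _rngs(config, 6)[2]
    n = len(donors)
    if n < 1:
        raise ValueError("need at least one clone member")
    ids = list(donors["donor_id"])
    clone = {loc: (int(180 + 2 * i * repeat_unit + rng.integers(0, 20) * repeat_unit),)
             for i, loc in enumerate(_SSR_LOCI)}
    clone = {loc: (a[0], a[0] + int(rng.integers(0, 6)) * repeat_unit)
             for loc, a in clone.items()}

    genos: dict[str, dict[str, tuple[int, int]]] = {
        s: {loc: clone[loc] for loc in _SSR_LOCI} for s in ids}
    truth = {s: "clone" for s in ids}

    n_var = min(config.n_ssr_variants, n - 1)
    var_samples = rng.choice(ids, size=n_var, replace=False) if n_var else []
    for s in var_samples:
        loc = _SSR_LOCI[rng.integers(len(_SSR_LOCI))]
        a, b = genos[s][loc]
        genos[s][loc] = tuple(sorted((a + repeat_unit, b)))
        truth[s] = "somatic_variant"

    for k in range(config.n_ssr_nonclone):
        s = f"NC{k+1:02d}"
        ids.append(s)
        g = {loc: clone[loc] for loc in _SSR_LOCI}
        n_diff = int(rng.integers(7, 12))
        loci = rng.choice(_SSR_LOCI, size=min(n_diff, len(_SSR_LOCI)),
                          replace=False)
        for loc in loci:  # alter one allele only, keeping one shared
            a, b = g[loc]
            g[loc] = tuple(sorted((a + int(rng.integers(2, 6)) * repeat_unit, b)))
        genos[s] = g
        truth[s] = "nonclone"

    n_rep = min(config.n_replicate_pairs, n)
    rep_samples = rng.choice(donors["donor_id"], size=n_rep, replace=False)
    rows = []
    for s in ids:
        for loc in _SSR_LOCI:
            a, b = sorted(genos[s][loc])
            rows.append((s, loc, a, b, None))
    for s in rep_samples:
        rid = f"{s}_rep"
        for loc in _SSR_LOCI:
            a, b = sorted(genos[s][loc])
            if rng.random() < config.ssr_error_rate:
                a = a + repeat_unit * (1 if rng.random() < 0.5 else -1)
                a, b = sorted((a, b))
            rows.append((rid, loc, a, b, s))
    genotypes = pd.DataFrame(
        rows, columns=["sample_id", "locus_id", "allele_a", "allele_b",
                       "replicate_of"])
    truth_df = pd.DataFrame(sorted(truth.items()),
                            columns=["sample_id", "true_class"])
    return SsrSimulation(genotypes, truth_df)


def simulate_budset(config: SimConfig, sites: pd.DataFrame,
                    donors: pd.DataFrame | None = None) -> BudSetSimulation:
    """Draw longitudinal ordinal bud-set scores for every ramet and day.

    Scores follow the cumulative-logit model with donor and ramet random
    intercepts; the site effect is ``site_effect_per_degree`` times the
    centred site January temperature; donor-level C:N is drawn jointly with
    ramet weight at correlation ``cn_weight_corr``.
    """
    p = config.clmm_params
    if donors is None:
        donors = donor_table(config, sites)
    rng = _rngs(config, 6)[3]
    t_jan = donors.merge(sites[["site_id", "t_jan"]], on="site_id")
    dt = t_jan["t_jan"].to_numpy() - t_jan["t_jan"].mean()
    site_eff_by_donor = p.site_effect_per_degree * dt
    site_effects = (pd.DataFrame({"site_id": donors["site_id"],
                                  "beta": site_eff_by_donor})
                    .groupby("site_id")["beta"].first())

    n_donor = len(donors)
    u_tree = p.sigma_tree * rng.standard_normal(n_donor)
    cn_donor = 12.0 + 1.5 * rng.standard_normal(n_donor)

    alphas = np.asarray(p.thresholds)
    rows = []
    ranef_ramet = {}
    rho = config.cn_weight_corr
    for d in range(n_donor):
        donor_id = donors["donor_id"].iloc[d]
        site_id = donors["site_id"].iloc[d]
        cn = cn_donor[d]
        for k in range(config.ramets_per_donor):
            ramet_id = f"{donor_id}_R{k+1:02d}"
            u_r = p.sigma_ramet * rng.standard_normal()
            ranef_ramet[ramet_id] = u_r
            # weight correlated with donor CN across ramets
            z_cn = (cn - 12.0) / 1.5
            weight = 40.0 + 10.0 * (rho * z_cn
                                    + np.sqrt(1 - rho**2) * rng.standard_normal())
            z = (p.beta_day * np.asarray(config.obs_days, dtype=float)
                 + site_eff_by_donor[d] + p.beta_cn * cn + u_tree[d] + u_r)
            probs = cumulative_logit_probs(alphas, z)
            cats = np.array([rng.choice(len(SCORE_LEVELS), p=pr) for pr in probs])
            for day, c in zip(config.obs_days, cats):
                rows.append((ramet_id, donor_id, site_id, int(day),
                             round(cn, 4), round(weight, 2), SCORE_LEVELS[c]))
    obs = pd.DataFrame(rows, columns=["ramet_id", "donor_id", "site_id",
                                      "day", "cn", "weight", "score"])
    return BudSetSimulation(
        obs,
        pd.Series(u_tree, index=donors["donor_id"], name="ranef_tree"),
        pd.Series(ranef_ramet, name="ranef_ramet"),
        site_effects,
    )


def simulate_study(config: SimConfig) -> StudyData:
    """Generate all four input tables plus latent truth for one study."""
    sites = simulate_sites(config)
    donors = donor_table(config, sites)
    msap = simulate_msap(config, sites, donors)
    ssr = simulate_ssr(config, donors)
    budset = simulate_budset(config, sites, donors)
    return StudyData(sites, donors, msap, ssr, budset)


def write_study(study: StudyData, outdir) -> dict[str, str]:
    """Write the study tables (and truth tables) as UTF-8 CSV with NA for
    missing values; returns the path of each file."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=index, na_rep="NA")
        paths[name] = str(path)

    _write("sites", study.sites)
    _write("donors", study.donors)
    _write("fragments", study.msap.profiles)
    _write("fragments_truth", study.msap.truth, index=True)
    _write("ssr", study.ssr.genotypes)
    _write("ssr_truth", study.ssr.truth)
    _write("budset", study.budset.observations)
    _write("budset_truth_tree",
           study.budset.ranef_tree.rename_axis("donor_id").reset_index())
    _write("budset_truth_ramet",
           study.budset.ranef_ramet.rename_axis("ramet_id").reset_index())
    return paths
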