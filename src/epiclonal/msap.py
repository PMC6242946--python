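"""MS-AFLP epigenotype scoring.

Dual-enzyme (HpaII / MspI) fragment presence-absence profiles are turned
into a binary methylation matrix in four steps:

1. per-primer-combination replicate scoring error rate, pooled over both
   enzymes (Bonin-style mismatch fraction between replicated samples);
2. fragment filtering by size (default 150-600 bp) and singleton removal;
3. classification of the (HpaII, MspI) presence pattern at each
   (sample, locus): (1,1) unmethylated U, (0,1) internal-CG methylation I,
   (1,0) hemimethylation H, (0,0) ambiguous A (full methylation or loss of
   the CCGG site by mutation);
4. selection of methylation-susceptible loci — those whose discordance
   frequency (patterns I, H or A) exceeds the per-combination technical
   threshold tau = 2e(1-e), the probability that two independent
   error-prone scorings of one band mismatch — and binarization: U -> 0,
   I/H -> 1, and A either missing (to allow for somatic mutation) or 0,
   depending on the scoring mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EpilocusMatrix",
    "replicate_error_rate",
    "filter_fragments",
    "classify_patterns",
    "select_methylation_susceptible",
    "binarize",
    "score_pipeline",
    "marker_summary",
    "combine_marker_summary",
]

log = logging.getLogger(__name__)

MODES = ("missing_on_double_absence", "absence_as_unmethylated")

_PATTERN = {(1, 1): "U", (0, 1): "I", (1, 0): "H", (0, 0): "A"}
_DISCORDANT = {"I", "H", "A"}


@dataclass
class EpilocusMatrix:
    """Binary methylation states per sample x methylation-susceptible locus.

    ``states``: DataFrame of 0/1/NaN, samples in rows.  ``meta``: per-locus
    metadata (primer_combo_id, size, is_methylation_susceptible,
    is_polymorphic, has_missing).  ``mode``: how double absence was scored.
    """

    states: pd.DataFrame
    meta: pd.DataFrame
    mode: str
    notes: list[str] = field(default_factory=list)

    @property
    def polymorphic(self) -> pd.DataFrame:
        keep = self.meta.index[self.meta["is_polymorphic"]]
        return self.states[keep]

    def drop_missing_loci(self) -> "EpilocusMatrix":
        """Remove loci with any missing state (used before diversity
        analyses)."""
        keep = self.meta.index[~self.meta["has_missing"]]
        return EpilocusMatrix(self.states[keep].copy(),
                              self.meta.loc[keep].copy(), self.mode,
                              self.notes + ["loci with missing values removed"])


def _check_profiles(profiles: pd.DataFrame) -> None:
    required = {"primer_combo_id", "enzyme", "sample_id", "locus_id", "size",
                "present"}
    missing = required - set(profiles.columns)
    if missing:
        raise ValueError(f"fragment table lacks columns {sorted(missing)}")
    bad = set(profiles["enzyme"].unique()) - {"HpaII", "MspI"}
    if bad:
        raise ValueError(f"unknown enzymes {sorted(bad)}")


def replicate_error_rate(profiles: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-combination replicate mismatch rate and the all-combination mean.

    The rate pools presence/absence mismatches between each replicated sample
    and its original over both enzymes and all loci of the combination.
    Combinations without replicates get NaN with a logged warning; the mean
    is the unweighted mean of the defined per-combination rates.
    """
    _check_profiles(profiles)
    if "replicate_of" not in profiles.columns:
        raise ValueError("fragment table lacks replicate links")
    rates = {}
    for combo, sub in profiles.groupby("primer_combo_id"):
        reps = sub[sub["replicate_of"].notna()]
        if reps.empty:
            log.warning("no replicates for %s; error rate undefined", combo)
            rates[combo] = np.nan
            continue
        orig = sub[sub["replicate_of"].isna()].set_index(
            ["sample_id", "enzyme", "locus_id"])["present"]
        compared = 0
        mismatched = 0
        for row in reps.itertuples():
            key = (row.replicate_of, row.enzyme, row.locus_id)
            if key in orig.index:
                compared += 1
                mismatched += int(orig[key] != row.present)
        rates[combo] = mismatched / compared if compared else np.nan
    series = pd.Series(rates, name="error_rate").sort_index()
    return series, float(series.dropna().mean())


def filter_fragments(profiles: pd.DataFrame, min_size: float = 150.0,
                     max_size: float = 600.0,
                     remove_singletons: bool = True,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop loci outside [min_size, max_size] and singleton loci.

    A singleton is a locus present (in either enzyme) in exactly one
    non-replicate sample, or absent from exactly one.  Returns the filtered
    table and a removal log (locus_id, reason).
    """
    _check_profiles(profiles)
    removed = []
    sizes = profiles.groupby("locus_id")["size"].first()
    bad_size = sizes[(sizes < min_size) | (sizes > max_size)].index
    removed += [(loc, "size") for loc in bad_size]

    keep = profiles[~profiles["locus_id"].isin(bad_size)]
    if remove_singletons:
        base = keep
        if "replicate_of" in keep.columns:
            base = keep[keep["replicate_of"].isna()]
        present = (base.groupby(["locus_id", "sample_id"])["present"].max()
                   .groupby("locus_id").agg(["sum", "count"]))
        singleton = present[(present["sum"] == 1)
                            | (present["sum"] == present["count"] - 1)].index
        removed += [(loc, "singleton") for loc in singleton]
        keep = keep[~keep["locus_id"].isin(singleton)]
    if keep.empty:
        raise ValueError("no fragments left after filtering")
    logdf = pd.DataFrame(removed, columns=["locus_id", "reason"])
    return keep.reset_index(drop=True), logdf


def classify_patterns(profiles: pd.DataFrame,
                      include_replicates: bool = False) -> pd.DataFrame:
    """(HpaII, MspI) presence -> methylation pattern per (sample, locus).

    Returns a samples x loci DataFrame of pattern codes U/I/H/A.  Requires
    both enzyme tables aligned on (sample, locus).
    """
    _check_profiles(profiles)
    df = profiles
    if not include_replicates and "replicate_of" in df.columns:
        df = df[df["replicate_of"].isna()]
    hpa = df[df["enzyme"] == "HpaII"].pivot(index="sample_id",
                                            columns="locus_id",
                                            values="present")
    msp = df[df["enzyme"] == "MspI"].pivot(index="sample_id",
                                           columns="locus_id",
                                           values="present")
    if not (hpa.index.equals(msp.index) and hpa.columns.equals(msp.columns)):
        raise ValueError("HpaII and MspI tables not aligned on (sample, locus)")
    if hpa.isna().any().any() or msp.isna().any().any():
        raise ValueError("incomplete profiles; every (sample, locus) needs "
                         "both enzyme scores")
    codes = np.full(hpa.shape, None, dtype=object)
    for (h, m), code in _PATTERN.items():
        codes[(hpa.to_numpy() == h) & (msp.to_numpy() == m)] = code
    if (codes == None).any():  # noqa: E711 - elementwise
        raise ValueError("presence values must be 0/1")
    return pd.DataFrame(codes, index=hpa.index, columns=hpa.columns)


def methylation_threshold(e: float) -> float:
    """tau = 2e(1-e): probability that two independent Bernoulli(e)-flipped
    copies of one band disagree."""
    if not 0.0 <= e < 0.5:
        raise ValueError("error rate must be in [0, 0.5)")
    return 2.0 * e * (1.0 - e)


def select_methylation_susceptible(patterns: pd.DataFrame,
                                   error_rates: pd.Series | dict,
                                   combo_of_locus: pd.Series | dict,
                                   test: str = "exceedance",
                                   alpha: float = 0.05,
                                   threshold_override: float | None = None,
                                   ) -> pd.Series:
    """Flag loci whose discordance frequency exceeds the technical threshold.

    Per combination, tau = 2e(1-e) from the replicate error rate e (or a
    single ``threshold_override``); a locus is methylation-susceptible iff
    the fraction of samples with pattern I, H or A strictly exceeds tau.
    ``test='binomial'`` instead requires a one-sided binomial test of the
    discordance count against tau to reject at ``alpha``.
    """
    if test not in ("exceedance", "binomial"):
        raise ValueError(f"unknown susceptibility test {test!r}")
    combo_of_locus = pd.Series(combo_of_locus)
    error_rates = pd.Series(error_rates)
    flags = {}
    for locus in patterns.columns:
        combo = combo_of_locus[locus]
        if threshold_override is not None:
            tau = threshold_override
        else:
            e = error_rates[combo]
            if np.isnan(e):
                raise ValueError(f"no error rate for combination {combo!r}")
            tau = methylation_threshold(e)
        col = patterns[locus].dropna()
        k = int(col.isin(_DISCORDANT).sum())
        n = len(col)
        if test == "exceedance":
            flags[locus] = (k / n) > tau
        else:
            from scipy.stats import binomtest
            if tau == 0.0:
                flags[locus] = k > 0
            else:
                flags[locus] = binomtest(k, n, tau,
                                         alternative="greater").pvalue < alpha
    return pd.Series(flags, name="is_methylation_susceptible")


def binarize(patterns: pd.DataFrame, flags: pd.Series, mode: str,
             sizes: pd.Series | None = None,
             combo_of_locus: pd.Series | None = None) -> EpilocusMatrix:
    """Binary methylation states restricted to methylation-susceptible loci.

    U -> 0, I -> 1, H -> 1; A -> missing under ``missing_on_double_absence``
    or 0 under ``absence_as_unmethylated``.  A locus is polymorphic iff both
    states occur among its non-missing entries.
    """
    if mode not in MODES:
        raise ValueError(f"unknown scoring mode {mode!r}; options: {MODES}")
    keep = [loc for loc in patterns.columns if flags.get(loc, False)]
    sub = patterns[keep]
    mapping = {"U": 0.0, "I": 1.0, "H": 1.0,
               "A": np.nan if mode == "missing_on_double_absence" else 0.0}
    states = sub.apply(lambda col: col.map(mapping)).astype(float)
    meta = pd.DataFrame(index=pd.Index(keep, name="locus_id"))
    meta["primer_combo_id"] = (pd.Series(combo_of_locus)[keep].values
                               if combo_of_locus is not None else None)
    meta["size"] = pd.Series(sizes)[keep].values if sizes is not None else np.nan
    meta["is_methylation_susceptible"] = True
    nn = states.notna()
    meta["is_polymorphic"] = [
        states.loc[nn[c], c].nunique() > 1 for c in states.columns]
    meta["has_missing"] = [bool((~nn[c]).any()) for c in states.columns]
    return EpilocusMatrix(states, meta, mode)


def score_pipeline(profiles: pd.DataFrame, mode: str,
                   min_size: float = 150.0, max_size: float = 600.0,
                   test: str = "exceedance",
                   threshold_override: float | None = None):
    """Full scoring chain: error rates -> filter -> patterns -> flags ->
    binary matrix.  Returns (EpilocusMatrix, per-combination error rates,
    mean error rate, removal log, pattern matrix)."""
    rates, mean_rate = replicate_error_rate(profiles)
    filtered, removal_log = filter_fragments(profiles, min_size, max_size)
    patterns = classify_patterns(filtered)
    combo_of_locus = filtered.groupby("locus_id")["primer_combo_id"].first()
    sizes = filtered.groupby("locus_id")["size"].first()
    flags = select_methylation_susceptible(
        patterns, rates, combo_of_locus, test=test,
        threshold_override=threshold_override)
    epi = binarize(patterns, flags, mode, sizes=sizes,
                   combo_of_locus=combo_of_locus)
    return epi, rates, mean_rate, removal_log, patterns


def marker_summary(patterns: pd.DataFrame, flags: pd.Series,
                   epi: EpilocusMatrix, rates: pd.Series,
                   combo_of_locus: pd.Series) -> pd.DataFrame:
    """Per-combination marker counts in the style of the study's marker
    table: total markers, scoring error rate, methylation-susceptible N and
    polymorphic N (%)."""
    combo_of_locus = pd.Series(combo_of_locus)
    rows = []
    for combo in sorted(rates.index):
        loci = combo_of_locus[combo_of_locus == combo].index
        n_total = len(loci)
        n_susc = int(flags.reindex(loci).astype("boolean")
                     .fillna(False).sum())
        poly = epi.meta.loc[epi.meta.index.isin(loci), "is_polymorphic"]
        n_poly = int(poly.sum())
        rows.append({"primer_combo_id": combo, "n_markers": n_total,
                     "error_rate": rates[combo],
                     "n_methylation_susceptible": n_susc,
                     "n_polymorphic": n_poly,
                     "pct_polymorphic": 100.0 * n_poly / n_susc
                     if n_susc else np.nan})
    return pd.DataFrame(rows)


def combine_marker_summary(summary: pd.DataFrame) -> pd.Series:
    """The 'all combined' row: column sums, the unweighted mean of the
    per-combination error rates, and the combined polymorphic percentage."""
    n_markers = int(summary["n_markers"].sum())
    n_susc = int(summary["n_methylation_susceptible"].sum())
    n_poly = int(summary["n_polymorphic"].sum())
    return pd.Series({
        "primer_combo_id": "all",
        "n_markers": n_markers,
        "error_rate": float(summary["error_rate"].mean()),
        "n_methylation_susceptible": n_susc,
        "n_polymorphic": n_poly,
        "pct_polymorphic": 100.0 * n_poly / n_susc if n_susc else np.nan,
    })
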