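"""Clone identification from multilocus SSR genotypes.

Samples sharing identical allele sets at every locus form a multilocus
genotype (MLG); the modal MLG is taken as the reference clone.  Samples whose
genotype differs from the reference by at most one allele — and only by a
single repeat unit — are classified as clone members carrying a possible
somatic mutation.  The genotyping error rate over replicated samples is

    100 * n_discordant_scores / (n_loci * n_replicated_individuals)

where a discordant score is a (sample, locus) whose allele multiset differs
between the two independent analyses.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["identify_mlgs", "classify_clonemates", "genotyping_error_rate"]

log = logging.getLogger(__name__)


def _genotype_map(genotypes: pd.DataFrame) -> tuple[dict, list[str]]:
    """sample -> {locus: sorted allele pair}; validates the locus set."""
    df = genotypes.copy()
    if df.duplicated(["sample_id", "locus_id"]).any():
        raise ValueError("duplicate (sample, locus) rows")
    loci = sorted(df["locus_id"].unique())
    gmap: dict[str, dict[str, tuple]] = {}
    dropped = []
    for sample, sub in df.groupby("sample_id", sort=False):
        if sorted(sub["locus_id"]) != loci:
            raise ValueError(f"sample {sample!r} has a different locus set")
        if sub[["allele_a", "allele_b"]].isna().any().any():
            dropped.append(sample)
            continue
        gmap[sample] = {
            row.locus_id: tuple(sorted((row.allele_a, row.allele_b)))
            for row in sub.itertuples()}
    if dropped:
        log.warning("excluded %d samples with missing alleles: %s",
                    len(dropped), dropped)
    return gmap, loci


def _mismatch(g1: dict, g2: dict, loci: list[str]) -> int:
    """Number of differing allele slots, alleles compared as per-locus
    multisets so heterozygote phase is irrelevant."""
    n = 0
    for loc in loci:
        a = list(g1[loc])
        b = list(g2[loc])
        for allele in g1[loc]:
            if allele in b:
                b.remove(allele)
            else:
                n += 1
    return n


def identify_mlgs(genotypes: pd.DataFrame,
                  include_replicates: bool = False) -> pd.DataFrame:
    """Group samples into MLGs and count allele mismatches to the modal MLG.

    Replicated samples (non-null ``replicate_of``) are excluded by default so
    they do not inflate the reference MLG count.  Returns one row per sample:
    sample_id, mlg_id, mismatch_to_reference, is_clone (initialised False).
    """
    df = genotypes
    if not include_replicates and "replicate_of" in df.columns:
        df = df[df["replicate_of"].isna()]
    if df.empty:
        raise ValueError("no samples")
    gmap, loci = _genotype_map(df)

    key_of = {s: tuple(sorted((loc, g[loc]) for loc in loci))
              for s, g in gmap.items()}
    mlg_ids: dict[tuple, str] = {}
    for s in gmap:
        key = key_of[s]
        if key not in mlg_ids:
            mlg_ids[key] = f"G{len(mlg_ids) + 1:02d}"
    counts = pd.Series([mlg_ids[key_of[s]] for s in gmap]).value_counts()
    top = counts[counts == counts.max()].index.sort_values()
    if len(top) > 1:
        log.warning("modal MLG tie among %s; using %s", list(top), top[0])
    ref_id = top[0]
    ref_geno = next(g for s, g in gmap.items() if mlg_ids[key_of[s]] == ref_id)

    rows = [(s, mlg_ids[key_of[s]], _mismatch(gmap[s], ref_geno, loci), False)
            for s in gmap]
    return pd.DataFrame(rows, columns=["sample_id", "mlg_id",
                                       "mismatch_to_reference", "is_clone"])


def classify_clonemates(assignment: pd.DataFrame, genotypes: pd.DataFrame,
                        max_mismatch: int = 1,
                        repeat_units: dict[str, int] | None = None,
                        default_repeat_unit: int = 2) -> pd.DataFrame:
    """Flag clone members: mismatch_to_reference <= max_mismatch and any
    differing allele off by exactly one repeat unit.

    ``repeat_units`` maps locus_id to its repeat length in bp (default 2,
    dinucleotide); loci absent from the map use the default with a warning.
    """
    gmap, loci = _genotype_map(
        genotypes[genotypes["replicate_of"].isna()]
        if "replicate_of" in genotypes.columns else genotypes)
    ref_samples = assignment.loc[assignment["mismatch_to_reference"] == 0,
                                 "sample_id"]
    if ref_samples.empty:
        raise ValueError("no reference-MLG sample in assignment")
    ref_geno = gmap[ref_samples.iloc[0]]
    repeat_units = repeat_units or {}

    out = assignment.copy()
    flags = []
    for row in out.itertuples():
        if row.mismatch_to_reference == 0:
            flags.append(True)
            continue
        if row.mismatch_to_reference > max_mismatch:
            flags.append(False)
            continue
        ok = True
        g = gmap[row.sample_id]
        for loc in loci:
            # alleles left unmatched after multiset comparison
            left_a = list(ref_geno[loc])
            left_b = list(g[loc])
            for allele in ref_geno[loc]:
                if allele in left_b:
                    left_b.remove(allele)
                    left_a.remove(allele)
            if not left_a:
                continue
            unit = repeat_units.get(loc)
            if unit is None:
                unit = default_repeat_unit
                if repeat_units:
                    log.warning("no repeat unit for %s; assuming %d bp",
                                loc, unit)
            diffs = [abs(x - y) for x, y in zip(sorted(left_a), sorted(left_b))]
            if any(d != unit for d in diffs):
                ok = False
        flags.append(ok)
    out["is_clone"] = flags
    return out


def genotyping_error_rate(genotypes: pd.DataFrame) -> float:
    """Percentage of discordant (sample, locus) scores between replicate
    pairs, over loci x replicated individuals."""
    if "replicate_of" not in genotypes.columns or \
            genotypes["replicate_of"].isna().all():
        raise ValueError("no replicate pairs in the genotype table")
    reps = genotypes[genotypes["replicate_of"].notna()]
    gmap_all, loci = _genotype_map(genotypes.assign(replicate_of=np.nan))
    discordant = 0
    n_individuals = 0
    for rep_id, sub in reps.groupby("sample_id"):
        orig = sub["replicate_of"].iloc[0]
        if orig not in gmap_all or rep_id not in gmap_all:
            continue
        n_individuals += 1
        for loc in loci:
            if gmap_all[rep_id][loc] != gmap_all[orig][loc]:
                discordant += 1
    if n_individuals == 0:
        raise ValueError("replicate pairs reference unknown samples")
    return 100.0 * discordant / (len(loci) * n_individuals)
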