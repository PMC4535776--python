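"""Microsatellite diversity statistics per population.

Works on a long genotype table (population, individual, locus, allele1,
allele2) with NaN for missing calls — the shape produced by the GenePop
reader and the Hardy–Weinberg simulator. Statistics are the standard
diversity columns: observed heterozygosity, expected heterozygosity
(plain gene diversity 1 - sum p^2, or Nei's small-sample unbiased
estimator 2n/(2n-1) * (1 - sum p^2)), and mean number of alleles per
locus. Allele-frequency denominators use scored alleles only, so missing
data is handled per locus.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "observed_heterozygosity",
    "expected_heterozygosity",
    "mean_alleles_per_locus",
    "summary_table",
]

GENOTYPE_COLUMNS = ["population", "individual", "locus", "allele1", "allele2"]


def _population_slice(table: pd.DataFrame, population: str) -> pd.DataFrame:
    sub = table[table["population"] == population]
    if sub.empty:
        raise KeyError(f"population {population!r} not in table")
    return sub


def _scored(sub: pd.DataFrame) -> pd.DataFrame:
    return sub.dropna(subset=["allele1", "allele2"])


def observed_heterozygosity(table: pd.DataFrame, population: str):
    """Per-locus fraction of scored individuals carrying two distinct
    alleles, and the mean over loci. Loci with no scored individuals are
    excluded with a warning."""
    sub = _scored(_population_slice(table, population))
    all_loci = _population_slice(table, population)["locus"].unique()
    values = {}
    for locus, grp in sub.groupby("locus"):
        het = (grp["allele1"] != grp["allele2"]).mean()
        values[locus] = float(het)
    dropped = set(all_loci) - set(values)
    if dropped:
        warnings.warn(
            f"loci with no scored individuals excluded: {sorted(dropped)}"
        )
    per_locus = pd.Series(values, name="H_obs").sort_index()
    return per_locus, float(per_locus.mean())


def expected_heterozygosity(
    table: pd.DataFrame, population: str, estimator: str = "nei_unbiased"
):
    """Per-locus expected heterozygosity and its mean over loci.

    ``estimator="plain"`` is gene diversity 1 - sum p_i^2;
    ``"nei_unbiased"`` multiplies by 2n/(2n - 1) (n = scored
    individuals), the small-sample correction used by the classic
    population-genetics packages. Monomorphic loci give 0.
    """
    if estimator not in ("nei_unbiased", "plain"):
        raise ValueError(f"unknown estimator {estimator!r}")
    sub = _scored(_population_slice(table, population))
    values = {}
    for locus, grp in sub.groupby("locus"):
        alleles = np.concatenate(
            [grp["allele1"].to_numpy(), grp["allele2"].to_numpy()]
        )
        n2 = len(alleles)  # 2n scored alleles
        _, counts = np.unique(alleles, return_counts=True)
        p = counts / n2
        h = 1.0 - float((p**2).sum())
        if estimator == "nei_unbiased" and n2 > 1:
            h *= n2 / (n2 - 1)
        values[locus] = h
    per_locus = pd.Series(values, name="H_exp").sort_index()
    return per_locus, float(per_locus.mean())


def mean_alleles_per_locus(table: pd.DataFrame, population: str) -> float:
    """Arithmetic mean over loci of the number of distinct observed alleles."""
    sub = _scored(_population_slice(table, population))
    counts = [
        len(
            set(grp["allele1"].astype(int)) | set(grp["allele2"].astype(int))
        )
        for _locus, grp in sub.groupby("locus")
    ]
    if not counts:
        raise ValueError(f"no scored loci for population {population!r}")
    return float(np.mean(counts))


def summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Diversity summary per population: N, H_obs, H_exp (both
    estimators) and mean alleles per locus."""
    rows = []
    for population in pd.unique(table["population"]):
        sub = _population_slice(table, population)
        n = sub["individual"].nunique()
        _, hobs = observed_heterozygosity(table, population)
        _, hexp_u = expected_heterozygosity(table, population, "nei_unbiased")
        _, hexp_p = expected_heterozygosity(table, population, "plain")
        aav = mean_alleles_per_locus(table, population)
        rows.append((population, n, hobs, hexp_u, hexp_p, aav))
    return pd.DataFrame(
        rows,
        columns=[
            "population", "N", "H_obs", "H_exp_unbiased", "H_exp_plain", "A_av",
        ],
    )
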