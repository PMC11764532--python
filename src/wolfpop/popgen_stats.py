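"""Per-population diversity statistics and pairwise F_ST.

Observed heterozygosity is the per-SNP fraction of heterozygous calls;
expected heterozygosity is 2p(1-p) from the within-population frequency of
the counted allele, with no small-sample correction (an optional 2n/(2n-1)
correction is available). Reported H values are means over all panel SNPs
with at least one non-missing call in the population, including SNPs that
are monomorphic within it.

F_ST uses the Weir & Cockerham (1984) two-population estimator as a ratio
of averages (sum of per-SNP among-population variance components over the
sum of total components); a Hudson-type estimator is available for
sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, Dataset, DatasetError


@dataclass
class PopulationSummary:
    population: str
    h_expected: float
    h_observed: float
    n_polymorphic: int
    missing_pct: float


@dataclass
class FstMatrix:
    """Symmetric pairwise F_ST matrix; negative estimates are clamped to 0
    in ``values`` and kept unclamped in ``raw``."""

    populations: list[str]
    values: np.ndarray
    raw: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations, columns=self.populations)


def _pop_genotypes(ds: Dataset, population: str) -> np.ndarray:
    return ds.genotypes[ds.sample_indices(population)]


def allele_frequencies(ds: Dataset, population: str) -> np.ndarray:
    """Per-SNP frequency of allele_b among non-missing calls; NaN where the
    SNP has no calls in the population."""
    g = _pop_genotypes(ds, population)
    obs = g != MISSING
    n_calls = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_calls > 0, g.clip(0).sum(axis=0) / n_calls, np.nan)
    return freq


def heterozygosity(ds: Dataset, population: str, correct_small_sample: bool = False) -> tuple[float, float]:
    """Mean observed and expected heterozygosity over panel SNPs.

    Returns ``(h_observed, h_expected)``.
    """
    g = _pop_genotypes(ds, population)
    if g.shape[0] < 2:
        raise DatasetError(f"population {population!r} needs >=2 samples for heterozygosity")
    obs = g != MISSING
    n_obs = obs.sum(axis=0)
    called = n_obs > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        h_obs = np.where(called, (g == 1).sum(axis=0) / n_obs, np.nan)
    p = allele_frequencies(ds, population)
    h_exp = 2.0 * p * (1.0 - p)
    if correct_small_sample:
        with np.errstate(invalid="ignore", divide="ignore"):
            h_exp = np.where(n_obs > 0, h_exp * (2.0 * n_obs) / (2.0 * n_obs - 1.0), np.nan)
    return float(np.nanmean(np.where(called, h_obs, np.nan))), float(
        np.nanmean(np.where(called, h_exp, np.nan))
    )


def count_polymorphic(ds: Dataset, population: str) -> int:
    """SNPs segregating within the population (0 < p < 1 among calls)."""
    p = allele_frequencies(ds, population)
    with np.errstate(invalid="ignore"):
        return int(np.sum((p > 0.0) & (p < 1.0)))


def missing_pct(ds: Dataset, population: str) -> float:
    g = _pop_genotypes(ds, population)
    return float((g == MISSING).mean() * 100.0)


def _wc_components(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Weir-Cockerham (1984) variance components (a, a+b+c) for two
    populations, from dosage matrices. SNPs monomorphic across both
    populations, or with a within-population sample size below 1 (or mean
    sample size of 1), contribute NaN."""
    r = 2.0
    res_a = []
    res_t = []
    obs1, obs2 = g1 != MISSING, g2 != MISSING
    n1 = obs1.sum(axis=0).astype(float)
    n2 = obs2.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, g1.clip(0).sum(0) / (2 * n1), np.nan)
        p2 = np.where(n2 > 0, g2.clip(0).sum(0) / (2 * n2), np.nan)
        h1 = np.where(n1 > 0, (g1 == 1).sum(0) / n1, np.nan)
        h2 = np.where(n2 > 0, (g2 == 1).sum(0) / n2, np.nan)

        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    invalid = (
        ~np.isfinite(p_bar)
        | (n1 < 1)
        | (n2 < 1)
        | (n_bar <= 1)
        | (p_bar <= 0.0)
        | (p_bar >= 1.0)
    )
    a = np.where(invalid, np.nan, a)
    total = np.where(invalid, np.nan, a + b + c)
    return a, total


def pairwise_fst(ds: Dataset, pop_a: str, pop_b: str, estimator: str = "wc") -> float:
    """Two-population F_ST as a ratio of averages across SNPs.

    ``estimator``: ``"wc"`` (Weir-Cockerham 1984, default) or ``"hudson"``
    (Bhatia et al. formulation). The raw estimate may be slightly negative
    for undifferentiated populations.
    """
    ia, ib = ds.sample_indices(pop_a), ds.sample_indices(pop_b)
    if pop_a == pop_b or np.intersect1d(ia, ib).size:
        raise DatasetError("populations overlap")
    g1, g2 = ds.genotypes[ia], ds.genotypes[ib]
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise DatasetError("both populations need >=2 samples for F_ST")
    if estimator == "wc":
        a, total = _wc_components(g1, g2)
        return float(np.nansum(a) / np.nansum(total))
    if estimator == "hudson":
        return _hudson_fst(g1, g2)
    raise ValueError(f"unknown estimator {estimator!r}")


def _hudson_fst(g1: np.ndarray, g2: np.ndarray) -> float:
    obs1, obs2 = g1 != MISSING, g2 != MISSING
    n1 = 2.0 * obs1.sum(axis=0)
    n2 = 2.0 * obs2.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = g1.clip(0).sum(0) / n1
        p2 = g2.clip(0).sum(0) / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    mono = ~np.isfinite(p1 + p2) | (((p1 + p2) == 0) | ((p1 + p2) == 2))
    num = np.where(mono | (n1 < 4) | (n2 < 4), np.nan, num)
    den = np.where(mono | (n1 < 4) | (n2 < 4), np.nan, den)
    return float(np.nansum(num) / np.nansum(den))


def fst_matrix(ds: Dataset, estimator: str = "wc") -> FstMatrix:
    pops = ds.populations()
    k = len(pops)
    raw = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            raw[i, j] = raw[j, i] = pairwise_fst(ds, pops[i], pops[j], estimator=estimator)
    return FstMatrix(populations=pops, values=np.clip(raw, 0.0, 1.0), raw=raw)


def stats_report(ds: Dataset, estimator: str = "wc") -> tuple[list[PopulationSummary], FstMatrix]:
    """Per-population summaries plus the full pairwise F_ST matrix."""
    pops = ds.populations()
    if len(pops) < 2:
        raise DatasetError("stats report needs >=2 populations")
    summaries = []
    for pop in pops:
        h_obs, h_exp = heterozygosity(ds, pop)
        summaries.append(
            PopulationSummary(
                population=pop,
                h_expected=h_exp,
                h_observed=h_obs,
                n_polymorphic=count_polymorphic(ds, pop),
                missing_pct=missing_pct(ds, pop),
            )
        )
    return summaries, fst_matrix(ds, estimator=estimator)


def summaries_to_frame(summaries: list[PopulationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "population": [s.population for s in summaries],
            "HE": [s.h_expected for s in summaries],
            "HO": [s.h_observed for s in summaries],
            "polymorphic_sites": [s.n_polymorphic for s in summaries],
            "missing_pct": [s.missing_pct for s in summaries],
        }
    )
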