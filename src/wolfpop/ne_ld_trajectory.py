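"""Historical effective population size from LD decay (Sved equation).

The expected squared correlation between genotypes at two loci a genetic
distance ``c`` Morgans apart, in a population of effective size N_E sampled
as n individuals, is

    E(r^2) = 1 / (1 + 4 N_E c) + 1/n

so each genetic-distance bin can be inverted to an N_E estimate, and LD at
distance c probes the population roughly t = 1/(2c) generations ago.
Distances come from physical positions at a fixed map rate (default
100 Mb = 1 Morgan). r^2 is the squared Pearson correlation of unphased
genotype dosages (composite LD), computed over individuals non-missing at
both SNPs.

Generation bins for t = 1..max_generations are centered at c = 1/(2t) with
edges at the harmonic midpoints 1/(2(t +- 0.5)); the t = 1 upper edge is
capped at 0.5 Morgans, so the bins exactly partition (0, 0.5].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, Dataset, DatasetError


@dataclass
class NeParams:
    max_generations: int = 30
    generation_interval_years: float = 3.0
    morgans_per_bp: float = 1e-8  # 100 Mb = 1 Morgan
    maf_min: float = 0.05
    sample_correction_n: int | None = None  # default: population sample count
    sampling_year: int = 2021
    chromosome_correction: bool = False  # use 1/(2n) instead of 1/n

    def __post_init__(self) -> None:
        if self.morgans_per_bp <= 0:
            raise ValueError("morgans_per_bp must be > 0")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


@dataclass
class SnpPairBin:
    t_generations: int
    c_low: float
    c_center: float
    c_high: float
    n_pairs: int
    mean_r2: float


@dataclass
class NePoint:
    t_generations: int
    calendar_year: float
    ne: float
    n_pairs: int
    mean_r2: float
    valid: bool


def expected_r2(ne: float, c: float, n: float = math.inf) -> float:
    """Sved expectation 1/(1 + 4*ne*c) + 1/n (n may be inf)."""
    if ne < 0 or c < 0 or n < 1:
        raise ValueError("ne and c must be >= 0 and n >= 1")
    return 1.0 / (1.0 + 4.0 * ne * c) + (0.0 if math.isinf(n) else 1.0 / n)


def invert_to_ne(mean_r2: float, c: float, n: float = math.inf) -> tuple[float, bool]:
    """Solve the Sved equation for N_E.

    Returns ``(ne, valid)``; invalid (not silently clamped) when the
    sample-corrected r^2 is at or below the sampling floor 1/n, or the
    resulting N_E is not positive.
    """
    if c <= 0:
        raise ValueError("c must be > 0")
    adj = mean_r2 - (0.0 if math.isinf(n) else 1.0 / n)
    if adj <= 0:
        return float("nan"), False
    ne = (1.0 / adj - 1.0) / (4.0 * c)
    if ne <= 0 or not math.isfinite(ne):
        return float("nan"), False
    return ne, True


def expected_new_variation(mu: float, n_generations: float, ne: float) -> float:
    """Expected fraction of new variants accumulated: mu * generations * N_E."""
    if min(mu, n_generations, ne) < 0:
        raise ValueError("inputs must be >= 0")
    return mu * n_generations * ne


def build_generation_bins(params: NeParams | None = None) -> list[tuple[int, float, float, float]]:
    """(t, c_low, c_center, c_high) for t = 1..max_generations, under the
    t = 1/(2c) correspondence; bins are disjoint and partition (0, 0.5]."""
    params = params or NeParams()
    bins = []
    for t in range(1, params.max_generations + 1):
        c_center = 1.0 / (2.0 * t)
        c_low = 1.0 / (2.0 * t + 1.0)
        c_high = 0.5 if t == 1 else 1.0 / (2.0 * t - 1.0)
        bins.append((t, c_low, c_center, c_high))
    return bins


def _pairwise_r2_matrix(g: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between all SNP pairs (columns of ``g``),
    using pairwise-complete observations; NaN where undefined.

    Exact missing-aware computation via matrix products of the value and
    observation-mask matrices.
    """
    obs = (g != MISSING).astype(np.float64)
    val = np.where(g == MISSING, 0.0, g).astype(np.float64)
    val2 = val * val
    n = obs.T @ obs
    sx = val.T @ obs
    sxy = val.T @ val
    sxx = val2.T @ obs
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx**2
        vary = varx.T
        r2 = cov**2 / (varx * vary)
    r2[(n < 2) | ~np.isfinite(r2)] = np.nan
    return r2


def _population_matrix(ds: Dataset, population: str, params: NeParams) -> np.ndarray:
    g = ds.genotypes[ds.sample_indices(population)]
    if g.shape[0] < 2:
        raise DatasetError(f"population {population!r} needs >=2 samples for LD")
    return g


def _bin_accumulate(
    g: np.ndarray, snps: pd.DataFrame, edges: np.ndarray, params: NeParams
) -> tuple[np.ndarray, np.ndarray]:
    """Sum of r^2 and pair counts per distance bin (edges ascending,
    [e_k, e_{k+1}) with the top edge closed), over intra-chromosomal pairs
    passing the within-population MAF filter."""
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    obs = g != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(obs.sum(0) > 0, g.clip(0).sum(0) / (2.0 * obs.sum(0)), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    pass_maf = np.isfinite(maf) & (maf >= params.maf_min)

    chroms = snps["chrom"].to_numpy()
    pos = snps["pos_bp"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        sel = (chroms == chrom) & pass_maf
        if sel.sum() < 2:
            continue
        p = pos[sel].astype(np.float64)
        r2 = _pairwise_r2_matrix(g[:, sel])
        iu, ju = np.triu_indices(len(p), k=1)
        d = np.abs(p[ju] - p[iu]) * params.morgans_per_bp
        v = r2[iu, ju]
        keep = np.isfinite(v)
        d, v = d[keep], v[keep]
        k = np.digitize(d, edges) - 1
        k[d == edges[-1]] = n_bins - 1  # close the top edge
        inside = (k >= 0) & (k < n_bins)
        np.add.at(sums, k[inside], v[inside])
        np.add.at(counts, k[inside], 1)
    return sums, counts


def pairwise_r2(
    ds: Dataset, population: str, c_low: float, c_high: float, params: NeParams | None = None
) -> SnpPairBin:
    """Mean pairwise r^2 over SNP pairs at genetic distance [c_low, c_high)."""
    params = params or NeParams()
    if c_high <= c_low:
        raise ValueError("c_high must exceed c_low")
    g = _population_matrix(ds, population, params)
    edges = np.array([c_low, c_high])
    sums, counts = _bin_accumulate(g, ds.snps, edges, params)
    n_pairs = int(counts[0])
    mean_r2 = float(sums[0] / counts[0]) if n_pairs else float("nan")
    c_center = 0.5 * (c_low + c_high)
    return SnpPairBin(
        t_generations=max(1, round(1.0 / (2.0 * c_center))),
        c_low=c_low, c_center=c_center, c_high=c_high,
        n_pairs=n_pairs, mean_r2=mean_r2,
    )


def ne_trajectory(ds: Dataset, population: str, params: NeParams | None = None) -> list[NePoint]:
    """N_E per generation bin for one population, ordered t = 1..max.

    Bins whose mean r^2 falls at or below the 1/n sampling floor are
    reported with ``valid=False`` rather than dropped.
    """
    params = params or NeParams()
    g = _population_matrix(ds, population, params)
    n_ind = g.shape[0]
    n_corr = params.sample_correction_n or n_ind
    if params.chromosome_correction:
        n_corr = 2 * n_corr

    bins = build_generation_bins(params)
    # ascending edges shared by all bins: c_low(T), ..., c_low(1), 0.5
    edges = np.array([b[1] for b in reversed(bins)] + [bins[0][3]])
    sums, counts = _bin_accumulate(g, ds.snps, edges, params)

    points = []
    for i, (t, c_low, c_center, c_high) in enumerate(bins):
        k = len(bins) - 1 - i  # ascending-edge index for this t
        n_pairs = int(counts[k])
        if n_pairs == 0:
            points.append(NePoint(t, params.sampling_year - t * params.generation_interval_years,
                                  float("nan"), 0, float("nan"), False))
            continue
        mean_r2 = float(sums[k] / n_pairs)
        ne, valid = invert_to_ne(mean_r2, c_center, n_corr)
        points.append(
            NePoint(
                t_generations=t,
                calendar_year=params.sampling_year - t * params.generation_interval_years,
                ne=ne, n_pairs=n_pairs, mean_r2=mean_r2, valid=valid,
            )
        )
    return points


def trajectory_to_frame(points: list[NePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_generations": [p.t_generations for p in points],
            "calendar_year": [p.calendar_year for p in points],
            "c_center": [1.0 / (2.0 * p.t_generations) for p in points],
            "n_pairs": [p.n_pairs for p in points],
            "mean_r2": [p.mean_r2 for p in points],
            "ne": [p.ne for p in points],
            "valid": [p.valid for p in points],
        }
    )
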