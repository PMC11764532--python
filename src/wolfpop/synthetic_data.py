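"""Forward-in-time diploid Wright-Fisher simulator for wolf/dog/hybrid data.

The generator emulates the statistical structure of multi-population
SNP-array panels: an ancestral canid pool with an array-like common-variant
frequency spectrum (truncated Beta), two parental pools (dog breed, wolf)
drifting apart under Wright-Fisher reproduction with recombination, and
hybrid breeds founded by a dog x wolf cross and propagated with a popular
sire mating bias and scheduled wild-wolf infusions. The full pedigree is
recorded, so pedigree inbreeding and realized effective sizes are available
as ground truth for parameter-recovery tests.

Modeling choices: no new mutation during breed history (decades are
mutation-negligible at array scale); one crossover count per chromosome per
meiosis drawn Poisson(map length in Morgans), crossover positions uniform,
no interference; sexes random 1:1 except founders (dog founders male, wolf
founders female, so first-generation animals are true hybrids).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .genotype_io import (
    MISSING,
    Dataset,
    write_map_table,
    write_plink_text,
    write_population_table,
)

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


class SimulationCollapseError(RuntimeError):
    """The breed lost all sires or all dams and cannot continue."""


class ConfigError(ValueError):
    """Invalid simulation configuration; message lists offending fields."""


@dataclass
class SimConfig:
    """Simulator parameters.

    ``popular_sire_weight`` is the symmetric Dirichlet concentration used to
    draw per-sire mating probabilities each generation: values well below 1
    concentrate matings on a few sires (strong popular-sire effect), large
    values approach uniform use of sires.
    """

    n_chromosomes: int = 10
    chromosome_length_bp: int = 100_000_000
    n_snps_per_chromosome: int = 2_000
    recombination_cm_per_mb: float = 1.0
    parental_split_generations: int = 60
    parental_sizes: tuple[int, int] = (100, 100)  # (dog pool, wolf pool)
    founder_cross: tuple[int, int] = (4, 4)  # (n dog founders, n wolf founders)
    infusion_schedule: tuple[tuple[int, int], ...] = ()
    breed_size_per_generation: tuple[int, ...] = (50,) * 21
    popular_sire_weight: float = 1.0
    missing_rate: float = 0.0
    ascertainment_maf: float = 0.05
    beta_shape: float = 0.8
    n_final_samples: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        bad = []
        if self.n_chromosomes < 1:
            bad.append("n_chromosomes")
        if self.n_snps_per_chromosome < 1:
            bad.append("n_snps_per_chromosome")
        if self.chromosome_length_bp < self.n_snps_per_chromosome:
            bad.append("chromosome_length_bp")
        if not (0.0 <= self.missing_rate <= 1.0):
            bad.append("missing_rate")
        if not (0.0 < self.ascertainment_maf < 0.5):
            bad.append("ascertainment_maf")
        if min(self.parental_sizes) < 1:
            bad.append("parental_sizes")
        if min(self.founder_cross) < 1:
            bad.append("founder_cross")
        if len(self.breed_size_per_generation) < 1 or min(self.breed_size_per_generation) < 1:
            bad.append("breed_size_per_generation")
        if self.popular_sire_weight <= 0:
            bad.append("popular_sire_weight")
        n_gens = len(self.breed_size_per_generation)
        if any(not (1 <= g <= n_gens) for g, _ in self.infusion_schedule):
            bad.append("infusion_schedule")
        if bad:
            raise ConfigError(f"invalid SimConfig fields: {', '.join(bad)}")

    @property
    def morgans_per_chromosome(self) -> float:
        return self.chromosome_length_bp * self.recombination_cm_per_mb * 1e-8


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    pedigree: pd.DataFrame | None = None  # iid, sire, dam, sex, generation
    f_ped: pd.DataFrame | None = None  # sample_id, f_ped
    realized_ne: pd.DataFrame | None = None  # per generation
    divergence_fst_expected: float = float("nan")


# ---------------------------------------------------------------------
# Genetic map and ancestral frequencies
# ---------------------------------------------------------------------

def _snp_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n = config.n_snps_per_chromosome
    for c in range(1, config.n_chromosomes + 1):
        pos = ((np.arange(n) + 0.5) / n * config.chromosome_length_bp).astype(np.int64) + 1
        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), n)
        for i in range(n):
            a, b = _ALLELE_PAIRS[pair_idx[i]]
            rows.append((f"snp{c}_{i + 1}", str(c), int(pos[i]), a, b))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"])


def _ancestral_frequencies(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Truncated Beta(shape, shape) on [maf, 1-maf]: the common-variant
    spectrum of an ascertained array."""
    a = config.beta_shape
    lo, hi = config.ascertainment_maf, 1.0 - config.ascertainment_maf
    u = rng.uniform(beta_dist.cdf(lo, a, a), beta_dist.cdf(hi, a, a),
                    config.n_chromosomes * config.n_snps_per_chromosome)
    return beta_dist.ppf(u, a, a)


def _pos_morgans(config: SimConfig, snps: pd.DataFrame) -> list[np.ndarray]:
    scale = config.recombination_cm_per_mb * 1e-8
    return [
        snps.loc[snps["chrom"] == str(c), "pos_bp"].to_numpy() * scale
        for c in range(1, config.n_chromosomes + 1)
    ]


# ---------------------------------------------------------------------
# Meiosis and Wright-Fisher drift
# ---------------------------------------------------------------------

def _gametes(
    haps: np.ndarray, parents: np.ndarray, pos_m: np.ndarray, length_m: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per entry of ``parents`` from haplotype matrix ``haps``
    ((2N, n_snps); individual i owns rows 2i, 2i+1). Crossover counts are
    Poisson(length_m), positions uniform, start phase random."""
    n_gam = parents.size
    k = rng.poisson(length_m, n_gam)
    kmax = int(k.max()) if n_gam else 0
    cross = np.zeros((n_gam, pos_m.size), dtype=np.int64)
    if kmax:
        pts = rng.uniform(0.0, length_m, (n_gam, kmax))
        pts[np.arange(kmax)[None, :] >= k[:, None]] = np.inf
        for col in range(kmax):
            cross += pts[:, col][:, None] <= pos_m[None, :]
    phase = rng.integers(0, 2, n_gam)
    use_first = (cross + phase[:, None]) % 2 == 0
    return np.where(use_first, haps[2 * parents], haps[2 * parents + 1])


def _offspring_haplotypes(
    haps: list[np.ndarray], sires: np.ndarray, dams: np.ndarray,
    pos_m: list[np.ndarray], length_m: float, rng: np.random.Generator,
) -> list[np.ndarray]:
    out = []
    for h, p in zip(haps, pos_m):
        pat = _gametes(h, sires, p, length_m, rng)
        mat = _gametes(h, dams, p, length_m, rng)
        new = np.empty((2 * sires.size, h.shape[1]), dtype=h.dtype)
        new[0::2] = pat
        new[1::2] = mat
        out.append(new)
    return out


def _founder_haplotypes(freqs: np.ndarray, n_ind: int, config: SimConfig,
                        rng: np.random.Generator) -> list[np.ndarray]:
    n = config.n_snps_per_chromosome
    draws = rng.random((2 * n_ind, freqs.size)) < freqs[None, :]
    return [draws[:, c * n:(c + 1) * n].astype(np.uint8) for c in range(config.n_chromosomes)]


def _drift(
    haps: list[np.ndarray], n_generations: int, size: int,
    pos_m: list[np.ndarray], length_m: float, rng: np.random.Generator,
) -> list[np.ndarray]:
    """Random-mating Wright-Fisher drift (monoecious, selfing allowed)."""
    for _ in range(n_generations):
        n_cur = haps[0].shape[0] // 2
        sires = rng.integers(0, n_cur, size)
        dams = rng.integers(0, n_cur, size)
        haps = _offspring_haplotypes(haps, sires, dams, pos_m, length_m, rng)
    return haps


def _haps_to_dataset(
    haps: list[np.ndarray], snps: pd.DataFrame, ids: list[str], population: str,
    missing_rate: float = 0.0, rng: np.random.Generator | None = None,
    indices: np.ndarray | None = None,
) -> Dataset:
    n_ind = haps[0].shape[0] // 2
    if indices is None:
        indices = np.arange(n_ind)
    dosage = np.concatenate(
        [(h[2 * indices] + h[2 * indices + 1]).astype(np.int8) for h in haps], axis=1
    )
    if missing_rate > 0:
        assert rng is not None
        dosage[rng.random(dosage.shape) < missing_rate] = MISSING
    samples = pd.DataFrame({"sample_id": ids, "population": population})
    ds = Dataset(snps=snps.reset_index(drop=True), samples=samples, genotypes=dosage)
    ds.phased = [h[np.stack([2 * indices, 2 * indices + 1], 1).ravel()] for h in haps]
    return ds


# ---------------------------------------------------------------------
# Parental pools
# ---------------------------------------------------------------------

def simulate_parental_pools(config: SimConfig) -> tuple[Dataset, Dataset, SimTruth]:
    """Two parental pools (dog, wolf) descended from one ancestral pool and
    drifted apart for ``parental_split_generations``.

    Returns ``(dog_pool, wolf_pool, truth)``; the Datasets carry phased
    haplotypes in ``.phased`` for downstream breed founding. The truth holds
    the closed-form drift expectation for their F_ST,
    ``1 - (1 - 1/(2N))^t`` at the harmonic-mean pool size.
    """
    ss = np.random.SeedSequence([config.seed, 0])
    rng_map, rng_dog, rng_wolf = [np.random.default_rng(s) for s in ss.spawn(3)]
    snps = _snp_table(config, rng_map)
    freqs = _ancestral_frequencies(config, rng_map)
    pos_m = _pos_morgans(config, snps)
    length_m = config.morgans_per_chromosome

    n_dog, n_wolf = config.parental_sizes
    pools = []
    for n_ind, rng, label in ((n_dog, rng_dog, "dog_pool"), (n_wolf, rng_wolf, "wolf_pool")):
        haps = _founder_haplotypes(freqs, n_ind, config, rng)
        haps = _drift(haps, config.parental_split_generations, n_ind, pos_m, length_m, rng)
        ids = [f"{label}_{i + 1}" for i in range(n_ind)]
        pools.append(_haps_to_dataset(haps, snps, ids, label))

    n_h = 2.0 / (1.0 / n_dog + 1.0 / n_wolf)
    t = config.parental_split_generations
    truth = SimTruth(divergence_fst_expected=1.0 - (1.0 - 1.0 / (2.0 * n_h)) ** t)
    return pools[0], pools[1], truth


# ---------------------------------------------------------------------
# Pedigree utilities
# ---------------------------------------------------------------------

def kinship(pedigree: pd.DataFrame) -> "callable":
    """Kinship-coefficient function phi(i, j) from a pedigree table with
    integer ``iid`` and nullable ``sire``/``dam`` columns (iids increase
    with time, so parents always precede offspring)."""
    parents = {
        int(r.iid): (None if pd.isna(r.sire) else int(r.sire),
                     None if pd.isna(r.dam) else int(r.dam))
        for r in pedigree.itertuples()
    }
    memo: dict[tuple[int, int], float] = {}

    def phi(i: int | None, j: int | None) -> float:
        if i is None or j is None:
            return 0.0
        key = (i, j) if i <= j else (j, i)
        if key in memo:
            return memo[key]
        if i == j:
            s, d = parents[i]
            v = 0.5 * (1.0 + phi(s, d))
        else:
            a, b = (i, j) if i > j else (j, i)  # a is the younger
            s, d = parents[a]
            v = 0.5 * (phi(s, b) + phi(d, b))
        memo[key] = v
        return v

    return phi


def pedigree_inbreeding(pedigree: pd.DataFrame, iids: list[int]) -> pd.Series:
    """F_ped per individual: kinship of its parents (founders get 0)."""
    phi = kinship(pedigree)
    parents = {
        int(r.iid): (None if pd.isna(r.sire) else int(r.sire),
                     None if pd.isna(r.dam) else int(r.dam))
        for r in pedigree.itertuples()
    }
    return pd.Series({i: phi(*parents[int(i)]) for i in iids})


def realized_ne_table(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Per-generation effective size over actual breeders: the sex-ratio
    formula 4 Nm Nf / (Nm + Nf), and a version adjusted for variance in
    offspring number (Crow-Denniston sex-specific Ne combined across
    sexes)."""
    sex = dict(zip(pedigree["iid"].astype(int), pedigree["sex"]))
    rows = []
    for gen, grp in pedigree.dropna(subset=["sire"]).groupby("generation"):
        sires = grp["sire"].astype(int)
        dams = grp["dam"].astype(int)
        n_m, n_f = sires.nunique(), dams.nunique()
        ne_sex = 4.0 * n_m * n_f / (n_m + n_f)

        def _ne_one_sex(counts: pd.Series) -> float:
            n = len(counts)
            kbar = counts.mean()
            vk = counts.var(ddof=0)
            denom = kbar - 1.0 + vk / kbar
            return (n * kbar - 1.0) / denom if denom > 0 else float("inf")

        ne_m = _ne_one_sex(sires.value_counts())
        ne_f = _ne_one_sex(dams.value_counts())
        ne_adj = (
            4.0 * ne_m * ne_f / (ne_m + ne_f)
            if np.isfinite(ne_m) and np.isfinite(ne_f)
            else ne_sex
        )
        rows.append((int(gen), n_m, n_f, ne_sex, ne_adj))
    return pd.DataFrame(rows, columns=["generation", "n_sires", "n_dams", "ne_sex_ratio", "ne_adjusted"])


# ---------------------------------------------------------------------
# Breed simulation
# ---------------------------------------------------------------------

def simulate_breed(
    parental: tuple[Dataset, Dataset],
    config: SimConfig,
    population_label: str = "breed",
    rng_stream: int = 1,
) -> tuple[Dataset, SimTruth]:
    """Found a hybrid breed from a dog x wolf cross and propagate it.

    Dog founders are male and wolf founders female, so every first
    generation animal is a true F1 hybrid. Each later generation mates dams
    (uniform) to sires drawn with Dirichlet-weighted popularity
    (``popular_sire_weight``); wolves from the wolf pool are injected into
    the breeding pool at the generations in ``infusion_schedule``. The final
    generation is sampled and genotyped with ``missing_rate``.
    """
    dog_ds, wolf_ds = parental
    if dog_ds.phased is None or wolf_ds.phased is None:
        raise ConfigError("parental Datasets must carry phased haplotypes (.phased)")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, rng_stream]))
    pos_m = _pos_morgans(config, dog_ds.snps)
    length_m = config.morgans_per_chromosome

    n_dog_f, n_wolf_f = config.founder_cross
    n_dog_pool = dog_ds.phased[0].shape[0] // 2
    n_wolf_pool = wolf_ds.phased[0].shape[0] // 2
    dog_pick = rng.choice(n_dog_pool, n_dog_f, replace=False)
    wolf_avail = list(rng.permutation(n_wolf_pool))
    wolf_pick = [wolf_avail.pop() for _ in range(n_wolf_f)]

    # pedigree rows: iid, sire, dam, sex (0 male, 1 female), generation
    ped_rows: list[tuple] = []
    next_iid = 1

    def _add(sire, dam, sex, gen):
        nonlocal next_iid
        ped_rows.append((next_iid, sire, dam, sex, gen))
        next_iid += 1
        return next_iid - 1

    cur_iids = []
    cur_sex = []
    cur_haps = [
        np.concatenate(
            [
                np.concatenate([dh[2 * i:2 * i + 2] for i in dog_pick]),
                np.concatenate([wh[2 * i:2 * i + 2] for i in wolf_pick]),
            ]
        )
        for dh, wh in zip(dog_ds.phased, wolf_ds.phased)
    ]
    for _ in range(n_dog_f):
        cur_iids.append(_add(None, None, 0, 0))
        cur_sex.append(0)
    for _ in range(n_wolf_f):
        cur_iids.append(_add(None, None, 1, 0))
        cur_sex.append(1)
    cur_sex = np.array(cur_sex)

    infusions = {g: k for g, k in config.infusion_schedule}
    sizes = config.breed_size_per_generation
    infusion_parity = 0

    for gen in range(1, len(sizes) + 1):
        if gen in infusions:
            k = infusions[gen]
            add_haps = [[] for _ in cur_haps]
            for _ in range(k):
                w = wolf_avail.pop() if wolf_avail else int(rng.integers(0, n_wolf_pool))
                for ci, wh in enumerate(wolf_ds.phased):
                    add_haps[ci].append(wh[2 * w:2 * w + 2])
                sex = 1 - (infusion_parity % 2)  # female first
                infusion_parity += 1
                cur_iids.append(_add(None, None, sex, gen - 1))
                cur_sex = np.append(cur_sex, sex)
            cur_haps = [np.concatenate([h] + extra) for h, extra in zip(cur_haps, add_haps)]

        sire_pool = np.flatnonzero(cur_sex == 0)
        dam_pool = np.flatnonzero(cur_sex == 1)
        if sire_pool.size == 0 or dam_pool.size == 0:
            raise SimulationCollapseError(
                f"{population_label}: generation {gen} has no "
                f"{'sires' if sire_pool.size == 0 else 'dams'}"
            )
        w_sire = rng.dirichlet(np.full(sire_pool.size, config.popular_sire_weight))
        size = sizes[gen - 1]
        sire_idx = sire_pool[rng.choice(sire_pool.size, size, p=w_sire)]
        dam_idx = dam_pool[rng.integers(0, dam_pool.size, size)]
        sexes = rng.integers(0, 2, size)

        cur_haps = _offspring_haplotypes(cur_haps, sire_idx, dam_idx, pos_m, length_m, rng)
        new_iids = [
            _add(cur_iids[s], cur_iids[d], int(x), gen)
            for s, d, x in zip(sire_idx, dam_idx, sexes)
        ]
        cur_iids = new_iids
        cur_sex = sexes

    pedigree = pd.DataFrame(ped_rows, columns=["iid", "sire", "dam", "sex", "generation"])
    pedigree = pedigree.astype({"iid": int, "sire": "Int64", "dam": "Int64"})

    n_final = len(cur_iids)
    n_take = min(config.n_final_samples or n_final, n_final)
    take = np.sort(rng.choice(n_final, n_take, replace=False))
    ids = [f"{population_label}_{cur_iids[i]}" for i in take]
    ds = _haps_to_dataset(
        cur_haps, dog_ds.snps, ids, population_label,
        missing_rate=config.missing_rate, rng=rng, indices=take,
    )
    f = pedigree_inbreeding(pedigree, [cur_iids[i] for i in take])
    truth = SimTruth(
        pedigree=pedigree,
        f_ped=pd.DataFrame({"sample_id": ids, "f_ped": f.to_numpy()}),
        realized_ne=realized_ne_table(pedigree),
    )
    return ds, truth


# ---------------------------------------------------------------------
# Constant-size population (LD-based Ne recovery)
# ---------------------------------------------------------------------

def simulate_constant_population(
    config: SimConfig, pop_size: int = 100, n_generations: int = 100,
    n_sample: int = 50, population_label: str = "constN",
) -> Dataset:
    """A single population held at constant size long enough for LD at the
    probed distances to equilibrate; returns a sample of ``n_sample``
    individuals."""
    ss = np.random.SeedSequence([config.seed, 2])
    rng_map, rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    snps = _snp_table(config, rng_map)
    freqs = _ancestral_frequencies(config, rng_map)
    pos_m = _pos_morgans(config, snps)
    haps = _founder_haplotypes(freqs, pop_size, config, rng)
    haps = _drift(haps, n_generations, pop_size, pos_m, config.morgans_per_chromosome, rng)
    take = np.sort(rng.choice(pop_size, n_sample, replace=False))
    ids = [f"{population_label}_{i + 1}" for i in take]
    return _haps_to_dataset(haps, snps, ids, population_label,
                            missing_rate=config.missing_rate, rng=rng, indices=take)


# ---------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------

def write_simulation(ds: Dataset, truth: SimTruth, out_dir: str | Path,
                     config: SimConfig | None = None) -> None:
    """Write PLINK PED/MAP plus population, allele and truth tables; the
    PED/MAP round-trips exactly through genotype_io using alleles.tsv as the
    orientation reference."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_plink_text(ds, out / "genotypes.ped", out / "genotypes.map")
    write_population_table(ds, out / "populations.tsv")
    write_map_table(ds, out / "snps.tsv")
    ds.snps[["snp_id", "allele_a", "allele_b"]].to_csv(out / "alleles.tsv", sep="\t", index=False)
    if truth.pedigree is not None:
        truth.pedigree.to_csv(out / "pedigree.tsv", sep="\t", index=False)
    if truth.f_ped is not None:
        truth.f_ped.to_csv(out / "f_ped.tsv", sep="\t", index=False)
    if truth.realized_ne is not None:
        truth.realized_ne.to_csv(out / "realized_ne.tsv", sep="\t", index=False)
    if config is not None:
        (out / "simconfig.json").write_text(json.dumps(dataclasses.asdict(config), indent=2))


# ---------------------------------------------------------------------
# Shipped two-breed scenario
# ---------------------------------------------------------------------

def scenario_config(seed: int = 0) -> SimConfig:
    """Base configuration of the shipped wolf/dog/two-hybrid-breed scenario
    (panel and parental-pool scale; per-breed settings are derived from it
    in :func:`two_breed_scenario`)."""
    return SimConfig(
        n_chromosomes=10,
        chromosome_length_bp=100_000_000,
        n_snps_per_chromosome=1_000,
        parental_split_generations=60,
        parental_sizes=(120, 120),
        missing_rate=0.01,
        seed=seed,
    )


def two_breed_scenario(seed: int = 0, base: SimConfig | None = None) -> tuple[Dataset, dict]:
    """Simulate the four-population study design: a wolf pool (WLF), an
    inbred parental dog breed sampled from two diverged show/work lines
    (GSH), a CSW-like hybrid breed (broader founder base, four wolf
    infusions, mild sire reuse) and a SAW-like hybrid breed (single founder
    pair, heavy sire reuse, fewer infusions, ~8 generations older).

    Sample sizes mirror the study design (46 CSW, 20 SAW, 12 GSH, 20 WLF).
    Returns the combined Dataset and a truth dict with per-breed pedigrees,
    pedigree inbreeding and realized Ne.
    """
    base = base or scenario_config(seed)
    if base.seed != seed:
        base = dataclasses.replace(base, seed=seed)
    dog_pool, wolf_pool, pool_truth = simulate_parental_pools(base)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9]))
    pos_m = _pos_morgans(base, dog_pool.snps)
    length_m = base.morgans_per_chromosome

    # GSH-like sample: two breed lines drifted apart from the dog pool
    # (closed stud books -> substructure and a heterozygote deficit).
    n_dog_pool = base.parental_sizes[0]
    line_size, line_gens = min(40, n_dog_pool // 3), 12
    picks = rng.choice(n_dog_pool, 2 * line_size, replace=False)
    gsh_parts = []
    for li in range(2):
        members = picks[li * line_size:(li + 1) * line_size]
        rows = np.stack([2 * members, 2 * members + 1], 1).ravel()
        haps = [h[rows] for h in dog_pool.phased]
        haps = _drift(haps, line_gens, line_size, pos_m, length_m, rng)
        take = np.sort(rng.choice(line_size, 6, replace=False))
        ids = [f"GSH_l{li + 1}_{i + 1}" for i in take]
        gsh_parts.append(_haps_to_dataset(haps, dog_pool.snps, ids, "GSH", indices=take))
    line_fst_expected = 1.0 - (1.0 - 1.0 / (2.0 * line_size)) ** line_gens

    csw_cfg = dataclasses.replace(
        base,
        founder_cross=(4, 4),
        breed_size_per_generation=(50,) * 21,
        infusion_schedule=((1, 1), (3, 1), (5, 1), (8, 1)),
        popular_sire_weight=1.0,
        n_final_samples=46,
    )
    saw_cfg = dataclasses.replace(
        base,
        founder_cross=(1, 1),
        breed_size_per_generation=(30,) * 29,
        infusion_schedule=((7, 1), (11, 1), (16, 1)),
        popular_sire_weight=0.25,
        n_final_samples=20,
    )
    csw_ds, csw_truth = simulate_breed((dog_pool, wolf_pool), csw_cfg, "CSW", rng_stream=11)
    saw_ds, saw_truth = simulate_breed((dog_pool, wolf_pool), saw_cfg, "SAW", rng_stream=12)

    wlf_take = np.sort(rng.choice(base.parental_sizes[1], 20, replace=False))
    wlf_ids = [f"WLF_{i + 1}" for i in wlf_take]
    wlf_ds = _haps_to_dataset(wolf_pool.phased, dog_pool.snps, wlf_ids, "WLF",
                              indices=wlf_take)

    parts = [saw_ds, csw_ds] + gsh_parts + [wlf_ds]
    geno = np.vstack([p.genotypes for p in parts])
    if base.missing_rate > 0:
        # wolf/GSH samples were genotyped without the breeds' missingness
        extra = [p for p in (gsh_parts + [wlf_ds])]
        start = saw_ds.n_samples + csw_ds.n_samples
        n_extra = sum(p.n_samples for p in extra)
        mask = rng.random((n_extra, geno.shape[1])) < base.missing_rate
        block = geno[start:start + n_extra]
        block[mask] = MISSING
    samples = pd.concat([p.samples for p in parts], ignore_index=True)
    combined = Dataset(snps=dog_pool.snps.reset_index(drop=True), samples=samples, genotypes=geno)

    truth = {
        "CSW": csw_truth,
        "SAW": saw_truth,
        "divergence_fst_expected": pool_truth.divergence_fst_expected,
        "line_fst_expected": line_fst_expected,
    }
    return combined, truth
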