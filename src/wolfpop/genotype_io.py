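"""Reading, harmonizing, merging and filtering SNP-array genotype data.

The central container is :class:`Dataset`: a diploid biallelic genotype
matrix (samples x SNPs, dosage of ``allele_b`` in {0, 1, 2}, ``-1`` for
missing) together with an ordered SNP map and a sample/population table.
Supported on-disk formats are PLINK text (PED/MAP) and PLINK binary
(BED/BIM/FAM, SNP-major), plus plain TSV side tables.

Only autosomes are analyzed: chromosome labels that do not parse as a
positive integer (X, Y, MT, XY, 0, ...) are excluded on load and counted.
Positions are 1-based inclusive, the PLINK convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


class PlinkParseError(ValueError):
    """A PLINK file line could not be parsed."""


class StructuralError(ValueError):
    """PED/MAP (or BED/BIM/FAM) components disagree in shape."""


class MergeError(ValueError):
    """Datasets cannot be merged (sample conflicts, empty intersection...)."""


class DatasetError(ValueError):
    """Invalid or degenerate Dataset for the requested operation."""


@dataclass
class MergeReport:
    """Bookkeeping for harmonization/merge/filter steps."""

    n_flipped: int = 0
    n_ambiguous_dropped: int = 0
    n_name_conflicts: int = 0
    n_removed_missingness: int = 0
    genotyping_rate: float = float("nan")


@dataclass
class Dataset:
    """Genotype matrix with SNP map and sample table.

    Attributes
    ----------
    snps : DataFrame with columns ``snp_id, chrom, pos_bp, allele_a, allele_b``,
        sorted by (chrom, pos_bp); dosage counts copies of ``allele_b``.
    samples : DataFrame with columns ``sample_id, population``.
    genotypes : int8 array, shape (n_samples, n_snps); -1 encodes missing.
    """

    snps: pd.DataFrame
    samples: pd.DataFrame
    genotypes: np.ndarray
    phased: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic api -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def validate(self) -> None:
        if self.genotypes.shape != (len(self.samples), len(self.snps)):
            raise StructuralError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()].iloc[0]
            raise DatasetError(f"duplicate sample_id {dup!r}")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps["snp_id"][self.snps["snp_id"].duplicated()].iloc[0]
            raise DatasetError(f"duplicate snp_id {dup!r}")
        if (self.snps["pos_bp"] <= 0).any():
            raise DatasetError("positions must be positive (1-based)")
        # strictly increasing position within chromosome
        for _, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos_bp"].is_monotonic_increasing:
                raise DatasetError("SNPs not sorted by position within chromosome")

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["population"] == population).to_numpy())
        if idx.size == 0:
            raise DatasetError(f"unknown population {population!r}")
        return idx

    def subset_samples(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            snps=self.snps.reset_index(drop=True),
            samples=self.samples.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[idx].copy(),
        )

    def subset_snps(self, keep: np.ndarray) -> "Dataset":
        """Subset columns by boolean mask or integer index (order preserved)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return Dataset(
            snps=self.snps.iloc[keep].reset_index(drop=True),
            samples=self.samples.reset_index(drop=True),
            genotypes=self.genotypes[:, keep].copy(),
        )

    def assign_populations(self, mapping: dict[str, str]) -> "Dataset":
        pops = [mapping.get(s, p) for s, p in zip(self.samples["sample_id"], self.samples["population"])]
        samples = self.samples.copy()
        samples["population"] = pops
        return Dataset(self.snps, samples, self.genotypes)


def _sort_key(ds_snps: pd.DataFrame) -> pd.DataFrame:
    key = ds_snps.assign(_c=ds_snps["chrom"].astype(int))
    return key.sort_values(["_c", "pos_bp"], kind="mergesort").drop(columns="_c")


def _is_autosome(label: str) -> bool:
    try:
        return int(label) > 0
    except ValueError:
        return False


# ---------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------

def read_map(map_path: str | Path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise PlinkParseError(f"{map_path}:{lineno}: expected 4 fields, got {len(parts)}")
            chrom, snp_id, _cm, pos = parts
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise PlinkParseError(f"{map_path}:{lineno}: bad position {pos!r}") from exc
            rows.append((snp_id, chrom, pos_i))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp"])


def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    allele_ref: pd.DataFrame | None = None,
) -> Dataset:
    """Read a PLINK PED/MAP pair into a :class:`Dataset`.

    Dosage counts the minor allele observed in the file (ties broken by
    nucleotide order), unless ``allele_ref`` — a table with columns
    ``snp_id, allele_a, allele_b`` — fixes the orientation explicitly.
    Non-autosomal SNPs are dropped. ``0 0`` encodes missing.
    """
    snp_map = read_map(map_path)
    n_snps = len(snp_map)

    sample_rows = []
    allele_calls = []  # per sample: array (n_snps, 2) of single characters
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 6 or (len(parts) - 6) % 2:
                raise PlinkParseError(f"{ped_path}:{lineno}: malformed PED line")
            n_geno = (len(parts) - 6) // 2
            if n_geno != n_snps:
                raise StructuralError(
                    f"{ped_path}:{lineno}: {n_geno} genotypes but MAP has {n_snps} SNPs"
                )
            fid, iid = parts[0], parts[1]
            sample_rows.append((iid, fid))
            allele_calls.append(np.array(parts[6:], dtype="U1").reshape(n_snps, 2))

    if not sample_rows:
        raise PlinkParseError(f"{ped_path}: no samples")
    calls = np.stack(allele_calls)  # (n_samples, n_snps, 2)
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "population"])

    ref = None
    if allele_ref is not None:
        ref = allele_ref.set_index("snp_id")

    a_list, b_list = [], []
    geno = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        col = calls[:, j, :]
        present = col != "0"
        observed = sorted(set(col[present]))
        if len(observed) > 2:
            raise PlinkParseError(
                f"{ped_path}: SNP {snp_map['snp_id'].iloc[j]!r} has >2 alleles {observed}"
            )
        if ref is not None and snp_map["snp_id"].iloc[j] in ref.index:
            a, b = ref.loc[snp_map["snp_id"].iloc[j], ["allele_a", "allele_b"]]
        else:
            if not observed:
                a, b = "0", "0"
            elif len(observed) == 1:
                a, b = observed[0], "0"  # monomorphic: counted allele unseen
            else:
                counts = {al: int((col == al).sum()) for al in observed}
                # minor allele is counted (allele_b); ties broken by order
                b, a = sorted(observed, key=lambda al: (counts[al], al))
        dos = (col == b).sum(axis=1).astype(np.int8)
        miss = ~present.all(axis=1)
        dos[miss] = MISSING
        geno[:, j] = dos
        a_list.append(a)
        b_list.append(b)

    snps = snp_map.assign(allele_a=a_list, allele_b=b_list)
    keep = snps["chrom"].map(_is_autosome).to_numpy()
    snps = snps[keep].reset_index(drop=True)
    geno = geno[:, keep]
    order = _sort_key(snps).index.to_numpy()
    snps = snps.iloc[order].reset_index(drop=True)
    return Dataset(snps=snps, samples=samples, genotypes=geno[:, order])


def write_plink_text(ds: Dataset, ped_path: str | Path, map_path: str | Path) -> None:
    with open(map_path, "w") as fh:
        for _, r in ds.snps.iterrows():
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos_bp}\n")
    a = ds.snps["allele_a"].to_numpy()
    b = ds.snps["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, (_, s) in enumerate(ds.samples.iterrows()):
            row = ds.genotypes[i]
            fields = [s.population, s.sample_id, "0", "0", "0", "-9"]
            for j, d in enumerate(row):
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a[j], a[j]]
                elif d == 1:
                    fields += [a[j], b[j]]
                else:
                    fields += [b[j], b[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------
# PLINK binary (BED/BIM/FAM, SNP-major)
# ---------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes, SNP-major: 00 hom A1, 01 missing, 10 het, 11 hom A2.
# We store allele_b = A1 (counted allele), so 00 -> 2, 10 -> 1, 11 -> 0.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, MISSING & 0xFF: 1, 1: 2, 0: 3}


def read_plink_binary(bed_path: str | Path, bim_path: str | Path, fam_path: str | Path) -> Dataset:
    """Read PLINK BED/BIM/FAM (SNP-major). Equivalent content yields the
    same Dataset as :func:`read_plink_text`; A1 in the BIM is the counted
    allele (``allele_b``)."""
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"fid": str, "iid": str},
    )
    n_snps, n_samples = len(bim), len(fam)
    raw = Path(bed_path).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkParseError(f"{bed_path}: bad magic bytes (not SNP-major PLINK BED)")
    bytes_per_snp = (n_samples + 3) // 4
    expected = 3 + bytes_per_snp * n_snps
    if len(raw) != expected:
        raise StructuralError(f"{bed_path}: expected {expected} bytes, found {len(raw)}")
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n_snps, bytes_per_snp)
    # unpack 2-bit codes, low bits first within each byte
    codes = np.stack([(data >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(n_snps, -1)[:, :n_samples]
    geno = _CODE_TO_DOSAGE[codes].T.copy()  # (n_samples, n_snps)

    snps = bim[["snp_id", "chrom", "pos_bp"]].copy()
    snps["allele_a"] = bim["a2"]
    snps["allele_b"] = bim["a1"]
    samples = pd.DataFrame({"sample_id": fam["iid"], "population": fam["fid"]})

    keep = snps["chrom"].map(_is_autosome).to_numpy()
    snps = snps[keep].reset_index(drop=True)
    geno = geno[:, keep]
    order = _sort_key(snps).index.to_numpy()
    snps = snps.iloc[order].reset_index(drop=True)
    return Dataset(snps=snps, samples=samples, genotypes=geno[:, order])


def write_plink_binary(ds: Dataset, bed_path: str | Path, bim_path: str | Path, fam_path: str | Path) -> None:
    with open(bim_path, "w") as fh:
        for _, r in ds.snps.iterrows():
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos_bp}\t{r.allele_b}\t{r.allele_a}\n")
    with open(fam_path, "w") as fh:
        for _, s in ds.samples.iterrows():
            fh.write(f"{s.population}\t{s.sample_id}\t0\t0\t0\t-9\n")
    n_samples = ds.n_samples
    bytes_per_snp = (n_samples + 3) // 4
    out = np.zeros((ds.n_snps, bytes_per_snp), dtype=np.uint8)
    code = np.empty_like(ds.genotypes, dtype=np.uint8)
    for dos, c in ((2, 0), (1, 2), (0, 3)):
        code[ds.genotypes == dos] = c
    code[ds.genotypes == MISSING] = 1
    padded = np.ones((ds.n_snps, bytes_per_snp * 4), dtype=np.uint8) * 0  # pad with 00
    padded[:, :n_samples] = code.T
    for k, shift in enumerate((0, 2, 4, 6)):
        out |= padded[:, k::4] << shift
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


# ---------------------------------------------------------------------
# Population table / TSV side outputs
# ---------------------------------------------------------------------

def read_population_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, population), optional header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise PlinkParseError(f"{path}: expected two tab-separated columns")
    if list(df.iloc[0]) [:2] == ["sample_id", "population"]:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_population_table(ds: Dataset, path: str | Path) -> None:
    ds.samples.to_csv(path, sep="\t", index=False)


def write_map_table(ds: Dataset, path: str | Path) -> None:
    ds.snps.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------
# Harmonization / merging / filtering
# ---------------------------------------------------------------------

def _is_ambiguous(a: str, b: str) -> bool:
    return {a, b} in _AMBIGUOUS_PAIRS


def harmonize_alleles(reference: Dataset, other: Dataset) -> tuple[Dataset, MergeReport]:
    """Align ``other``'s allele strands and orientation to ``reference``.

    For shared SNPs whose allele pair in ``other`` is the reverse complement
    of the reference's, alleles are complemented (counted as a strand flip)
    and, if additionally swapped, dosage is reversed. Strand-ambiguous SNPs
    ({A,T} or {C,G}) cannot be checked and are removed; since downstream
    merging intersects SNP sets, they are thereby excluded from the merged
    panel entirely. SNPs with irreconcilable alleles are removed and counted.
    """
    report = MergeReport()
    shared = set(reference.snps["snp_id"]) & set(other.snps["snp_id"])
    if not shared:
        raise MergeError("datasets share no snp_ids")

    ref_alleles = reference.snps.set_index("snp_id")[["allele_a", "allele_b"]]
    snps = other.snps.copy()
    geno = other.genotypes.copy()
    drop = np.zeros(len(snps), dtype=bool)

    for j, row in enumerate(snps.itertuples()):
        if row.snp_id not in shared:
            continue
        ra, rb = ref_alleles.loc[row.snp_id]
        oa, ob = row.allele_a, row.allele_b
        if _is_ambiguous(ra, rb) or _is_ambiguous(oa, ob):
            drop[j] = True
            report.n_ambiguous_dropped += 1
            continue
        if {oa, ob} == {ra, rb}:
            pass
        elif {_COMPLEMENT.get(oa, "?"), _COMPLEMENT.get(ob, "?")} == {ra, rb}:
            oa, ob = _COMPLEMENT[oa], _COMPLEMENT[ob]
            report.n_flipped += 1
        else:
            drop[j] = True
            report.n_name_conflicts += 1
            continue
        if (oa, ob) != (ra, rb):  # counted allele swapped
            oa, ob = ob, oa
            col = geno[:, j]
            col[col != MISSING] = 2 - col[col != MISSING]
        snps.iat[j, snps.columns.get_loc("allele_a")] = oa
        snps.iat[j, snps.columns.get_loc("allele_b")] = ob

    keep = ~drop
    out = Dataset(
        snps=snps[keep].reset_index(drop=True),
        samples=other.samples.reset_index(drop=True),
        genotypes=geno[:, keep],
    )
    return out, report


def orient_to_minor(ds: Dataset) -> Dataset:
    """Make allele_b the global minor allele (ties keep orientation)."""
    geno = ds.genotypes.copy()
    snps = ds.snps.copy()
    obs = geno != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(obs.sum(0) > 0, geno.clip(0).sum(0) / (2.0 * obs.sum(0)), 0.0)
    flip = freq > 0.5
    for j in np.flatnonzero(flip):
        col = geno[:, j]
        col[col != MISSING] = 2 - col[col != MISSING]
        a, b = snps.iat[j, snps.columns.get_loc("allele_a")], snps.iat[j, snps.columns.get_loc("allele_b")]
        snps.iat[j, snps.columns.get_loc("allele_a")] = b
        snps.iat[j, snps.columns.get_loc("allele_b")] = a
    return Dataset(snps=snps, samples=ds.samples, genotypes=geno)


def merge_datasets(datasets: list[Dataset]) -> Dataset:
    """Merge pairwise-harmonized datasets: SNP intersection, sample union.

    Duplicate-position SNPs on a chromosome keep the lexicographically first
    snp_id. After merging, dosage is re-oriented so allele_b is the global
    minor allele.
    """
    if not datasets:
        raise MergeError("no datasets to merge")
    all_ids = [s for ds in datasets for s in ds.samples["sample_id"]]
    dup = pd.Series(all_ids).duplicated()
    if dup.any():
        raise MergeError(f"duplicate sample_id across inputs: {pd.Series(all_ids)[dup].iloc[0]!r}")

    common = set(datasets[0].snps["snp_id"])
    for ds in datasets[1:]:
        common &= set(ds.snps["snp_id"])
    if not common:
        raise MergeError("SNP intersection is empty")

    base = datasets[0]
    keep = base.snps["snp_id"].isin(common).to_numpy()
    snps = base.snps[keep].reset_index(drop=True)
    # drop duplicate positions, keeping first snp_id lexicographically
    snps = snps.sort_values(["chrom", "pos_bp", "snp_id"], kind="mergesort")
    snps = snps.drop_duplicates(subset=["chrom", "pos_bp"], keep="first")
    order_ids = _sort_key(snps)["snp_id"].tolist()

    base_alleles = snps.set_index("snp_id").loc[order_ids]
    blocks, sample_frames = [], []
    for ds in datasets:
        idx = {s: i for i, s in enumerate(ds.snps["snp_id"])}
        cols = np.array([idx[s] for s in order_ids])
        g = ds.genotypes[:, cols].copy()
        # orientation check against the base panel
        oth = ds.snps.iloc[cols].reset_index(drop=True)
        mism = oth["allele_a"].to_numpy() != base_alleles["allele_a"].to_numpy()
        for j in np.flatnonzero(mism):
            sa = {oth["allele_a"].iloc[j], oth["allele_b"].iloc[j]}
            ta_row = base_alleles.iloc[j]
            if sa != {ta_row["allele_a"], ta_row["allele_b"]}:
                raise MergeError(
                    f"allele conflict at {order_ids[j]!r}; harmonize datasets first"
                )
            col = g[:, j]
            col[col != MISSING] = 2 - col[col != MISSING]
        blocks.append(g)
        sample_frames.append(ds.samples)

    merged = Dataset(
        snps=snps.set_index("snp_id").loc[order_ids].reset_index()[
            ["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"]
        ],
        samples=pd.concat(sample_frames, ignore_index=True),
        genotypes=np.vstack(blocks),
    )
    return orient_to_minor(merged)


def genotyping_rate(ds: Dataset) -> float:
    """Fraction of non-missing calls over the whole matrix."""
    if ds.genotypes.size == 0:
        raise DatasetError("empty dataset has no genotyping rate")
    return float((ds.genotypes != MISSING).mean())


def filter_by_missing_count(ds: Dataset, max_missing_samples: int = 6) -> tuple[Dataset, MergeReport]:
    """Drop SNPs missing in strictly more than ``max_missing_samples`` samples."""
    if max_missing_samples < 0:
        raise DatasetError("max_missing_samples must be >= 0")
    n_missing = (ds.genotypes == MISSING).sum(axis=0)
    keep = n_missing <= max_missing_samples
    out = ds.subset_snps(keep)
    report = MergeReport(
        n_removed_missingness=int((~keep).sum()),
        genotyping_rate=genotyping_rate(out) if out.genotypes.size else float("nan"),
    )
    return out, report
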