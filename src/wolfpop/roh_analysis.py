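"""Runs of homozygosity: sliding-window detection, length classes, F_ROH.

Detection follows the classic SNP-array sliding-window procedure: windows
of ``window_snps`` consecutive SNPs are scanned along each chromosome; a
window is called homozygous when it contains at most ``max_het_per_window``
heterozygous and ``max_missing_per_window`` missing calls. Each SNP's
support is the fraction of overlapping windows called homozygous (SNPs near
chromosome ends use the actual number of overlapping windows as the
denominator). SNPs whose support reaches ``snp_inclusion_threshold`` are
in-run; maximal in-run stretches become segments if they hold at least
``min_snps_in_run`` SNPs, span at least ``min_length_bp``, and contain no
adjacent-SNP gap above ``max_gap_bp`` (larger gaps split the stretch).

Segment coordinates are SNP-bounded: first to last in-run SNP, 1-based
inclusive, so ``length_bp = end_bp - start_bp + 1``.

F_ROH is the summed segment length divided by the SNP-covered genome length
(per chromosome: max position - min position + 1).

Length classes are the five intervals 0-2, 2-4, 4-8, 8-16 and >16 Mbp,
half-open ``[lo, hi)`` (a segment of exactly 2.0 Mbp falls in 2-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, Dataset, DatasetError

MBP = 1_000_000
CLASS_EDGES_MBP = (0.0, 2.0, 4.0, 8.0, 16.0)
CLASS_LABELS = ("0-2", "2-4", "4-8", "8-16", ">16")


@dataclass
class RohParams:
    """Window-scan parameters. window_snps=50 and min_snps_in_run=20 are the
    study settings; the remaining knobs default to the conventions of the
    standard sliding-window ROH packages."""

    window_snps: int = 50
    min_snps_in_run: int = 20
    max_het_per_window: int = 1
    max_missing_per_window: int = 1
    snp_inclusion_threshold: float = 0.05
    min_length_bp: int = 1_000
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.min_snps_in_run < 1:
            raise ValueError("window_snps and min_snps_in_run must be >= 1")
        if not (0.0 < self.snp_inclusion_threshold <= 1.0):
            raise ValueError("snp_inclusion_threshold must be in (0, 1]")
        if min(self.max_het_per_window, self.max_missing_per_window, self.min_length_bp, self.max_gap_bp) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class RohSegment:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class RohClassSummary:
    population: str
    class_labels: tuple = CLASS_LABELS
    pct_per_class: np.ndarray = field(default_factory=lambda: np.zeros(5))
    mean_length_per_class: np.ndarray = field(default_factory=lambda: np.full(5, np.nan))
    mean_froh: float = float("nan")


@dataclass
class FrohResult:
    sample_id: str
    froh: float
    covered_length_bp: int


def _chrom_in_run(dosage: np.ndarray, params: RohParams) -> np.ndarray:
    """Boolean in-run flag per SNP on one chromosome (window support rule)."""
    n = dosage.size
    w = params.window_snps
    if n < w:
        return np.zeros(n, dtype=bool)
    het = (dosage == 1).astype(np.int64)
    mis = (dosage == MISSING).astype(np.int64)
    kern = np.ones(w, dtype=np.int64)
    het_w = np.convolve(het, kern, mode="valid")  # n - w + 1 windows
    mis_w = np.convolve(mis, kern, mode="valid")
    ok = (het_w <= params.max_het_per_window) & (mis_w <= params.max_missing_per_window)
    ok_cum = np.concatenate(([0], np.cumsum(ok)))
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n - w)
    support = (ok_cum[hi + 1] - ok_cum[lo]) / (hi - lo + 1)
    return support >= params.snp_inclusion_threshold


def _emit_segments(
    sample_id: str, chrom: str, pos: np.ndarray, in_run: np.ndarray, params: RohParams
) -> list[RohSegment]:
    segments = []
    idx = np.flatnonzero(in_run)
    if idx.size == 0:
        return segments
    # break at non-consecutive indices or at physical gaps above max_gap_bp
    breaks = np.flatnonzero(
        (np.diff(idx) > 1) | (np.diff(pos[idx]) > params.max_gap_bp)
    )
    for chunk in np.split(idx, breaks + 1):
        if chunk.size < params.min_snps_in_run:
            continue
        start, end = int(pos[chunk[0]]), int(pos[chunk[-1]])
        if end - start + 1 < params.min_length_bp:
            continue
        segments.append(RohSegment(sample_id, chrom, start, end, int(chunk.size)))
    return segments


def detect_roh_individual(
    genotypes: np.ndarray, snps: pd.DataFrame, params: RohParams | None = None, sample_id: str = ""
) -> list[RohSegment]:
    """Detect ROH segments for one individual.

    ``genotypes``: dosage vector aligned with ``snps`` (columns snp_id,
    chrom, pos_bp, sorted by chromosome then position).
    """
    params = params or RohParams()
    segments: list[RohSegment] = []
    chroms = snps["chrom"].to_numpy()
    pos = snps["pos_bp"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        p = pos[sel]
        if np.any(np.diff(p) <= 0):
            raise DatasetError(f"chromosome {chrom}: map not sorted by position")
        in_run = _chrom_in_run(np.asarray(genotypes)[sel], params)
        segments.extend(_emit_segments(sample_id, str(chrom), p, in_run, params))
    return segments


def classify_segments(segments: list[RohSegment]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class (counts, total length bp, mean length bp) over the five
    length classes."""
    counts = np.zeros(5, dtype=int)
    totals = np.zeros(5, dtype=float)
    for seg in segments:
        k = int(np.digitize(seg.length_bp / MBP, CLASS_EDGES_MBP) - 1)
        counts[k] += 1
        totals[k] += seg.length_bp
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)
    return counts, totals, means


def covered_genome_length(snps: pd.DataFrame) -> int:
    """Genome length covered by the map: sum over chromosomes of
    (max position - min position + 1)."""
    if len(snps) == 0:
        raise DatasetError("empty SNP map")
    span = snps.groupby("chrom")["pos_bp"].agg(["min", "max"])
    return int((span["max"] - span["min"] + 1).sum())


def froh(segments: list[RohSegment], snps: pd.DataFrame) -> FrohResult:
    """Genomic inbreeding coefficient: summed ROH length over the
    SNP-covered genome length, for one individual."""
    covered = covered_genome_length(snps)
    total = sum(s.length_bp for s in segments)
    sample_id = segments[0].sample_id if segments else ""
    return FrohResult(sample_id=sample_id, froh=total / covered, covered_length_bp=covered)


def population_roh_summary(
    ds: Dataset, params: RohParams | None = None
) -> tuple[list[RohClassSummary], pd.DataFrame, list[RohSegment]]:
    """Per-population ROH class breakdown (individual-wise mean percentage of
    each individual's total ROH coverage per class), per-class mean lengths,
    and per-sample F_ROH.

    Returns (class summaries, froh table, all segments).
    """
    params = params or RohParams()
    covered = covered_genome_length(ds.snps)
    froh_rows = []
    all_segments: list[RohSegment] = []
    per_pop_pct: dict[str, list[np.ndarray]] = {}
    per_pop_segments: dict[str, list[RohSegment]] = {}
    pops = ds.populations()
    for pop in pops:
        per_pop_pct[pop] = []
        per_pop_segments[pop] = []
    for i in range(ds.n_samples):
        sid = ds.samples["sample_id"].iloc[i]
        pop = ds.samples["population"].iloc[i]
        segs = detect_roh_individual(ds.genotypes[i], ds.snps, params, sample_id=sid)
        all_segments.extend(segs)
        per_pop_segments[pop].extend(segs)
        total = sum(s.length_bp for s in segs)
        froh_rows.append((sid, pop, total / covered, covered))
        if total > 0:
            _, totals, _ = classify_segments(segs)
            per_pop_pct[pop].append(100.0 * totals / total)
    froh_table = pd.DataFrame(froh_rows, columns=["sample_id", "population", "froh", "covered_length_bp"])

    summaries = []
    for pop in pops:
        _, _, means = classify_segments(per_pop_segments[pop])
        pcts = (
            np.mean(np.vstack(per_pop_pct[pop]), axis=0)
            if per_pop_pct[pop]
            else np.zeros(5)
        )
        summaries.append(
            RohClassSummary(
                population=pop,
                pct_per_class=pcts,
                mean_length_per_class=means,
                mean_froh=float(froh_table.loc[froh_table["population"] == pop, "froh"].mean()),
            )
        )
    return summaries, froh_table, all_segments


def segments_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in segments],
            "chrom": [s.chromosome for s in segments],
            "start_bp": [s.start_bp for s in segments],
            "end_bp": [s.end_bp for s in segments],
            "n_snps": [s.n_snps for s in segments],
            "length_bp": [s.length_bp for s in segments],
        }
    )


def class_summary_to_frame(summaries: list[RohClassSummary]) -> pd.DataFrame:
    """Table-4-style layout: one row per class (plus F_ROH), one column per
    population."""
    data = {"class_mbp": list(CLASS_LABELS) + ["F_ROH"]}
    for s in summaries:
        data[s.population] = [f"{p:.1f}%" for p in s.pct_per_class] + [f"{s.mean_froh:.3f}"]
    return pd.DataFrame(data)
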