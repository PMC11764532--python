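"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity with plain Python loops,
separate from the vectorized implementations they check.
"""

from __future__ import annotations

import math


def brute_roh_segments(dosage, pos, params):
    """Window-enumeration ROH scan: returns (start_bp, end_bp, n_snps)
    tuples for one chromosome."""
    n = len(dosage)
    w = params.window_snps
    if n < w:
        return []
    window_ok = []
    for i in range(n - w + 1):
        win = dosage[i:i + w]
        het = sum(1 for d in win if d == 1)
        mis = sum(1 for d in win if d < 0)
        window_ok.append(
            het <= params.max_het_per_window and mis <= params.max_missing_per_window
        )
    in_run = []
    for j in range(n):
        overlapping = [window_ok[i] for i in range(max(0, j - w + 1), min(j, n - w) + 1)]
        in_run.append(sum(overlapping) / len(overlapping) >= params.snp_inclusion_threshold)

    stretches, cur = [], []
    for j in range(n):
        if in_run[j]:
            if cur and pos[j] - pos[cur[-1]] > params.max_gap_bp:
                stretches.append(cur)
                cur = []
            cur.append(j)
        elif cur:
            stretches.append(cur)
            cur = []
    if cur:
        stretches.append(cur)

    out = []
    for s in stretches:
        length = pos[s[-1]] - pos[s[0]] + 1
        if len(s) >= params.min_snps_in_run and length >= params.min_length_bp:
            out.append((int(pos[s[0]]), int(pos[s[-1]]), len(s)))
    return out


def wc_fst_loop(g1, g2):
    """Per-locus transcription of the Weir & Cockerham (1984) two-population
    estimator, combined as a ratio of sums; scalar arithmetic per SNP."""
    sum_a, sum_t = 0.0, 0.0
    n_snps = len(g1[0])
    r = 2.0
    for j in range(n_snps):
        col1 = [row[j] for row in g1 if row[j] >= 0]
        col2 = [row[j] for row in g2 if row[j] >= 0]
        n1, n2 = len(col1), len(col2)
        if n1 < 1 or n2 < 1 or (n1 + n2) / 2.0 <= 1:
            continue
        p1 = sum(col1) / (2.0 * n1)
        p2 = sum(col2) / (2.0 * n2)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        if pbar <= 0.0 or pbar >= 1.0:
            continue
        h1 = sum(1 for d in col1 if d == 1) / n1
        h2 = sum(1 for d in col2 if d == 1) / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        sum_a += a
        sum_t += a + b + c
    return sum_a / sum_t


def pearson_r2_loop(x, y):
    """Squared Pearson correlation over pairwise-complete entries."""
    pairs = [(a, b) for a, b in zip(x, y) if a >= 0 and b >= 0]
    n = len(pairs)
    mx = sum(a for a, _ in pairs) / n
    my = sum(b for _, b in pairs) / n
    cov = sum((a - mx) * (b - my) for a, b in pairs)
    vx = sum((a - mx) ** 2 for a, _ in pairs)
    vy = sum((b - my) ** 2 for _, b in pairs)
    if vx == 0 or vy == 0:
        return math.nan
    return cov * cov / (vx * vy)


def mean_het_loop(rows):
    """(h_obs, h_exp) means by per-SNP loops, for fully generic dosage rows."""
    n_snps = len(rows[0])
    ho_vals, he_vals = [], []
    for j in range(n_snps):
        col = [row[j] for row in rows if row[j] >= 0]
        if not col:
            continue
        ho_vals.append(sum(1 for d in col if d == 1) / len(col))
        p = sum(col) / (2.0 * len(col))
        he_vals.append(2.0 * p * (1.0 - p))
    return sum(ho_vals) / len(ho_vals), sum(he_vals) / len(he_vals)
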