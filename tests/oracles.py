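"""Brute-force oracles, implemented independently of the package's
statistical code (pure ``math``/``itertools``): exhaustive permutation
enumeration, the even-df chi-square upper-tail series, and hypergeometric
tail enumeration. Not performance-optimized by design.
"""

from __future__ import annotations

import math
from itertools import combinations

MAX_EXHAUSTIVE_SAMPLES = 12


def pooled_t(xs, ys) -> float:
    """Equal-variance two-sample t, first group minus second."""
    n1, n2 = len(xs), len(ys)
    m1 = sum(xs) / n1
    m2 = sum(ys) / n2
    ss = sum((x - m1) ** 2 for x in xs) + sum((y - m2) ** 2 for y in ys)
    se = math.sqrt(ss / (n1 + n2 - 2) * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 0.0 if m1 == m2 else math.copysign(math.inf, m1 - m2)
    return (m1 - m2) / se


def exhaustive_permutation_p(ds, genes) -> tuple[float, float]:
    """Exact (p_up, p_down) for the mean-t pathway score of ``genes``.

    Enumerates every distinct group-size-preserving label assignment
    (identity included) of a small collapsed dataset. Refuses designs with
    more than 12 samples.
    """
    n_samples = ds.n_samples
    if n_samples > MAX_EXHAUSTIVE_SAMPLES:
        raise ValueError(f"too many samples for enumeration: {n_samples}")
    gene_rows = {}
    for probe in ds.values.index:
        gene = ds.gene_of_probe.loc[probe]
        if gene in genes:
            gene_rows[gene] = [float(v) for v in ds.values.loc[probe]]
    if not gene_rows:
        raise ValueError("no member gene present")
    tumor_mask = list(ds.tumor_mask())
    n_tumor = sum(tumor_mask)

    def score(tumor_idx: set[int]) -> float:
        ts = []
        for row in gene_rows.values():
            xs = [row[i] for i in range(n_samples) if i in tumor_idx]
            ys = [row[i] for i in range(n_samples) if i not in tumor_idx]
            ts.append(pooled_t(xs, ys))
        return sum(ts) / len(ts)

    observed = score({i for i, m in enumerate(tumor_mask) if m})
    ge = le = total = 0
    for combo in combinations(range(n_samples), n_tumor):
        s = score(set(combo))
        total += 1
        if s >= observed:
            ge += 1
        if s <= observed:
            le += 1
    return ge / total, le / total


def chisq_upper_tail_even_df(x: float, df: int) -> float:
    """Closed-form chi-square upper tail for even df:
    ``exp(-x/2) * sum_{j<df/2} (x/2)^j / j!``."""
    if df <= 0 or df % 2 != 0:
        raise ValueError("df must be a positive even integer")
    if x < 0:
        raise ValueError("x must be >= 0")
    half = x / 2.0
    total = 0.0
    term = 1.0
    for j in range(df // 2):
        if j > 0:
            term *= half / j
        total += term
    return math.exp(-half) * total


def hypergeom_upper_tail(n_background: int, n_pathway: int, n_sig: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(n_background, n_pathway, n_sig)."""
    denom = math.comb(n_background, n_sig)
    total = 0
    for i in range(x, min(n_pathway, n_sig) + 1):
        total += math.comb(n_pathway, i) * math.comb(n_background - n_pathway, n_sig - i)
    return total / denom


def hypergeom_upper_tail_enumerated(
    background: list[str], pathway: set[str], n_sig: int, x: int
) -> float:
    """Same tail probability by enumerating all significant-set draws.

    Feasible only for small backgrounds (C(|background|, n_sig) draws).
    """
    hits = total = 0
    for draw in combinations(background, n_sig):
        total += 1
        if len(pathway & set(draw)) >= x:
            hits += 1
    return hits / total
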