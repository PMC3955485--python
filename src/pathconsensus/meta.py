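"""Gene-level meta-analysis across cohorts by Fisher's combined probability.

Each cohort contributes an unpaired (pooled-variance) two-sided t-test p per
gene — the same statistic the pathway stage uses, shared implementation.
For a gene observed in k cohorts with p-values P_1..P_k,

    X^2 = -2 * sum_i ln(P_i),   df = 2k,

and the combined p is the upper-tail chi-square probability of X^2 at df.
Genes missing from some cohorts keep a reduced k rather than being dropped.
Significance at the meta level uses strict p < alpha (unlike the pathway
stage's <=, mirroring how the two stage rules are stated).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionDataset
from .errors import InvalidPValueError
from .gsea import gene_t_statistics

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

# two-sided t p-values can underflow to exactly 0.0 for extreme t; Fisher's
# combine rejects p = 0, so contributions are floored just above underflow
P_FLOOR = 1e-300


def unpaired_gene_p(ds: ExpressionDataset, gene: str) -> tuple[float, float]:
    """(t, two-sided p) for one gene of a preprocessed cohort."""
    tstats = gene_t_statistics(ds)
    if gene not in tstats.index:
        raise KeyError(f"{ds.dataset_id}: gene {gene!r} not present after preprocessing")
    row = tstats.loc[gene]
    return float(row["t"]), float(row["p_two_sided"])


def fisher_combine(pvalues) -> tuple[float, int, float]:
    """Fisher's method: (chi_square, df, p_combined) from k p-values.

    Natural logarithms; df = 2k; the combined p is the chi-square upper
    tail. p = 0 is a domain error (callers floor at the smallest
    representable p of their test); p outside (0, 1] is rejected.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise InvalidPValueError("need at least one p-value")
    if np.any(p == 0.0):
        raise InvalidPValueError("p = 0 is outside Fisher's domain; floor it first")
    if np.any((p < 0.0) | (p > 1.0)):
        raise InvalidPValueError(f"p-values outside (0, 1]: {p[(p < 0) | (p > 1)]}")
    chi_square = float(-2.0 * np.log(p).sum())
    df = 2 * int(p.size)
    p_combined = float(stats.chi2.sf(chi_square, df))
    return chi_square, df, max(p_combined, 0.0)


def run_meta(datasets: list[ExpressionDataset]) -> pd.DataFrame:
    """Fisher meta-analysis over every gene present in >= 1 cohort.

    Returns a DataFrame indexed by gene with one ``p_<dataset_id>`` and
    ``t_<dataset_id>`` column per cohort (NaN where the gene is absent),
    plus ``k``, ``chi_square``, ``df``, ``p_combined``, ``mean_t`` (average
    of contributing t statistics) and ``mean_direction`` in {UP, DOWN,
    UNDEFINED}.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    per_ds = {ds.dataset_id: gene_t_statistics(ds) for ds in datasets}
    all_genes = sorted(set().union(*(set(t.index) for t in per_ds.values())))

    cols: dict[str, pd.Series] = {}
    for ds_id, tstats in per_ds.items():
        cols[f"t_{ds_id}"] = tstats["t"].reindex(all_genes)
        cols[f"p_{ds_id}"] = tstats["p_two_sided"].reindex(all_genes)
    table = pd.DataFrame(cols, index=pd.Index(all_genes, name="gene"))

    p_cols = [c for c in table.columns if c.startswith("p_")]
    t_cols = [c for c in table.columns if c.startswith("t_")]
    pmat = table[p_cols].to_numpy()
    tmat = table[t_cols].to_numpy()

    k = (~np.isnan(pmat)).sum(axis=1)
    logs = np.where(np.isnan(pmat), 0.0, np.log(np.clip(pmat, P_FLOOR, 1.0)))
    chi_square = -2.0 * logs.sum(axis=1)
    df = 2 * k
    p_combined = stats.chi2.sf(chi_square, df)
    mean_t = np.nanmean(tmat, axis=1)
    sign = np.sign(mean_t)

    table["k"] = k
    table["chi_square"] = chi_square
    table["df"] = df
    table["p_combined"] = p_combined
    table["mean_t"] = mean_t
    table["mean_direction"] = np.where(
        sign > 0, "UP", np.where(sign < 0, "DOWN", "UNDEFINED")
    )
    n_undef = int((table["mean_direction"] == "UNDEFINED").sum())
    if n_undef:
        logger.warning("%d gene(s) with exactly zero mean t: direction UNDEFINED", n_undef)
    return table


def select_significant_genes(
    results: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> set[str]:
    """Genes with combined p strictly below ``alpha``."""
    return set(results.index[results["p_combined"] < alpha])
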