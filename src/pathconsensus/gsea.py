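"""Per-cohort pathway significance by sample-label permutation.

Each gene gets a classical equal-variance (pooled) two-sample Student's t
statistic, oriented TUMOR minus NORMAL. A pathway's score is the arithmetic
mean of its member genes' t statistics. Significance comes from permuting
sample group labels (group sizes preserved): for B permutations the whole
gene-level t vector is recomputed and every pathway rescored against one
shared shuffle stream, giving

    p_up   = (1 + #{permuted score >= observed}) / (B + 1)
    p_down = (1 + #{permuted score <= observed}) / (B + 1)

(the plus-one estimator counts the observed labeling in the null, so p
never reaches 0 and is floored at 1/(B+1)). An exhaustive mode replaces the
random stream with all distinct group-size-preserving label assignments,
identity included, and reports exact enumeration fractions.

A pathway enters the per-cohort up (down) set when p_up (p_down) <= alpha;
cross-cohort "common" pathways are the intersection of the per-cohort sets,
so a pathway significant up in some cohorts and down in others qualifies in
neither direction.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionDataset, GeneSetCollection

logger = logging.getLogger(__name__)

UP = "UP"
DOWN = "DOWN"

DEFAULT_PERMUTATIONS = 1000
DEFAULT_ALPHA = 0.05
_MAX_EXHAUSTIVE = 200_000  # refuse designs with more label assignments


def pooled_t_arrays(
    X: np.ndarray, tumor_mask: np.ndarray
) -> tuple[np.ndarray, int]:
    """Pooled-variance two-sample t per row of ``X`` (TUMOR minus NORMAL).

    Rows with zero pooled variance get t = 0 when the group means agree
    and +/-inf otherwise (callers flag those rows as degenerate).
    Returns (t, df) with df = n_T + n_N - 2.
    """
    X = np.asarray(X, dtype=float)
    t_cols = X[:, tumor_mask]
    n_cols = X[:, ~tumor_mask]
    n1, n2 = t_cols.shape[1], n_cols.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    m1 = t_cols.mean(axis=1)
    m2 = n_cols.mean(axis=1)
    ss = ((t_cols - m1[:, None]) ** 2).sum(axis=1) + (
        (n_cols - m2[:, None]) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    se = np.sqrt(ss / df * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t[(se == 0) & (diff == 0)] = 0.0
    t[(se == 0) & (diff > 0)] = np.inf
    t[(se == 0) & (diff < 0)] = -np.inf
    return t, df


def gene_t_statistics(ds: ExpressionDataset) -> pd.DataFrame:
    """Per-gene pooled two-sample t statistics for a preprocessed cohort.

    Returns a DataFrame indexed by gene symbol with columns ``t``, ``df``
    and ``p_two_sided``. Genes whose pooled variance is zero while the
    group means differ have an infinite t; they are excluded with a logged
    warning. Zero variance with equal means yields t = 0, p = 1.
    """
    X = ds.gene_matrix()
    t, df = pooled_t_arrays(X.to_numpy(), ds.tumor_mask())
    out = pd.DataFrame(
        {
            "t": t,
            "df": df,
            "p_two_sided": 2.0 * stats.t.sf(np.abs(t), df),
        },
        index=X.index,
    )
    bad = ~np.isfinite(out["t"])
    if bad.any():
        logger.warning(
            "%s: excluding %d degenerate gene(s) with zero pooled variance "
            "and nonzero mean difference: %s",
            ds.dataset_id,
            int(bad.sum()),
            list(out.index[bad][:10]),
        )
        out = out[~bad]
    return out


def pathway_score(tstats: pd.DataFrame, genes) -> float:
    """Mean member-gene t statistic; the pathway-level test statistic."""
    members = tstats.index.intersection(list(genes))
    if len(members) == 0:
        raise ValueError("no member gene present in the t-statistic table")
    return float(tstats.loc[members, "t"].mean())


def _permutation_masks(
    n_samples: int, n_tumor: int, n_permutations: int, seed: int
) -> np.ndarray:
    """(n_samples x B) boolean indicator of permuted TUMOR assignments."""
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_samples, n_permutations), dtype=bool)
    for b in range(n_permutations):
        idx = rng.permutation(n_samples)[:n_tumor]
        masks[idx, b] = True
    return masks


def _exhaustive_masks(n_samples: int, n_tumor: int) -> np.ndarray:
    from math import comb

    total = comb(n_samples, n_tumor)
    if total > _MAX_EXHAUSTIVE:
        raise ValueError(
            f"exhaustive enumeration of {total} assignments refused "
            f"(limit {_MAX_EXHAUSTIVE}); use the random stream"
        )
    masks = np.zeros((n_samples, total), dtype=bool)
    for b, idx in enumerate(combinations(range(n_samples), n_tumor)):
        masks[list(idx), b] = True
    return masks


def _t_matrix_for_masks(X: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """t statistics (genes x assignments) for many label assignments at once.

    Uses sum / sum-of-squares matmuls so the permutation loop is two BLAS
    calls. Cells with zero pooled variance map to t = 0 (under a continuous
    noise model this has probability zero; the guard keeps pathological
    inputs finite so pathway means stay defined).
    """
    X = np.asarray(X, dtype=float)
    n_genes, n_samples = X.shape
    n1 = int(masks[:, 0].sum())
    n2 = n_samples - n1
    ind = masks.astype(float)
    s1 = X @ ind
    q1 = (X**2) @ ind
    stot = X.sum(axis=1)[:, None]
    qtot = (X**2).sum(axis=1)[:, None]
    m1 = s1 / n1
    m2 = (stot - s1) / n2
    ss = (q1 - n1 * m1**2) + ((qtot - q1) - n2 * m2**2)
    ss = np.maximum(ss, 0.0)  # guard tiny negative rounding
    se = np.sqrt(ss / (n1 + n2 - 2) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    t[~np.isfinite(t)] = 0.0
    return t


def permutation_test(
    ds: ExpressionDataset,
    gsc: GeneSetCollection,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Permutation p-values for every pathway of one preprocessed cohort.

    Returns one row per pathway with >= 1 member gene present: pathway_id,
    n_genes_tested, score (observed mean t), p_up, p_down, direction
    (UP if p_up <= p_down else DOWN), p_perm = min(p_up, p_down),
    n_permutations and seed. Pathways with no member present are skipped
    with a logged warning. In exhaustive mode all group-size-preserving
    assignments are enumerated instead of sampled and exact fractions are
    reported (n_permutations then records the enumeration size).
    """
    if not exhaustive and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    tstats = gene_t_statistics(ds)
    genes_present = tstats.index
    X = ds.gene_matrix().loc[genes_present].to_numpy()
    tumor_mask = ds.tumor_mask()
    n_tumor = int(tumor_mask.sum())

    # pathway membership indicator over the tested genes
    ids, rows = [], []
    gene_pos = {g: i for i, g in enumerate(genes_present)}
    for pid in gsc.ids():
        members = [gene_pos[g] for g in gsc[pid].genes if g in gene_pos]
        if not members:
            logger.warning(
                "%s: pathway %s has no member gene in the dataset; skipped",
                ds.dataset_id,
                pid,
            )
            continue
        ids.append(pid)
        rows.append(members)
    if not ids:
        return pd.DataFrame(
            columns=[
                "pathway_id", "n_genes_tested", "score",
                "p_up", "p_down", "direction", "p_perm",
                "n_permutations", "seed",
            ]
        )
    M = np.zeros((len(ids), len(genes_present)))
    for i, members in enumerate(rows):
        M[i, members] = 1.0
    sizes = M.sum(axis=1)

    if exhaustive:
        masks = _exhaustive_masks(len(tumor_mask), n_tumor)
    else:
        masks = _permutation_masks(len(tumor_mask), n_tumor, n_permutations, seed)
    B = masks.shape[1]
    # observed mask stacked into the same BLAS call as the permutations so
    # the identity assignment ties the observed score bit-exactly
    stacked = np.concatenate([tumor_mask[:, None], masks], axis=1)
    all_t = _t_matrix_for_masks(X, stacked)
    all_scores = (M @ all_t) / sizes[:, None]
    obs_scores = all_scores[:, 0]
    perm_scores = all_scores[:, 1:]
    ge = (perm_scores >= obs_scores[:, None]).sum(axis=1)
    le = (perm_scores <= obs_scores[:, None]).sum(axis=1)
    if exhaustive:
        p_up = ge / B
        p_down = le / B
        n_reported = B
    else:
        p_up = (1.0 + ge) / (n_permutations + 1.0)
        p_down = (1.0 + le) / (n_permutations + 1.0)
        n_reported = n_permutations

    out = pd.DataFrame(
        {
            "pathway_id": ids,
            "n_genes_tested": sizes.astype(int),
            "score": obs_scores,
            "p_up": p_up,
            "p_down": p_down,
            "direction": np.where(p_up <= p_down, UP, DOWN),
            "p_perm": np.minimum(p_up, p_down),
            "n_permutations": n_reported,
            "seed": seed,
        }
    )
    return out


def significant_pathways(
    results: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> tuple[set[str], set[str]]:
    """Directional significant sets at ``alpha`` ("not more than" -> <=).

    If a pathway somehow passes both one-sided tests the smaller p wins;
    an exact tie is excluded with a warning.
    """
    up: set[str] = set()
    down: set[str] = set()
    for row in results.itertuples(index=False):
        pass_up = row.p_up <= alpha
        pass_down = row.p_down <= alpha
        if pass_up and pass_down:
            if row.p_up < row.p_down:
                up.add(row.pathway_id)
            elif row.p_down < row.p_up:
                down.add(row.pathway_id)
            else:
                logger.warning(
                    "pathway %s significant in both directions with tied p; excluded",
                    row.pathway_id,
                )
        elif pass_up:
            up.add(row.pathway_id)
        elif pass_down:
            down.add(row.pathway_id)
    return up, down


def common_pathways(
    per_dataset: list[tuple[set[str], set[str]]]
) -> tuple[set[str], set[str]]:
    """Cross-cohort intersection of the directional significant sets.

    A pathway must be significant with the same direction in every cohort;
    direction-discordant pathways fall out of both intersections.
    """
    if not per_dataset:
        return set(), set()
    up = set.intersection(*(set(u) for u, _ in per_dataset))
    down = set.intersection(*(set(d) for _, d in per_dataset))
    return up, down


def gsea_summary(
    ds: ExpressionDataset,
    tstats: pd.DataFrame,
    up: set[str],
    down: set[str],
    alpha: float = DEFAULT_ALPHA,
) -> dict:
    """One summary row per cohort: sizes, significant genes, pathway counts.

    "Significant genes" are genes whose two-sided t-test p is <= alpha.
    """
    groups = ds.group_of_sample
    return {
        "dataset": ds.dataset_id,
        "n_tumor": int((groups == "TUMOR").sum()),
        "n_normal": int((groups == "NORMAL").sum()),
        "n_genes_tested": int(len(tstats)),
        "n_significant_genes": int((tstats["p_two_sided"] <= alpha).sum()),
        "n_up_pathways": len(up),
        "n_down_pathways": len(down),
    }
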