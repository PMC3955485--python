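"""Local pathway over-representation of the meta-significant gene list.

The test is the one-sided hypergeometric upper tail (Fisher's exact
test): with a background of N pathway-annotated, tested genes, n of them
significant, and a pathway of K background members overlapping the
significant list in x genes,

    p_enrich = P(X >= x),  X ~ Hypergeometric(N, K, n).

Pathways with zero overlap are omitted (P(X >= 0) = 1 carries no
evidence). An optional EASE-style variant scores the tail on the overlap
reduced by one — the conservative correction familiar from annotation
servers; it is off by default.

Each enriched pathway gets an UP/DOWN label by majority vote over the
meta-analysis directions of its overlapping genes (tie -> sign of the
summed mean t; still tied -> UNDEFINED).
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .data_io import GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def hypergeometric_enrichment(
    sig_genes: set[str],
    gsc: GeneSetCollection,
    background: set[str],
    ease: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of every pathway with overlap >= 1.

    ``background`` is the pathway-annotated universe intersected with the
    genes actually tested; ``sig_genes`` must be a subset of it. Returns
    rows sorted by p_enrich ascending then pathway_id, with columns
    pathway_id, name, classification, n_overlap, n_pathway, n_sig,
    n_background, p_enrich and member_genes (sorted overlap list).
    """
    sig_genes = set(sig_genes)
    background = set(background)
    stray = sig_genes - background
    if stray:
        raise ValueError(
            f"significant genes outside the background: {sorted(stray)[:10]}"
        )
    n_background = len(background)
    n_sig = len(sig_genes)
    rows = []
    for pid in gsc.ids():
        gs = gsc[pid]
        members_bg = gs.genes & background
        overlap = sorted(members_bg & sig_genes)
        x = len(overlap)
        if x == 0:
            continue
        k_eff = x - 1 if ease else x
        p = float(stats.hypergeom.sf(k_eff - 1, n_background, len(members_bg), n_sig))
        rows.append(
            {
                "pathway_id": pid,
                "name": gs.name,
                "classification": gs.classification,
                "n_overlap": x,
                "n_pathway": len(members_bg),
                "n_sig": n_sig,
                "n_background": n_background,
                "p_enrich": min(p, 1.0),
                "member_genes": overlap,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "pathway_id", "name", "classification", "n_overlap", "n_pathway",
            "n_sig", "n_background", "p_enrich", "member_genes",
        ],
    )
    if len(out):
        out = out.sort_values(["p_enrich", "pathway_id"]).reset_index(drop=True)
    return out


def assign_direction(records: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Label each enriched pathway UP/DOWN from its overlapping genes.

    Majority vote over the genes' meta ``mean_direction``; an exact tie is
    broken by the sign of the overlapping genes' summed ``mean_t``; a zero
    sum leaves the direction UNDEFINED with a warning.
    """
    directions = []
    for row in records.itertuples(index=False):
        genes = [g for g in row.member_genes if g in meta.index]
        sub = meta.loc[genes]
        n_up = int((sub["mean_direction"] == "UP").sum())
        n_down = int((sub["mean_direction"] == "DOWN").sum())
        if n_up > n_down:
            directions.append("UP")
        elif n_down > n_up:
            directions.append("DOWN")
        else:
            net = float(sub["mean_t"].sum())
            if net > 0:
                directions.append("UP")
            elif net < 0:
                directions.append("DOWN")
            else:
                logger.warning(
                    "pathway %s direction undecidable (tied vote, zero net t)",
                    row.pathway_id,
                )
                directions.append("UNDEFINED")
    out = records.copy()
    out["direction"] = directions
    return out


def significant_enrichment(
    records: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> dict[str, str]:
    """Pathways with p_enrich < alpha, mapped to their direction label."""
    keep = records[records["p_enrich"] < alpha]
    return dict(zip(keep["pathway_id"], keep["direction"]))
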