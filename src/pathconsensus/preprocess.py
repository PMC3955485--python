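"""Per-cohort preprocessing: restrict to pathway-annotated genes, drop
low-variability probes, collapse multi-probe genes.

The pipeline order is restrict -> IQR filter -> collapse:

1. keep only probes whose gene symbol belongs to the pathway-annotated
   universe (probes with no gene symbol are dropped);
2. remove probes whose interquartile range across all samples (both groups
   pooled) is strictly below the cutoff (default 0.5 on the log2 scale;
   a probe sitting exactly at the cutoff is kept);
3. where several probes target one gene, retain the probe with the largest
   IQR (ties broken by lexicographically smallest probe id), leaving one
   row per gene sorted by gene symbol.

Quartiles use linear interpolation between order statistics (the q-th
quantile of n sorted values interpolates at position ``(n-1)*q``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import ExpressionDataset, GeneSetCollection
from .errors import EmptyDatasetError

DEFAULT_IQR_CUTOFF = 0.5


def compute_iqr(values) -> float:
    """Interquartile range Q3 - Q1 with linearly interpolated quartiles."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("IQR requires a 1-D sequence of at least 2 values")
    q1, q3 = np.quantile(arr, [0.25, 0.75], method="linear")
    return float(q3 - q1)


def probe_iqrs(ds: ExpressionDataset) -> pd.Series:
    """IQR of every probe across all samples (groups pooled)."""
    q1, q3 = np.quantile(ds.values.to_numpy(), [0.25, 0.75], axis=1, method="linear")
    return pd.Series(q3 - q1, index=ds.values.index, name="iqr")


def restrict_to_pathway_genes(
    ds: ExpressionDataset, gsc: GeneSetCollection
) -> ExpressionDataset:
    """Keep only probes whose gene is in the pathway-annotated universe."""
    universe = gsc.universe
    genes = ds.gene_of_probe.loc[ds.values.index]
    keep = ds.values.index[[g != "" and g in universe for g in genes]]
    if len(keep) == 0:
        raise EmptyDatasetError(
            f"{ds.dataset_id}: no probe maps to a pathway-annotated gene"
        )
    return ds.subset_probes(keep)


def filter_by_iqr(
    ds: ExpressionDataset, cutoff: float = DEFAULT_IQR_CUTOFF
) -> ExpressionDataset:
    """Drop probes with IQR strictly below ``cutoff`` (boundary kept)."""
    iqrs = probe_iqrs(ds)
    keep = iqrs.index[iqrs >= cutoff]
    if len(keep) == 0:
        raise EmptyDatasetError(
            f"{ds.dataset_id}: IQR filter at {cutoff} removed every probe"
        )
    return ds.subset_probes(keep)


def collapse_probes(ds: ExpressionDataset) -> ExpressionDataset:
    """One probe per gene: the max-IQR probe; ties -> smallest probe id.

    The retained row keeps its probe id; rows come out sorted by gene
    symbol. Applying the operation twice is the identity.
    """
    iqrs = probe_iqrs(ds)
    info = pd.DataFrame(
        {
            "probe": ds.values.index,
            "gene": ds.gene_of_probe.loc[ds.values.index].to_numpy(),
            "iqr": iqrs.to_numpy(),
        }
    )
    # max IQR wins; lexicographic probe id breaks exact ties deterministically
    info = info.sort_values(["gene", "iqr", "probe"], ascending=[True, False, True])
    winners = info.drop_duplicates("gene", keep="first")["probe"].tolist()
    return ExpressionDataset(  # winners are already in gene-sorted order
        dataset_id=ds.dataset_id,
        values=ds.values.loc[winners].copy(),
        gene_of_probe=ds.gene_of_probe.loc[winners].copy(),
        group_of_sample=ds.group_of_sample.copy(),
        pair_of_sample=None if ds.pair_of_sample is None else ds.pair_of_sample.copy(),
    )


def preprocess(
    ds: ExpressionDataset,
    gsc: GeneSetCollection,
    iqr_cutoff: float = DEFAULT_IQR_CUTOFF,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Run restrict -> filter -> collapse; return the result plus an audit.

    The audit table has one row per input probe: probe, gene, iqr, kept
    (bool) and the reason a probe was removed (``unannotated``,
    ``low_iqr``, ``collapsed`` or empty for survivors).
    """
    universe = gsc.universe
    iqrs = probe_iqrs(ds)
    genes = ds.gene_of_probe.loc[ds.values.index]

    restricted = restrict_to_pathway_genes(ds, gsc)
    filtered = filter_by_iqr(restricted, iqr_cutoff)
    collapsed = collapse_probes(filtered)
    survivors = set(collapsed.values.index)
    after_filter = set(filtered.values.index)

    reasons = []
    for probe in ds.values.index:
        gene = genes.loc[probe]
        if probe in survivors:
            reasons.append("")
        elif gene == "" or gene not in universe:
            reasons.append("unannotated")
        elif iqrs.loc[probe] < iqr_cutoff:
            reasons.append("low_iqr")
        elif probe in after_filter:
            reasons.append("collapsed")
        else:  # pragma: no cover - exhaustive above
            reasons.append("removed")
    audit = pd.DataFrame(
        {
            "probe": ds.values.index,
            "gene": genes.to_numpy(),
            "iqr": iqrs.to_numpy(),
            "kept": [p in survivors for p in ds.values.index],
            "reason": reasons,
        }
    )
    return collapsed, audit
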