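"""Shared data model and readers/writers for every on-disk format.

Formats are plain UTF-8 text throughout: tab-delimited expression matrices
(probes x samples, first column the probe id), sample-annotation TSV
(``sample_id``, ``group``, optional ``pair``), probe-map TSV (``probe_id``,
``gene_symbol``), GMT gene-set files, and tab-delimited result tables.

Group labels are normalized to the canonical strings ``TUMOR`` / ``NORMAL``
(case-insensitive on read). The GMT description field is overloaded as
``name|classification`` so pathway classification labels survive the format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIDError,
    GMTParseError,
    MissingAnnotationError,
    NonNumericValueError,
    UnknownGroupError,
)

TUMOR = "TUMOR"
NORMAL = "NORMAL"
GROUPS = (TUMOR, NORMAL)


@dataclass
class ExpressionDataset:
    """One cohort: a log2 intensity matrix plus probe and sample metadata.

    Parameters
    ----------
    dataset_id:
        Free-text cohort label (e.g. a GEO-style accession).
    values:
        DataFrame of log2 intensities, index = probe ids, columns = sample
        ids. No missing values are permitted.
    gene_of_probe:
        Series mapping probe id -> gene symbol; the empty string marks a
        probe with no gene annotation (retained on load, dropped by
        preprocessing).
    group_of_sample:
        Series mapping sample id -> ``TUMOR`` or ``NORMAL``.
    pair_of_sample:
        Optional Series mapping sample id -> pair label. Stored but unused
        by the statistics (the analysis deliberately applies unpaired tests).
    """

    dataset_id: str
    values: pd.DataFrame
    gene_of_probe: pd.Series
    group_of_sample: pd.Series
    pair_of_sample: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DuplicateIDError(
                f"{self.dataset_id}: duplicate probe id {dup!r}"
            )
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DuplicateIDError(
                f"{self.dataset_id}: duplicate sample id {dup!r}"
            )
        if self.values.isna().any().any():
            probe = self.values.index[self.values.isna().any(axis=1)][0]
            raise NonNumericValueError(
                f"{self.dataset_id}: missing/non-numeric value at probe {probe!r}"
            )
        missing = set(self.values.columns) - set(self.group_of_sample.index)
        if missing:
            raise MissingAnnotationError(
                f"{self.dataset_id}: samples without annotation: {sorted(missing)}"
            )
        bad = self.group_of_sample[~self.group_of_sample.isin(GROUPS)]
        if len(bad):
            raise UnknownGroupError(
                f"{self.dataset_id}: unknown group {bad.iloc[0]!r} "
                f"for sample {bad.index[0]!r}"
            )
        # align metadata to the matrix ordering
        self.gene_of_probe = self.gene_of_probe.reindex(
            self.values.index, fill_value=""
        ).fillna("")
        self.group_of_sample = self.group_of_sample.loc[self.values.columns]
        if self.pair_of_sample is not None:
            self.pair_of_sample = self.pair_of_sample.reindex(self.values.columns)

    # -- conveniences --------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.group_of_sample.index[self.group_of_sample == group])

    def tumor_mask(self) -> np.ndarray:
        """Boolean array over sample columns, True for TUMOR."""
        return (self.group_of_sample.loc[self.values.columns] == TUMOR).to_numpy()

    def subset_probes(self, probes) -> "ExpressionDataset":
        """Return a dataset restricted to ``probes`` (order preserved)."""
        probes = [p for p in self.values.index if p in set(probes)]
        return ExpressionDataset(
            dataset_id=self.dataset_id,
            values=self.values.loc[probes].copy(),
            gene_of_probe=self.gene_of_probe.loc[probes].copy(),
            group_of_sample=self.group_of_sample.copy(),
            pair_of_sample=None
            if self.pair_of_sample is None
            else self.pair_of_sample.copy(),
        )

    def gene_matrix(self) -> pd.DataFrame:
        """Matrix re-indexed by gene symbol; requires one probe per gene."""
        genes = self.gene_of_probe.loc[self.values.index]
        if genes.duplicated().any():
            raise ValueError(
                f"{self.dataset_id}: gene symbols not unique; collapse probes first"
            )
        out = self.values.copy()
        out.index = pd.Index(genes.to_numpy(), name="gene")
        return out

    def equals(self, other: "ExpressionDataset") -> bool:
        same = (
            self.dataset_id == other.dataset_id
            and self.values.equals(other.values)
            and self.gene_of_probe.equals(other.gene_of_probe)
            and self.group_of_sample.equals(other.group_of_sample)
        )
        if not same:
            return False
        if (self.pair_of_sample is None) != (other.pair_of_sample is None):
            return False
        if self.pair_of_sample is not None:
            return bool(self.pair_of_sample.equals(other.pair_of_sample))
        return True


@dataclass(frozen=True)
class GeneSet:
    name: str
    classification: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """Pathway id -> (name, classification, member gene symbols)."""

    entries: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.entries

    def __getitem__(self, pathway_id: str) -> GeneSet:
        return self.entries[pathway_id]

    def ids(self) -> list[str]:
        return list(self.entries)

    @property
    def universe(self) -> frozenset[str]:
        """Union of all member genes: the pathway-annotated universe."""
        out: set[str] = set()
        for gs in self.entries.values():
            out |= gs.genes
        return frozenset(out)

    def add(self, pathway_id: str, name: str, classification: str, genes) -> None:
        if pathway_id in self.entries:
            raise DuplicateIDError(f"duplicate pathway id {pathway_id!r}")
        genes = frozenset(genes)
        if not genes:
            raise GMTParseError(f"gene set {pathway_id!r} is empty")
        self.entries[pathway_id] = GeneSet(name, classification, genes)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(
    matrix_path, annotation_path, probe_map_path, dataset_id: str | None = None
) -> ExpressionDataset:
    """Load one cohort from its three tab-delimited files.

    Probes absent from the probe map get an empty gene symbol and are
    retained (preprocessing drops them later). Every validation failure
    raises a distinct :mod:`pathconsensus.errors` class.
    """
    matrix_path = Path(matrix_path)
    # pandas mangles duplicate header fields; check the raw header first
    with open(matrix_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise DuplicateIDError(f"{matrix_path}: duplicate sample id {col!r}")
        seen.add(col)
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise DuplicateIDError(f"{matrix_path}: duplicate probe id {dup!r}")
    coerced = raw.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna()
    if bad.any().any():
        probe = coerced.index[bad.any(axis=1)][0]
        sample = coerced.columns[bad.loc[probe]][0]
        raise NonNumericValueError(
            f"{matrix_path}: non-numeric or missing cell at "
            f"probe {probe!r}, sample {sample!r}"
        )
    # numpy's string->float conversion is correctly rounded (exact text
    # round-trip); pandas' fast parser can be 1 ulp off
    values = pd.DataFrame(
        np.asarray(raw.to_numpy(), dtype=float),
        index=raw.index,
        columns=raw.columns,
    )

    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    if "sample_id" not in ann.columns or "group" not in ann.columns:
        raise MissingAnnotationError(
            f"{annotation_path}: expected columns sample_id, group"
        )
    if ann["sample_id"].duplicated().any():
        dup = ann.loc[ann["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DuplicateIDError(f"{annotation_path}: duplicate sample id {dup!r}")
    ann = ann.set_index("sample_id")
    missing = [s for s in values.columns if s not in ann.index]
    if missing:
        raise MissingAnnotationError(
            f"{annotation_path}: no annotation for matrix samples {missing}"
        )
    groups = ann["group"].str.upper().str.strip()
    unknown = groups[~groups.isin(GROUPS)]
    if len(unknown):
        raise UnknownGroupError(
            f"{annotation_path}: unknown group {ann['group'].loc[unknown.index[0]]!r} "
            f"for sample {unknown.index[0]!r}"
        )
    pair = None
    if "pair" in ann.columns and ann["pair"].notna().any():
        pair = ann["pair"].reindex(values.columns)

    pm = pd.read_csv(probe_map_path, sep="\t", dtype=str)
    if "probe_id" not in pm.columns or "gene_symbol" not in pm.columns:
        raise GMTParseError(
            f"{probe_map_path}: expected columns probe_id, gene_symbol"
        )
    if pm["probe_id"].duplicated().any():
        dup = pm.loc[pm["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise DuplicateIDError(f"{probe_map_path}: duplicate probe id {dup!r}")
    gene_of_probe = (
        pm.set_index("probe_id")["gene_symbol"]
        .reindex(values.index, fill_value="")
        .fillna("")
    )

    if dataset_id is None:
        dataset_id = matrix_path.stem
        if dataset_id.endswith("_matrix"):  # our own writers' naming convention
            dataset_id = dataset_id[: -len("_matrix")]
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=values,
        gene_of_probe=gene_of_probe,
        group_of_sample=groups.reindex(values.columns),
        pair_of_sample=pair,
    )


def write_expression(ds: ExpressionDataset, matrix_path, annotation_path, probe_map_path) -> None:
    """Write one cohort back to the three tab-delimited files."""
    out = ds.values.copy()
    out.index.name = "probe_id"
    # 17 significant digits: float64 round-trips exactly through text
    out.to_csv(matrix_path, sep="\t", float_format="%.17g")

    ann = pd.DataFrame(
        {
            "sample_id": ds.values.columns,
            "group": ds.group_of_sample.loc[ds.values.columns].to_numpy(),
        }
    )
    if ds.pair_of_sample is not None:
        ann["pair"] = ds.pair_of_sample.loc[ds.values.columns].to_numpy()
    ann.to_csv(annotation_path, sep="\t", index=False)

    pm = pd.DataFrame(
        {
            "probe_id": ds.values.index,
            "gene_symbol": ds.gene_of_probe.loc[ds.values.index].to_numpy(),
        }
    )
    pm.to_csv(probe_map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file; the description field carries ``name|classification``."""
    gsc = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            pathway_id, desc = fields[0], fields[1]
            name, _, classification = desc.partition("|")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise GMTParseError(f"{path}: line {lineno}: empty gene set")
            if pathway_id in gsc:
                raise DuplicateIDError(
                    f"{path}: line {lineno}: duplicate pathway id {pathway_id!r}"
                )
            gsc.add(pathway_id, name, classification, genes)
    return gsc


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, gs in gsc.entries.items():
            desc = f"{gs.name}|{gs.classification}"
            fh.write("\t".join([pid, desc, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# result tables


def write_table(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV; floats keep >= 6 significant digits."""
    cols = list(table.columns)
    if len(cols) != len(set(cols)) or any(not str(c) for c in cols):
        raise ValueError("table column names must be non-empty and unique")
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
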