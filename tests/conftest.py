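import numpy as np
import pandas as pd
import pytest

from pathconsensus import ExpressionDataset, GeneSetCollection, SimulationConfig, simulate_study
from pathconsensus.data_io import NORMAL, TUMOR


def make_dataset(
    values: np.ndarray,
    genes: list[str],
    n_tumor: int,
    dataset_id: str = "toy",
    probes: list[str] | None = None,
) -> ExpressionDataset:
    """Small in-memory cohort: first ``n_tumor`` columns are TUMOR."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probes = probes or [f"p{i:03d}" for i in range(n_probes)]
    samples = [f"T{i}" for i in range(n_tumor)] + [
        f"N{i}" for i in range(n_samples - n_tumor)
    ]
    groups = [TUMOR] * n_tumor + [NORMAL] * (n_samples - n_tumor)
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=pd.DataFrame(values, index=probes, columns=samples),
        gene_of_probe=pd.Series(genes, index=probes),
        group_of_sample=pd.Series(groups, index=samples),
    )


def make_collection(sets: dict[str, list[str]]) -> GeneSetCollection:
    gsc = GeneSetCollection()
    for pid, genes in sets.items():
        gsc.add(pid, f"name {pid}", "Test class", genes)
    return gsc


@pytest.fixture
def toy_files(tmp_path):
    """3-probe x 4-sample cohort written as the three TSV files."""
    (tmp_path / "matrix.tsv").write_text(
        "probe_id\tS1\tS2\tS3\tS4\n"
        "p1\t1.0\t2.0\t3.0\t4.0\n"
        "p2\t5.5\t6.5\t7.5\t8.5\n"
        "p3\t0.1\t0.2\t0.3\t0.4\n"
    )
    (tmp_path / "annotation.tsv").write_text(
        "sample_id\tgroup\tpair\nS1\ttumor\tA\nS2\tTumor\tB\nS3\tNORMAL\tA\nS4\tnormal\tB\n"
    )
    (tmp_path / "probe_map.tsv").write_text(
        "probe_id\tgene_symbol\np1\tIDH1\np2\tFH\n"
    )
    return (
        tmp_path / "matrix.tsv",
        tmp_path / "annotation.tsv",
        tmp_path / "probe_map.tsv",
    )


@pytest.fixture(scope="session")
def small_study():
    """A modest planted study shared by read-only tests."""
    cfg = SimulationConfig(
        n_datasets=2,
        samples_per_group=(6, 8),
        n_genes=300,
        n_pathways=15,
        genes_per_pathway=12,
        probes_per_gene=(1, 2),
        seed=11,
    )
    return simulate_study(cfg), cfg
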