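import numpy as np
import pandas as pd
import pytest

from pathconsensus import (
    build_report,
    format_gene_cell,
    intersect_pathways,
    parse_gene_cell,
    run_all,
)
from pathconsensus.consensus import format_p_value


def _enrichment_records(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "pathway_id", "name", "classification", "n_overlap", "n_pathway",
            "n_sig", "n_background", "p_enrich", "member_genes", "direction",
        ],
    )


def _meta(genes_p):
    return pd.DataFrame(
        {
            "p_combined": list(genes_p.values()),
            "mean_t": [1.0] * len(genes_p),
            "mean_direction": ["UP"] * len(genes_p),
        },
        index=pd.Index(genes_p.keys(), name="gene"),
    )


class TestIntersectPathways:
    def test_set_logic(self):
        records = _enrichment_records(
            [
                ("B", "b", "c", 1, 2, 3, 10, 0.01, ["g1"], "UP"),
                ("C", "c", "c", 1, 2, 3, 10, 0.02, ["g2"], "DOWN"),
            ]
        )
        meta = _meta({"g1": 0.001, "g2": 0.002})
        out = intersect_pathways({"A", "B"}, set(), records, meta)
        assert list(out["pathway_id"]) == ["B"]
        assert out.loc[0, "direction"] == "UP"

    def test_direction_conflict_excluded(self, caplog):
        records = _enrichment_records(
            [("A", "a", "c", 1, 2, 3, 10, 0.01, ["g1"], "DOWN")]
        )
        meta = _meta({"g1": 0.001})
        with caplog.at_level("WARNING"):
            out = intersect_pathways({"A"}, set(), records, meta)
        assert len(out) == 0
        assert "conflict" in caplog.text

    def test_disjoint_inputs_give_empty_report(self):
        records = _enrichment_records(
            [("Z", "z", "c", 1, 2, 3, 10, 0.01, ["g1"], "UP")]
        )
        out = intersect_pathways({"A"}, {"B"}, records, _meta({"g1": 0.001}))
        assert len(out) == 0

    def test_key_genes_meta_significant_and_sorted(self):
        records = _enrichment_records(
            [("A", "a", "c", 3, 5, 3, 10, 0.001, ["g1", "g2", "g3"], "UP")]
        )
        meta = _meta({"g1": 0.04, "g2": 0.002, "g3": 0.2})
        out = intersect_pathways({"A"}, set(), records, meta)
        assert out.loc[0, "key_genes"] == [("g2", 0.002), ("g1", 0.04)]
        assert out.loc[0, "n_key_genes"] == 2


class TestReportFormatting:
    def test_report_style_cell(self):
        assert format_gene_cell([("FH", 8.33e-05)]) == "FH(8.33E-05)"

    def test_parse_is_inverse_of_format(self):
        genes = [("FH", 8.33e-05), ("IDH2", 4.67e-07), ("MDH2", 0.04143)]
        assert parse_gene_cell(format_gene_cell(genes)) == [
            (g, float(format_p_value(p))) for g, p in genes
        ]

    def test_empty_consensus_builds_header_only_table(self):
        report = build_report(pd.DataFrame())
        assert len(report) == 0
        assert "key_genes" in report.columns

    def test_n_key_genes_matches_parsed_cell(self):
        records = _enrichment_records(
            [("A", "a", "c", 2, 5, 2, 10, 0.001, ["g1", "g2"], "UP")]
        )
        meta = _meta({"g1": 0.01, "g2": 0.02})
        report = build_report(intersect_pathways({"A"}, set(), records, meta))
        for row in report.itertuples(index=False):
            assert row.n_key_genes == len(parse_gene_cell(row.key_genes))


SMALL_CONFIG = {
    "simulate": {
        "n_datasets": 2,
        "samples_per_group": [5, 6],
        "n_genes": 150,
        "n_pathways": 10,
        "genes_per_pathway": 12,
        "probes_per_gene": [1, 2],
        "effect_size": 2.0,
        "seed": 23,
    },
    "gsea": {"n_permutations": 200, "seed": 7},
}


@pytest.fixture(scope="module")
def outcome(tmp_path_factory):
    out_dir = tmp_path_factory.mktemp("pipeline")
    return run_all(SMALL_CONFIG, out_dir), out_dir


class TestRunAll:
    def test_all_stage_outputs_present(self, outcome):
        _, out_dir = outcome
        expected = [
            "simulated/SIM1_matrix.tsv",
            "simulated/gene_sets.gmt",
            "simulated/ground_truth.tsv",
            "preprocessed/SIM1_matrix.tsv",
            "preprocessed/SIM1_audit.tsv",
            "gsea/SIM1_pathways.tsv",
            "gsea/summary.tsv",
            "meta/gene_results.tsv",
            "meta/significant_genes.txt",
            "enrichment/pathways.tsv",
            "consensus/report.tsv",
            "run_log.txt",
        ]
        for rel in expected:
            assert (out_dir / rel).is_file(), rel

    def test_strong_planted_up_pathway_reaches_report(self, outcome):
        results, _ = outcome
        truth = results["ground_truth"]
        report = results["report"]
        in_report = dict(zip(report["pathway_id"], report["direction"]))
        recovered_up = truth.up_pathways & set(in_report)
        assert recovered_up  # delta=2 effects are essentially always found
        for pid in recovered_up:
            assert in_report[pid] == "UP"

    def test_consensus_subset_of_sources(self, outcome):
        results, _ = outcome
        report_ids = set(results["report"]["pathway_id"])
        assert report_ids <= (results["common_up"] | results["common_down"])
        enriched = set(results["enrichment"]["pathway_id"])
        assert report_ids <= enriched

    def test_direction_concordance_in_report(self, outcome):
        results, _ = outcome
        for row in results["report"].itertuples(index=False):
            if row.direction == "UP":
                assert row.pathway_id in results["common_up"]
            else:
                assert row.pathway_id in results["common_down"]

    def test_null_study_yields_alpha_level_consensus_only(self, tmp_path):
        config = {
            "simulate": {
                **SMALL_CONFIG["simulate"],
                "effect_size": 0.0,
                "iqr_decoy_frac": 0.0,
            },
            "gsea": {"n_permutations": 200, "seed": 3},
        }
        results = run_all(config, tmp_path / "null")
        # needing joint GSEA+enrichment significance, far below alpha*n_pathways
        assert len(results["report"]) <= 2
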