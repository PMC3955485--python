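"""Consensus between the permutation-GSEA pathway sets and the
meta-analysis enrichment set, plus end-to-end orchestration.

A pathway is a consensus pathway iff it is significant with a direction in
every cohort's permutation analysis (the cross-cohort common sets), it is
significantly over-represented in the meta-significant gene list, and the
two directions agree. Each consensus row carries its "key genes": the
pathway's meta-significant members (combined p < 0.05), rendered in the
report as comma-joined ``GENE(p)`` cells, e.g. ``FH(8.33E-05)``.

:func:`run_all` wires the whole pipeline (simulate -> preprocess -> GSEA ->
meta -> enrichment -> consensus), writing every intermediate table and a
run log; two runs with an identical configuration produce bit-identical
output trees.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .data_io import (
    ExpressionDataset,
    GeneSetCollection,
    read_expression,
    read_gmt,
    write_expression,
    write_gmt,
    write_table,
)
from .enrichment import (
    assign_direction,
    hypergeometric_enrichment,
    significant_enrichment,
)
from .errors import ConfigError
from .gsea import (
    common_pathways,
    gene_t_statistics,
    gsea_summary,
    permutation_test,
    significant_pathways,
)
from .meta import run_meta, select_significant_genes
from .preprocess import preprocess
from .simulate import config_from_dict, ground_truth_table, simulate_study

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# report-cell formatting


def format_p_value(p: float) -> str:
    """Render a p-value with 3 significant digits, uppercase exponent."""
    return f"{float(p):.3G}"


def format_gene_cell(genes: list[tuple[str, float]]) -> str:
    """``[('FH', 8.33e-05)] -> 'FH(8.33E-05)'``; entries comma-joined."""
    return ", ".join(f"{g}({format_p_value(p)})" for g, p in genes)


_GENE_CELL_RE = re.compile(r"^\s*(?P<gene>[^()\s,]+)\((?P<p>[^()]+)\)\s*$")


def parse_gene_cell(cell: str) -> list[tuple[str, float]]:
    """Inverse of :func:`format_gene_cell`."""
    if not cell or not str(cell).strip():
        return []
    out = []
    for part in str(cell).split(","):
        m = _GENE_CELL_RE.match(part.strip())
        if not m:
            raise ValueError(f"malformed gene cell entry: {part!r}")
        out.append((m.group("gene"), float(m.group("p"))))
    return out


# ---------------------------------------------------------------------------
# consensus


def intersect_pathways(
    gsea_up: set[str],
    gsea_down: set[str],
    enriched_records: pd.DataFrame,
    meta: pd.DataFrame,
    enrich_alpha: float = 0.05,
    gene_alpha: float = 0.05,
) -> pd.DataFrame:
    """Consensus pathways: GSEA-common AND enriched AND direction-concordant.

    ``enriched_records`` is the direction-labelled enrichment table;
    ``meta`` the gene-level meta table (indexed by gene). Key genes are the
    pathway's overlapping genes with combined p < ``gene_alpha``, sorted by
    combined p ascending. Rows come out sorted by pathway_id; an empty
    consensus is a valid outcome.
    """
    enriched = significant_enrichment(enriched_records, enrich_alpha)
    records_by_id = {
        r.pathway_id: r for r in enriched_records.itertuples(index=False)
    }
    rows = []
    for pid, enrich_dir in sorted(enriched.items()):
        if pid in gsea_up:
            gsea_dir = "UP"
        elif pid in gsea_down:
            gsea_dir = "DOWN"
        else:
            continue
        if gsea_dir != enrich_dir:
            logger.warning(
                "pathway %s direction conflict (GSEA %s vs enrichment %s); excluded",
                pid, gsea_dir, enrich_dir,
            )
            continue
        rec = records_by_id[pid]
        key = [
            (g, float(meta.loc[g, "p_combined"]))
            for g in rec.member_genes
            if g in meta.index and meta.loc[g, "p_combined"] < gene_alpha
        ]
        key.sort(key=lambda gp: (gp[1], gp[0]))
        rows.append(
            {
                "pathway_id": pid,
                "name": rec.name,
                "classification": rec.classification,
                "direction": gsea_dir,
                "p_enrich": rec.p_enrich,
                "n_key_genes": len(key),
                "key_genes": key,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway_id", "name", "classification", "direction",
            "p_enrich", "n_key_genes", "key_genes",
        ],
    )


def build_report(consensus: pd.DataFrame) -> pd.DataFrame:
    """Flatten the consensus into the final writable report table."""
    if len(consensus) == 0:
        return pd.DataFrame(
            columns=[
                "pathway_id", "name", "classification", "direction",
                "p_enrich", "n_key_genes", "key_genes",
            ]
        )
    out = consensus.sort_values("pathway_id").reset_index(drop=True).copy()
    out["key_genes"] = out["key_genes"].map(format_gene_cell)
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline


_DEFAULTS = {
    "preprocess": {"iqr_cutoff": 0.5},
    "gsea": {"n_permutations": 1000, "alpha": 0.05, "seed": 0, "exhaustive": False},
    "meta": {"alpha": 0.05},
    "enrichment": {"alpha": 0.05, "ease": False},
}


def _stage_params(config: dict, stage: str) -> dict:
    params = dict(_DEFAULTS[stage])
    extra = config.get(stage, {}) or {}
    unknown = set(extra) - set(params)
    if unknown:
        raise ConfigError(f"unknown {stage} config keys: {sorted(unknown)}")
    params.update(extra)
    return params


def load_pipeline_inputs(
    config: dict,
) -> tuple[list[ExpressionDataset], GeneSetCollection, object | None]:
    """Resolve the input block: either ``simulate:`` or ``inputs:``+``gmt:``."""
    if "simulate" in config:
        sim_cfg = config_from_dict(config.get("simulate") or {})
        datasets, gsc, truth = simulate_study(sim_cfg)
        return datasets, gsc, truth
    if "inputs" not in config or "gmt" not in config:
        raise ConfigError("config needs either a 'simulate' block or 'inputs' + 'gmt'")
    datasets = [
        read_expression(
            item["matrix"], item["annotation"], item["probe_map"],
            dataset_id=item.get("id"),
        )
        for item in config["inputs"]
    ]
    return datasets, read_gmt(config["gmt"]), None


def run_all(config: dict, out_dir) -> dict:
    """Execute the full pipeline and write every stage artifact.

    Returns a dict with the in-memory results of each stage (datasets,
    preprocessed cohorts, per-cohort pathway tables, GSEA common sets,
    meta table, enrichment table, consensus report, ground truth if
    simulated). Any stage failure propagates with the stage named.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    datasets, gsc, truth = load_pipeline_inputs(config)

    if truth is not None:
        sim_dir = out_dir / "simulated"
        sim_dir.mkdir(exist_ok=True)
        for ds in datasets:
            write_expression(
                ds,
                sim_dir / f"{ds.dataset_id}_matrix.tsv",
                sim_dir / f"{ds.dataset_id}_annotation.tsv",
                sim_dir / f"{ds.dataset_id}_probe_map.tsv",
            )
        write_gmt(gsc, sim_dir / "gene_sets.gmt")
        write_table(ground_truth_table(truth), sim_dir / "ground_truth.tsv")

    pp = _stage_params(config, "preprocess")
    pre_dir = out_dir / "preprocessed"
    pre_dir.mkdir(exist_ok=True)
    preprocessed = []
    for ds in datasets:
        reduced, audit = preprocess(ds, gsc, iqr_cutoff=pp["iqr_cutoff"])
        preprocessed.append(reduced)
        write_expression(
            reduced,
            pre_dir / f"{reduced.dataset_id}_matrix.tsv",
            pre_dir / f"{reduced.dataset_id}_annotation.tsv",
            pre_dir / f"{reduced.dataset_id}_probe_map.tsv",
        )
        write_table(audit, pre_dir / f"{reduced.dataset_id}_audit.tsv")

    gp = _stage_params(config, "gsea")
    gsea_dir = out_dir / "gsea"
    gsea_dir.mkdir(exist_ok=True)
    per_dataset_sets = []
    summaries = []
    pathway_tables = {}
    for i, ds in enumerate(preprocessed):
        results = permutation_test(
            ds, gsc,
            n_permutations=gp["n_permutations"],
            seed=int(gp["seed"]) + i,
            exhaustive=gp["exhaustive"],
        )
        pathway_tables[ds.dataset_id] = results
        write_table(results, gsea_dir / f"{ds.dataset_id}_pathways.tsv")
        up, down = significant_pathways(results, alpha=gp["alpha"])
        per_dataset_sets.append((up, down))
        summaries.append(
            gsea_summary(ds, gene_t_statistics(ds), up, down, alpha=gp["alpha"])
        )
    write_table(pd.DataFrame(summaries), gsea_dir / "summary.tsv")
    common_up, common_down = common_pathways(per_dataset_sets)

    mp = _stage_params(config, "meta")
    meta_dir = out_dir / "meta"
    meta_dir.mkdir(exist_ok=True)
    meta_table = run_meta(preprocessed)
    out_meta = meta_table.reset_index().rename(columns={"index": "gene"})
    write_table(out_meta, meta_dir / "gene_results.tsv")
    sig_genes = select_significant_genes(meta_table, alpha=mp["alpha"])
    (meta_dir / "significant_genes.txt").write_text(
        "\n".join(sorted(sig_genes)) + ("\n" if sig_genes else "")
    )

    ep = _stage_params(config, "enrichment")
    enr_dir = out_dir / "enrichment"
    enr_dir.mkdir(exist_ok=True)
    background = set(meta_table.index) & set(gsc.universe)
    records = hypergeometric_enrichment(
        sig_genes & background, gsc, background, ease=ep["ease"]
    )
    records = assign_direction(records, meta_table)
    writable = records.copy()
    if len(writable):
        writable["member_genes"] = writable["member_genes"].map(",".join)
    write_table(writable, enr_dir / "pathways.tsv")

    cons_dir = out_dir / "consensus"
    cons_dir.mkdir(exist_ok=True)
    consensus = intersect_pathways(
        common_up, common_down, records, meta_table,
        enrich_alpha=ep["alpha"], gene_alpha=mp["alpha"],
    )
    report = build_report(consensus)
    write_table(report, cons_dir / "report.tsv")

    _write_run_log(
        out_dir / "run_log.txt", config, datasets, preprocessed,
        per_dataset_sets, common_up, common_down, sig_genes, records, report,
        gp, mp, ep, pp,
    )
    return {
        "datasets": datasets,
        "gene_sets": gsc,
        "ground_truth": truth,
        "preprocessed": preprocessed,
        "pathway_tables": pathway_tables,
        "per_dataset_sets": per_dataset_sets,
        "common_up": common_up,
        "common_down": common_down,
        "meta": meta_table,
        "significant_genes": sig_genes,
        "enrichment": records,
        "consensus": consensus,
        "report": report,
    }


def _write_run_log(
    path, config, datasets, preprocessed, per_dataset_sets,
    common_up, common_down, sig_genes, records, report, gp, mp, ep, pp,
) -> None:
    lines = [
        f"pathconsensus {__version__}",
        "config:",
        yaml.safe_dump(config, sort_keys=True).rstrip(),
        f"iqr_cutoff: {pp['iqr_cutoff']}",
        f"gsea: permutations={gp['n_permutations']} alpha={gp['alpha']} "
        f"base_seed={gp['seed']} exhaustive={gp['exhaustive']}",
        f"meta: alpha={mp['alpha']}",
        f"enrichment: alpha={ep['alpha']} ease={ep['ease']}",
    ]
    for ds, reduced, (up, down) in zip(datasets, preprocessed, per_dataset_sets):
        lines.append(
            f"dataset {ds.dataset_id}: probes {ds.n_probes} -> {reduced.n_probes}, "
            f"samples {ds.n_samples}, up {len(up)}, down {len(down)}"
        )
    lines += [
        f"common pathways: up {len(common_up)}, down {len(common_down)}",
        f"meta significant genes: {len(sig_genes)}",
        f"enriched pathways tested: {len(records)}",
        f"consensus pathways: {len(report)}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
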