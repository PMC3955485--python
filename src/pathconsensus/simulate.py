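"""Synthetic multi-cohort tumor/normal expression studies with planted
pathway effects.

The generator emulates three paired cohorts (7/7, 10/10 and 23/23
tumor/normal samples by default) profiled on a shared probe universe:
multiple probes per gene, pathway-structured mean shifts on the log2 scale,
homoscedastic Gaussian noise, and a fraction of near-constant "decoy" genes
that exercise the IQR filter. Effects are planted at the gene level,
uniformly across a pathway's members and with the same direction in every
cohort, so "up-regulated pathway" is well defined and the cross-cohort
consensus logic has a ground truth to recover.

Generation is a pure function of the configuration: the same
:class:`SimulationConfig` (including its seed) yields bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionDataset, GeneSetCollection, NORMAL, TUMOR
from .errors import ConfigError


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for :func:`simulate_study`.

    Defaults mirror the three-cohort paired design the pipeline targets:
    cohorts of 7/7, 10/10 and 23/23 tumor/normal samples, 50 disjoint
    pathways of 15 genes each, 10 planted up- and 10 down-regulated at a
    mean log2 shift of 1.0 against unit-SD noise.

    Attributes
    ----------
    n_datasets : number of cohorts.
    samples_per_group : per-cohort tumor (= normal) sample count.
    n_genes : total genes; must cover ``n_pathways * genes_per_pathway``.
    n_pathways : number of disjoint gene sets.
    genes_per_pathway : members per gene set.
    probes_per_gene : inclusive (lo, hi) range; each gene's probe count is
        drawn once and shared by all cohorts.
    frac_up_pathways, frac_down_pathways : fractions of pathways planted
        up-/down-regulated; the rest are null.
    effect_size : mean log2 shift added to TUMOR samples of affected genes
        (subtracted for down-pathways).
    noise_sd : per-observation Gaussian SD on the log2 scale.
    baseline_mean : center of the per-gene baseline intensities.
    iqr_decoy_frac : fraction of *unaffected* genes given near-constant
        expression (SD ``decoy_sd``) so their expected IQR falls below 0.5.
    decoy_sd : noise SD for decoy genes (expected IQR ~ 1.35 * decoy_sd).
    seed : RNG seed; the sole source of randomness.
    """

    n_datasets: int = 3
    samples_per_group: tuple[int, ...] = (7, 10, 23)
    n_genes: int = 800
    n_pathways: int = 50
    genes_per_pathway: int = 15
    probes_per_gene: tuple[int, int] = (1, 3)
    frac_up_pathways: float = 0.2
    frac_down_pathways: float = 0.2
    effect_size: float = 1.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    iqr_decoy_frac: float = 0.1
    decoy_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_datasets < 1:
            raise ConfigError("n_datasets must be >= 1")
        if len(self.samples_per_group) != self.n_datasets:
            raise ConfigError(
                "samples_per_group must list one count per dataset "
                f"(got {len(self.samples_per_group)} for {self.n_datasets})"
            )
        if any(n < 2 for n in self.samples_per_group):
            raise ConfigError("each group needs >= 2 samples")
        if self.n_genes < self.n_pathways * self.genes_per_pathway:
            raise ConfigError(
                "n_genes must cover n_pathways * genes_per_pathway "
                f"({self.n_pathways * self.genes_per_pathway})"
            )
        if min(self.n_pathways, self.genes_per_pathway) < 1:
            raise ConfigError("n_pathways and genes_per_pathway must be positive")
        lo, hi = self.probes_per_gene
        if lo < 1 or hi < lo:
            raise ConfigError("probes_per_gene must be a range with 1 <= lo <= hi")
        if not (0.0 <= self.frac_up_pathways <= 1.0 and 0.0 <= self.frac_down_pathways <= 1.0):
            raise ConfigError("pathway fractions must lie in [0, 1]")
        if self.frac_up_pathways + self.frac_down_pathways > 1.0 + 1e-12:
            raise ConfigError("frac_up_pathways + frac_down_pathways must be <= 1")
        if self.noise_sd <= 0 or self.decoy_sd <= 0:
            raise ConfigError("noise SDs must be positive")
        if not 0.0 <= self.iqr_decoy_frac <= 1.0:
            raise ConfigError("iqr_decoy_frac must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for one simulated study.

    The three pathway-id sets are disjoint and together cover every
    simulated pathway; ``affected_genes`` maps gene symbol -> signed mean
    shift (+effect_size for up-pathway members, -effect_size for down).
    """

    up_pathways: frozenset[str]
    down_pathways: frozenset[str]
    null_pathways: frozenset[str]
    affected_genes: dict[str, float]


_CLASSIFICATIONS = (
    "Metabolism",
    "Cellular processes",
    "Environmental information processing",
    "Organismal systems",
    "Human diseases",
)


def simulate_study(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], GeneSetCollection, GroundTruth]:
    """Generate the cohorts, the gene-set collection and the ground truth.

    All cohorts share one gene universe, one probe map and one effect
    assignment; only the noise draws differ between cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    # disjoint pathway membership over the leading genes
    gsc = GeneSetCollection()
    pathway_ids = [f"sim{i:05d}" for i in range(config.n_pathways)]
    for i, pid in enumerate(pathway_ids):
        members = genes[
            i * config.genes_per_pathway : (i + 1) * config.genes_per_pathway
        ]
        gsc.add(
            pid,
            f"Synthetic pathway {i}",
            _CLASSIFICATIONS[i % len(_CLASSIFICATIONS)],
            members,
        )

    # planted directions: a seeded draw over pathways
    n_up = int(round(config.frac_up_pathways * config.n_pathways))
    n_down = int(round(config.frac_down_pathways * config.n_pathways))
    shuffled = [str(p) for p in rng.permutation(pathway_ids)]
    up_ids = frozenset(shuffled[:n_up])
    down_ids = frozenset(shuffled[n_up : n_up + n_down])
    null_ids = frozenset(shuffled[n_up + n_down :])

    effect_of_gene: dict[str, float] = {}
    for pid in pathway_ids:
        if pid in up_ids:
            delta = config.effect_size
        elif pid in down_ids:
            delta = -config.effect_size
        else:
            continue
        for g in gsc[pid].genes:
            effect_of_gene[g] = delta

    # decoys drawn only from unaffected genes so planted effects stay intact
    unaffected = [g for g in genes if g not in effect_of_gene]
    n_decoy = int(round(config.iqr_decoy_frac * config.n_genes))
    if n_decoy > len(unaffected):
        raise ConfigError(
            "iqr_decoy_frac requests more decoys than there are unaffected genes"
        )
    decoys = (
        {str(g) for g in rng.choice(np.array(unaffected), size=n_decoy, replace=False)}
        if n_decoy
        else set()
    )

    # shared probe map and per-gene baselines
    lo, hi = config.probes_per_gene
    probe_counts = rng.integers(lo, hi + 1, size=config.n_genes)
    probe_ids: list[str] = []
    probe_gene: list[str] = []
    for g, cnt in zip(genes, probe_counts):
        for j in range(cnt):
            probe_ids.append(f"{g}_p{j}")
            probe_gene.append(g)
    gene_baseline = config.baseline_mean + rng.normal(0.0, 1.0, size=config.n_genes)
    baseline_of_gene = dict(zip(genes, gene_baseline))

    effect_arr = np.array([effect_of_gene.get(g, 0.0) for g in probe_gene])
    base_arr = np.array([baseline_of_gene[g] for g in probe_gene])
    sd_arr = np.array(
        [config.decoy_sd if g in decoys else config.noise_sd for g in probe_gene]
    )

    datasets: list[ExpressionDataset] = []
    for d, n_per in enumerate(config.samples_per_group):
        ds_id = f"SIM{d + 1}"
        tumor_samples = [f"{ds_id}_T{i + 1:02d}" for i in range(n_per)]
        normal_samples = [f"{ds_id}_N{i + 1:02d}" for i in range(n_per)]
        samples = tumor_samples + normal_samples
        n_probes = len(probe_ids)

        means = np.tile(base_arr[:, None], (1, 2 * n_per))
        means[:, :n_per] += effect_arr[:, None]  # TUMOR columns first
        noise = rng.normal(0.0, 1.0, size=(n_probes, 2 * n_per)) * sd_arr[:, None]
        values = pd.DataFrame(means + noise, index=probe_ids, columns=samples)

        groups = pd.Series(
            [TUMOR] * n_per + [NORMAL] * n_per, index=samples, name="group"
        )
        pairs = pd.Series(
            [f"{ds_id}_pair{i + 1:02d}" for i in range(n_per)] * 2,
            index=samples,
            name="pair",
        )
        datasets.append(
            ExpressionDataset(
                dataset_id=ds_id,
                values=values,
                gene_of_probe=pd.Series(probe_gene, index=probe_ids, name="gene"),
                group_of_sample=groups,
                pair_of_sample=pairs,
            )
        )

    truth = GroundTruth(
        up_pathways=up_ids,
        down_pathways=down_ids,
        null_pathways=null_ids,
        affected_genes=effect_of_gene,
    )
    return datasets, gsc, truth


def expected_detectable_power(
    config: SimulationConfig,
    n_sim: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """Monte-Carlo power of a single affected gene in the smallest cohort.

    Estimates the probability that one gene carrying the configured mean
    shift reaches two-sided p < ``alpha`` in an equal-variance two-sample
    t test with ``min(samples_per_group)`` samples per group. Deliberately
    independent of the pipeline's own t-test code (simulates and tests with
    scipy directly); used to set expectations in tests, not for analysis.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    n = min(config.samples_per_group)
    x = rng.normal(config.effect_size, config.noise_sd, size=(n_sim, n))
    y = rng.normal(0.0, config.noise_sd, size=(n_sim, n))
    _, p = stats.ttest_ind(x, y, axis=1, equal_var=True)
    return float(np.mean(p < alpha))


def ground_truth_table(truth: GroundTruth) -> pd.DataFrame:
    """Flatten a :class:`GroundTruth` into a writable two-column table."""
    rows = []
    for pid in sorted(truth.up_pathways):
        rows.append({"kind": "pathway", "id": pid, "label": "UP"})
    for pid in sorted(truth.down_pathways):
        rows.append({"kind": "pathway", "id": pid, "label": "DOWN"})
    for pid in sorted(truth.null_pathways):
        rows.append({"kind": "pathway", "id": pid, "label": "NULL"})
    for gene in sorted(truth.affected_genes):
        rows.append(
            {"kind": "gene", "id": gene, "label": f"{truth.affected_genes[gene]:+g}"}
        )
    return pd.DataFrame(rows, columns=["kind", "id", "label"])


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a YAML-style mapping, with validation."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("samples_per_group", "probes_per_gene"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
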