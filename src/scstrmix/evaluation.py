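"""Scenario runner reproducing the simulation studies at configurable scale.

A scenario fixes the mixture design (relationship, cells per contributor,
ploidy), the error model (D, D2, e), the population model (panel, Fst) and
the NOC estimator, then repeats: simulate contributor genotypes, simulate and
pool cells, estimate the NOC, and — only when the NOC is correct — build a
consensus per cluster, match clusters to true contributors by maximum total
IBS, and score consensus accuracy.  Replicates are fully reproducible from
the scenario seed.

Aggregates are the fraction of replicates with a correct NOC (with a 95%
Wilson score interval) and the mean over correct-NOC replicates of the
per-replicate mean per-contributor consensus accuracy, mirroring how the
reference accuracy tables are tallied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .cell_sim import DropModel, assemble_mixture
from .clustering import encode_profiles, estimate_noc, estimate_noc_ibs
from .consensus import consensus_profile, consensus_accuracy, match_clusters_to_truth
from .freq_panel import AlleleFrequencyTable, load_frequency_table, synthesize_frequency_table
from .genotype_sim import MutationModel, RelationshipSpec, simulate_contributors
from .inference import prob_missing_contributor
from .similarity import ibs_count

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "run_scenario",
    "detection_table",
    "ibs_distribution_study",
    "wilson_interval",
]

#: DNA mass per cell (pg), used for the detection-probability table.
DNA_PG_DIPLOID = 6.6
DNA_PG_HAPLOID = 3.3


def wilson_interval(successes: int, trials: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """95% Wilson score interval for a binomial proportion."""
    if trials == 0:
        return (0.0, 1.0)
    phat = successes / trials
    denom = 1.0 + z * z / trials
    center = (phat + z * z / (2 * trials)) / denom
    half = z * np.sqrt(phat * (1 - phat) / trials + z * z / (4 * trials * trials)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


@dataclass
class ScenarioConfig:
    """Full specification of one simulation scenario."""

    relationship_kind: str = "unrelated-set"
    cell_counts: tuple[int, ...] = (20, 20)
    ploidy: str = "diploid"
    D: float = 0.2
    e: float = 0.01
    D2: float | None = None
    fst: float = 0.01
    replicates: int = 10_000
    seed: int = 0
    noc_algorithm: str = "em"  # em | kmeans | ibs
    k_min: int = 2
    k_max: int = 6
    ibs_threshold: int = 24
    panel_path: str | None = None
    panel_n_loci: int = 21
    panel_alleles_per_locus: int = 8
    panel_concentration: float = 1.0
    mutation_rate: float = 1.5e-3
    mutation_p_single_step: float = 0.9
    mutation_geometric_p: float = 0.5

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        self.cell_counts = tuple(int(c) for c in self.cell_counts)
        if self.noc_algorithm not in ("em", "kmeans", "ibs"):
            raise ValueError(f"unknown noc_algorithm {self.noc_algorithm!r}")

    @property
    def n_contributors(self) -> int:
        return len(self.cell_counts)

    def relationship(self) -> RelationshipSpec:
        return RelationshipSpec(kind=self.relationship_kind,
                                n_contributors=self.n_contributors)

    def drop_model(self) -> DropModel:
        return DropModel(D=self.D, e=self.e, D2=self.D2)

    def mutation_model(self) -> MutationModel:
        return MutationModel(rate_per_locus=self.mutation_rate,
                             p_single_step=self.mutation_p_single_step,
                             geometric_p=self.mutation_geometric_p)

    def panel(self) -> AlleleFrequencyTable:
        if self.panel_path:
            return load_frequency_table(self.panel_path)
        return synthesize_frequency_table(
            n_loci=self.panel_n_loci,
            alleles_per_locus=self.panel_alleles_per_locus,
            concentration=self.panel_concentration,
            seed=self.seed,
        )

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        text = open(path).read()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class ScenarioResult:
    """Aggregated NOC and consensus accuracy over the replicates of a scenario."""

    replicates: int
    n_correct_noc: int
    noc_accuracy: float
    noc_accuracy_ci: tuple[float, float]
    consensus_accuracy: float | None
    consensus_accuracy_ci: tuple[float, float] | None
    per_contributor_accuracy: tuple[float, ...] | None
    noc_counts: dict[int, int]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["noc_counts"] = {str(k): v for k, v in self.noc_counts.items()}
        return d


def _estimate(config: ScenarioConfig, dataset, matrix, rep_seed: int):
    if config.noc_algorithm == "ibs":
        return estimate_noc_ibs(dataset, min_same_source_ibs=config.ibs_threshold)
    return estimate_noc(matrix, algorithm=config.noc_algorithm,
                        k_min=config.k_min, k_max=config.k_max, seed=rep_seed)


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Run every replicate of a scenario and aggregate the accuracy statistics."""
    n_true = config.n_contributors
    if sum(config.cell_counts) < config.k_min and config.noc_algorithm != "ibs":
        raise ValueError("fewer cells than k_min: scenario is infeasible")
    panel = config.panel()
    spec = config.relationship()
    drop = config.drop_model()
    mutation = config.mutation_model()
    master = np.random.SeedSequence(config.seed)
    rep_streams = master.spawn(config.replicates)

    n_correct = 0
    noc_counts: dict[int, int] = {}
    replicate_means: list[float] = []
    per_contrib_sums = np.zeros(n_true)
    per_contrib_n = 0

    for rep, stream in enumerate(rep_streams):
        rng = np.random.default_rng(stream)
        contributors = simulate_contributors(spec, panel, fst=config.fst,
                                             model=mutation, rng=rng)
        dataset = assemble_mixture(contributors, list(config.cell_counts), panel,
                                   drop, rng, ploidy=config.ploidy)
        matrix = encode_profiles(dataset)
        rep_seed = int(stream.generate_state(1)[0] % (2**31))
        estimate = _estimate(config, dataset, matrix, rep_seed)
        noc_counts[estimate.noc] = noc_counts.get(estimate.noc, 0) + 1
        if estimate.noc != n_true:
            continue
        n_correct += 1
        assignment = estimate.best_clustering.assignment
        consensus_list = [
            consensus_profile([dataset.cells[i] for i in np.flatnonzero(assignment == j)])
            for j in range(estimate.noc)
        ]
        mapping = match_clusters_to_truth(consensus_list, list(contributors))
        accs = np.zeros(n_true)
        for i, j in enumerate(mapping):
            accs[j] = consensus_accuracy(consensus_list[i], contributors[j])
        replicate_means.append(float(accs.mean()))
        per_contrib_sums += accs
        per_contrib_n += 1

    noc_accuracy = n_correct / config.replicates
    ci = wilson_interval(n_correct, config.replicates)
    if replicate_means:
        arr = np.array(replicate_means)
        mean = float(arr.mean())
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        cons_ci = (max(0.0, mean - 1.96 * sem), min(1.0, mean + 1.96 * sem))
        per_contrib = tuple(per_contrib_sums / per_contrib_n)
    else:
        mean = None
        cons_ci = None
        per_contrib = None
    return ScenarioResult(
        replicates=config.replicates,
        n_correct_noc=n_correct,
        noc_accuracy=noc_accuracy,
        noc_accuracy_ci=ci,
        consensus_accuracy=mean,
        consensus_accuracy_ci=cons_ci,
        per_contributor_accuracy=per_contrib,
        noc_counts=dict(sorted(noc_counts.items())),
    )


_DEFAULT_PROPORTIONS = (0.01, 0.05, 0.10, 0.20, 0.50)
_DEFAULT_CELL_COUNTS = (1, 5, 10, 15, 20, 40, 80, 160, 500)


def detection_table(proportions=None, cell_counts=None):
    """Grid of probabilities of not detecting a minor contributor while sampling.

    Returns a pandas DataFrame with one row per total cell count (plus the
    DNA mass a diploid and a haploid sample of that size would carry) and one
    column per mixture proportion, each entry ``(1 - p)**n``.
    """
    import pandas as pd

    proportions = tuple(proportions) if proportions is not None else _DEFAULT_PROPORTIONS
    cell_counts = tuple(cell_counts) if cell_counts is not None else _DEFAULT_CELL_COUNTS
    rows = []
    for n in cell_counts:
        row = {
            "n_cells": n,
            "dna_pg_diploid": round(DNA_PG_DIPLOID * n, 4),
            "dna_pg_haploid": round(DNA_PG_HAPLOID * n, 4),
        }
        for p in proportions:
            row[f"p={p:g}"] = prob_missing_contributor(p, n)
        rows.append(row)
    return pd.DataFrame(rows)


def ibs_distribution_study(
    panel: AlleleFrequencyTable,
    relationship_kinds=("unrelated-set", "parent-child", "full-siblings"),
    cells_per_consensus=(1, 2, 5, 10),
    D: float = 0.2,
    e: float = 0.01,
    fst: float = 0.01,
    ploidy: str = "diploid",
    replicates: int = 1000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """IBS samples for relationship pairs and for consensus-vs-truth profiles.

    Returns a mapping from sample label (``"UR"``, ``"PC"``, ``"FS"``,
    ``"1 cell"``, ``"5 cells"``, ...) to an integer array of IBS values, one
    per replicate.  Relationship samples pair two true genotypes; consensus
    samples compare a contributor's true genotype with the consensus of ``n``
    of its simulated cells (missing consensus alleles contribute no matches).
    """
    from .cell_sim import simulate_diploid_cell, simulate_haploid_cell

    short = {"unrelated-set": "UR", "parent-child": "PC", "full-siblings": "FS"}
    drop = DropModel(D=D, e=e)
    mutation = MutationModel()
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for kind in relationship_kinds:
        spec = RelationshipSpec(kind=kind, n_contributors=2)
        vals = np.empty(replicates, dtype=int)
        for i in range(replicates):
            pair = simulate_contributors(spec, panel, fst=fst, model=mutation, rng=rng)
            vals[i] = ibs_count(pair[0], pair[1])
        out[short.get(kind, kind)] = vals
    simulate = simulate_diploid_cell if ploidy == "diploid" else simulate_haploid_cell
    from .genotype_sim import sample_genotype_fst

    for n in cells_per_consensus:
        vals = np.empty(replicates, dtype=int)
        for i in range(replicates):
            truth = sample_genotype_fst(panel, fst, rng)
            cells = [simulate(truth, panel, drop, rng) for _ in range(n)]
            vals[i] = ibs_count(consensus_profile(cells), truth)
        out[f"{n} cell" + ("s" if n != 1 else "")] = vals
    return out
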