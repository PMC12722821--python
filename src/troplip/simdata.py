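"""Synthetic single-cell and bulk count data with known ground truth.

The generator emulates the study design the pipeline was built for: a
case/control single-cell dataset stratified into trophoblast-like clusters
(VCT/SCT/EVT by default) with biological replicates, and a small bulk
RNA-seq experiment (hypoxia-model-like, a few replicates per arm).  Counts
are negative binomial with mean/dispersion parameterisation
``var = mu + phi * mu**2``.  Per-gene expected counts factorise as

    mu = baseline(gene) * cluster_factor(gene, cluster)
         * sample_factor(sample) * 2**(condition * log2FC)
         * cell_size_factor(cell)

Condition effects ("spikes") are applied to named gene sets in chosen
clusters, so every downstream stage — percentile-CPM dot plots,
differential expression, GSEA, direction-aware Fisher tests and regulon
scoring — can be checked against the generating truth.

Randomness is a single ``numpy`` Generator per dataset, seeded from the
config.  Stream order is: baselines, cluster factors, set membership,
regulon assembly, sample factors, cell sizes, counts — so downstream draws
never perturb earlier ones for a fixed gene universe.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError
from .io_formats import (
    BulkDataset,
    CellDataset,
    GeneSetCollection,
    RegulonTable,
)

DEFAULT_CLUSTERS = {
    # cluster -> condition -> n cells; sizes echo a VCT-heavy trophoblast mix
    "VCT": {"Ctrl": 600, "PE": 600},
    "SCT": {"Ctrl": 500, "PE": 500},
    "EVT": {"Ctrl": 300, "PE": 300},
}


@dataclass
class SpikeSpec:
    """A gene set whose members get a condition log2 fold change."""

    label: str
    size: int
    log2fc: float
    clusters: tuple[str, ...] = ()   # empty = every cluster (and bulk)


@dataclass
class RegulonSpec:
    """A simulated TF regulon; ``active`` TFs have responsive targets spiked."""

    tf: str
    n_targets: int
    activation_frac: float = 1.0     # remaining targets are Repression
    unknown_frac: float = 0.0
    responsive_frac: float = 0.8
    log2fc: float = 2.0
    active: bool = True


@dataclass
class SimConfig:
    """Everything the generator needs; identical config + seed ⇒ identical data."""

    n_genes: int = 1000
    clusters: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_CLUSTERS.items()
    })
    conditions: tuple[str, str] = ("Ctrl", "PE")   # (control, case)
    n_samples_per_condition: int = 4
    baseline_log_mean: float = 0.0       # natural-log scale of per-cell mean counts
    baseline_log_sd: float = 1.0
    cluster_log_sd: float = 0.3
    dispersion_sc: float = 0.4
    dispersion_bulk: float = 0.05
    sample_log_sd: float = 0.15
    cell_size_log_sd: float = 0.25
    bulk_depth: float = 200.0            # multiplier from per-cell to bulk means
    length_range: tuple[int, int] = (500, 5000)
    spike_table: list = field(default_factory=list)       # list[SpikeSpec]
    regulon_spec: list = field(default_factory=list)      # list[RegulonSpec]
    n_null_sets: int = 5
    null_set_size: int = 19
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if not self.clusters:
            raise ConfigError("at least one cluster is required")
        for cluster, sizes in self.clusters.items():
            for cond, n in sizes.items():
                if cond not in self.conditions:
                    raise ConfigError(
                        f"cluster {cluster!r} names unknown condition {cond!r}"
                    )
                if n <= 0:
                    raise ConfigError(
                        f"cluster {cluster!r} has non-positive cell count for {cond!r}"
                    )
        if self.n_samples_per_condition < 1:
            raise ConfigError("n_samples_per_condition must be >= 1")
        if self.dispersion_sc <= 0 or self.dispersion_bulk <= 0:
            raise ConfigError("dispersions must be strictly positive")
        if self.baseline_log_mean is None or not np.isfinite(self.baseline_log_mean):
            raise ConfigError("baseline_log_mean must be finite")
        total_set = 0
        for spike in self.spike_table:
            if spike.size <= 0:
                raise ConfigError(f"spiked set {spike.label!r} has size <= 0")
            total_set += spike.size
            for cluster in spike.clusters:
                if cluster not in self.clusters:
                    raise ConfigError(
                        f"spiked set {spike.label!r} names unknown cluster {cluster!r}"
                    )
        for reg in self.regulon_spec:
            if reg.n_targets <= 0:
                raise ConfigError(f"regulon {reg.tf!r} has no targets")
            total_set += reg.n_targets
        if total_set > self.n_genes:
            raise ConfigError(
                f"spiked sets and regulons need {total_set} genes but the "
                f"universe has only {self.n_genes}"
            )


@dataclass
class SimTruth:
    """Generating truth: per-gene log2FC per cluster, set membership, TF states."""

    log2fc: pd.DataFrame                 # genes × clusters (+ "bulk" column)
    set_members: dict[str, list[str]]
    active_tfs: list[str]
    inactive_tfs: list[str]


# ---------------------------------------------------------------------------
# Shared deterministic scaffolding
# ---------------------------------------------------------------------------

def _gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def _base_rng(config: SimConfig, stream: str) -> np.random.Generator:
    # crc32 is stable across processes, unlike builtin str hashing
    return np.random.default_rng([config.seed, zlib.crc32(stream.encode())])


def _structure(config: SimConfig):
    """Baselines, cluster factors, set/regulon membership — shared by all outputs.

    Spiked-set and regulon-target members are sampled from genes whose
    baseline exceeds the median, mirroring the well-detected metabolic gene
    families the fixtures stand in for; membership blocks are disjoint.
    """
    config.validate()
    genes = _gene_ids(config.n_genes)

    rng = np.random.default_rng(config.seed)
    baseline = np.exp(rng.normal(config.baseline_log_mean,
                                 config.baseline_log_sd, config.n_genes))
    cluster_factor = {
        cluster: np.exp(rng.normal(0.0, config.cluster_log_sd, config.n_genes))
        for cluster in config.clusters
    }

    order = np.flatnonzero(baseline > np.median(baseline))
    order = order[rng.permutation(order.size)]
    cursor = 0
    set_members: dict[str, list[str]] = {}
    for spike in config.spike_table:
        if cursor + spike.size > order.size:
            raise ConfigError(
                "not enough well-expressed genes to host all spiked sets; "
                "increase n_genes"
            )
        idx = order[cursor:cursor + spike.size]
        cursor += spike.size
        set_members[spike.label] = [genes[i] for i in sorted(idx)]

    regulon_rows = []
    responsive: dict[str, list[tuple[str, str]]] = {}
    for reg in config.regulon_spec:
        if cursor + reg.n_targets > order.size:
            raise ConfigError("not enough well-expressed genes to host regulons")
        idx = order[cursor:cursor + reg.n_targets]
        cursor += reg.n_targets
        targets = [genes[i] for i in sorted(idx)]
        n_unknown = int(round(reg.unknown_frac * reg.n_targets))
        n_act = int(round(reg.activation_frac * (reg.n_targets - n_unknown)))
        modes = (["Activation"] * n_act
                 + ["Repression"] * (reg.n_targets - n_unknown - n_act)
                 + ["Unknown"] * n_unknown)
        rng.shuffle(modes)
        resp = []
        n_resp = int(round(reg.responsive_frac * reg.n_targets))
        eligible = [i for i, m in enumerate(modes) if m != "Unknown"]
        chosen = rng.choice(eligible, size=min(n_resp, len(eligible)),
                            replace=False)
        for i, (target, mode) in enumerate(zip(targets, modes)):
            regulon_rows.append((reg.tf, target, mode))
            if reg.active and i in chosen:
                resp.append((target, mode))
        responsive[reg.tf] = resp

    return genes, baseline, cluster_factor, set_members, regulon_rows, responsive


def _truth_log2fc(config: SimConfig, genes, set_members, responsive) -> pd.DataFrame:
    cols = list(config.clusters) + ["bulk"]
    lfc = pd.DataFrame(0.0, index=genes, columns=cols)
    for spike in config.spike_table:
        targets = set_members[spike.label]
        where = spike.clusters or tuple(cols)
        for cluster in where:
            lfc.loc[targets, cluster] += spike.log2fc
    for reg in config.regulon_spec:
        for target, mode in responsive.get(reg.tf, []):
            sign = 1.0 if mode == "Activation" else -1.0
            lfc.loc[target, "bulk"] += sign * reg.log2fc
    return lfc


def _make_truth(config: SimConfig, genes, set_members, responsive) -> SimTruth:
    lfc = _truth_log2fc(config, genes, set_members, responsive)
    active = [r.tf for r in config.regulon_spec if r.active]
    inactive = [r.tf for r in config.regulon_spec if not r.active]
    return SimTruth(lfc, set_members, active, inactive)


# ---------------------------------------------------------------------------
# Dataset generators
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, var = mean + phi mean^2) via the gamma–Poisson mixture."""
    shape = 1.0 / phi
    lam = rng.gamma(shape, mean * phi)
    return rng.poisson(lam)


def simulate_single_cell_dataset(config: SimConfig) -> tuple[CellDataset, SimTruth]:
    """Simulate clustered case/control single-cell counts with known spikes."""
    genes, baseline, cluster_factor, set_members, _, responsive = _structure(config)
    truth = _make_truth(config, genes, set_members, responsive)
    control, case = config.conditions

    rng = _base_rng(config, "single_cell")
    sample_ids = {
        cond: [f"{cond}_s{i+1}" for i in range(config.n_samples_per_condition)]
        for cond in config.conditions
    }
    sample_factor = {
        sid: np.exp(rng.normal(0.0, config.sample_log_sd))
        for cond in config.conditions for sid in sample_ids[cond]
    }

    blocks = []
    meta_rows = []
    cell_no = 0
    for cluster, sizes in config.clusters.items():
        lfc = truth.log2fc[cluster].to_numpy()
        for cond in config.conditions:
            n_cells = sizes.get(cond, 0)
            if n_cells == 0:
                continue
            fold = 2.0 ** lfc if cond == case else np.ones_like(lfc)
            base = baseline * cluster_factor[cluster] * fold
            assign = rng.integers(0, config.n_samples_per_condition, n_cells)
            sizes_c = np.exp(rng.normal(0.0, config.cell_size_log_sd, n_cells))
            sfac = np.array([sample_factor[sample_ids[cond][a]] for a in assign])
            mu = base[:, None] * (sfac * sizes_c)[None, :]
            blocks.append(sp.csr_matrix(_nb_draw(rng, mu, config.dispersion_sc)))
            for j in range(n_cells):
                cell_no += 1
                meta_rows.append((f"cell{cell_no:06d}",
                                  sample_ids[cond][assign[j]], cluster, cond))

    counts = sp.hstack(blocks, format="csr")
    meta = pd.DataFrame(meta_rows, columns=["cell_id", "sample_id",
                                            "cluster", "condition"])
    return CellDataset(counts, genes, meta), truth


def simulate_bulk_dataset(config: SimConfig) -> tuple[BulkDataset, SimTruth]:
    """Simulate a small bulk case/control experiment (few replicates per arm)."""
    if config.n_samples_per_condition < 2:
        raise ConfigError("bulk simulation needs >= 2 samples per condition")
    genes, baseline, _, set_members, _, responsive = _structure(config)
    if (baseline <= 0).any():
        raise ConfigError("all baseline means must be strictly positive")
    truth = _make_truth(config, genes, set_members, responsive)
    control, case = config.conditions
    lfc = truth.log2fc["bulk"].to_numpy()

    rng = _base_rng(config, "bulk")
    cols, conds = [], []
    mat = np.empty((config.n_genes, 2 * config.n_samples_per_condition),
                   dtype=np.int64)
    j = 0
    for cond in config.conditions:
        fold = 2.0 ** lfc if cond == case else np.ones_like(lfc)
        for i in range(config.n_samples_per_condition):
            size = np.exp(rng.normal(0.0, config.sample_log_sd))
            mu = baseline * config.bulk_depth * fold * size
            mat[:, j] = _nb_draw(rng, mu, config.dispersion_bulk)
            cols.append(f"{cond}_b{i+1}")
            conds.append(cond)
            j += 1

    lengths = pd.Series(
        rng.integers(config.length_range[0], config.length_range[1],
                     config.n_genes),
        index=genes, name="length_bp", dtype=float,
    )
    counts = pd.DataFrame(mat, index=genes, columns=cols)
    samples = pd.DataFrame({"sample_id": cols, "condition": conds})
    return BulkDataset(counts, samples, lengths), truth


def make_gene_set_catalog(config: SimConfig) -> GeneSetCollection:
    """Gene sets matching the simulation: spiked sets plus null decoys.

    Null sets are drawn from genes not used by any spike or regulon, so
    enrichment specificity can be assessed against truly unperturbed sets.
    """
    genes, _, _, set_members, regulon_rows, _ = _structure(config)
    sets = {label: list(members) for label, members in set_members.items()}
    used = {g for members in set_members.values() for g in members}
    used |= {t for _, t, _ in regulon_rows}
    free = [g for g in genes if g not in used]
    rng = _base_rng(config, "null_sets")
    for i in range(config.n_null_sets):
        size = min(config.null_set_size, len(free))
        if size == 0:
            raise ConfigError("universe too small for the requested null sets")
        pick = sorted(rng.choice(len(free), size=size, replace=False))
        sets[f"NULL_SET_{i+1:02d}"] = [free[k] for k in pick]
        free = [g for k, g in enumerate(free) if k not in set(pick)]
    descriptions = {name: "simulated gene set" for name in sets}
    for label in set_members:
        descriptions[label] = "spiked gene set"
    return GeneSetCollection(sets, descriptions)


def make_regulon_table(config: SimConfig) -> RegulonTable:
    """TRRUST-like (tf, target, mode) rows matching the simulated regulons."""
    _, _, _, _, regulon_rows, _ = _structure(config)
    table = pd.DataFrame(regulon_rows, columns=["tf", "target", "mode"])
    return RegulonTable(table)
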