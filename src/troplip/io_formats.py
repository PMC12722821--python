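"""Readers and writers for the on-disk formats the pipeline touches.

Single-cell counts travel as MatrixMarket coordinate files (genes as rows,
1-based indices) with two TSV side-cars (gene ids, cell metadata).  Bulk
counts, sample sheets, gene lengths, regulon tables and generic result
tables are TSV with a header row.  Gene sets use the MSigDB GMT dialect:
``name<TAB>description<TAB>member...``.

Every reader is a total validator: an object it returns satisfies the
invariants of its type, and any violation raises :class:`FormatError`
naming the offending record — there is no silent coercion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError

REGULON_MODES = ("Activation", "Repression", "Unknown")

CELL_META_COLUMNS = ("cell_id", "sample_id", "cluster", "condition")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class CellDataset:
    """Sparse gene × cell count matrix plus per-cell metadata.

    ``counts`` holds raw non-negative integer counts with genes as rows.
    ``cell_meta`` is indexed positionally in matrix column order and has
    columns ``cell_id, sample_id, cluster, condition``.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"gene id list has {len(self.gene_ids)} entries for a "
                f"{n_genes}-row matrix"
            )
        if len(self.cell_meta) != n_cells:
            raise FormatError(
                f"cell metadata has {len(self.cell_meta)} rows for a "
                f"{n_cells}-column matrix"
            )
        if len(set(self.gene_ids)) != n_genes:
            dup = _first_duplicate(self.gene_ids)
            raise FormatError(f"duplicate gene id {dup!r}")
        missing = [c for c in CELL_META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise FormatError(f"cell metadata missing column(s) {missing}")
        ids = self.cell_meta["cell_id"]
        if ids.duplicated().any():
            raise FormatError(
                f"duplicate cell_id {ids[ids.duplicated()].iloc[0]!r}"
            )
        for col in ("cluster", "condition"):
            bad = self.cell_meta[col].isna() | (self.cell_meta[col].astype(str) == "")
            if bad.any():
                raise FormatError(
                    f"cell {ids[bad].iloc[0]!r} has missing {col}"
                )
        data = self.counts.data
        if data.size and (data < 0).any():
            raise FormatError("count matrix contains negative entries")
        if data.size and not np.allclose(data, np.round(data)):
            raise FormatError("count matrix contains non-integer entries")
        self.counts = self.counts.astype(np.int64)
        self.cell_meta = self.cell_meta.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class BulkDataset:
    """Gene × sample count matrix with a sample sheet and gene lengths (bp)."""

    counts: pd.DataFrame          # genes × samples, integer
    sample_meta: pd.DataFrame     # columns: sample_id, condition
    gene_lengths: pd.Series       # indexed by gene id, bp

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise FormatError("duplicate gene id in bulk counts")
        if self.sample_meta["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in sample sheet")
        if list(self.counts.columns) != list(self.sample_meta["sample_id"]):
            raise FormatError(
                "sample sheet order does not match count matrix columns"
            )
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise FormatError("bulk counts contain negative entries")
        if not np.allclose(vals, np.round(vals)):
            raise FormatError("bulk counts contain non-integer entries")
        self.counts = self.counts.astype(np.int64)
        lengths = self.gene_lengths.reindex(self.counts.index)
        if lengths.isna().any():
            gene = lengths.index[lengths.isna()][0]
            raise FormatError(f"gene {gene!r} has no length")
        if (lengths <= 0).any():
            gene = lengths.index[lengths <= 0][0]
            raise FormatError(f"gene {gene!r} has non-positive length")
        self.gene_lengths = lengths.astype(float)
        self.sample_meta = self.sample_meta.reset_index(drop=True)

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.sample_meta["condition"]))


@dataclass
class GeneSetCollection:
    """Named gene sets with optional free-text descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {name!r} has duplicate members")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def restrict(self, universe) -> "GeneSetCollection":
        """Drop members outside ``universe``; sets left empty are removed."""
        uni = set(universe)
        kept = {
            name: [g for g in members if g in uni]
            for name, members in self.sets.items()
        }
        kept = {n: m for n, m in kept.items() if m}
        return GeneSetCollection(kept, {n: self.descriptions[n] for n in kept})


@dataclass
class RegulonTable:
    """TF → target edges with a regulation mode, TRRUST-style."""

    table: pd.DataFrame           # columns: tf, target, mode

    def __post_init__(self) -> None:
        need = ("tf", "target", "mode")
        missing = [c for c in need if c not in self.table.columns]
        if missing:
            raise FormatError(f"regulon table missing column(s) {missing}")
        bad = ~self.table["mode"].isin(REGULON_MODES)
        if bad.any():
            row = self.table[bad].iloc[0]
            raise FormatError(
                f"unknown regulon mode {row['mode']!r} for "
                f"({row['tf']}, {row['target']})"
            )
        # duplicate (tf, target) pairs collapse to the first occurrence
        self.table = (
            self.table.drop_duplicates(subset=["tf", "target"])
            .reset_index(drop=True)[list(need)]
        )

    def targets_of(self, tf: str) -> pd.DataFrame:
        return self.table[self.table["tf"] == tf]

    @property
    def tfs(self) -> list[str]:
        return list(pd.unique(self.table["tf"]))


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# Single-cell matrix IO
# ---------------------------------------------------------------------------

def read_single_cell(matrix_path, genes_path, cells_path) -> CellDataset:
    """Read a MatrixMarket count matrix with gene/cell side-car TSVs."""
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}")
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    if "gene_id" not in genes.columns:
        raise FormatError(f"{genes_path} missing 'gene_id' column")
    cells = pd.read_csv(cells_path, sep="\t", dtype=str)
    return CellDataset(sp.csr_matrix(mat), list(genes["gene_id"]), cells)


def write_single_cell(dataset: CellDataset, matrix_path, genes_path, cells_path) -> None:
    scipy.io.mmwrite(str(matrix_path), dataset.counts.tocoo(), field="integer")
    pd.DataFrame({"gene_id": dataset.gene_ids}).to_csv(
        genes_path, sep="\t", index=False
    )
    dataset.cell_meta.to_csv(cells_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bulk IO
# ---------------------------------------------------------------------------

def read_bulk(counts_path, samples_path, lengths_path) -> BulkDataset:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", dtype=str)
    if "sample_id" not in samples.columns or "condition" not in samples.columns:
        raise FormatError(f"{samples_path} must have sample_id and condition columns")
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0)
    if lengths.shape[1] != 1:
        raise FormatError(f"{lengths_path} must have exactly one value column")
    return BulkDataset(counts, samples, lengths.iloc[:, 0])


def write_bulk(dataset: BulkDataset, counts_path, samples_path, lengths_path) -> None:
    dataset.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    dataset.sample_meta.to_csv(samples_path, sep="\t", index=False)
    dataset.gene_lengths.rename("length_bp").rename_axis("gene_id").to_csv(
        lengths_path, sep="\t"
    )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs name, description and "
                f"at least one member"
            )
        name, desc, *members = fields
        members = [m for m in members if m]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        if not members:
            raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, ""), *members])
        for name, members in collection
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Regulon tables
# ---------------------------------------------------------------------------

def read_regulons(path) -> RegulonTable:
    table = pd.read_csv(path, sep="\t", dtype=str)
    try:
        return RegulonTable(table)
    except FormatError:
        # re-raise with a line number for the first offending row
        bad = ~table["mode"].isin(REGULON_MODES)
        if "mode" in table.columns and bad.any():
            lineno = int(np.flatnonzero(bad)[0]) + 2  # header + 1-based
            raise FormatError(
                f"{path}:{lineno}: unknown regulon mode "
                f"{table.loc[bad, 'mode'].iloc[0]!r}"
            )
        raise


def write_regulons(regulons: RegulonTable, path) -> None:
    regulons.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_table(result: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV, floats at 6 significant digits."""
    result.to_csv(path, sep="\t", index=index, float_format="%.6g")
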