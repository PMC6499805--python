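"""Domain types and readers/writers shared by every pipeline stage.

The pipeline's entry points are a gene x sample count matrix with a
sample-to-group mapping (control RPE, TNT-treated RPE, patient PVR
membrane), and a STRING-style weighted interaction network.  All
identifiers are opaque strings; no symbol/Ensembl mapping is attempted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CountMatrix",
    "GeneSet",
    "PipelineConfig",
    "read_count_matrix",
    "read_interaction_network",
    "write_count_matrix",
    "write_gene_set",
    "read_gene_set",
    "write_table",
    "write_graph",
]


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts plus group labels.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    counts : ndarray of shape (n_genes, n_samples)
        Non-negative integers.
    group_of : mapping sample_id -> group label
        Every sample must be mapped to exactly one group.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def sample_indices(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.group_of[s] == group]
        if not idx:
            raise KeyError(f"no samples in group {group!r}")
        return np.asarray(idx)

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        keep = set(genes)
        rows = [i for i, g in enumerate(self.gene_ids) if g in keep]
        return CountMatrix(
            [self.gene_ids[i] for i in rows],
            list(self.sample_ids),
            self.counts[rows, :],
            dict(self.group_of),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (set semantics, no duplicates)."""

    name: str
    genes: frozenset[str]

    def __init__(self, name: str, genes: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", frozenset(genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))


@dataclass
class PipelineConfig:
    """Tunable parameters for the whole pipeline.

    fc_threshold is on the linear scale (2 means two-fold);
    score_min is on the STRING combined-score scale (0-1000), with the
    conventional high-confidence cutoff of 700 as default.
    expression_filter is (min CPM, min number of samples).
    """

    fc_threshold: float = 2.0
    fdr_alpha: float = 0.05
    n_iterations: int = 1000
    k_hops: int = 2
    score_min: float = 700.0
    rng_seed: int = 0
    expression_filter: tuple[float, int] = (1.0, 2)
    prior_count: float = 0.5

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.k_hops < 1:
            raise ValueError("k_hops must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "expression_filter" in raw:
            raw["expression_filter"] = tuple(raw["expression_filter"])
        return cls(**raw)

    def manifest(self, inputs: Mapping[str, str | Path] | None = None) -> dict:
        """Run manifest: config values plus checksums of the input files."""
        entry = dataclasses.asdict(self)
        entry["expression_filter"] = list(entry["expression_filter"])
        checksums = {}
        for label, p in (inputs or {}).items():
            h = hashlib.sha256(Path(p).read_bytes()).hexdigest()
            checksums[label] = {"path": str(p), "sha256": h}
        return {"config": entry, "inputs": checksums}


# ---------------------------------------------------------------------------
# readers


def _read_group_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("group table needs >= 2 columns (sample, group)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_count_matrix(
    path: str | Path,
    group_table: str | Path,
    fmt: str | None = None,
) -> CountMatrix:
    """Read a gene x sample count matrix (TSV/CSV/MTX) plus its group table.

    TSV/CSV: first column gene ids, header row of sample ids.  MTX: a
    MatrixMarket triplet file with ``<stem>.rows`` / ``<stem>.cols``
    sidecar files holding gene and sample names, one per line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(path.suffix, "tsv")
    group_of = _read_group_table(group_table)

    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("non-numeric entries in count matrix")
        bad = np.argwhere((values < 0) | (values != np.round(values)))
        if bad.size:
            g, s = bad[0]
            raise ValueError(
                f"invalid count {values[g, s]!r} at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )
        gene_ids = [str(g) for g in df.index]
        sample_ids = [str(s) for s in df.columns]
        counts = values.astype(np.int64)
    elif fmt == "mtx":
        from scipy.io import mmread

        counts = np.asarray(mmread(path).todense())
        stem = path.with_suffix("")
        gene_ids = Path(f"{stem}.rows").read_text().split()
        sample_ids = Path(f"{stem}.cols").read_text().split()
    else:
        raise ValueError(f"unsupported format {fmt!r}")

    missing = [s for s in sample_ids if s not in group_of]
    if missing:
        raise ValueError(f"samples missing from group table: {missing}")
    return CountMatrix(gene_ids, sample_ids, counts, group_of)


def read_interaction_network(path: str | Path, score_min: float = 700.0) -> nx.Graph:
    """Read a STRING-style edge list: protein1 protein2 combined_score.

    Whitespace- or tab-delimited; an optional header line whose third
    field is non-numeric is skipped.  Self-loops are dropped; duplicate
    pairs in either orientation are collapsed keeping the maximum score;
    edges with score below ``score_min`` are removed.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(f"line {lineno}: expected 3 fields, got {len(fields)}")
            a, b, raw = fields
            try:
                score = float(raw)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"line {lineno}: non-numeric score {raw!r}") from None
            if a == b:
                continue
            if graph.has_edge(a, b):
                score = max(score, graph[a][b]["score"])
            graph.add_edge(a, b, score=score)
    drop = [(a, b) for a, b, s in graph.edges(data="score") if s < score_min]
    graph.remove_edges_from(drop)
    return graph


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    genes = [g for g in Path(path).read_text().split() if g]
    return GeneSet(name or Path(path).stem, genes)


# ---------------------------------------------------------------------------
# writers


def write_count_matrix(cm: CountMatrix, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        cm.to_frame().to_csv(path, sep=sep, index_label="gene")
    elif fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(cm.counts))
        stem = path.with_suffix("")
        Path(f"{stem}.rows").write_text("\n".join(cm.gene_ids) + "\n")
        Path(f"{stem}.cols").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def write_group_table(cm: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": cm.sample_ids, "group": [cm.group_of[s] for s in cm.sample_ids]}
    ).to_csv(path, sep="\t", index=False)


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(gs.genes)))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_graph(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_results(obj, path: str | Path, fmt: str | None = None) -> None:
    """Type-dispatching writer: GeneSet -> gene-per-line text, DataFrame ->
    TSV with header, Graph -> GraphML, CountMatrix -> tsv/csv/mtx."""
    if isinstance(obj, GeneSet):
        write_gene_set(obj, path)
    elif isinstance(obj, pd.DataFrame):
        write_table(obj, path)
    elif isinstance(obj, nx.Graph):
        write_graph(obj, path)
    elif isinstance(obj, CountMatrix):
        write_count_matrix(obj, path, fmt or "tsv")
    else:
        raise ValueError(f"unsupported object type {type(obj).__name__}")


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
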