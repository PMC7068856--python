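"""Readers, writers and expression preprocessing.

External formats are deliberately plain text:

* expression matrices -- tab-separated, genes in rows, a header row of
  sample identifiers, first column the gene symbol;
* interaction networks -- two-column whitespace-separated edge lists
  (three columns for fused networks, the third being the edge frequency);
* gene sets -- one symbol per line;
* disease--gene association catalogs -- two-column TSV (disease id, gene).

Lines starting with ``#`` are comments in every line-oriented format.
All gene matching is exact string match on symbols; identifier mapping
(e.g. protein to gene) is assumed to have happened upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("raw", "tpm", "log2tpm")
CONDITIONS = ("case", "control")
NETWORK_KINDS = ("static", "single_sample", "fused")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a condition flag.

    ``stage`` tracks the unit of the values: ``raw`` (FPKM/RPKM as
    downloaded), ``tpm`` (columns rescaled to one million), or
    ``log2tpm`` (log2(TPM+1) after preprocessing).
    """

    data: pd.DataFrame
    condition: str
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class GeneNetwork:
    """An undirected simple graph over gene symbols.

    ``kind`` distinguishes the static PPI backbone, one patient's
    activation-induced subgraph, and a cluster's fused network.  Fused
    networks carry per-edge frequency counts in the ``count`` edge
    attribute (exposed through :attr:`edge_count`).
    """

    graph: nx.Graph
    kind: str = "static"

    def __post_init__(self) -> None:
        if self.kind not in NETWORK_KINDS:
            raise ValueError(f"kind must be one of {NETWORK_KINDS}, got {self.kind!r}")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loop on node {loops[0][0]!r}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def edge_count(self) -> dict[frozenset, int]:
        """Per-edge frequency counts (fused networks only)."""
        return {frozenset((u, v)): d["count"] for u, v, d in self.graph.edges(data=True) if "count" in d}

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], kind: str = "static") -> "GeneNetwork":
        g = nx.Graph()
        g.add_edges_from(edges)
        return cls(g, kind)


@dataclass(frozen=True)
class DiseaseAssociationCatalog:
    """Deduplicated (disease id, gene symbol) association pairs."""

    records: frozenset

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty association catalog")

    @property
    def diseases(self) -> set[str]:
        return {d for d, _ in self.records}

    @property
    def genes(self) -> set[str]:
        return {g for _, g in self.records}

    def genes_of(self, disease: str) -> set[str]:
        return {g for d, g in self.records if d == disease}


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path, condition: str) -> ExpressionMatrix:
    """Parse a TSV expression file into a stage=``raw`` matrix.

    Duplicate gene rows are collapsed by their arithmetic mean, keeping
    first-occurrence order.  Any non-numeric cell raises with the
    offending gene and sample named.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                          keep_default_na=False, na_values=[])
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty expression file: {path}") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"expression file has no data rows/columns: {path}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-numeric value {raw.iat[r, c]!r} at gene {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r} in {path}"
        )
    if numeric.index.has_duplicates:
        order = pd.unique(numeric.index)
        numeric = numeric.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionMatrix(numeric, condition=condition, stage="raw")


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene")


def to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample column to sum to 1e6 (TPM).

    Input values are assumed already length-normalized (FPKM/RPKM), so
    per-sample proportional rescaling is all that is needed.  All-zero
    columns are preserved as all-zero.
    """
    if m.stage != "raw":
        raise ValueError(f"to_tpm expects stage='raw', got {m.stage!r}")
    v = m.values.astype(float)
    sums = v.sum(axis=0)
    scale = np.divide(1e6, sums, out=np.zeros_like(sums), where=sums > 0)
    out = pd.DataFrame(v * scale, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(out, condition=m.condition, stage="tpm")


def preprocess(
    case: ExpressionMatrix,
    control: ExpressionMatrix,
    net: GeneNetwork,
    min_frac: float = 0.10,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Gene-level cleanup applied to TPM matrices, in order:

    1. TPM values below 1 are zeroed (unreliable quantification);
    2. values are replaced by log2(TPM+1);
    3. genes expressed (nonzero) in fewer than ``min_frac`` of the pooled
       case+control samples are removed;
    4. genes absent from the static interaction network are removed.

    Case and control are first restricted to their common gene universe
    and both outputs share the same surviving gene list and order.
    """
    if case.stage != "tpm" or control.stage != "tpm":
        raise ValueError("preprocess expects stage='tpm' matrices")
    if not 0 < min_frac < 1:
        raise ValueError("min_frac must be in (0, 1)")
    common = [g for g in case.gene_ids if g in set(control.gene_ids)]
    c = case.data.loc[common].astype(float).copy()
    k = control.data.loc[common].astype(float).copy()
    for df in (c, k):
        df[df < 1] = 0.0
    c = np.log2(c + 1.0)
    k = np.log2(k + 1.0)
    n_pooled = c.shape[1] + k.shape[1]
    expressed = (c > 0).sum(axis=1) + (k > 0).sum(axis=1)
    keep = expressed >= min_frac * n_pooled
    keep &= c.index.isin(net.nodes)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("preprocess: dropped %d of %d genes", n_dropped, len(common))
    genes = c.index[keep]
    if len(genes) == 0:
        raise ValueError("no genes survive preprocessing")
    return (
        ExpressionMatrix(c.loc[genes], condition=case.condition, stage="log2tpm"),
        ExpressionMatrix(k.loc[genes], condition=control.condition, stage="log2tpm"),
    )


# ---------------------------------------------------------------------------
# networks and gene sets


def read_edge_list(path: str | Path, kind: str = "static") -> GeneNetwork:
    """Read a two-column edge list; ``#`` comments skipped, self-loops
    dropped with a warning, duplicate/reversed edges deduplicated."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tokens, got {len(tokens)}")
            u, v = tokens
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
                continue
            g.add_edge(u, v)
    return GeneNetwork(g, kind=kind)


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    """Write a network as a sorted edge list; fused networks gain a third
    column with the edge frequency count."""
    with open(path, "w") as fh:
        for u, v, d in sorted(net.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
            a, b = sorted((u, v))
            if net.kind == "fused":
                fh.write(f"{a}\t{b}\t{d.get('count', 0)}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_fused_network(path: str | Path) -> GeneNetwork:
    """Read a three-column (gene, gene, count) fused-network edge list."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tokens, got {len(tokens)}")
            u, v, count = tokens
            g.add_edge(u, v, count=int(count))
    return GeneNetwork(g, kind="fused")


def read_gene_set(path: str | Path) -> set[str]:
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_catalog(path: str | Path) -> DiseaseAssociationCatalog:
    records = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t")
            if len(tokens) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated tokens")
            records.add((tokens[0], tokens[1]))
    return DiseaseAssociationCatalog(frozenset(records))


def write_catalog(cat: DiseaseAssociationCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for d, g in sorted(cat.records):
            fh.write(f"{d}\t{g}\n")
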