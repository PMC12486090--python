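"""Domain types and tabular/graph I/O shared by every pipeline stage.

The pipeline moves three kinds of tabular data around — per-layer molecule
abundance matrices (samples × molecules), a covariate table, and a genotype
dosage matrix — plus mixed graphs (molecule networks with directed and
undirected edges).  Matrices are CSV/TSV with a header row and an identifier
column; networks are written as edge-list TSV or GraphML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

MISSING_TOKENS = ("", "NA")

#: Covariate columns treated as categorical when building design matrices.
CATEGORICAL_COVARIATES = ("race_ethnicity", "batch", "batch_a", "batch_b")


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# Matrix-like containers
# ---------------------------------------------------------------------------


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DataError(f"duplicated {what} identifier {x!r}")
        seen.add(x)


@dataclass
class OmicsMatrix:
    """One omics layer: a samples × molecules abundance matrix.

    ``missing_mask`` is True where the measurement is absent; ``values`` is
    undefined (NaN) there and finite everywhere else.
    """

    layer_id: str
    sample_ids: list[str]
    molecule_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.molecule_ids, "molecule")
        n, p = len(self.sample_ids), len(self.molecule_ids)
        if self.values.shape != (n, p):
            raise DataError(
                f"values shape {self.values.shape} != ({n}, {p}) for layer {self.layer_id!r}"
            )
        if self.missing_mask.shape != self.values.shape:
            raise DataError("missing_mask shape differs from values shape")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise DataError(f"non-finite value outside missing_mask in layer {self.layer_id!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    def copy(self) -> "OmicsMatrix":
        return replace(
            self,
            sample_ids=list(self.sample_ids),
            molecule_ids=list(self.molecule_ids),
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.molecule_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, layer_id: str) -> "OmicsMatrix":
        vals = df.to_numpy(dtype=float)
        mask = ~np.isfinite(vals)
        vals = np.where(mask, np.nan, vals)
        return cls(
            layer_id=layer_id,
            sample_ids=[str(s) for s in df.index],
            molecule_ids=[str(c) for c in df.columns],
            values=vals,
            missing_mask=mask,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise DataError(f"samples not present in layer {self.layer_id!r}: {missing[:5]}")
        rows = [idx[s] for s in sample_ids]
        return OmicsMatrix(
            layer_id=self.layer_id,
            sample_ids=list(sample_ids),
            molecule_ids=list(self.molecule_ids),
            values=self.values[rows],
            missing_mask=self.missing_mask[rows],
        )

    def drop_molecules(self, names: Iterable[str]) -> "OmicsMatrix":
        drop = set(names)
        keep = [j for j, m in enumerate(self.molecule_ids) if m not in drop]
        return OmicsMatrix(
            layer_id=self.layer_id,
            sample_ids=list(self.sample_ids),
            molecule_ids=[self.molecule_ids[j] for j in keep],
            values=self.values[:, keep],
            missing_mask=self.missing_mask[:, keep],
        )


@dataclass
class CovariateTable:
    """Per-sample covariates (age, sex, race/ethnicity, batch, events, statin).

    Thin wrapper around a DataFrame indexed by sample id.  Columns listed in
    :data:`CATEGORICAL_COVARIATES` are expanded to indicator contrasts when a
    design matrix is built; all other columns are treated as numeric.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique([str(s) for s in self.table.index], "sample")
        self.table = self.table.copy()
        self.table.index = [str(s) for s in self.table.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def columns(self) -> list[str]:
        return list(self.table.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CovariateTable":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise DataError(f"samples without covariates: {missing[:5]}")
        return CovariateTable(self.table.loc[list(sample_ids)])


@dataclass
class GenotypeMatrix:
    """Samples × variants dosage matrix with per-variant minor allele frequency."""

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.variant_ids, "variant")
        n, p = len(self.sample_ids), len(self.variant_ids)
        if self.dosages.shape != (n, p):
            raise DataError(f"dosages shape {self.dosages.shape} != ({n}, {p})")
        if np.nanmin(self.dosages, initial=0.0) < -1e-9 or np.nanmax(self.dosages, initial=0.0) > 2 + 1e-9:
            raise DataError("dosages outside [0, 2]")
        if self.maf.shape != (p,):
            raise DataError("maf length differs from number of variants")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise DataError(f"samples without genotypes: {missing[:5]}")
        rows = [idx[s] for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            variant_ids=list(self.variant_ids),
            dosages=self.dosages[rows],
            maf=self.maf.copy(),
        )

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {v: j for j, v in enumerate(self.variant_ids)}
        cols = [idx[v] for v in variant_ids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=list(variant_ids),
            dosages=self.dosages[:, cols],
            maf=self.maf[cols],
        )


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def edge_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered node pair."""
    if a == b:
        raise DataError(f"self-edge on node {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class Edge:
    """One network edge.

    ``direction`` is None for an undirected edge, otherwise the ordered
    (source, target) pair.  ``strength_p`` is the worst-case (maximum)
    p-value over every conditional-independence test run for the pair; an
    edge survives only if that maximum is still below alpha, so small values
    mean the dependence could not be explained away by any tested subset.
    """

    strength_p: float
    direction: tuple[str, str] | None = None
    separating_set: frozenset[str] | None = None  # only for removed pairs

    @property
    def orientation(self) -> str:
        return "directed" if self.direction else "undirected"


@dataclass
class MoleculeNetwork:
    """Mixed graph over the molecules of one layer."""

    layer_id: str
    nodes: list[str]
    edges: dict[tuple[str, str], Edge] = field(default_factory=dict)
    alpha: float = math.nan
    #: separating sets recorded for removed pairs (used for collider detection)
    sepsets: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.nodes, "node")
        self.validate()

    def validate(self) -> None:
        node_set = set(self.nodes)
        for (a, b), e in self.edges.items():
            if a == b:
                raise DataError(f"self-edge on {a!r}")
            if (a, b) != edge_key(a, b):
                raise DataError(f"edge key {(a, b)} not in canonical order")
            if a not in node_set or b not in node_set:
                raise DataError(f"edge {(a, b)} references unknown node")
            if e.direction is not None and set(e.direction) != {a, b}:
                raise DataError(f"edge {(a, b)} direction {e.direction} inconsistent")
            if math.isfinite(self.alpha) and not (e.strength_p < self.alpha):
                raise DataError(
                    f"edge {(a, b)} strength_p {e.strength_p} not below alpha {self.alpha}"
                )
        dg = self.directed_subgraph()
        if not nx.is_directed_acyclic_graph(dg):
            raise DataError(f"directed subgraph of layer {self.layer_id!r} has a cycle")

    def adjacent(self, node: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == node:
                out.add(b)
            elif b == node:
                out.add(a)
        return out

    def has_edge(self, a: str, b: str) -> bool:
        return edge_key(a, b) in self.edges

    def directed_subgraph(self) -> nx.DiGraph:
        dg = nx.DiGraph()
        dg.add_nodes_from(self.nodes)
        for e in self.edges.values():
            if e.direction is not None:
                dg.add_edge(*e.direction)
        return dg

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edges)

    def directed_edges(self) -> set[tuple[str, str]]:
        return {e.direction for e in self.edges.values() if e.direction is not None}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), e in self.edges.items():
            g.add_edge(a, b, strength_p=e.strength_p, orientation=e.orientation,
                       source=e.direction[0] if e.direction else "",
                       target=e.direction[1] if e.direction else "")
        return g

    def copy(self) -> "MoleculeNetwork":
        return MoleculeNetwork(
            layer_id=self.layer_id,
            nodes=list(self.nodes),
            edges={k: Edge(e.strength_p, e.direction, e.separating_set) for k, e in self.edges.items()},
            alpha=self.alpha,
            sepsets=dict(self.sepsets),
        )


@dataclass
class IntegratedNetwork:
    """Union of frozen per-layer networks plus cross-layer bridge edges.

    The within-layer edge sets are never modified by integration (the
    structural-independence premise: each layer's network is learned on its
    maximal sample and treated as fixed).
    """

    layer_networks: dict[str, MoleculeNetwork]
    bridge_edges: dict[tuple[str, str], Edge]
    alpha_integration: float
    node_layer: dict[str, str]

    def __post_init__(self) -> None:
        for (a, b) in self.bridge_edges:
            la, lb = self.node_layer.get(a), self.node_layer.get(b)
            if la is None or lb is None:
                raise DataError(f"bridge edge {(a, b)} references unknown node")
            if la == lb:
                raise DataError(f"bridge edge {(a, b)} connects nodes of the same layer {la!r}")

    @property
    def bridging_molecules(self) -> list[str]:
        nodes = set()
        for a, b in self.bridge_edges:
            nodes.update((a, b))
        return sorted(nodes)


@dataclass
class AssociationTable:
    """Pairwise regression screen results (one row per molecule pair)."""

    table: pd.DataFrame  # columns: molecule_a, molecule_b, effect, se, p_value, fdr

    REQUIRED = ("molecule_a", "molecule_b", "effect", "se", "p_value", "fdr")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataError(f"AssociationTable missing columns {missing}")
        t = self.table
        if np.any(t["fdr"].to_numpy() + 1e-12 < t["p_value"].to_numpy()):
            raise DataError("fdr below p_value")

    def significant(self, level: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] < level].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _read_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
        dtype=str,
    )
    df.index = [str(s) for s in df.index]
    _check_unique(list(df.index), "sample")
    _check_unique([str(c) for c in df.columns], "column")
    return df


def _numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise DataError(
                f"non-numeric cell in {path.name}: row {row!r}, column {col!r}"
            )
        # python's float() is correctly rounded (pandas' fast parser is not),
        # so written matrices round-trip to full precision
        out[col] = df[col].astype(float)
    return pd.DataFrame(out, index=df.index)


def read_matrix(path: str | Path, kind: str, layer_id: str | None = None):
    """Read a samples × features table as the requested domain type.

    kind is one of ``omics``, ``covariates``, ``genotypes``.  Empty cells and
    the token ``NA`` are treated as missing; missing cells are flagged, never
    silently zero-filled.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    raw = _read_table(path)
    if kind == "omics":
        df = _numeric(raw, path)
        return OmicsMatrix.from_frame(df, layer_id=layer_id or path.stem)
    if kind == "covariates":
        cols = {}
        for col in raw.columns:
            if col in CATEGORICAL_COVARIATES:
                cols[col] = raw[col].astype(str)
            else:
                cols[col] = _numeric(raw[[col]], path)[col]
        return CovariateTable(pd.DataFrame(cols, index=raw.index))
    if kind == "genotypes":
        df = _numeric(raw, path)
        dosages = df.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(dosages, axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        return GenotypeMatrix(
            sample_ids=list(df.index),
            variant_ids=[str(c) for c in df.columns],
            dosages=dosages,
            maf=maf,
        )
    raise DataError(f"unknown matrix kind {kind!r}")


def write_matrix(m: OmicsMatrix | GenotypeMatrix | CovariateTable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(m, OmicsMatrix):
        df = m.to_frame()
    elif isinstance(m, GenotypeMatrix):
        df = pd.DataFrame(m.dosages, index=m.sample_ids, columns=m.variant_ids)
    else:
        df = m.table
    df.to_csv(path, sep=_sep_for(path), index_label="sample_id", na_rep="NA",
              float_format="%.17g")


def _edge_rows(net: MoleculeNetwork | IntegratedNetwork):
    if isinstance(net, MoleculeNetwork):
        for (a, b), e in sorted(net.edges.items()):
            src, tgt = e.direction if e.direction else (a, b)
            yield src, tgt, e.orientation, e.strength_p, net.layer_id
    else:
        for lid, ln in sorted(net.layer_networks.items()):
            for (a, b), e in sorted(ln.edges.items()):
                src, tgt = e.direction if e.direction else (a, b)
                yield src, tgt, e.orientation, e.strength_p, lid
        for (a, b), e in sorted(net.bridge_edges.items()):
            src, tgt = e.direction if e.direction else (a, b)
            layers = f"{net.node_layer[src]}|{net.node_layer[tgt]}"
            yield src, tgt, e.orientation, e.strength_p, layers


def write_network(net: MoleculeNetwork | IntegratedNetwork, path: str | Path,
                  format: str = "tsv") -> None:
    """Serialize a network as edge-list TSV or GraphML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = list(_edge_rows(net))
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\torientation\tstrength_p\tlayer\n")
            for src, tgt, orient, p, layer in rows:
                fh.write(f"{src}\t{tgt}\t{orient}\t{p:.12e}\t{layer}\n")
    elif format == "graphml":
        g = nx.Graph()
        if isinstance(net, MoleculeNetwork):
            g.add_nodes_from((n, {"layer": net.layer_id}) for n in net.nodes)
        else:
            for lid, ln in net.layer_networks.items():
                g.add_nodes_from((n, {"layer": lid}) for n in ln.nodes)
        for src, tgt, orient, p, layer in rows:
            g.add_edge(src, tgt, orientation=orient, strength_p=p, layer=layer,
                       source_node=src, target_node=tgt)
        nx.write_graphml(g, path)
    else:
        raise DataError(f"unknown network format {format!r}")


def read_network_tsv(path: str | Path, layer_id: str = "network",
                     alpha: float = math.nan) -> MoleculeNetwork:
    """Read an edge-list TSV written by :func:`write_network` (single layer)."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    edges: dict[tuple[str, str], Edge] = {}
    nodes: list[str] = []
    seen = set()
    for _, row in df.iterrows():
        a, b = str(row["source"]), str(row["target"])
        for n in (a, b):
            if n not in seen:
                seen.add(n)
                nodes.append(n)
        direction = (a, b) if row["orientation"] == "directed" else None
        edges[edge_key(a, b)] = Edge(float(row["strength_p"]), direction)
    return MoleculeNetwork(layer_id=layer_id, nodes=nodes, edges=edges, alpha=alpha)


def write_association_table(t: AssociationTable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
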