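"""Within-layer conditional-independence network learning.

An edge between two molecules survives only if their partial correlation
given every tested subset of the other molecules remains significant — the
retained edge's ``strength_p`` is the *worst-case* (largest) p-value across
all of those tests, so it quantifies how robustly the dependence resists
explanation by other molecules.

The skeleton search is the order-independent ("stable") variant of the
constraint-based PC adjacency search: conditioning sets of growing size are
drawn from the adjacency sets frozen at the start of each size level, which
makes the result invariant to molecule ordering.  The significance level is
chosen with the SPOT rule: learn the skeleton on a grid alpha = 10^-i,
i = 2..5, and pick the level where the topology stabilizes (minimal Hamming
distance between consecutive levels).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import DataError, Edge, MoleculeNetwork, OmicsMatrix, edge_key


@dataclass
class CITestRecord:
    pair: tuple[str, str]
    conditioning_set: frozenset[str]
    statistic: float
    p_value: float


@dataclass
class SPOTConfig:
    """Alpha grid for SPOT selection, sorted descending."""

    alpha_grid: list[float] = field(default_factory=lambda: [1e-2, 1e-3, 1e-4, 1e-5])

    def __post_init__(self) -> None:
        if len(self.alpha_grid) < 2:
            raise DataError("SPOT grid needs at least 2 levels")
        if any(a2 >= a1 for a1, a2 in zip(self.alpha_grid, self.alpha_grid[1:])):
            raise DataError("SPOT grid must be sorted descending")


def partial_correlation(X: np.ndarray, i: int, j: int, S: tuple[int, ...]) -> float:
    """Sample partial correlation of columns i, j given columns S."""
    x, y = X[:, i], X[:, j]
    if S:
        Z = np.column_stack([np.ones(X.shape[0]), X[:, list(S)]])
        coef, _, rank, _ = np.linalg.lstsq(Z, np.column_stack([x, y]), rcond=None)
        if rank < Z.shape[1]:
            raise DataError(f"singular conditioning design for columns {list(S)}")
        res = np.column_stack([x, y]) - Z @ coef
        rx, ry = res[:, 0], res[:, 1]
    else:
        rx, ry = x - x.mean(), y - y.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom <= 0:
        raise DataError("zero-variance residual in partial correlation")
    return float(np.clip((rx @ ry) / denom, -1.0, 1.0))


def fisher_z_test(r: float, n: int, k: int) -> tuple[float, float]:
    """Fisher-z statistic and two-sided p for a partial correlation.

    z = sqrt(n - k - 3) * atanh(r) with k the conditioning-set size.
    """
    dof = n - k - 3
    if dof < 1:
        raise DataError(f"n={n} too small for conditioning-set size {k}")
    r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    z = np.sqrt(dof) * np.arctanh(r)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def ci_test(
    x: str,
    y: str,
    S: tuple[str, ...] | frozenset[str],
    data: OmicsMatrix,
) -> CITestRecord:
    """Conditional-independence test between two molecules given a subset."""
    cols = {m: j for j, m in enumerate(data.molecule_ids)}
    S = tuple(sorted(S))
    if x in S or y in S:
        raise DataError("conditioning set must exclude the tested pair")
    r = partial_correlation(data.values, cols[x], cols[y], tuple(cols[s] for s in S))
    z, p = fisher_z_test(r, data.n_samples, len(S))
    return CITestRecord(pair=(x, y), conditioning_set=frozenset(S), statistic=z, p_value=p)


def _pc_skeleton(
    X: np.ndarray,
    nodes: list[str],
    alpha: float,
    max_cond_size: int,
    record_tests: list[CITestRecord] | None = None,
) -> tuple[dict[tuple[str, str], Edge], dict[tuple[str, str], frozenset[str]]]:
    """Stable PC adjacency search over a data matrix; see module docstring."""
    n, p = X.shape
    if n - max_cond_size - 3 < 1:
        raise DataError(f"n={n} too small for max_cond_size={max_cond_size}")
    idx = {m: j for j, m in enumerate(nodes)}
    adj: dict[str, set[str]] = {m: set(nodes) - {m} for m in nodes}
    max_p: dict[tuple[str, str], float] = {}
    sepsets: dict[tuple[str, str], frozenset[str]] = {}

    for level in range(max_cond_size + 1):
        frozen = {m: frozenset(adj[m]) for m in nodes}
        pairs = sorted(
            edge_key(a, b) for a in nodes for b in adj[a] if a < b
        )
        any_tested = False
        for a, b in pairs:
            if b not in adj[a]:
                continue
            cands: set[frozenset[str]] = set()
            for base in (frozen[a] - {b}, frozen[b] - {a}):
                if len(base) >= level:
                    for S in itertools.combinations(sorted(base), level):
                        cands.add(frozenset(S))
            removed = False
            for S in sorted(cands, key=lambda s: tuple(sorted(s))):
                any_tested = True
                r = partial_correlation(X, idx[a], idx[b], tuple(idx[s] for s in sorted(S)))
                z, pv = fisher_z_test(r, n, len(S))
                if record_tests is not None:
                    record_tests.append(CITestRecord((a, b), S, z, pv))
                key = (a, b)
                if pv > max_p.get(key, -1.0):
                    max_p[key] = pv
                if pv >= alpha:
                    adj[a].discard(b)
                    adj[b].discard(a)
                    sepsets[key] = frozenset(S)
                    removed = True
                    break
            if removed:
                continue
        if not any_tested:
            break

    edges = {
        edge_key(a, b): Edge(strength_p=max_p[edge_key(a, b)])
        for a in nodes
        for b in adj[a]
        if a < b
    }
    return edges, sepsets


def learn_skeleton(
    data: OmicsMatrix,
    alpha: float,
    max_cond_size: int = 3,
    record_tests: list[CITestRecord] | None = None,
) -> MoleculeNetwork:
    """Learn the undirected conditional-independence skeleton of one layer.

    ``data`` must hold standardized residuals with no missing values.
    Retained edges carry their worst-case conditional p-value; removed pairs
    record the separating set that explained them away.
    """
    if data.n_molecules < 2:
        raise DataError("need at least 2 molecules")
    if data.missing_mask.any():
        raise DataError("learn_skeleton expects fully observed data")
    edges, sepsets = _pc_skeleton(
        data.values, list(data.molecule_ids), alpha, max_cond_size, record_tests
    )
    return MoleculeNetwork(
        layer_id=data.layer_id,
        nodes=list(data.molecule_ids),
        edges=edges,
        alpha=alpha,
        sepsets=sepsets,
    )


def hamming_distance(g1: MoleculeNetwork, g2: MoleculeNetwork) -> int:
    """Number of unordered node pairs whose edge presence differs."""
    if set(g1.nodes) != set(g2.nodes):
        raise DataError("Hamming distance requires identical node sets")
    return len(g1.edge_set() ^ g2.edge_set())


def spot_select_alpha(
    data: OmicsMatrix,
    cfg: SPOTConfig | None = None,
    max_cond_size: int = 3,
) -> tuple[float, list[tuple[float, float, int]], dict[float, MoleculeNetwork]]:
    """Select the significance level by topology stability (SPOT).

    Learns the skeleton at every grid level, computes the Hamming distance
    between consecutive levels, and returns the larger alpha of the
    consecutive pair with minimal distance (ties prefer the larger alpha),
    together with the full (alpha_i, alpha_{i+1}, HD) profile and the
    per-level networks.
    """
    cfg = cfg or SPOTConfig()
    nets = {a: learn_skeleton(data, a, max_cond_size) for a in cfg.alpha_grid}
    profile = [
        (a1, a2, hamming_distance(nets[a1], nets[a2]))
        for a1, a2 in zip(cfg.alpha_grid, cfg.alpha_grid[1:])
    ]
    best = min(profile, key=lambda t: t[2])  # min() is stable: earlier (larger-alpha) pair wins ties
    return best[0], profile, nets
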