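"""Cross-layer network integration and the residual-independence direction test.

Per-layer networks are learned on each layer's maximal sample and then
*frozen*: integration never edits within-layer edges (the structural-
independence premise of cross-sectional multi-omics — each layer's topology
is already shaped by, and therefore robust to, variation in the others).
On the overlapping samples, every cross-layer molecule pair is tested for
conditional dependence given subsets drawn from the pair's within-layer
neighborhoods and any already-accepted bridge neighbors; a bridge edge
survives only if every tested subset fails to explain the dependence.

Direction between bridge endpoints is probed by residual independence: after
regressing y on x, the fitted residual is exactly uncorrelated with x, so a
*distance-correlation* permutation test of residual-vs-regressor is
conservative (p near 1) when x→y is the true linear direction with
independent noise, while in the anti-causal direction non-Gaussian noise
leaves genuine nonlinear dependence in the residual (small p).  Under
bivariate Gaussianity both directions look independent and the verdict is
inconclusive — the known non-identifiable case.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core_io import DataError, Edge, IntegratedNetwork, MoleculeNetwork, OmicsMatrix
from .network import fisher_z_test, partial_correlation


@dataclass
class IntegrationConfig:
    alpha_integration: float = 1e-2
    max_cond_size: int = 3
    min_overlap: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.alpha_integration < 1):
            raise DataError("alpha_integration must be in (0, 1)")


@dataclass
class DirectionTestResult:
    pair: tuple[str, str]
    p_forward: float  # independence p of residual(y|x) vs x
    p_reverse: float  # independence p of residual(x|y) vs y
    verdict: str  # "x->y", "y->x", or "inconclusive"
    dcor_forward: float
    dcor_reverse: float


def integrate_networks(
    net_a: MoleculeNetwork,
    net_b: MoleculeNetwork,
    data_a: OmicsMatrix,
    data_b: OmicsMatrix,
    cfg: IntegrationConfig | None = None,
) -> IntegratedNetwork:
    """Add cross-layer bridge edges between two frozen within-layer networks.

    ``data_a``/``data_b`` are the layers' preprocessed matrices; only their
    overlapping samples are used.  Within-layer edges are carried over
    untouched.  Each retained bridge carries the maximum conditional p-value
    observed across its tests.
    """
    cfg = cfg or IntegrationConfig()
    overlap = [s for s in data_a.sample_ids if s in set(data_b.sample_ids)]
    if len(overlap) == 0:
        raise DataError("no overlapping samples between layers")
    if len(overlap) < cfg.min_overlap:
        raise DataError(f"overlap {len(overlap)} below minimum {cfg.min_overlap}")
    A = data_a.subset_samples(overlap)
    B = data_b.subset_samples(overlap)
    if A.missing_mask.any() or B.missing_mask.any():
        raise DataError("integration expects fully observed (preprocessed) layers")
    if set(A.molecule_ids) & set(B.molecule_ids):
        raise DataError("layers share molecule identifiers")
    X = np.column_stack([A.values, B.values])
    names = list(A.molecule_ids) + list(B.molecule_ids)
    col = {m: j for j, m in enumerate(names)}
    n = len(overlap)
    alpha = cfg.alpha_integration

    candidates: set[tuple[str, str]] = {
        (a, b) for a in A.molecule_ids for b in B.molecule_ids
    }
    max_p: dict[tuple[str, str], float] = {}

    for level in range(cfg.max_cond_size + 1):
        if n - level - 3 < 1:
            break
        # bridge adjacency frozen at level start
        bridge_adj: dict[str, set[str]] = {}
        for a, b in candidates:
            bridge_adj.setdefault(a, set()).add(b)
            bridge_adj.setdefault(b, set()).add(a)
        removed: set[tuple[str, str]] = set()
        for a, b in sorted(candidates):
            pool = (
                net_a.adjacent(a)
                | net_b.adjacent(b)
                | (bridge_adj.get(a, set()) - {b})
                | (bridge_adj.get(b, set()) - {a})
            ) - {a, b}
            if len(pool) < level:
                continue
            for S in itertools.combinations(sorted(pool), level):
                r = partial_correlation(X, col[a], col[b], tuple(col[s] for s in S))
                _, pv = fisher_z_test(r, n, len(S))
                key = (a, b)
                if pv > max_p.get(key, -1.0):
                    max_p[key] = pv
                if pv >= alpha:
                    removed.add(key)
                    break
        candidates -= removed

    bridge_edges = {
        (a, b): Edge(strength_p=max_p[(a, b)]) for a, b in sorted(candidates)
    }
    node_layer = {m: net_a.layer_id for m in net_a.nodes}
    node_layer.update({m: net_b.layer_id for m in net_b.nodes})
    return IntegratedNetwork(
        layer_networks={net_a.layer_id: net_a.copy(), net_b.layer_id: net_b.copy()},
        bridge_edges=bridge_edges,
        alpha_integration=alpha,
        node_layer=node_layer,
    )


def find_bridges(net: IntegratedNetwork) -> list[dict]:
    """Bridging molecules with their cross-layer degree and strength.

    Strength is the summed −log10 of bridge-edge worst-case p-values; the
    list is sorted by strength, strongest first.
    """
    degree: dict[str, int] = {}
    strength: dict[str, float] = {}
    for (a, b), e in net.bridge_edges.items():
        s = -np.log10(max(e.strength_p, 1e-300))
        for node in (a, b):
            degree[node] = degree.get(node, 0) + 1
            strength[node] = strength.get(node, 0.0) + s
    out = [
        {
            "molecule": m,
            "layer": net.node_layer[m],
            "bridge_degree": degree[m],
            "bridge_strength": float(strength[m]),
        }
        for m in degree
    ]
    out.sort(key=lambda d: (-d["bridge_strength"], d["molecule"]))
    return out


# ---------------------------------------------------------------------------
# Distance correlation and the direction test
# ---------------------------------------------------------------------------


def _centered_distance_matrix(x: np.ndarray) -> np.ndarray:
    d = np.abs(x[:, None] - x[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Székely's (biased, V-statistic) sample distance correlation of two
    univariate samples."""
    A = _centered_distance_matrix(np.asarray(x, dtype=float))
    B = _centered_distance_matrix(np.asarray(y, dtype=float))
    dcov2 = (A * B).mean()
    dvx = (A * A).mean()
    dvy = (B * B).mean()
    if dvx <= 0 or dvy <= 0:
        raise DataError("zero-variance input to distance correlation")
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvx * dvy)))


def dcor_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 1999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation p-value for dependence between x and y via distance
    correlation (one-sided: large statistic = dependence).

    Returns (dcor, p).  p uses the add-one convention
    (1 + #{perm ≥ obs}) / (n_permutations + 1).
    """
    rng = rng or np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A = _centered_distance_matrix(x)
    B = _centered_distance_matrix(y)
    dvx = (A * A).mean()
    dvy = (B * B).mean()
    if dvx <= 0 or dvy <= 0:
        raise DataError("zero-variance input to distance correlation")
    denom = np.sqrt(dvx * dvy)
    obs = max((A * B).mean(), 0.0) / denom
    count = 0
    n = len(x)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        Bp = B[np.ix_(perm, perm)]
        stat = max((A * Bp).mean(), 0.0) / denom
        if stat >= obs:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return float(np.sqrt(obs)), float(p)


def residual_direction_test(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 1999,
    rng: np.random.Generator | None = None,
    alpha_verdict: float = 0.05,
    margin: float = 10.0,
    pair: tuple[str, str] = ("x", "y"),
) -> DirectionTestResult:
    """Probe the causal direction between two molecules by residual independence.

    p_forward tests residual(y|x) against x; p_reverse tests residual(x|y)
    against y.  In the *true* linear direction the fitted residual is
    independent of the regressor, so that test is calibrated: its p-value is
    roughly uniform, and a large value cannot be demanded.  What identifies
    the direction (with non-Gaussian noise) is the *anti-causal* residual
    retaining genuine dependence.  The verdict therefore favors x→y when the
    reverse test rejects independence (p_reverse < ``alpha_verdict``) while
    the forward test clearly does not (p_forward ≥ ``margin`` · p_reverse),
    and symmetrically for y→x; anything else — notably the bivariate
    Gaussian case, where both residuals are independent — is inconclusive.
    """
    rng = rng or np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise DataError("zero-variance input to direction test")

    def fitted_residual(resp: np.ndarray, pred: np.ndarray) -> np.ndarray:
        Z = np.column_stack([np.ones_like(pred), pred])
        beta, *_ = np.linalg.lstsq(Z, resp, rcond=None)
        return resp - Z @ beta

    d_f, p_f = dcor_permutation_test(fitted_residual(y, x), x, n_permutations, rng)
    d_r, p_r = dcor_permutation_test(fitted_residual(x, y), y, n_permutations, rng)
    if p_r < alpha_verdict and p_f >= margin * p_r:
        verdict = "x->y"
    elif p_f < alpha_verdict and p_r >= margin * p_f:
        verdict = "y->x"
    else:
        verdict = "inconclusive"
    return DirectionTestResult(
        pair=pair, p_forward=p_f, p_reverse=p_r, verdict=verdict,
        dcor_forward=d_f, dcor_reverse=d_r,
    )
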