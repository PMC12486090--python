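"""Causal-network construction from polygenic instruments.

Classical Mendelian randomization needs a single variant strongly associated
with each exposure; molecular traits rarely have one.  Instead, variants that
pass a per-layer association screen are summarized by principal components
("polygenic factors"), and factors that are strongly associated with exactly
one molecule's worth of signal (no pleiotropy) act as instrumental variables.
Because genotypes are fixed at conception, factor nodes are exogenous: their
edges always point into the molecular network, and that background knowledge
— together with collider detection and Meek propagation — orients molecule
edges.  Edges whose direction cannot be identified stay undirected.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core_io import (
    CovariateTable,
    DataError,
    Edge,
    GenotypeMatrix,
    MoleculeNetwork,
    OmicsMatrix,
    edge_key,
)
from .network import fisher_z_test, partial_correlation
from .pairwise import bulk_slope_tests
from .preprocess import build_design

logger = logging.getLogger(__name__)

ROLE_INDEPENDENT = "independent"
ROLE_ABSOLUTE_RECEIVER = "absolute_receiver"
ROLE_BROADCASTER = "broadcaster"
ROLE_RECEIVER = "receiver"
ROLE_MIXED = "mixed"


@dataclass
class PolygenicFactorSet:
    """Principal-component summaries of screened variants, with validity flags."""

    factor_ids: list[str]
    sample_ids: list[str]
    scores: np.ndarray  # samples × factors
    loadings: np.ndarray  # variants × factors
    variant_ids: list[str]
    explained_variance_frac: np.ndarray
    strong: dict[str, bool] = field(default_factory=dict)
    pleiotropic: dict[str, bool] = field(default_factory=dict)
    target: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.explained_variance_frac = np.asarray(self.explained_variance_frac, dtype=float)
        n, k = len(self.sample_ids), len(self.factor_ids)
        if self.scores.shape != (n, k):
            raise DataError(f"scores shape {self.scores.shape} != ({n}, {k})")
        if np.any(np.diff(self.explained_variance_frac) > 1e-12):
            raise DataError("explained_variance_frac must be non-increasing")

    @property
    def valid_factor_ids(self) -> list[str]:
        """Factors usable as instruments: strong and not pleiotropic."""
        return [
            f
            for f in self.factor_ids
            if self.strong.get(f, False) and not self.pleiotropic.get(f, True)
        ]

    def subset_samples(self, sample_ids) -> "PolygenicFactorSet":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return PolygenicFactorSet(
            factor_ids=list(self.factor_ids),
            sample_ids=list(sample_ids),
            scores=self.scores[rows],
            loadings=self.loadings,
            variant_ids=list(self.variant_ids),
            explained_variance_frac=self.explained_variance_frac,
            strong=dict(self.strong),
            pleiotropic=dict(self.pleiotropic),
            target=dict(self.target),
        )


@dataclass
class CausalNetwork:
    """A molecule network with (partially) oriented edges plus factor attachments."""

    network: MoleculeNetwork
    factor_ids: list[str]
    factor_edges: dict[tuple[str, str], Edge]  # (factor, molecule), always factor→molecule
    roles: dict[str, str] = field(default_factory=dict)
    strength: dict[str, float] = field(default_factory=dict)
    n_samples_orientation: int = 0
    conflicts: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (f, m), e in self.factor_edges.items():
            if e.direction != (f, m):
                raise DataError(f"factor edge {(f, m)} must point out of the factor")


# ---------------------------------------------------------------------------
# Variant screen and factor construction
# ---------------------------------------------------------------------------


def genotype_pcs(g: GenotypeMatrix, n_pcs: int) -> np.ndarray:
    """Top principal-component scores of the centered dosage matrix
    (population-stratification adjustment)."""
    X = g.dosages - g.dosages.mean(axis=0)
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    return pca.fit_transform(X)


def screen_variants(
    g: GenotypeMatrix,
    m: OmicsMatrix,
    cov: CovariateTable | None,
    n_pop_pcs: int = 5,
    p_cut: float = 0.05,
    covariate_names: tuple[str, ...] = ("sex", "age", "race_ethnicity"),
) -> tuple[list[str], pd.DataFrame]:
    """Per-variant association screen against a layer's molecules.

    Each molecule is regressed on each variant's dosage, adjusting for the
    listed covariates and the top genotype PCs; a variant survives if any
    molecule association has p < ``p_cut``.  Returns the surviving variant
    ids and the full variants × molecules p-value table.
    """
    common = [s for s in m.sample_ids if s in set(g.sample_ids)]
    if cov is not None:
        common = [s for s in common if s in set(cov.sample_ids)]
    if len(common) <= n_pop_pcs + len(covariate_names) + 3:
        raise DataError(f"too few samples ({len(common)}) for the variant screen")
    gs = g.subset_samples(common)
    ms = m.subset_samples(common)
    if ms.missing_mask.any():
        raise DataError("screen_variants expects fully observed molecules")

    sd = gs.dosages.std(axis=0)
    keep = sd > 0
    dropped = [v for v, k in zip(gs.variant_ids, keep) if not k]
    if dropped:
        warnings.warn(f"excluding {len(dropped)} constant dosage column(s): {dropped[:5]}")
    gs = gs.subset_variants([v for v, k in zip(gs.variant_ids, keep) if k])

    pcs = genotype_pcs(gs, n_pop_pcs)
    if cov is not None and covariate_names:
        C, _ = build_design(cov.subset_samples(common), list(covariate_names))
    else:
        C = np.ones((len(common), 1))
    C = np.column_stack([C, pcs])
    _, _, p = bulk_slope_tests(ms.values, gs.dosages, C)
    ptab = pd.DataFrame(p, index=gs.variant_ids, columns=ms.molecule_ids)
    screened = [v for v in gs.variant_ids if ptab.loc[v].min() < p_cut]
    return screened, ptab


def build_polygenic_factors(
    g: GenotypeMatrix,
    cumulative_variance: float = 0.80,
    n_factors: int | None = None,
) -> PolygenicFactorSet:
    """Polygenic factors as principal components of standardized dosages.

    Retains the smallest number of components reaching the cumulative
    explained-variance target (default 80%), or exactly ``n_factors`` when
    given; if fewer components exist than requested, all are retained.
    Component signs are fixed so the largest-magnitude loading is positive.
    """
    if len(g.variant_ids) < 2:
        raise DataError("need at least 2 screened variants for factor construction")
    sd = g.dosages.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DataError("constant dosage column; screen variants first")
    Z = (g.dosages - g.dosages.mean(axis=0)) / sd
    k_max = min(Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=k_max, svd_solver="full")
    scores = pca.fit_transform(Z)
    evr = pca.explained_variance_ratio_
    if n_factors is not None:
        k = min(n_factors, k_max)
    else:
        k = int(np.searchsorted(np.cumsum(evr), cumulative_variance) + 1)
        k = min(k, k_max)
    loadings = pca.components_.T[:, :k].copy()
    scores = scores[:, :k].copy()
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PolygenicFactorSet(
        factor_ids=[f"PF{j + 1}" for j in range(k)],
        sample_ids=list(g.sample_ids),
        scores=scores,
        loadings=loadings,
        variant_ids=list(g.variant_ids),
        explained_variance_frac=evr[:k],
    )


def assess_instruments(
    f: PolygenicFactorSet,
    m: OmicsMatrix,
    strong_p: float = 1e-3,
) -> PolygenicFactorSet:
    """Flag each factor's instrument validity against a layer's molecules.

    strong: marginally associated (p < strong_p) with at least one molecule.
    pleiotropic: no single candidate target molecule explains all of the
    factor's associations — i.e. for every candidate target the factor stays
    conditionally associated with some other molecule given that target.
    Only strong, non-pleiotropic factors are used for orientation.
    """
    common = [s for s in f.sample_ids if s in set(m.sample_ids)]
    fs = f.subset_samples(common)
    ms = m.subset_samples(common)
    n = len(common)
    C = np.ones((n, 1))
    _, _, p = bulk_slope_tests(ms.values, fs.scores, C)  # factors × molecules
    mol_idx = {mol: j for j, mol in enumerate(ms.molecule_ids)}
    for fi, fid in enumerate(fs.factor_ids):
        pvals = p[fi]
        candidates = [mol for j, mol in enumerate(ms.molecule_ids) if pvals[j] < strong_p]
        strong = len(candidates) > 0
        f.strong[fid] = strong
        if not strong:
            f.pleiotropic[fid] = False
            f.target[fid] = None
            continue
        X = np.column_stack([fs.scores[:, fi : fi + 1], ms.values])
        explaining: list[str] = []
        for t in candidates:
            t_col = 1 + mol_idx[t]
            residual_assoc = False
            for mol, j in mol_idx.items():
                if mol == t:
                    continue
                r = partial_correlation(X, 0, 1 + j, (t_col,))
                _, pv = fisher_z_test(r, n, 1)
                if pv < strong_p:
                    residual_assoc = True
                    break
            if not residual_assoc:
                explaining.append(t)
        f.pleiotropic[fid] = len(explaining) == 0
        if explaining:
            f.target[fid] = min(explaining, key=lambda t: pvals[mol_idx[t]])
        else:
            f.target[fid] = None
    return f


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------


def _attach_factors(
    skeleton: MoleculeNetwork,
    F: np.ndarray,
    factor_ids: list[str],
    M: np.ndarray,
    molecule_ids: list[str],
    alpha: float,
    max_cond_size: int,
) -> tuple[dict[tuple[str, str], Edge], dict[tuple[str, str], frozenset[str]]]:
    """Conditional-independence attachment of factor nodes to molecules.

    Same level-wise adjacency-restricted search as the skeleton: a factor
    stays attached to a molecule only if no tested conditioning subset
    (molecule neighbors and co-attached nodes) explains the dependence.
    """
    n = F.shape[0]
    X = np.column_stack([F, M])
    col = {fid: j for j, fid in enumerate(factor_ids)}
    col.update({mid: len(factor_ids) + j for j, mid in enumerate(molecule_ids)})
    attached: dict[str, set[str]] = {fid: set(molecule_ids) for fid in factor_ids}
    max_p: dict[tuple[str, str], float] = {}
    sepsets: dict[tuple[str, str], frozenset[str]] = {}

    for level in range(max_cond_size + 1):
        frozen_f = {fid: frozenset(attached[fid]) for fid in factor_ids}
        frozen_m: dict[str, frozenset[str]] = {}
        for mid in molecule_ids:
            co = {fid for fid in factor_ids if mid in attached[fid]}
            frozen_m[mid] = frozenset(skeleton.adjacent(mid)) | co
        any_tested = False
        for fid in factor_ids:
            for mid in sorted(frozen_f[fid]):
                if mid not in attached[fid]:
                    continue
                cands: set[frozenset[str]] = set()
                for base in (frozen_f[fid] - {mid}, frozen_m[mid] - {fid}):
                    if len(base) >= level:
                        for S in itertools.combinations(sorted(base), level):
                            cands.add(frozenset(S))
                for S in sorted(cands, key=lambda s: tuple(sorted(s))):
                    any_tested = True
                    r = partial_correlation(
                        X, col[fid], col[mid], tuple(col[s] for s in sorted(S))
                    )
                    _, pv = fisher_z_test(r, n, len(S))
                    key = (fid, mid)
                    if pv > max_p.get(key, -1.0):
                        max_p[key] = pv
                    if pv >= alpha:
                        attached[fid].discard(mid)
                        sepsets[key] = frozenset(S)
                        break
        if not any_tested:
            break

    edges = {
        (fid, mid): Edge(strength_p=max_p[(fid, mid)], direction=(fid, mid))
        for fid in factor_ids
        for mid in attached[fid]
    }
    return edges, sepsets


def _would_cycle(directions: dict[tuple[str, str], tuple[str, str]], src: str, tgt: str) -> bool:
    """True if adding src→tgt to the current directed edges creates a cycle."""
    adj: dict[str, set[str]] = {}
    for s, t in directions.values():
        adj.setdefault(s, set()).add(t)
    adj.setdefault(src, set()).add(tgt)
    # DFS from tgt looking for src
    stack, seen = [tgt], set()
    while stack:
        u = stack.pop()
        if u == src:
            return True
        if u in seen:
            continue
        seen.add(u)
        stack.extend(adj.get(u, ()))
    return False


def orient_edges(
    skeleton: MoleculeNetwork,
    factors: PolygenicFactorSet | None,
    data: OmicsMatrix,
    alpha: float,
    max_cond_size: int = 3,
    alpha_sep: float = 0.05,
) -> CausalNetwork:
    """Orient skeleton edges using valid polygenic instruments.

    Valid factors are attached to molecules by CI testing, forced to point
    outward (genotypes are exogenous), and the resulting unshielded triples
    are scanned for colliders; Meek rules 1–3 then propagate orientations.
    Molecule edges with no identified direction stay undirected; a rule
    conflict or a would-be cycle leaves the edge undirected with a warning.
    """
    nodes = list(skeleton.nodes)
    valid = factors.valid_factor_ids if factors is not None else []
    if factors is not None and valid:
        common = [s for s in data.sample_ids if s in set(factors.sample_ids)]
        fs = factors.subset_samples(common)
        ms = data.subset_samples(common)
        fcols = [factors.factor_ids.index(f) for f in valid]
        F = fs.scores[:, fcols]
        factor_edges, _ = _attach_factors(
            skeleton, F, valid, ms.values, ms.molecule_ids, alpha, max_cond_size
        )
        n_orient = len(common)
    else:
        factor_edges = {}
        n_orient = 0

    # adjacency over the augmented graph
    adj: dict[str, set[str]] = {v: skeleton.adjacent(v) for v in nodes}
    for fid in valid:
        adj.setdefault(fid, set())
    for fid, mid in factor_edges:
        adj[fid].add(mid)
        adj[mid].add(fid)

    # data matrix for triple re-testing: factors + molecules on the
    # orientation (intersection) sample when instruments exist
    if valid:
        X_orient = np.column_stack([F, ms.values])
        ocol = {fid: j for j, fid in enumerate(valid)}
        ocol.update({m: len(valid) + j for j, m in enumerate(ms.molecule_ids)})
        n_x = X_orient.shape[0]
    else:
        X_orient = data.values
        ocol = {m: j for j, m in enumerate(data.molecule_ids)}
        n_x = data.n_samples

    def separating_fraction(a: str, b: str, c: str) -> float | None:
        """Majority-rule collider evidence: fraction of separating sets of
        the nonadjacent pair (a, b) that contain c.  None if no tested
        subset separates the pair (ambiguous triple)."""
        cands: set[frozenset[str]] = set()
        for base in (adj[a] - {b}, adj[b] - {a}):
            pool = sorted(base)
            for size in range(0, min(len(pool), max_cond_size) + 1):
                if n_x - size - 3 < 1:
                    break
                for S in itertools.combinations(pool, size):
                    cands.add(frozenset(S))
        n_sep = n_with_c = 0
        for S in cands:
            r = partial_correlation(X_orient, ocol[a], ocol[b], tuple(ocol[s] for s in sorted(S)))
            _, pv = fisher_z_test(r, n_x, len(S))
            # declaring a set "separating" is an acceptance of independence;
            # the conventional alpha_sep level is used here rather than the
            # (much stricter) edge-retention alpha, which would overcall
            # independence and poison the collider vote
            if pv >= alpha_sep:
                n_sep += 1
                n_with_c += c in S
        if n_sep == 0:
            return None
        return n_with_c / n_sep

    directions: dict[tuple[str, str], tuple[str, str]] = {}
    conflicts: set[tuple[str, str]] = set()

    def orient(src: str, tgt: str) -> None:
        key = edge_key(src, tgt)
        if key in conflicts:
            return
        cur = directions.get(key)
        if cur == (src, tgt):
            return
        if cur is not None:
            logger.warning("orientation conflict on %s; leaving undirected", key)
            conflicts.add(key)
            del directions[key]
            return
        if tgt in valid:
            logger.warning("rule attempted to orient into factor %s; skipped", tgt)
            return
        if _would_cycle(directions, src, tgt):
            logger.warning("orientation %s→%s would create a cycle; skipped", src, tgt)
            conflicts.add(key)
            return
        directions[key] = (src, tgt)

    # v-structure (collider) detection on unshielded triples a—c—b, decided
    # by majority vote over all separating subsets (robust to an unlucky
    # single recorded separating set); triples with no clear vote are marked
    # ambiguous and excluded from orientation propagation
    triple_status: dict[tuple[str, str, str], str] = {}
    for c in nodes:  # a collider center cannot be a factor
        neigh = sorted(adj[c])
        for a, b in itertools.combinations(neigh, 2):
            if b in adj[a]:
                continue  # shielded
            frac = separating_fraction(a, b, c)
            if frac is None:
                triple_status[(a, b, c)] = "ambiguous"
            elif frac < 0.5:
                triple_status[(a, b, c)] = "collider"
            else:
                triple_status[(a, b, c)] = "noncollider"
    for (a, b, c), status in sorted(triple_status.items()):
        if status == "collider":
            orient(a, c)
            orient(b, c)

    def is_noncollider(z: str, x: str, y: str) -> bool:
        a, b = (z, y) if z < y else (y, z)
        return triple_status.get((a, b, x)) == "noncollider"

    # Meek propagation (rules 1–3), factor edges already directed outward
    changed = True
    while changed:
        changed = False
        undirected = [
            k for k in _molecule_edge_keys(skeleton) if k not in directions and k not in conflicts
        ]
        for a, b in undirected:
            for x, y in ((a, b), (b, a)):
                # R1: z→x, x–y, z and y nonadjacent, triple z-x-y a definite
                # non-collider  ⇒  x→y
                fired = False
                for z in sorted(adj[x]):
                    if z in (x, y) or y in adj[z]:
                        continue
                    if not is_noncollider(z, x, y):
                        continue
                    if directions.get(edge_key(z, x)) == (z, x) or (z, x) in factor_edges:
                        orient(x, y)
                        fired = True
                        break
                if fired and edge_key(x, y) in directions:
                    changed = True
                    break
                # R2: x→z→y with x–y  ⇒  x→y
                for z in sorted(adj[x] & adj[y]):
                    zx = directions.get(edge_key(x, z))
                    zy = directions.get(edge_key(z, y))
                    if zx == (x, z) and zy == (z, y):
                        orient(x, y)
                        if edge_key(x, y) in directions:
                            changed = True
                        fired = True
                        break
                if fired:
                    break
                # R3: x–z1→y, x–z2→y, z1,z2 nonadjacent, x–y  ⇒  x→y
                into_y = [
                    z
                    for z in sorted(adj[x] & adj[y])
                    if directions.get(edge_key(z, y)) == (z, y)
                    and edge_key(x, z) not in directions
                ]
                done = False
                for z1, z2 in itertools.combinations(into_y, 2):
                    if z2 not in adj[z1]:
                        orient(x, y)
                        if edge_key(x, y) in directions:
                            changed = True
                        done = True
                        break
                if done:
                    break

    out = skeleton.copy()
    for key, e in out.edges.items():
        e.direction = directions.get(key)
    out.validate()
    net = CausalNetwork(
        network=out,
        factor_ids=list(valid),
        factor_edges=factor_edges,
        n_samples_orientation=n_orient,
        conflicts=sorted(conflicts),
    )
    net.roles = classify_roles(net)
    net.strength = node_strength(net)
    return net


def _molecule_edge_keys(skeleton: MoleculeNetwork) -> list[tuple[str, str]]:
    return sorted(skeleton.edges)


# ---------------------------------------------------------------------------
# Node analytics
# ---------------------------------------------------------------------------


def classify_roles(net: CausalNetwork) -> dict[str, str]:
    """Role per molecule from directed in/out degree (undirected edges count
    toward neither): independent, absolute_receiver, broadcaster, receiver,
    or mixed.  Factor attachments are not counted."""
    mol_net = net.network
    indeg: dict[str, int] = {v: 0 for v in mol_net.nodes}
    outdeg: dict[str, int] = {v: 0 for v in mol_net.nodes}
    deg: dict[str, int] = {v: 0 for v in mol_net.nodes}
    for (a, b), e in mol_net.edges.items():
        deg[a] += 1
        deg[b] += 1
        if e.direction is not None:
            s, t = e.direction
            outdeg[s] += 1
            indeg[t] += 1
    roles = {}
    for v in mol_net.nodes:
        if deg[v] == 0:
            roles[v] = ROLE_INDEPENDENT
        elif outdeg[v] == 0 and indeg[v] >= 1:
            roles[v] = ROLE_ABSOLUTE_RECEIVER
        elif indeg[v] == 0 and outdeg[v] >= 1:
            roles[v] = ROLE_BROADCASTER
        elif indeg[v] > outdeg[v]:
            roles[v] = ROLE_RECEIVER
        else:
            roles[v] = ROLE_MIXED
    return roles


def node_strength(net: CausalNetwork, floor: float = 1e-300) -> dict[str, float]:
    """Connectivity strength per molecule: sum of −log10(strength_p) over
    incident molecule edges.  Zero p-values are clamped at ``floor``."""
    strength = {v: 0.0 for v in net.network.nodes}
    for (a, b), e in net.network.edges.items():
        p = e.strength_p
        if p <= 0:
            logger.warning("strength_p of %s is 0; clamping at %g", (a, b), floor)
            p = floor
        s = -np.log10(p)
        strength[a] += s
        strength[b] += s
    return strength
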