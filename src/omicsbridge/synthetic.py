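"""Synthetic multi-omics study generator with known ground truth.

Emulates the structure of a cross-sectional glycomics/lipidomics cohort:
two molecule layers generated from sparse linear structural equation models
(SEMs) with a planted cross-layer bridge edge, per-molecule polygenic
anchors in a simulated genotype panel, covariate and batch effects, a
compositional (percent-of-total) readout for the glycan-like layer, nested
sample overlap (layer A ⊇ overlap ⊇ genotyped), and per-molecule
missingness.  Every draw flows from one seed, so identical specs give
byte-identical studies.

Noise defaults to a scaled, centered log-normal ("skewed") because the
residual-independence direction test is non-identifiable under Gaussian
noise; Gaussian noise is available for null calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CovariateTable, DataError, GenotypeMatrix, OmicsMatrix
from .causal import PolygenicFactorSet

GLYCAN_NAMES = [f"GP{i}" for i in range(1, 25)]
SPM_NAMES = [
    "5-HEPE", "18-HEPE", "15-HEPE", "EPA", "AA", "LTB4", "MCTR2",
    "PCTR2", "RvE2", "RvD1", "RvD2", "MaR1", "PD1", "LXA4",
]


@dataclass
class BridgeSpec:
    source_layer: str
    source: str
    target_layer: str
    target: str
    effect: float


@dataclass
class SyntheticStudySpec:
    seed: int = 0
    n_total: int = 456
    n_layer_a: int = 456
    n_overlap: int = 368
    n_genotyped: int = 266
    p_a: int = 24
    p_b: int = 14
    dag_density_a: float = 0.10
    dag_density_b: float = 0.10
    edge_weight_low: float = 0.4
    edge_weight_high: float = 0.8
    bridge_edges: list[BridgeSpec] = field(
        default_factory=lambda: [BridgeSpec("spms", "5-HEPE", "glycans", "GP21", 0.5)]
    )
    n_variants_a: int = 455
    n_variants_b: int = 750
    causal_variants_per_molecule: int = 4
    variant_effect_size: float = 0.25
    maf_low: float = 0.05
    maf_high: float = 0.5
    noise_family: str = "skewed"  # or "gaussian"
    noise_sd: float = 0.6
    covariate_effect_scale: float = 0.2
    batch_count_a: int = 3
    batch_count_b: int = 2
    batch_shift_sd: float = 0.3
    missing_rate_a: float = 0.0
    missing_rate_b: float = 0.03
    missing_rates: dict = field(default_factory=dict)  # per-molecule overrides
    compositional_a: bool = True
    compositional_base_low: float = 10.0
    compositional_base_high: float = 40.0
    population_structure: bool = False
    maf_divergence: float = 0.1

    def __post_init__(self) -> None:
        if not (self.n_genotyped <= self.n_overlap <= self.n_layer_a <= self.n_total):
            raise DataError("require n_genotyped <= n_overlap <= n_layer_a <= n_total")
        for d in (self.dag_density_a, self.dag_density_b):
            if not (0 <= d < 1):
                raise DataError("dag density must be in [0, 1)")
        if not (0.01 < self.maf_low <= self.maf_high <= 0.5):
            raise DataError("maf range must lie in (0.01, 0.5]")
        if self.noise_family not in ("gaussian", "skewed"):
            raise DataError("noise_family must be 'gaussian' or 'skewed'")


@dataclass
class GroundTruth:
    """Generating DAGs, SEM weights and wiring — the oracle for every test."""

    molecule_names: dict[str, list[str]]
    weights: dict[str, np.ndarray]  # weights[layer][i, j] = effect of mol i on mol j
    bridges: list[BridgeSpec]
    variant_effects: dict[str, np.ndarray]  # (n_variants, p) per layer
    latent_values: dict[str, np.ndarray]  # pre-compositional molecule values

    def skeleton_edges(self, layer: str) -> set[frozenset[str]]:
        names = self.molecule_names[layer]
        W = self.weights[layer]
        return {
            frozenset((names[i], names[j]))
            for i in range(len(names))
            for j in range(len(names))
            if W[i, j] != 0
        }

    def directed_edges(self, layer: str) -> set[tuple[str, str]]:
        names = self.molecule_names[layer]
        W = self.weights[layer]
        return {
            (names[i], names[j])
            for i in range(len(names))
            for j in range(len(names))
            if W[i, j] != 0
        }

    def sinks(self, layer: str) -> list[str]:
        """True absolute receivers within the layer DAG."""
        names = self.molecule_names[layer]
        W = self.weights[layer]
        out = []
        for j, name in enumerate(names):
            if np.any(W[:, j]) and not np.any(W[j, :]):
                out.append(name)
        return out


@dataclass
class SyntheticStudy:
    a: OmicsMatrix
    b: OmicsMatrix
    covariates: CovariateTable
    genotypes: GenotypeMatrix
    truth: GroundTruth
    spec: SyntheticStudySpec


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------


def _noise(rng: np.random.Generator, size, family: str, sd: float) -> np.ndarray:
    if family == "gaussian":
        return rng.normal(0.0, sd, size=size)
    # centered, scaled log-normal: right-skewed with mean 0 and SD `sd`
    s = 0.8
    raw = rng.lognormal(mean=0.0, sigma=s, size=size)
    mu = np.exp(s**2 / 2)
    sigma = np.sqrt((np.exp(s**2) - 1) * np.exp(s**2))
    return (raw - mu) / sigma * sd


def random_dag_weights(
    rng: np.random.Generator, p: int, density: float, w_low: float, w_high: float
) -> np.ndarray:
    """Weight matrix of a random DAG: a random topological order, each
    admissible pair present with probability ``density``, weights uniform in
    ±[w_low, w_high]."""
    order = rng.permutation(p)
    W = np.zeros((p, p))
    for a in range(p):
        for b in range(a + 1, p):
            if rng.random() < density:
                w = rng.uniform(w_low, w_high) * rng.choice([-1.0, 1.0])
                W[order[a], order[b]] = w
    return W


def simulate_genotypes(
    spec: SyntheticStudySpec,
    rng: np.random.Generator,
    n: int,
    n_variants: int,
    prefix: str,
) -> GenotypeMatrix:
    """Independent biallelic dosages, Binomial(2, MAF) per variant.

    With ``population_structure`` on, two equal subpopulations with MAFs
    diverged by ±maf_divergence exercise the PC adjustment downstream.
    """
    maf = rng.uniform(spec.maf_low, spec.maf_high, size=n_variants)
    if spec.population_structure:
        delta = rng.uniform(-spec.maf_divergence, spec.maf_divergence, size=n_variants)
        maf1 = np.clip(maf + delta, 0.011, 0.5)
        maf2 = np.clip(maf - delta, 0.011, 0.5)
        half = n // 2
        d1 = rng.binomial(2, maf1, size=(half, n_variants))
        d2 = rng.binomial(2, maf2, size=(n - half, n_variants))
        dosages = np.vstack([d1, d2]).astype(float)
    else:
        dosages = rng.binomial(2, maf, size=(n, n_variants)).astype(float)
    return GenotypeMatrix(
        sample_ids=[f"S{i + 1:04d}" for i in range(n)],
        variant_ids=[f"{prefix}{j + 1}" for j in range(n_variants)],
        dosages=dosages,
        maf=maf,
    )


def _simulate_covariates(spec: SyntheticStudySpec, rng: np.random.Generator, ids: list[str]) -> CovariateTable:
    n = len(ids)
    table = pd.DataFrame(
        {
            "age": rng.normal(66.0, 8.0, size=n),
            "sex": rng.binomial(1, 0.38, size=n),
            "race_ethnicity": rng.choice(["W", "B", "H"], size=n, p=[0.71, 0.17, 0.12]),
            "batch_a": [f"A{b + 1}" for b in rng.integers(0, spec.batch_count_a, size=n)],
            "batch_b": [f"B{b + 1}" for b in rng.integers(0, spec.batch_count_b, size=n)],
            "cvd_event": rng.binomial(1, 0.05, size=n),
            "statin_use": rng.binomial(1, 0.5, size=n),
        },
        index=ids,
    )
    return CovariateTable(table)


def simulate_layer(
    spec: SyntheticStudySpec,
    rng: np.random.Generator,
    layer: str,
    names: list[str],
    W: np.ndarray,
    genotype_std: np.ndarray | None,
    variant_effects: np.ndarray | None,
    cov: CovariateTable | None,
    batch_col: str | None,
    bridge_in: list[tuple[str, np.ndarray, float]] | None = None,
    n: int | None = None,
    compositional: bool = False,
) -> np.ndarray:
    """Generate one layer's latent molecule values in topological order.

    Each molecule is a linear combination of its within-layer parents,
    genetic anchors, incoming bridge values, covariate/batch effects, and
    noise from the configured family.  When ``compositional`` is set, a
    positive baseline is added and rows are rescaled to sum to 100 (the
    percent-of-total readout); the returned array is then the observed
    compositional matrix.
    """
    p = len(names)
    if n is None:
        n = genotype_std.shape[0] if genotype_std is not None else len(cov.sample_ids)
    vals = np.zeros((n, p))
    order = _topological_order(W)

    cov_coefs = {}
    if cov is not None:
        cov_coefs["age"] = rng.normal(0, spec.covariate_effect_scale, size=p)
        cov_coefs["sex"] = rng.normal(0, spec.covariate_effect_scale, size=p)
        cov_coefs["cvd_event"] = rng.normal(0, spec.covariate_effect_scale, size=p)
        cov_coefs["statin_use"] = rng.normal(0, spec.covariate_effect_scale, size=p)
        race_levels = sorted(set(cov.table["race_ethnicity"]))
        cov_coefs["race"] = {
            lv: rng.normal(0, spec.covariate_effect_scale, size=p) for lv in race_levels
        }
        if batch_col is not None:
            batch_levels = sorted(set(cov.table[batch_col]))
            cov_coefs["batch"] = {
                lv: rng.normal(0, spec.batch_shift_sd, size=p) for lv in batch_levels
            }

    noise = _noise(rng, (n, p), spec.noise_family, spec.noise_sd)
    bridge_map: dict[str, list[tuple[np.ndarray, float]]] = {}
    for tgt, src_vals, eff in bridge_in or []:
        bridge_map.setdefault(tgt, []).append((src_vals, eff))

    for j in order:
        v = noise[:, j].copy()
        parents = np.nonzero(W[:, j])[0]
        for i in parents:
            v += W[i, j] * vals[:, i]
        if genotype_std is not None and variant_effects is not None:
            wired = np.nonzero(variant_effects[:, j])[0]
            if wired.size:
                v += genotype_std[:, wired] @ variant_effects[wired, j]
        for src_vals, eff in bridge_map.get(names[j], []):
            v += eff * src_vals
        if cov is not None:
            age = (cov.table["age"].to_numpy(dtype=float) - 66.0) / 8.0
            v += cov_coefs["age"][j] * age
            v += cov_coefs["sex"][j] * cov.table["sex"].to_numpy(dtype=float)
            v += cov_coefs["cvd_event"][j] * cov.table["cvd_event"].to_numpy(dtype=float)
            v += cov_coefs["statin_use"][j] * cov.table["statin_use"].to_numpy(dtype=float)
            race = cov.table["race_ethnicity"].to_numpy()
            for lv, coefs in cov_coefs["race"].items():
                v += np.where(race == lv, coefs[j], 0.0)
            if batch_col is not None:
                batch = cov.table[batch_col].to_numpy()
                for lv, coefs in cov_coefs["batch"].items():
                    v += np.where(batch == lv, coefs[j], 0.0)
        vals[:, j] = v

    if compositional:
        base = rng.uniform(spec.compositional_base_low, spec.compositional_base_high, size=p)
        raw = np.maximum(base[None, :] + vals, 0.1)
        vals = raw / raw.sum(axis=1, keepdims=True) * 100.0
    return vals


def _topological_order(W: np.ndarray) -> list[int]:
    p = W.shape[0]
    indeg = {j: int(np.count_nonzero(W[:, j])) for j in range(p)}
    ready = sorted(j for j in range(p) if indeg[j] == 0)
    out: list[int] = []
    while ready:
        j = ready.pop(0)
        out.append(j)
        for k in np.nonzero(W[j, :])[0]:
            indeg[int(k)] -= 1
            if indeg[int(k)] == 0:
                ready.append(int(k))
        ready.sort()
    if len(out) != p:
        raise DataError("weight matrix has a directed cycle")
    return out


def _inject_missing(
    m: OmicsMatrix, rng: np.random.Generator, default_rate: float, overrides: dict
) -> OmicsMatrix:
    out = m.copy()
    for j, name in enumerate(out.molecule_ids):
        rate = float(overrides.get(name, default_rate))
        if rate <= 0:
            continue
        miss = rng.random(out.n_samples) < rate
        out.missing_mask[:, j] |= miss
        out.values[miss, j] = np.nan
    return out


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------


def simulate_study(spec: SyntheticStudySpec) -> SyntheticStudy:
    """Generate a complete two-layer study with genetics and ground truth.

    Layer B (lipid-like) is generated before layer A (glycan-like) so the
    default bridge (a layer-B molecule feeding a layer-A molecule) acts on
    every sample; observation then follows the nested design: layer A for
    ``n_layer_a`` samples, layer B for the ``n_overlap`` subset, genotypes
    for the ``n_genotyped`` subset.
    """
    rng = np.random.default_rng(spec.seed)
    all_ids = [f"S{i + 1:04d}" for i in range(spec.n_total)]
    order = rng.permutation(spec.n_total)
    ids_a = [all_ids[i] for i in sorted(order[: spec.n_layer_a])]
    ids_overlap = sorted(ids_a[i] for i in range(spec.n_overlap))
    ids_geno = sorted(ids_overlap[: spec.n_genotyped])

    cov = _simulate_covariates(spec, rng, all_ids)
    geno_a = simulate_genotypes(spec, rng, spec.n_total, spec.n_variants_a, "va_")
    geno_b = simulate_genotypes(spec, rng, spec.n_total, spec.n_variants_b, "vb_")

    names = {"glycans": GLYCAN_NAMES[: spec.p_a], "spms": SPM_NAMES[: spec.p_b]}
    if spec.p_a > len(GLYCAN_NAMES):
        names["glycans"] = [f"GP{i}" for i in range(1, spec.p_a + 1)]
    if spec.p_b > len(SPM_NAMES):
        names["spms"] = SPM_NAMES + [f"SPM{i}" for i in range(len(SPM_NAMES) + 1, spec.p_b + 1)]

    W_a = random_dag_weights(rng, spec.p_a, spec.dag_density_a, spec.edge_weight_low, spec.edge_weight_high)
    W_b = random_dag_weights(rng, spec.p_b, spec.dag_density_b, spec.edge_weight_low, spec.edge_weight_high)

    def wire(n_variants: int, p: int) -> np.ndarray:
        eff = np.zeros((n_variants, p))
        k = spec.causal_variants_per_molecule
        for j in range(p):
            lo = j * k
            if lo + k > n_variants:
                break
            signs = rng.choice([-1.0, 1.0], size=k)
            eff[lo : lo + k, j] = spec.variant_effect_size * signs
        return eff

    eff_a = wire(spec.n_variants_a, spec.p_a)
    eff_b = wire(spec.n_variants_b, spec.p_b)

    def std_dosages(g: GenotypeMatrix) -> np.ndarray:
        sd = g.dosages.std(axis=0)
        sd[sd == 0] = 1.0
        return (g.dosages - g.dosages.mean(axis=0)) / sd

    gstd_a, gstd_b = std_dosages(geno_a), std_dosages(geno_b)

    for br in spec.bridge_edges:
        if br.source_layer == br.target_layer:
            raise DataError("bridge must connect different layers")
        if br.source_layer != "spms" or br.target_layer != "glycans":
            raise DataError("bridges are generated from the 'spms' layer into 'glycans'")

    vals_b = simulate_layer(
        spec, rng, "spms", names["spms"], W_b, gstd_b, eff_b, cov, "batch_b", n=spec.n_total
    )
    b_idx = {m: j for j, m in enumerate(names["spms"])}
    bridge_in = [
        (br.target, vals_b[:, b_idx[br.source]], br.effect) for br in spec.bridge_edges
    ]
    vals_a_latent = simulate_layer(
        spec, rng, "glycans", names["glycans"], W_a, gstd_a, eff_a, cov, "batch_a",
        bridge_in=bridge_in, n=spec.n_total,
    )
    if spec.compositional_a:
        base = rng.uniform(spec.compositional_base_low, spec.compositional_base_high, size=spec.p_a)
        raw = np.maximum(base[None, :] + vals_a_latent, 0.1)
        vals_a = raw / raw.sum(axis=1, keepdims=True) * 100.0
    else:
        vals_a = vals_a_latent

    id_pos = {s: i for i, s in enumerate(all_ids)}
    rows_a = [id_pos[s] for s in ids_a]
    rows_ov = [id_pos[s] for s in ids_overlap]

    a = OmicsMatrix(
        layer_id="glycans",
        sample_ids=ids_a,
        molecule_ids=names["glycans"],
        values=vals_a[rows_a],
        missing_mask=np.zeros((len(ids_a), spec.p_a), dtype=bool),
    )
    b = OmicsMatrix(
        layer_id="spms",
        sample_ids=ids_overlap,
        molecule_ids=names["spms"],
        values=vals_b[rows_ov],
        missing_mask=np.zeros((len(ids_overlap), spec.p_b), dtype=bool),
    )
    a = _inject_missing(a, rng, spec.missing_rate_a, spec.missing_rates)
    b = _inject_missing(b, rng, spec.missing_rate_b, spec.missing_rates)

    genotypes = GenotypeMatrix(
        sample_ids=list(geno_a.sample_ids),
        variant_ids=list(geno_a.variant_ids) + list(geno_b.variant_ids),
        dosages=np.hstack([geno_a.dosages, geno_b.dosages]),
        maf=np.concatenate([geno_a.maf, geno_b.maf]),
    ).subset_samples(ids_geno)

    truth = GroundTruth(
        molecule_names=names,
        weights={"glycans": W_a, "spms": W_b},
        bridges=list(spec.bridge_edges),
        variant_effects={"glycans": eff_a, "spms": eff_b},
        latent_values={"glycans": vals_a_latent, "spms": vals_b},
    )
    return SyntheticStudy(a=a, b=b, covariates=cov, genotypes=genotypes, truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# Instrumented SEM fixture (for orientation studies)
# ---------------------------------------------------------------------------


def simulate_instrumented_sem(
    rng: np.random.Generator,
    n: int,
    p: int,
    density: float,
    instrument_strength: float = 0.6,
    noise_family: str = "gaussian",
    noise_sd: float = 0.6,
    w_low: float = 0.4,
    w_high: float = 0.8,
) -> tuple[OmicsMatrix, PolygenicFactorSet, np.ndarray]:
    """Linear SEM with one exogenous instrument per source node.

    Every node with at least one child receives its own standard-normal
    polygenic-factor instrument with the given strength, wired to that node
    only — the textbook valid-instrument condition.  Returns the molecule
    matrix, the factor set (scores = instrument values), and the true
    weight matrix.
    """
    W = random_dag_weights(rng, p, density, w_low, w_high)
    names = [f"M{j + 1}" for j in range(p)]
    sources = [j for j in range(p) if np.any(W[j, :])]
    G = rng.normal(size=(n, len(sources)))
    noise = _noise(rng, (n, p), noise_family, noise_sd)
    vals = np.zeros((n, p))
    src_pos = {j: k for k, j in enumerate(sources)}
    for j in _topological_order(W):
        v = noise[:, j].copy()
        for i in np.nonzero(W[:, j])[0]:
            v += W[i, j] * vals[:, i]
        if j in src_pos:
            v += instrument_strength * G[:, src_pos[j]]
        vals[:, j] = v
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    data = OmicsMatrix(
        layer_id="sem",
        sample_ids=sample_ids,
        molecule_ids=names,
        values=vals,
        missing_mask=np.zeros((n, p), dtype=bool),
    )
    k = len(sources)
    factors = PolygenicFactorSet(
        factor_ids=[f"PF{j + 1}" for j in range(k)],
        sample_ids=sample_ids,
        scores=G,
        loadings=np.eye(k),
        variant_ids=[f"v{j + 1}" for j in range(k)],
        explained_variance_frac=np.full(k, 1.0 / max(k, 1)),
    )
    return data, factors, W
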