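import numpy as np
import pandas as pd
import pytest

from omicsbridge import (
    CovariateTable,
    DataError,
    GenotypeMatrix,
    PolygenicFactorSet,
    assess_instruments,
    build_polygenic_factors,
    classify_roles,
    learn_skeleton,
    node_strength,
    orient_edges,
    screen_variants,
)
from omicsbridge.causal import CausalNetwork
from omicsbridge.core_io import Edge, MoleculeNetwork, edge_key
from omicsbridge.synthetic import simulate_instrumented_sem

from conftest import make_matrix


def _geno(rng, n, n_variants, maf=0.3):
    return GenotypeMatrix(
        sample_ids=[f"S{i + 1}" for i in range(n)],
        variant_ids=[f"v{j + 1}" for j in range(n_variants)],
        dosages=rng.binomial(2, maf, size=(n, n_variants)).astype(float),
        maf=np.full(n_variants, maf),
    )


def _cov(rng, n):
    return CovariateTable(
        pd.DataFrame(
            {
                "age": rng.normal(60, 8, n),
                "sex": rng.binomial(1, 0.4, n),
                "race_ethnicity": rng.choice(["W", "B", "H"], n),
            },
            index=[f"S{i + 1}" for i in range(n)],
        )
    )


class TestScreenVariants:
    def test_planted_effect_retained_with_high_power(self):
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n = 300
            # panel wide enough that the 5 stratification PCs cannot absorb
            # any single variant's signal
            g = _geno(rng, n, 30)
            dos = (g.dosages[:, 0] - g.dosages[:, 0].mean()) / g.dosages[:, 0].std()
            mols = rng.normal(size=(n, 3))
            mols[:, 1] += 0.5 * dos
            screened, _ = screen_variants(g, make_matrix(mols), _cov(rng, n))
            hits += "v1" in screened
        assert hits >= 24  # beta=0.5 at n=300 is essentially always detected

    def test_null_retention_matches_union_bound(self):
        # retention prob for a null variant ~ 1-(1-0.05)^n_molecules
        rng = np.random.default_rng(5)
        n, n_var, n_mol = 400, 300, 5
        g = _geno(rng, n, n_var)
        screened, _ = screen_variants(g, make_matrix(rng.normal(size=(n, n_mol))), _cov(rng, n))
        expected = 1 - 0.95**n_mol  # 0.226
        rate = len(screened) / n_var
        assert abs(rate - expected) < 4 * np.sqrt(expected * (1 - expected) / n_var)

    def test_zero_molecules_empty_screen(self, rng):
        g = _geno(rng, 100, 3)
        screened, ptab = screen_variants(g, make_matrix(np.zeros((100, 0))), _cov(rng, 100))
        assert screened == [] and ptab.shape == (3, 0)

    def test_constant_dosage_excluded_with_warning(self, rng):
        g = _geno(rng, 100, 3)
        g.dosages[:, 2] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            screened, ptab = screen_variants(g, make_matrix(rng.normal(size=(100, 2))), _cov(rng, 100))
        assert "v3" not in ptab.index


class TestPolygenicFactors:
    def test_rank_one_pair_gives_single_factor(self, rng):
        d = rng.binomial(2, 0.3, size=(200, 1)).astype(float)
        g = GenotypeMatrix(
            sample_ids=[f"S{i}" for i in range(200)],
            variant_ids=["v1", "v2"],
            dosages=np.hstack([d, d]),
            maf=np.array([0.3, 0.3]),
        )
        f = build_polygenic_factors(g)
        assert len(f.factor_ids) == 1
        assert f.explained_variance_frac[0] > 0.999

    def test_identity_covariance_spectrum_flat(self, rng):
        g = _geno(rng, 4000, 8)
        f = build_polygenic_factors(g, n_factors=8)
        assert f.explained_variance_frac.max() < 0.2  # ~1/8 each

    def test_reconstruction_with_all_components(self, rng):
        g = _geno(rng, 150, 6)
        f = build_polygenic_factors(g, n_factors=6)
        Z = (g.dosages - g.dosages.mean(0)) / g.dosages.std(0, ddof=1)
        np.testing.assert_allclose(f.scores @ f.loadings.T, Z, atol=1e-8)

    def test_scores_orthogonal(self, rng):
        g = _geno(rng, 300, 10)
        f = build_polygenic_factors(g, n_factors=5)
        gram = f.scores.T @ f.scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_single_variant_rejected(self, rng):
        with pytest.raises(DataError):
            build_polygenic_factors(_geno(rng, 50, 1))


class TestAssessInstruments:
    def _factors(self, scores, ids=None):
        n, k = scores.shape
        return PolygenicFactorSet(
            factor_ids=ids or [f"PF{j + 1}" for j in range(k)],
            sample_ids=[f"S{i + 1}" for i in range(n)],
            scores=scores,
            loadings=np.eye(k),
            variant_ids=[f"v{j + 1}" for j in range(k)],
            explained_variance_frac=np.full(k, 1.0 / k),
        )

    def test_single_target_factor_is_valid(self, rng):
        n = 500
        g = rng.normal(size=(n, 1))
        mols = rng.normal(size=(n, 4))
        mols[:, 0] += 0.6 * g[:, 0]
        mols[:, 1] += 0.7 * mols[:, 0]  # downstream molecule: mediated, not pleiotropy
        f = assess_instruments(self._factors(g), make_matrix(mols))
        assert f.strong["PF1"] and not f.pleiotropic["PF1"]
        assert f.target["PF1"] == "M1"
        assert f.valid_factor_ids == ["PF1"]

    def test_direct_two_target_factor_flagged_pleiotropic(self):
        flagged = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 500
            g = rng.normal(size=(n, 1))
            mols = rng.normal(size=(n, 4))
            mols[:, 0] += 0.6 * g[:, 0]
            mols[:, 2] += 0.6 * g[:, 0]
            f = assess_instruments(self._factors(g), make_matrix(mols))
            flagged += f.pleiotropic["PF1"]
        assert flagged >= 9

    def test_null_factor_not_strong(self, rng):
        f = assess_instruments(self._factors(rng.normal(size=(400, 1))),
                               make_matrix(rng.normal(size=(400, 3))))
        assert not f.strong["PF1"] and f.valid_factor_ids == []


class TestOrientEdges:
    def test_mr_core_case(self, rng):
        # G -> X -> Y: instrument adjacent to X, separated from Y given X
        n = 1000
        g = rng.normal(size=n)
        x = 0.6 * g + rng.normal(size=n)
        y = 0.8 * x + rng.normal(size=n)
        data = make_matrix(np.column_stack([x, y]), molecules=["X", "Y"])
        f = TestAssessInstruments()._factors(g[:, None])
        f = assess_instruments(f, data)
        net = orient_edges(learn_skeleton(data, 1e-3), f, data, 1e-3)
        assert net.network.directed_edges() == {("X", "Y")}
        assert ("PF1", "X") in net.factor_edges

    def test_no_factors_all_undirected_without_colliders(self, rng):
        n = 800
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(size=n)
        data = make_matrix(np.column_stack([x, y]), molecules=["X", "Y"])
        net = orient_edges(learn_skeleton(data, 1e-3), None, data, 1e-3)
        assert net.network.directed_edges() == set()

    def test_collider_oriented_without_instruments(self, rng):
        n = 1000
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        z = 0.7 * x + 0.7 * y + rng.normal(size=n) * 0.6
        data = make_matrix(np.column_stack([x, y, z]), molecules=["X", "Y", "Z"])
        net = orient_edges(learn_skeleton(data, 1e-3), None, data, 1e-3)
        assert net.network.directed_edges() == {("X", "Z"), ("Y", "Z")}

    def test_factor_edges_always_point_outward(self, rng):
        data, factors, _ = simulate_instrumented_sem(rng, 500, 10, 0.25)
        factors = assess_instruments(factors, data)
        net = orient_edges(learn_skeleton(data, 1e-3), factors, data, 1e-3)
        assert all(e.direction[0] == f for (f, _), e in net.factor_edges.items())
        net.network.validate()  # directed subgraph acyclic

    def test_removing_instruments_only_removes_directions(self):
        # with no instruments, the remaining directed edges (collider-driven)
        # are a subset of the instrumented ones; no identified edge flips
        for seed in range(5):
            rng = np.random.default_rng(seed)
            data, factors, _ = simulate_instrumented_sem(rng, 500, 8, 0.3)
            factors = assess_instruments(factors, data)
            skel = learn_skeleton(data, 1e-3)
            with_f = orient_edges(skel, factors, data, 1e-3).network.directed_edges()
            without = orient_edges(skel, None, data, 1e-3).network.directed_edges()
            flipped = {(b, a) for a, b in without} & with_f
            assert not flipped


class TestRolesAndStrength:
    def _causal(self, nodes, directed, undirected=(), strengths=None):
        edges = {}
        for a, b in directed:
            edges[edge_key(a, b)] = Edge((strengths or {}).get((a, b), 1e-9), direction=(a, b))
        for a, b in undirected:
            edges[edge_key(a, b)] = Edge((strengths or {}).get((a, b), 1e-9))
        mol = MoleculeNetwork(layer_id="L", nodes=list(nodes), edges=edges, alpha=1e-2)
        return CausalNetwork(network=mol, factor_ids=[], factor_edges={})

    def test_role_classification(self):
        net = self._causal(
            "ABCDEF",
            directed=[("A", "B"), ("A", "C"), ("A", "D"), ("C", "B"), ("D", "C")],
            undirected=[("E", "D")],
        )
        roles = classify_roles(net)
        assert roles["F"] == "independent"  # isolated
        assert roles["B"] == "absolute_receiver"  # in 2, out 0
        assert roles["A"] == "broadcaster"  # in 0, out 3
        assert roles["C"] == "receiver"  # in 2, out 1
        assert roles["E"] == "mixed"  # only undirected

    def test_node_strength_arithmetic(self):
        net = self._causal(
            "ABC", directed=[("A", "B")], undirected=[("B", "C")],
            strengths={("A", "B"): 1e-30, ("B", "C"): 1e-5},
        )
        s = node_strength(net)
        assert s["B"] == pytest.approx(35.0)
        assert s["A"] == pytest.approx(30.0)

    def test_independent_node_zero_strength(self):
        assert node_strength(self._causal("AB", directed=[], undirected=[]))["A"] == 0.0

    def test_zero_p_clamped(self):
        net = self._causal("AB", directed=[("A", "B")], strengths={("A", "B"): 0.0})
        assert net and node_strength(net)["A"] == pytest.approx(300.0)
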