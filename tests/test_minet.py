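"""MI estimation, thresholding, DPI pruning and network construction."""

import itertools

import numpy as np
import pytest

from cortexreg import minet, synthio
from cortexreg.minet import MINetwork, _edge_key
from cortexreg.study import ExpressionStudy
from tests.conftest import small_config


def gaussian_pair(rng, rho, n):
    z = rng.standard_normal((2, n))
    return z[0], rho * z[0] + np.sqrt(1 - rho * rho) * z[1]


class TestMutualInformation:
    @pytest.mark.parametrize("method", ["kde", "binned"])
    def test_symmetric_and_nonnegative(self, rng, method):
        x, y = gaussian_pair(rng, 0.5, 200)
        a = minet.mutual_information(x, y, method=method)
        b = minet.mutual_information(y, x, method=method)
        assert a >= 0
        assert abs(a - b) <= 1e-12

    def test_self_information_beats_shuffled(self, rng):
        x = rng.standard_normal(300)
        shuffled = rng.permutation(x)
        assert minet.mutual_information(x, x) > minet.mutual_information(x, shuffled)

    def test_kde_tracks_gaussian_closed_form(self, rng):
        # single mid-size check; the full oracle grid runs in acceptance
        x, y = gaussian_pair(rng, 0.6, 2000)
        truth = -0.5 * np.log(1 - 0.36)
        assert minet.mutual_information(x, y) == pytest.approx(truth, abs=0.05)

    def test_binned_orders_dependence(self, rng):
        x0, y0 = gaussian_pair(rng, 0.0, 500)
        x8, y8 = gaussian_pair(rng, 0.8, 500)
        assert minet.mutual_information(
            x8, y8, method="binned"
        ) > minet.mutual_information(x0, y0, method="binned")

    def test_constant_vector_warns_zero(self, rng):
        with pytest.warns(UserWarning):
            mi = minet.mutual_information(np.ones(50), rng.standard_normal(50))
        assert mi == 0.0

    def test_short_input_rejected(self, rng):
        with pytest.raises(ValueError):
            minet.mutual_information(np.arange(10.0), np.arange(10.0))


def _random_study(rng, g=40, n=120):
    return ExpressionStudy(
        genes=[f"g{i}" for i in range(g)],
        samples=[f"s{j}" for j in range(n)],
        values=rng.standard_normal((g, n)),
    )


class TestMIThreshold:
    def test_monotone_in_p(self, rng):
        study = _random_study(rng)
        t_loose = minet.mi_threshold(study, p_value=0.5, n_null=2000, seed=1)
        t_tight = minet.mi_threshold(study, p_value=1e-7, n_null=2000, seed=1)
        assert 0 < t_loose < t_tight

    def test_reproducible_under_seed(self, rng):
        study = _random_study(rng)
        a = minet.mi_threshold(study, p_value=1e-4, n_null=2000, seed=5)
        b = minet.mi_threshold(study, p_value=1e-4, n_null=2000, seed=5)
        assert a == b

    def test_small_null_rejected(self, rng):
        with pytest.raises(ValueError):
            minet.mi_threshold(_random_study(rng), n_null=500)

    def test_retained_fraction_calibrated_at_p01(self):
        # on independent genes the p=0.01 threshold should retain roughly
        # 1% of pairs (tail extrapolation tolerance: [0.003, 0.03])
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            study = _random_study(rng, g=40, n=120)
            thr = minet.mi_threshold(
                study, p_value=0.01, n_null=3000, seed=seed
            )
            mi = minet._all_pairs_binned_mi(
                study.values, minet.default_bins(study.n_samples)
            )
            iu = np.triu_indices(study.n_genes, 1)
            fracs.append(float((mi[iu] >= thr).mean()))
        assert 0.003 <= np.mean(fracs) <= 0.03


def brute_force_dpi(net: MINetwork, eps: float) -> set:
    """Independent triple-loop DPI oracle with the TF-protection rule."""
    removed = set()
    nodes = net.nodes
    mi = net.edges
    for i, j, k in itertools.combinations(nodes, 3):
        e_ij, e_ik, e_jk = _edge_key(i, j), _edge_key(i, k), _edge_key(j, k)
        if e_ij not in mi or e_ik not in mi or e_jk not in mi:
            continue
        # weakest edge of the triangle, tolerance-scaled
        for (a, b), other1, other2 in (
            (e_ij, e_ik, e_jk),
            (e_ik, e_ij, e_jk),
            (e_jk, e_ij, e_ik),
        ):
            w = mi[(a, b)]
            if not w < min(mi[other1], mi[other2]) * (1 - eps):
                continue
            if net.is_tf.get(a) or net.is_tf.get(b):
                third = ({i, j, k} - {a, b}).pop()
                alt_ok = []
                for end in (a, b):
                    alt_ok.append(
                        not net.is_tf.get(end, False)
                        and not net.is_tf.get(third, False)
                    )
                if any(alt_ok):
                    continue
            removed.add((a, b))
    return removed


def random_network(rng, n_nodes=12, p_edge=0.5, tf_frac=0.25):
    nodes = [f"n{i}" for i in range(n_nodes)]
    is_tf = {v: bool(rng.random() < tf_frac) for v in nodes}
    edges = {}
    for a, b in itertools.combinations(nodes, 2):
        if rng.random() < p_edge:
            edges[_edge_key(a, b)] = float(rng.uniform(0.05, 1.0))
    return MINetwork(nodes=nodes, is_tf=is_tf, edges=edges)


class TestDPI:
    def test_chain_triangle_weakest_edge_removed(self):
        net = MINetwork(
            nodes=["x", "y", "z"],
            is_tf={"x": False, "y": False, "z": False},
            edges={("x", "y"): 0.9, ("y", "z"): 0.8, ("x", "z"): 0.3},
        )
        out = minet.apply_dpi(net, 0.1)
        assert set(out.edges) == {("x", "y"), ("y", "z")}

    def test_tf_edge_protected_from_nontf_alternative(self):
        # x is a TF; eliminating (x, z) would favor the (y, z) edge between
        # two non-TFs, which the protection rule forbids
        net = MINetwork(
            nodes=["x", "y", "z"],
            is_tf={"x": True, "y": False, "z": False},
            edges={("x", "y"): 0.9, ("y", "z"): 0.8, ("x", "z"): 0.3},
        )
        out = minet.apply_dpi(net, 0.1)
        assert ("x", "z") in out.edges

    def test_tolerance_one_preserves_everything(self, rng):
        net = random_network(rng)
        out = minet.apply_dpi(net, 1.0)
        assert out.edges == net.edges

    def test_idempotent(self, rng):
        net = random_network(rng)
        once = minet.apply_dpi(net, 0.1)
        twice = minet.apply_dpi(once, 0.1)
        assert once.edges == twice.edges

    def test_monotone_in_tolerance(self, rng):
        for _ in range(10):
            net = random_network(rng)
            previous = None
            for eps in (0.0, 0.1, 0.3, 0.7, 1.0):
                kept = set(minet.apply_dpi(net, eps).edges)
                if previous is not None:
                    assert previous <= kept
                previous = kept

    def test_matches_bruteforce_on_random_graphs(self, rng):
        for _ in range(30):
            net = random_network(rng, n_nodes=int(rng.integers(4, 13)))
            expected = set(net.edges) - brute_force_dpi(net, 0.1)
            assert set(minet.apply_dpi(net, 0.1).edges) == expected


class TestBuildNetwork:
    def test_markov_chain_keeps_direct_edges_only(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(500 + seed)
            n = 2000
            x = rng.standard_normal(n)
            y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(n)
            z = 0.9 * y + np.sqrt(1 - 0.81) * rng.standard_normal(n)
            study = ExpressionStudy(
                genes=["X", "Y", "Z"],
                samples=[f"s{i}" for i in range(n)],
                values=np.array([x, y, z]),
            )
            net = minet.build_mi_network(
                study, [], p_value=1e-4, seed=seed, n_null=2000
            )
            if set(net.edges) == {("X", "Y"), ("Y", "Z")}:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_independent_genes_give_almost_no_edges(self, rng):
        study = _random_study(rng, g=30, n=100)
        net = minet.build_mi_network(study, [], p_value=1e-4, seed=0)
        assert net.n_edges() <= 3

    def test_too_few_samples_rejected(self, rng):
        study = _random_study(rng, g=5, n=10)
        with pytest.raises(ValueError):
            minet.build_mi_network(study, [])

    def test_missing_tfs_ignored(self, rng):
        study = _random_study(rng, g=20, n=100)
        net = minet.build_mi_network(study, ["g0", "nope"], p_value=1e-3, seed=0)
        assert net.is_tf["g0"] and "nope" not in net.is_tf


class TestBootstrapConsensus:
    @pytest.fixture(scope="class")
    @classmethod
    def consensus(cls):
        cfg = small_config(seed=31, n_genes=250, n_module_genes=50, regulon_size=10)
        study, truth = synthio.generate_expression(cfg)
        net = minet.bootstrap_consensus(
            study,
            rounds=25,
            tf_list=sorted(truth.regulons),
            seed=3,
        )
        return study, truth, net

    def test_planted_regulon_edges_recovered_with_high_support(self, consensus):
        _, truth, net = consensus
        supports = []
        for tf in truth.driver_tfs:
            for target in truth.regulons[tf]:
                e = _edge_key(tf, target)
                if e in net.support:
                    supports.append(net.support[e])
        assert len(supports) >= 0.6 * sum(
            len(truth.regulons[tf]) for tf in truth.driver_tfs
        )
        assert np.mean(supports) >= 0.8

    def test_consensus_contains_unanimous_edges(self, consensus):
        _, _, net = consensus
        unanimous = [e for e, s in net.support.items() if s == 1.0]
        assert unanimous
        assert all(e in net.edges for e in unanimous)

    def test_round_guards(self, rng):
        study = _random_study(rng)
        with pytest.raises(ValueError):
            minet.bootstrap_consensus(study, rounds=1)
        with pytest.raises(ValueError):
            minet.bootstrap_consensus(study, rounds=10_001)


class TestRegulons:
    def test_targets_are_neighbors(self):
        net = MINetwork(
            nodes=["t", "a", "b", "c", "x"],
            is_tf={"t": True, "a": False, "b": False, "c": False, "x": False},
            edges={("a", "t"): 0.5, ("b", "t"): 0.4, ("c", "t"): 0.3, ("a", "b"): 0.2},
        )
        regs = minet.extract_regulons(net)
        assert regs == {"t": {"a", "b", "c"}}

    def test_planted_regulons_recovered(self, small_bundle):
        study, truth = small_bundle.study, small_bundle.truth
        net = minet.build_mi_network(study, sorted(truth.regulons), seed=2)
        regs = minet.extract_regulons(net)
        jacs = []
        for tf in truth.driver_tfs:
            rec, planted = regs.get(tf, set()), truth.regulons[tf]
            jacs.append(len(rec & planted) / len(rec | planted))
        assert np.mean(jacs) >= 0.6
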