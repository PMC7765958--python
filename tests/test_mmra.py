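"""Master-regulator analysis: consensus, Fisher, MI, SLR, full chain."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from mirmaster.containers import Signature, TargetDatabaseSet
from mirmaster.mmra import (
    MMRAConfig,
    build_network,
    consensus_targets,
    desk_scale_config,
    estimate_mi,
    mi_threshold,
    network_enrichment,
    run_mmra,
    stepwise_regression,
    target_enrichment,
    _ols_aic,
)
from mirmaster.simulate import SimulationConfig, generate_study, generate_target_databases

from conftest import make_matrix


def hypergeom_tail_oracle(overlap, n_targets, n_signature, n_universe):
    """Brute-force P(X >= overlap) by summing the hypergeometric pmf."""
    total = 0.0
    for k in range(overlap, min(n_targets, n_signature) + 1):
        total += (
            comb(n_signature, k, exact=True)
            * comb(n_universe - n_signature, n_targets - k, exact=True)
        )
    return total / comb(n_universe, n_targets, exact=True)


class TestConsensus:
    def test_two_source_pair_included(self):
        dbset = TargetDatabaseSet(
            sources={"A": {"m1": {"g1"}}, "B": {"m1": {"g1"}}, "C": {}}
        )
        assert consensus_targets(dbset)["m1"] == {"g1"}

    def test_single_source_pair_excluded(self):
        dbset = TargetDatabaseSet(sources={"A": {"m1": {"g1"}}, "B": {}, "C": {}})
        assert "m1" not in consensus_targets(dbset)

    def test_min_sources_exceeding_sources_rejected(self):
        dbset = TargetDatabaseSet(sources={"A": {}})
        with pytest.raises(ValueError):
            consensus_targets(dbset, min_sources=2)

    def test_randomized_fixture_matches_brute_force(self, rng):
        mirnas = [f"m{i}" for i in range(6)]
        genes = [f"g{i}" for i in range(15)]
        sources = {
            s: {
                m: {g for g in genes if rng.random() < 0.3} for m in mirnas
            }
            for s in "ABC"
        }
        dbset = TargetDatabaseSet(sources=sources)
        for min_sources in (1, 2, 3):
            result = consensus_targets(dbset, min_sources)
            for m in mirnas:
                for g in genes:
                    count = sum(g in sources[s].get(m, set()) for s in "ABC")
                    assert (g in result.get(m, set())) == (count >= min_sources)
            # nesting: consensus(k) subset of consensus(k-1)
            if min_sources > 1:
                weaker = consensus_targets(dbset, min_sources - 1)
                for m, gs in result.items():
                    assert gs <= weaker.get(m, set())


class TestFisherEnrichment:
    def test_hand_computed_tail(self):
        sig = Signature("c", frozenset({"g1", "g2", "g3", "g4", "g5"}), frozenset())
        universe = {f"g{i}" for i in range(1, 11)}
        up, down = target_enrichment("m", {"g1", "g2"}, sig, universe)
        assert up.table == (2, 0, 3, 5)
        assert np.isclose(up.p_value, 10 / 45)

    def test_zero_overlap_cannot_enrich(self):
        sig = Signature("c", frozenset({"g1", "g2"}), frozenset())
        universe = {f"g{i}" for i in range(10)} | {"g1", "g2"}
        up, _ = target_enrichment("m", {"g5", "g6"}, sig, universe)
        assert up.p_value == 1.0 and not up.passed

    def test_empty_targets_give_p_one_not_passed(self):
        sig = Signature("c", frozenset({"g1"}), frozenset())
        up, down = target_enrichment("m", set(), sig, {"g1", "g2"})
        assert up.p_value == 1.0 and not up.passed and not down.passed

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            target_enrichment("m", set(), Signature("c", frozenset(), frozenset()), set())

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_hypergeometric_tail_sum(self, data):
        n_universe = data.draw(st.integers(4, 60))
        n_signature = data.draw(st.integers(0, n_universe))
        n_targets = data.draw(st.integers(1, n_universe))
        universe = {f"g{i}" for i in range(n_universe)}
        sig_genes = set(itertools.islice(sorted(universe), n_signature))
        targets = set(sorted(universe)[-n_targets:])
        sig = Signature("c", frozenset(sig_genes), frozenset())
        up, _ = target_enrichment("m", targets, sig, universe)
        overlap = len(targets & sig_genes)
        assert np.isclose(
            up.p_value, hypergeom_tail_oracle(overlap, n_targets, n_signature, n_universe)
        )


class TestMutualInformation:
    def test_independent_vectors_near_zero(self, rng):
        x = rng.normal(size=200)
        y = rng.permutation(rng.normal(size=200))
        assert estimate_mi(x, y) < 0.1

    def test_identity_gives_log_bins(self, rng):
        x = rng.normal(size=24)  # 24 distinct values -> 3 equal-frequency bins
        # plug-in entropy of the uniform diagonal histogram is log(k)
        assert np.isclose(estimate_mi(x, x, miller_madow=False), math.log(3))
        assert np.isclose(estimate_mi(x, x, n_bins=4, miller_madow=False), math.log(4))
        # Miller-Madow subtracts (k_xy - k_x - k_y + 1)/(2n) = -2/48
        assert np.isclose(estimate_mi(x, x), math.log(3) + 2 / 48)

    def test_symmetry_and_nonnegativity(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert estimate_mi(x, y) == pytest.approx(estimate_mi(y, x))
        assert estimate_mi(x, y) >= 0

    def test_constant_vector_zero(self, rng):
        assert estimate_mi(np.ones(20), rng.normal(size=20)) == 0.0

    def test_gaussian_oracle_moderate_n(self, rng):
        rho = 0.9
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 5000)
        truth = -0.5 * math.log(1 - rho**2)
        assert abs(estimate_mi(z[:, 0], z[:, 1]) - truth) < 0.05

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            estimate_mi(np.arange(5), np.arange(5))


@pytest.fixture(scope="module")
def matrices():
    rng = np.random.default_rng(1)
    genes = make_matrix(rng.normal(size=(40, 24)))
    mirnas = make_matrix(rng.normal(size=(10, 24)))
    return genes, mirnas


class TestMiThreshold:

    def test_p_target_one_gives_zero(self, matrices):
        assert mi_threshold(*matrices, p_target=1.0) == 0.0

    def test_monotone_in_p_target(self, matrices):
        ts = [
            mi_threshold(*matrices, p_target=p, n_perm=1500, seed=3)
            for p in (1e-2, 1e-4, 1e-7)
        ]
        assert ts[0] < ts[1] < ts[2]

    def test_deterministic_under_seed(self, matrices):
        a = mi_threshold(*matrices, p_target=1e-4, n_perm=1200, seed=5)
        b = mi_threshold(*matrices, p_target=1e-4, n_perm=1200, seed=5)
        assert a == b

    def test_extrapolation_agrees_with_direct_permutation(self, matrices):
        genes, mirnas = matrices
        fitted = mi_threshold(genes, mirnas, p_target=0.01, n_perm=4000, seed=7)
        rng = np.random.default_rng(99)
        g = genes.to_numpy()
        m = mirnas.to_numpy()
        null = np.array(
            [
                estimate_mi(
                    g[rng.integers(g.shape[0])],
                    rng.permutation(m[rng.integers(m.shape[0])]),
                )
                for _ in range(10000)
            ]
        )
        direct = np.quantile(null, 0.99)
        assert abs(fitted - direct) / direct < 0.10

    def test_too_few_permutations_rejected(self, matrices):
        with pytest.raises(ValueError, match="n_perm"):
            mi_threshold(*matrices, p_target=1e-7, n_perm=200)


class TestBuildNetwork:
    def test_infinite_threshold_empty_network(self, small_study):
        _, study, _ = small_study
        hub = study.mirna_matrix.index[0]
        net = build_network(hub, study.gene_matrix, study.mirna_matrix, np.inf)
        assert net.edges == []

    def test_gene_row_order_invariance(self, small_study):
        _, study, _ = small_study
        hub = study.mirna_matrix.index[0]
        thr = 0.4
        a = build_network(hub, study.gene_matrix, study.mirna_matrix, thr)
        shuffled = study.gene_matrix.sample(frac=1, random_state=0)
        b = build_network(hub, shuffled, study.mirna_matrix, thr)
        assert a.genes == b.genes

    def test_planted_targets_recovered_at_desk_threshold(self):
        cfg = SimulationConfig(repression_strength=0.9, seed=3)
        study = generate_study(cfg)
        thr = mi_threshold(
            study.gene_matrix, study.mirna_matrix, p_target=1e-3, n_perm=2000, seed=3
        )
        regs: dict[str, set[str]] = {}
        for m, g, _ in study.truth.regulations:
            regs.setdefault(m, set()).add(g)
        hub = sorted(regs)[0]
        net = build_network(hub, study.gene_matrix, study.mirna_matrix, thr)
        targets = regs[hub]
        nontargets = set(study.gene_matrix.index) - targets
        assert len(net.genes & targets) / len(targets) >= 0.8
        assert len(net.genes - targets) / len(nontargets) <= 0.1


class TestStepwiseRegression:
    def test_orthogonal_candidate_rejected_by_aic(self, rng):
        n = 24
        y = pd.Series(rng.normal(size=n), name="g")
        x = rng.normal(size=n)
        x -= x.mean()
        yc = y - y.mean()
        x -= (x @ yc) / (yc @ yc) * yc  # exactly orthogonal to the response
        model = stepwise_regression(y, make_matrix([x], features=["m1"]))
        assert model.selected_mirnas == []
        # exhaustive confirmation: the intercept model beats the 1-var model
        aic0, _ = _ols_aic(y.to_numpy(), np.ones((n, 1)))
        aic1, _ = _ols_aic(y.to_numpy(), np.column_stack([np.ones(n), x]))
        assert aic0 < aic1

    def test_perfect_predictor_recovers_slope(self, rng):
        n = 24
        x = rng.normal(size=n)
        y = pd.Series(3.0 - 1.7 * x, name="g")
        model = stepwise_regression(y, make_matrix([x], features=["m1"]))
        assert model.selected_mirnas == ["m1"]
        assert model.coefficients["m1"] == pytest.approx(-1.7, abs=1e-8)

    def test_no_candidates_gives_intercept_model(self, rng):
        y = pd.Series(rng.normal(size=20), name="g")
        model = stepwise_regression(y, pd.DataFrame(np.empty((0, 20))))
        assert model.selected_mirnas == []

    def test_zero_variance_candidate_dropped(self, rng):
        n = 20
        y = pd.Series(rng.normal(size=n), name="g")
        X = make_matrix([np.ones(n), rng.normal(size=n)], features=["flat", "ok"])
        with pytest.warns(UserWarning, match="zero-variance"):
            model = stepwise_regression(y, X)
        assert model.candidate_mirnas == ["ok"]

    def test_greedy_is_local_optimum_and_usually_global(self, rng):
        n, p = 24, 6
        global_matches = 0
        reps = 25
        for _ in range(reps):
            X = rng.normal(size=(p, n))
            beta = np.zeros(p)
            beta[:2] = [1.0, -0.8]
            y = beta @ X + rng.normal(0, 1.0, n)
            model = stepwise_regression(
                pd.Series(y, name="g"), make_matrix(X, features=[f"m{i}" for i in range(p)])
            )
            # exhaustive subset oracle
            best_aic, best_set = np.inf, None
            for r in range(p + 1):
                for sub in itertools.combinations(range(p), r):
                    D = np.column_stack([np.ones(n)] + [X[i] for i in sub])
                    aic, _ = _ols_aic(y, D)
                    if aic < best_aic - 1e-12:
                        best_aic, best_set = aic, {f"m{i}" for i in sub}
            # local optimality: no single add/remove improves on the greedy model
            sel = set(model.selected_mirnas)
            for i in range(p):
                name = f"m{i}"
                neighbor = sel ^ {name}
                D = np.column_stack(
                    [np.ones(n)] + [X[int(s[1:])] for s in sorted(neighbor)]
                )
                aic, _ = _ols_aic(y, D)
                assert model.aic <= aic + 1e-9
            if sel == best_set:
                global_matches += 1
        assert global_matches / reps >= 0.7

    def test_candidate_truncation_when_underdetermined(self, rng):
        n = 12
        y = pd.Series(rng.normal(size=n), name="g")
        X = make_matrix(rng.normal(size=(n + 3, n)), features=[f"m{i:02d}" for i in range(n + 3)])
        model = stepwise_regression(y, X)
        assert len(model.candidate_mirnas) <= n - 3


class TestRunMMRA:
    def test_step_counts_monotone_nonincreasing(self, small_study):
        _, study, dbset = small_study
        result = run_mmra(study, dbset, "HFepa_vs_reference", desk_scale_config(seed=7))
        counts = result.step_counts
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert set(result.surviving) <= set(study.mirna_matrix.index)

    def test_empty_consensus_empties_the_result(self, small_study):
        cfg, study, _ = small_study
        import dataclasses

        cfg0 = dataclasses.replace(cfg, db_overlap=0.0, db_false_rate=0.0)
        dbset = generate_target_databases(study.truth, cfg0)
        result = run_mmra(study, dbset, "HFepa_vs_reference", desk_scale_config(seed=7))
        assert result.surviving == {}
        assert result.step_counts[1] == 0

    def test_audit_covers_every_de_mirna(self, small_study):
        _, study, dbset = small_study
        result = run_mmra(study, dbset, "HFepa_vs_reference", desk_scale_config(seed=7))
        de = set(result.mirna_de.loc[result.mirna_de["direction"] != "ns", "feature_id"])
        for m in de:
            assert result.audit[m] in {"step2", "step3", "step4", "survived"}
        survivors = {m for m, v in result.audit.items() if v == "survived"}
        assert survivors == set(result.surviving)

    def test_result_table_mirrors_surviving_pairs(self, small_study):
        _, study, dbset = small_study
        result = run_mmra(study, dbset, "HFepa_vs_reference", desk_scale_config(seed=7))
        table = result.to_table()
        assert set(zip(table["mirna"], table["gene"])) == result.pairs
        assert set(table["gene_signature"]) <= {"up", "down"}
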