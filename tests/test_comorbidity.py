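import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr, ttest_1samp

from layerprop.comorbidity import (
    CooccurrenceTable,
    ExperimentConfig,
    auc,
    build_labels,
    enrichment_by_tier,
    enrichment_ttest,
    run_experiment,
    shared_symptom_counts,
    shared_symptom_report,
)
from layerprop.network import Layer, MultiLayerNetwork
from layerprop.propagation import solve_single
from layerprop.simulate import GeneratorConfig, generate


def pairwise_auc_oracle(scores, truth):
    """Exhaustive Mann-Whitney comparison, ties counted one half."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    total = n = 0
    for sp in scores[truth]:
        for sn in scores[~truth]:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
            n += 1
    return total / n


def tiny_symptom_network():
    """4 diseases, 7 symptoms with hand-placed links.

    A ~ {s0,s1}; C ~ {s0..s5}; B ~ {s2..s5}; X ~ {s6} only.
    Shared counts: A&C = 2, B&C = 4, A&B = 0, X shares nothing.
    """
    d = Layer("disease", ("A", "B", "C", "X"))
    s = Layer("symptom", tuple(f"s{i}" for i in range(7)))
    inter = np.zeros((4, 7))
    inter[0, [0, 1]] = 1.0
    inter[2, [0, 1, 2, 3, 4, 5]] = 1.0
    inter[1, [2, 3, 4, 5]] = 1.0
    inter[3, 6] = 1.0
    return MultiLayerNetwork([d, s], [np.zeros((4, 4)), np.zeros((7, 7))], [inter])


class TestAuc:
    @pytest.mark.parametrize(
        "scores, truth, expected",
        [
            ((3, 2, 1), (1, 1, 0), 1.0),
            ((1, 2, 3), (1, 1, 0), 0.0),
            ((5, 5, 5, 5), (1, 0, 1, 0), 0.5),
        ],
    )
    def test_reference_cases(self, scores, truth, expected):
        assert auc(scores, truth) == expected

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], [1, 1])

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 25))
            scores = rng.choice([0.0, 0.25, 0.5, 1.0, 2.0], size=n)
            truth = rng.random(n) < 0.5
            if truth.all() or not truth.any():
                continue
            assert auc(scores, truth) == pytest.approx(
                pairwise_auc_oracle(scores, truth), abs=1e-12
            )


class TestCooccurrenceTable:
    def test_unordered_storage_and_membership(self):
        t = CooccurrenceTable([("b", "a"), ("a", "c")])
        assert len(t) == 2
        assert ("a", "b") in t and ("b", "a") in t
        assert t.neighbors()["a"] == {"b", "c"}

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            CooccurrenceTable([("a", "a")])

    def test_validation_against_network(self):
        net = tiny_symptom_network()
        CooccurrenceTable([("A", "B")]).validate_against(net, "disease")
        with pytest.raises(ValueError):
            CooccurrenceTable([("A", "nope")]).validate_against(net, "disease")


class TestBuildLabels:
    @pytest.fixture
    def planted(self):
        cfg = GeneratorConfig(n_diseases=20, n_symptoms=12, n_proteins=30, n_modules=4, seed=5)
        net, cooc, _ = generate(cfg)
        return net, cooc

    def test_fraction_zero_labels_no_symptoms(self, planted):
        net, cooc = planted
        target = sorted(cooc.neighbors())[0]
        cfg = ExperimentConfig(target_disease=target, symptom_label_fraction=0.0, seed=1)
        assign = build_labels(net, cfg, cooc)
        assert assign.labeled_symptoms == ()
        sympt = net.layer_slice("symptom")
        assert not assign.labels.values[sympt].any()

    def test_fraction_one_labels_every_related_symptom(self, planted):
        net, cooc = planted
        target = sorted(cooc.neighbors())[0]
        cfg = ExperimentConfig(target_disease=target, symptom_label_fraction=1.0, seed=1)
        assign = build_labels(net, cfg, cooc)
        t_local = net.layers[0].node_ids.index(target)
        related = {
            net.layers[1].node_ids[j]
            for j in np.flatnonzero(net.inter_blocks[0][t_local] > 0)
        }
        assert set(assign.labeled_symptoms) == related

    def test_same_seed_reproduces_labels(self, planted):
        net, cooc = planted
        target = sorted(cooc.neighbors())[0]
        cfg = ExperimentConfig(target_disease=target, symptom_label_fraction=0.5, seed=9)
        a1 = build_labels(net, cfg, cooc)
        a2 = build_labels(net, cfg, cooc)
        assert np.array_equal(a1.labels.values, a2.labels.values)
        assert a1.prior_diseases == a2.prior_diseases

    def test_target_without_partners_rejected(self):
        net = tiny_symptom_network()
        cfg = ExperimentConfig(target_disease="X")
        with pytest.raises(ValueError):
            build_labels(net, cfg, CooccurrenceTable([("A", "B")]))

    def test_prior_share_leaves_at_least_one_partner_hidden(self, planted):
        net, cooc = planted
        target = max(cooc.neighbors(), key=lambda d: len(cooc.neighbors()[d]))
        cfg = ExperimentConfig(
            target_disease=target, prior_cooccurrence_fraction=1.0, seed=2
        )
        assign = build_labels(net, cfg, cooc)
        assert len(assign.prior_diseases) == len(cooc.neighbors()[target]) - 1


class TestRunExperiment:
    @pytest.fixture
    def small_case(self):
        cfg = GeneratorConfig(n_diseases=30, n_symptoms=15, n_proteins=60, n_modules=6, seed=11)
        net, cooc, _ = generate(cfg)
        return net, cooc

    def test_reproducible_per_target_auc(self, small_case):
        net, cooc = small_case
        ec = ExperimentConfig(
            fractions=(0.0, 1.0), repeats=1, seed=4, mu_grid=((1.0, 0.1),)
        )
        r1 = run_experiment(net, cooc, ec)
        r2 = run_experiment(net, cooc, ec)
        pd.testing.assert_frame_equal(r1.records, r2.records)

    def test_symptom_labels_add_signal_on_planted_structure(self, small_case):
        net, cooc = small_case
        ec = ExperimentConfig(
            fractions=(0.0, 1.0), repeats=10, seed=0, mu_grid=((1.0, 0.1),)
        )
        res = run_experiment(net, cooc, ec)
        assert res.mean_auc_by_fraction[1.0] > res.mean_auc_by_fraction[0.0]

    def test_noise_inter_layer_leaves_auc_unchanged(self):
        # overlap == background: symptom links carry no co-occurrence signal
        deltas = []
        for seed in (0, 1, 2):
            cfg = GeneratorConfig(
                n_diseases=40,
                n_symptoms=20,
                n_proteins=80,
                n_modules=8,
                within_module_symptom_overlap=0.05,
                background_symptom_rate=0.05,
                seed=seed,
            )
            net, cooc, _ = generate(cfg)
            ec = ExperimentConfig(
                fractions=(0.0, 1.0), repeats=5, seed=seed, mu_grid=((1.0, 0.1),)
            )
            res = run_experiment(net, cooc, ec)
            deltas.append(res.mean_auc_by_fraction[1.0] - res.mean_auc_by_fraction[0.0])
        assert abs(float(np.mean(deltas))) <= 0.05

    def test_fraction_zero_equals_single_layer_solve(self, small_case):
        net, cooc = small_case
        ec = ExperimentConfig(fractions=(0.0,), repeats=1, seed=7, mu_grid=((2.0, 1.0),))
        res = run_experiment(net, cooc, ec)
        # recompute one target by hand through the single-layer path
        target = res.records["target"].iloc[0]
        rng = np.random.default_rng(np.random.SeedSequence(entropy=7, spawn_key=(0, 0, 0)))
        cfg1 = ExperimentConfig(
            target_disease=target, symptom_label_fraction=0.0, prior_cooccurrence_fraction=0.2
        )
        assign = build_labels(net, cfg1, cooc, rng)
        d_slice = net.layer_slice("disease")
        y_d = assign.labels.values[d_slice]
        f = solve_single(net.intra_blocks[0], y_d, 2.0).values
        disease_ids = net.layers[0].node_ids
        hidden = set(assign.prior_diseases) | {target}
        keep = [i for i, d in enumerate(disease_ids) if d not in hidden]
        truth = [disease_ids[i] in cooc.neighbors()[target] for i in keep]
        expect = auc(f[keep], truth)
        got = res.records[res.records["target"] == target]["auc"].iloc[0]
        assert got == pytest.approx(expect, abs=1e-12)

    def test_prior_labeled_diseases_never_enter_truth_set(self, small_case):
        # with 100% priors revealed, only one partner remains a positive;
        # records exist, so the evaluation set excluded the revealed labels
        net, cooc = small_case
        ec = ExperimentConfig(
            fractions=(1.0,),
            repeats=1,
            seed=3,
            prior_cooccurrence_fraction=1.0,
            mu_grid=((1.0, 0.1),),
        )
        res = run_experiment(net, cooc, ec)
        assert (res.records["auc"] <= 1.0).all()
        n_d = net.layers[0].size
        nbrs = cooc.neighbors()
        for target in res.records["target"]:
            # evaluation pool: all diseases minus target minus revealed priors
            assert len(nbrs[target]) >= 1

    def test_grid_selection_reports_best_pair(self, small_case):
        net, cooc = small_case
        ec = ExperimentConfig(
            fractions=(1.0,), repeats=2, seed=5, mu_grid=((1.0, 0.1), (0.01, 0.01))
        )
        res = run_experiment(net, cooc, ec)
        by_grid = res.records.groupby(["mu_a", "mu_b"])["auc"].mean()
        assert res.chosen_params == by_grid.idxmax()
        assert set(res.per_target_auc(1.0)) <= set(net.layers[0].node_ids)


class TestEnrichment:
    def test_hand_computed_t_statistic(self):
        # differences (1, 2, 3): mean 2, sd 1, t = 2 sqrt(3), df = 2
        net = tiny_symptom_network()
        cooc = CooccurrenceTable([("A", "B"), ("A", "C"), ("B", "C")])
        res = enrichment_ttest(net, cooc)
        assert sorted(res.per_disease_differences) == [1.0, 2.0, 3.0]
        assert res.df == 2
        assert res.sd == pytest.approx(1.0)
        assert res.t_statistic == pytest.approx(2 * math.sqrt(3), abs=1e-12)
        assert res.n_dropped == 1  # X has no co-occurring partner

    def test_matches_scipy_one_sided_ttest(self):
        cfg = GeneratorConfig(n_diseases=30, n_symptoms=15, n_proteins=40, n_modules=5, seed=3)
        net, cooc, _ = generate(cfg)
        res = enrichment_ttest(net, cooc)
        ref = ttest_1samp(res.per_disease_differences, 0.0, alternative="greater")
        assert res.t_statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_all_zero_differences_give_t_zero_p_half(self):
        d = Layer("disease", ("A", "B", "C"))
        s = Layer("symptom", ("s0",))
        net = MultiLayerNetwork(
            [d, s], [np.zeros((3, 3)), np.zeros((1, 1))], [np.zeros((3, 1))]
        )
        res = enrichment_ttest(net, CooccurrenceTable([("A", "B")]))
        assert res.degenerate and res.t_statistic == 0.0 and res.p_value == 0.5

    def test_constant_nonzero_differences_reported_degenerate(self):
        # two identical diseases sharing symptoms only with each other
        d = Layer("disease", ("A", "B", "C", "D"))
        s = Layer("symptom", ("s0", "s1"))
        inter = np.zeros((4, 2))
        inter[0] = inter[1] = [1.0, 1.0]  # A and B share both symptoms
        net = MultiLayerNetwork([d, s], [np.zeros((4, 4)), np.zeros((2, 2))], [inter])
        res = enrichment_ttest(net, CooccurrenceTable([("A", "B")]))
        assert res.degenerate
        assert math.isinf(res.t_statistic) and res.t_statistic > 0
        assert res.p_value == 0.0

    def test_too_few_retained_diseases_rejected(self):
        d = Layer("disease", ("A", "B"))
        s = Layer("symptom", ("s0",))
        net = MultiLayerNetwork(
            [d, s], [np.zeros((2, 2)), np.zeros((1, 1))], [np.zeros((2, 1))]
        )
        with pytest.raises(ValueError):
            enrichment_ttest(net, CooccurrenceTable([("A", "B")]))

    def test_tier_binning_partitions_retained_diseases(self):
        cfg = GeneratorConfig(n_diseases=30, n_symptoms=15, n_proteins=40, n_modules=5, seed=3)
        net, cooc, _ = generate(cfg)
        tiers = enrichment_by_tier(net, cooc, thresholds=(6, 2))
        retained = set(tiers["total"].diseases)
        binned = set()
        for key in ("tier1", "tier2", "tier3"):
            if key in tiers:
                binned |= set(tiers[key].diseases)
        assert binned <= retained


class TestSharedSymptomReport:
    def test_counts_and_sort_contract(self):
        net = tiny_symptom_network()
        scores = np.array([0.9, 0.5, 0.5, 0.1])  # disease-layer scores
        rep = shared_symptom_report(net, "A", scores)
        assert list(rep.columns) == ["disease", "shared_symptom_count", "f"]
        assert "A" not in set(rep["disease"])
        # descending f; B before C on the tie (id order)
        assert list(rep["disease"]) == ["B", "C", "X"]
        assert list(rep["shared_symptom_count"]) == [0, 2, 0]

    def test_disease_sharing_nothing_has_zero_counts(self):
        net = tiny_symptom_network()
        rep = shared_symptom_report(net, "X", np.arange(4, dtype=float))
        assert set(rep["shared_symptom_count"]) == {0}

    def test_score_correlates_with_shared_symptoms_on_planted_data(self):
        cfg = GeneratorConfig(n_diseases=40, n_symptoms=20, n_proteins=60, n_modules=8, seed=5)
        net, cooc, _ = generate(cfg)
        target = net.layers[0].node_ids[0]
        ec = ExperimentConfig(target_disease=target, symptom_label_fraction=1.0, seed=5)
        assign = build_labels(net, ec, cooc)
        from layerprop.network import separate
        from layerprop.propagation import SSLParameters, solve_multi_direct

        f = solve_multi_direct(separate(net), assign.labels, SSLParameters(1.0, 0.1))
        rep = shared_symptom_report(net, target, f)
        rho = spearmanr(rep["shared_symptom_count"], rep["f"]).statistic
        assert rho > 0

    def test_unknown_target_rejected(self):
        net = tiny_symptom_network()
        with pytest.raises(KeyError):
            shared_symptom_report(net, "nope", np.zeros(4))

    def test_shared_counts_matrix_symmetric(self):
        net = tiny_symptom_network()
        s = shared_symptom_counts(net)
        assert np.array_equal(s, s.T)
        assert s[0, 2] == 2 and s[1, 2] == 4 and s[0, 1] == 0
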