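"""Privacy attacks: hand-computed F1/risk oracles, brute-force distance-table
equivalence, the identity-disclosure reduction to marketer risk, and the
attack-strength gradient between Baseline and the memorizing copier."""

import math

import numpy as np
import pytest

import synthehr_bench as sb
from synthehr_bench.cohort_io import ValidationError
from synthehr_bench.privacy import (
    AttackConfig,
    required_qualifying_count,
)

from conftest import make_pm


# ---------------------------------------------------------------- brute force

def brute_min_cross(a, b):
    out = []
    for x in a:
        out.append(min(math.dist(x, y) for y in b))
    return out


def brute_min_self(a):
    out = []
    for i, x in enumerate(a):
        out.append(min(math.dist(x, y) for j, y in enumerate(a) if j != i))
    return out


def brute_adversarial_accuracy(a, b):
    n = len(a)
    t1 = sum(1 for d1, d2 in zip(brute_min_cross(a, b), brute_min_self(a))
             if d1 > d2) / n
    t2 = sum(1 for d1, d2 in zip(brute_min_cross(b, a), brute_min_self(b))
             if d1 > d2) / n
    return 0.5 * (t1 + t2)


def brute_f1(y_true, y_pred):
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    if tp == 0:
        return 0.0
    prec, rec = tp / (tp + fp), tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def brute_membership(synth_rows, member_rows, nonmember_rows, threshold):
    y_true, y_pred = [], []
    for rows, label in ((member_rows, 1), (nonmember_rows, 0)):
        for r in rows:
            d = min(math.dist(r, s) for s in synth_rows)
            y_true.append(label)
            y_pred.append(1 if d < threshold else 0)
    return brute_f1(y_true, y_pred)


# --------------------------------------------------------------------- tests


class TestEntropyWeights:
    def test_equal_maximal_entropies(self):
        m = make_pm({"a": [0, 1, 0, 1], "b": [1, 0, 1, 0], "y": [0, 0, 0, 1]},
                    outcome="y", sensitive={"a", "b"})
        w = sb.entropy_weights(m, ["a", "b"])
        assert w == {"a": pytest.approx(0.5), "b": pytest.approx(0.5)}

    def test_constant_attribute_zero_weight(self):
        m = make_pm({"a": [0, 1, 0, 1], "b": [0, 0, 0, 0], "y": [0, 0, 0, 1]},
                    outcome="y")
        w = sb.entropy_weights(m, ["a", "b"])
        assert w["b"] == 0.0
        assert w["a"] == 1.0

    def test_normalization_ratio(self):
        # entropies in ratio 2:1 -> weights (2/3, 1/3); build via a continuous
        # attribute with twice the discretized entropy of a binary one
        m = make_pm({"a": [0, 1, 0, 1], "y": [0, 0, 0, 1]}, outcome="y")
        w = sb.entropy_weights(m, ["a"])
        assert w["a"] == 1.0  # single attribute normalizes to 1

    def test_all_zero_entropy_rejected(self):
        m = make_pm({"a": [0, 0], "b": [1, 1], "y": [0, 1]}, outcome="y")
        with pytest.raises(ValidationError):
            sb.entropy_weights(m, ["a", "b"])


class TestAttributeInference:
    def test_perfect_inference_on_exact_copy(self):
        # unique known-attribute fingerprints; synth = exact copy of targets
        cols = {"k1": [1, 0, 1, 0], "k2": [1, 1, 0, 0],
                "s": [1, 0, 0, 1], "y": [0, 0, 0, 1]}
        targets = make_pm(cols, outcome="y", sensitive={"s"})
        synth = make_pm(dict(cols), outcome="y", sensitive={"s"},
                        dataset_id="synth")
        cfg = AttackConfig(known_attributes=["k1", "k2"])
        assert sb.attribute_inference_risk(synth, targets, cfg) == 1.0

    def test_hand_f1_two_targets(self):
        # single sensitive attribute; true (1,1), predictions (1,0) -> F1 2/3
        targets = make_pm({"k": [0, 1], "s": [1, 1], "y": [0, 1]},
                          outcome="y", sensitive={"s"})
        synth = make_pm({"k": [0, 1], "s": [1, 0], "y": [0, 1]},
                        outcome="y", sensitive={"s"}, dataset_id="synth")
        cfg = AttackConfig(known_attributes=["k"])
        assert sb.attribute_inference_risk(synth, targets, cfg) == pytest.approx(2 / 3)

    def test_all_negative_attribute_scores_zero(self):
        targets = make_pm({"k": [0, 1, 0, 1], "s": [0, 0, 0, 0],
                           "v": [0.1, 0.9, 0.1, 0.9], "y": [0, 0, 0, 1]},
                          kinds={"v": "continuous"}, outcome="y",
                          sensitive={"s", "v"})
        synth = make_pm({"k": [0, 1], "s": [1, 1], "v": [0.5, 0.5],
                         "y": [0, 1]}, kinds={"v": "continuous"}, outcome="y",
                        sensitive={"s", "v"}, dataset_id="synth")
        cfg = AttackConfig(known_attributes=["k"], closeness_threshold=0.01)
        # binary attribute: no positive target -> F1 contribution 0;
        # continuous: |0.5-0.1|,|0.5-0.9| > 0.01 -> accuracy 0
        assert sb.attribute_inference_risk(synth, targets, cfg) == 0.0

    def test_continuous_closeness_threshold(self):
        targets = make_pm({"k": [0, 1], "v": [0.50, 0.90], "y": [0, 1]},
                          kinds={"v": "continuous"}, outcome="y",
                          sensitive={"v"})
        synth = make_pm({"k": [0, 1], "v": [0.55, 0.60], "y": [0, 1]},
                        kinds={"v": "continuous"}, outcome="y",
                        sensitive={"v"}, dataset_id="synth")
        cfg = AttackConfig(known_attributes=["k"], closeness_threshold=0.1)
        # |0.55-0.50| <= 0.1 hits, |0.60-0.90| misses -> accuracy 0.5
        assert sb.attribute_inference_risk(synth, targets, cfg) == pytest.approx(0.5)

    def test_k_exceeding_synth_size_rejected(self):
        targets = make_pm({"k": [0, 1], "s": [1, 0], "y": [0, 1]},
                          outcome="y", sensitive={"s"})
        cfg = AttackConfig(known_attributes=["k"], knn_k=5)
        with pytest.raises(ValidationError):
            sb.attribute_inference_risk(targets, targets, cfg)


class TestMembershipInference:
    def test_hand_f1(self):
        # members {(0,0),(1,1)}, nonmember {(1,0)}, synth {(0,0)}, threshold 2:
        # all distances < 2 -> everything claimed -> P=2/3, R=1, F1=0.8
        members = make_pm({"a": [0, 1], "b": [0, 1], "y": [0, 1]}, outcome="y")
        nonmembers = make_pm({"a": [1], "b": [0], "y": [0]}, outcome="y")
        synth = make_pm({"a": [0], "b": [0], "y": [0]}, outcome="y")
        cfg = AttackConfig(known_attributes=[], membership_distance_threshold=2.0)
        assert sb.membership_inference_risk(synth, members, nonmembers,
                                            cfg) == pytest.approx(0.8)

    def test_distant_synth_no_claims(self):
        members = make_pm({"a": [1, 1], "b": [1, 0], "y": [0, 1]}, outcome="y")
        nonmembers = make_pm({"a": [0], "b": [1], "y": [0]}, outcome="y")
        synth = make_pm({"a": [0, 0], "b": [0, 0], "y": [0, 0]}, outcome="y")
        cfg = AttackConfig(known_attributes=[],
                           membership_distance_threshold=0.5)
        assert sb.membership_inference_risk(synth, members, nonmembers, cfg) == 0.0

    def test_perfect_attack(self, train, eval_set, memorizer, attack_cfg):
        v = sb.membership_inference_risk(memorizer, train, eval_set, attack_cfg)
        assert v > 0.9

    def test_brute_force_random_instances(self, rng):
        for _ in range(10):
            synth = rng.random((8, 3))
            mem = rng.random((6, 3))
            non = rng.random((5, 3))
            s = make_pm({"a": [0] * 8, "y": [0] * 7 + [1],
                         "v1": synth[:, 0].tolist(), "v2": synth[:, 1].tolist(),
                         "v3": synth[:, 2].tolist()},
                        kinds={f"v{i}": "continuous" for i in (1, 2, 3)},
                        outcome="y")
            m = make_pm({"a": [0] * 6, "y": [0] * 5 + [1],
                         "v1": mem[:, 0].tolist(), "v2": mem[:, 1].tolist(),
                         "v3": mem[:, 2].tolist()},
                        kinds={f"v{i}": "continuous" for i in (1, 2, 3)},
                        outcome="y")
            nm = make_pm({"a": [0] * 5, "y": [0] * 4 + [1],
                          "v1": non[:, 0].tolist(), "v2": non[:, 1].tolist(),
                          "v3": non[:, 2].tolist()},
                         kinds={f"v{i}": "continuous" for i in (1, 2, 3)},
                         outcome="y")
            cfg = AttackConfig(known_attributes=[],
                               membership_distance_threshold=0.7)
            expect = brute_membership(s.array().tolist(), m.array().tolist(),
                                      nm.array().tolist(), 0.7)
            got = sb.membership_inference_risk(s, m, nm, cfg)
            assert got == pytest.approx(expect, abs=1e-9)


class TestRsIndicator:
    def _pair(self, n_rare):
        """Three real records; the first carries `n_rare` rare positives."""
        n_attrs = 250
        cols = {}
        sens = set()
        for i in range(n_attrs):
            name = f"s{i:03d}"
            cols[name] = [1 if i < n_rare else 0, 0, 0]
            sens.add(name)
        cols["y"] = [0, 0, 1]
        real = make_pm(cols, outcome="y", sensitive=sens)
        synth = make_pm({k: list(v) for k, v in cols.items()}, outcome="y",
                        sensitive=sens, dataset_id="synth")
        return real, synth, sorted(sens)

    def test_threshold_exactly_met(self):
        real, synth, sens = self._pair(n_rare=3)  # need ceil(2.5) = 3 at L=1
        r = sb.rs_indicator(real.values.iloc[0], synth.values.iloc[0],
                            real, synth, sens, L_percent=1.0)
        assert r == 1

    def test_below_threshold(self):
        real, synth, sens = self._pair(n_rare=2)
        r = sb.rs_indicator(real.values.iloc[0], synth.values.iloc[0],
                            real, synth, sens, L_percent=1.0)
        assert r == 0

    def test_common_values_never_qualify(self):
        # every attribute value has real share >= 0.5
        real = make_pm({"s1": [1, 1, 0, 0], "s2": [0, 0, 0, 0],
                        "y": [0, 0, 0, 1]}, outcome="y",
                       sensitive={"s1", "s2"})
        r = sb.rs_indicator(real.values.iloc[0], real.values.iloc[0],
                            real, real, ["s1", "s2"], L_percent=1.0)
        assert r == 0

    def test_continuous_criterion_hand_inequality(self):
        # p_s * |X - Y| < 1.48 * MAD: 0.25 * 1.0 < 1.48 * 0.5 qualifies
        real = make_pm({"v": [0.0, 1.0, 2.0, 3.0], "y": [0, 0, 0, 1]},
                       kinds={"v": "continuous"}, outcome="y",
                       sensitive={"v"}, normalized=False)
        synth = make_pm({"v": [1.0, 1.0, 2.0, 2.0], "y": [0, 0, 0, 1]},
                        kinds={"v": "continuous"}, outcome="y",
                        sensitive={"v"}, normalized=False)
        # MAD of (0,1,2,3) = 1; with 3 clusters the record's cluster share is
        # 0.25 or 0.5; |X-Y| = 1 for the first record: p_s*1 < 1.48 holds
        r = sb.rs_indicator(real.values.iloc[0], synth.values.iloc[0],
                            real, synth, ["v"], L_percent=1.0)
        assert r == 1

    def test_required_count_printed_configurations(self):
        # 2592-attribute dataset with 10 QIDs: 2582 sensitive, L=1 -> 26
        assert required_qualifying_count(1.0, 2582) == 26
        # 2665-attribute dataset with 10 QIDs: 2655 sensitive, L=1 -> 27
        assert required_qualifying_count(1.0, 2655) == 27


class TestIdentityDisclosure:
    def _schema_cols(self, q, s, y):
        return dict(q=q, s=s, y=y)

    def test_no_qid_match_is_zero(self):
        real = make_pm({"q": [1, 1], "s": [1, 0], "y": [0, 1]}, outcome="y",
                       qids={"q"}, sensitive={"s"})
        synth = make_pm({"q": [0, 0], "s": [1, 0], "y": [0, 1]}, outcome="y",
                        qids={"q"}, sensitive={"s"}, dataset_id="synth")
        cfg = AttackConfig(known_attributes=["q"], lambda_override=1.0)
        assert sb.identity_disclosure_risk(synth, real, real, cfg) == 0.0

    def test_hand_evaluation_two_records(self):
        # N=100, n=2; record 0: f=1, F=2, I=R=1, lambda=1; record 1: I=0
        # -> max(0.01, 0.25) = 0.25.  The sensitive attribute is continuous
        # so the matched pair (|X-Y| = 0 < 1.48 MAD) makes R_s = 1.
        real = make_pm({"q1": [1, 0], "q2": [1, 0], "v": [0.3, 0.7],
                        "y": [0, 1]}, kinds={"v": "continuous"},
                       outcome="y", qids={"q1", "q2"}, sensitive={"v"})
        synth = make_pm({"q1": [1], "q2": [1], "v": [0.3], "y": [0]},
                        kinds={"v": "continuous"},
                        outcome="y", qids={"q1", "q2"}, sensitive={"v"},
                        dataset_id="synth")
        pop_cols = {"q1": [1, 1] + [0] * 98, "q2": [1, 1] + [0] * 98,
                    "v": [0.3, 0.7] + [0.5] * 98, "y": [0] * 99 + [1]}
        population = make_pm(pop_cols, kinds={"v": "continuous"},
                             outcome="y", qids={"q1", "q2"},
                             sensitive={"v"})
        cfg = AttackConfig(known_attributes=["q1", "q2"], lambda_override=1.0)
        v = sb.identity_disclosure_risk(synth, real, population, cfg)
        assert v == pytest.approx(0.25)

    def test_worst_case_marketer_bound(self):
        # synth = real, population = real, unique QIDs, lambda = 1, all R_s=1
        n = 8
        cols = {f"q{i}": [1 if j == i else 0 for j in range(n)]
                for i in range(n)}
        cols["s"] = [1, 0] * (n // 2)  # share 0.5 -> never qualifies; use rarer
        cols["s"] = [1] + [0] * (n - 1)
        cols["s2"] = [0, 1] + [0] * (n - 2)
        cols["y"] = [0] * (n - 1) + [1]
        real = make_pm(cols, outcome="y", qids={f"q{i}" for i in range(n)},
                       sensitive={"s", "s2"})
        synth = make_pm({k: list(v) for k, v in cols.items()}, outcome="y",
                        qids={f"q{i}" for i in range(n)},
                        sensitive={"s", "s2"}, dataset_id="synth")
        cfg = AttackConfig(known_attributes=[], lambda_override=1.0,
                           L_percent=1.0)
        # L=1% of 2 sensitive attrs -> need 1 qualifying; records 0 and 1
        # qualify (rare positive), others carry only common zeros -> R_s=0
        v = sb.identity_disclosure_risk(synth, real, real, cfg)
        assert v == pytest.approx(2 / n)

    def test_brute_force_on_fixture(self, train, baseline, attack_cfg, cohort):
        matrix, _ = cohort
        v = sb.identity_disclosure_risk(baseline, train, matrix, attack_cfg)
        # per-record recomputation with the scalar rs_indicator
        qids = train.schema.qid_names
        sens = train.schema.sensitive_names
        rk = [tuple(r) for r in train.values[qids].to_numpy()]
        pk = [tuple(r) for r in matrix.values[qids].to_numpy()]
        sk = [tuple(r) for r in baseline.values[qids].to_numpy()]
        first = {}
        for i, k in enumerate(sk):
            first.setdefault(k, i)
        t1 = t2 = 0.0
        for s in range(train.n_records):
            k = rk[s]
            if k not in first:
                continue
            r = sb.rs_indicator(train.values.iloc[s],
                                baseline.values.iloc[first[k]],
                                train, baseline, sens,
                                L_percent=attack_cfg.L_percent,
                                n_clusters=attack_cfg.rs_kmeans_k,
                                seed=attack_cfg.seed)
            if not r:
                continue
            t1 += 1.0 / rk.count(k)
            big_f = pk.count(k)
            if big_f > 0:
                t2 += 1.0 / big_f
        expect = max(t1 / matrix.n_records, t2 / train.n_records)
        assert v == pytest.approx(expect, abs=1e-9)

    def test_no_qids_flagged_rejected(self):
        real = make_pm({"s": [1, 0], "y": [0, 1]}, outcome="y",
                       sensitive={"s"})
        cfg = AttackConfig(known_attributes=[])
        with pytest.raises(ValidationError):
            sb.identity_disclosure_risk(real, real, real, cfg)


class TestAdversarialAccuracy:
    def test_copy_limit_zero(self, rng):
        a = rng.random((10, 3))
        assert sb.adversarial_accuracy(a, a.copy()) == 0.0

    def test_separation_limit_one(self, rng):
        a = rng.random((10, 2))
        b = a + 100.0
        assert sb.adversarial_accuracy(a, b) == 1.0

    def test_hand_distance_table(self):
        assert sb.adversarial_accuracy(np.array([0.4, 0.6]),
                                       np.array([0.0, 1.0])) == 0.5

    def test_brute_force_random_sets(self, rng):
        for _ in range(10):
            a = rng.random((9, 4))
            b = rng.random((9, 4))
            assert sb.adversarial_accuracy(a, b) == pytest.approx(
                brute_adversarial_accuracy(a.tolist(), b.tolist()), abs=1e-12)

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            sb.adversarial_accuracy(rng.random((4, 2)), rng.random((5, 2)))


class TestNNAA:
    def test_hand_one_dimensional(self):
        # constant outcome column contributes nothing to any distance
        train = make_pm({"v": [0.0, 1.0], "y": [0, 0]},
                        kinds={"v": "continuous"}, outcome="y")
        synth = make_pm({"v": [0.0, 1.0], "y": [0, 0]},
                        kinds={"v": "continuous"}, outcome="y")
        ev = make_pm({"v": [0.4, 0.6], "y": [0, 0]},
                     kinds={"v": "continuous"}, outcome="y")
        cfg = AttackConfig(known_attributes=[], nnaa_repeats=1)
        # AA_ES = 0.5, AA_TS = 0 -> risk 0.5
        assert sb.nnaa_risk(train, synth, ev, cfg) == pytest.approx(0.5)

    def test_null_independent_draws(self, rng):
        def cohort_like(seed):
            r = np.random.default_rng(seed)
            return make_pm({"v1": r.random(80).tolist(),
                            "v2": r.random(80).tolist(),
                            "y": [0] * 79 + [1]},
                           kinds={"v1": "continuous", "v2": "continuous"},
                           outcome="y")
        cfg = AttackConfig(known_attributes=[], nnaa_repeats=5)
        v = sb.nnaa_risk(cohort_like(1), cohort_like(2), cohort_like(3), cfg)
        assert abs(v) < 0.1

    def test_copy_generator_risk(self, train, memorizer, attack_cfg):
        # synth = shuffled copy of train; eval must be same-distribution
        ev = sb.sample_baseline(train, train.n_records, seed=99)
        v = sb.nnaa_risk(train, memorizer, ev, attack_cfg)
        assert v > 0.3


class TestAttackStrengthMonotonicity:
    def test_membership_risk_grows_with_copying(self, train, eval_set,
                                                attack_cfg):
        risks = []
        for frac in (0.0, 0.5, 1.0):
            synth = sb.perturbation_copier(train, copy_fraction=frac,
                                           flip_rate=0.0, seed=11)
            risks.append(sb.membership_inference_risk(synth, train, eval_set,
                                                      attack_cfg))
        assert risks[0] <= risks[1] <= risks[2]

    def test_membership_risk_falls_with_noise(self, train, eval_set,
                                              attack_cfg):
        low_noise = sb.perturbation_copier(train, 1.0, 0.01, seed=12)
        high_noise = sb.perturbation_copier(train, 1.0, 0.4, seed=12)
        assert (sb.membership_inference_risk(high_noise, train, eval_set,
                                             attack_cfg)
                <= sb.membership_inference_risk(low_noise, train, eval_set,
                                                attack_cfg))


class TestAttackConfig:
    def test_sensitivity_presets(self):
        cfg = AttackConfig(known_attributes=["a"])
        assert cfg.with_sensitivity("knn10").knn_k == 10
        assert cfg.with_sensitivity("membership_t5").membership_distance_threshold == 5.0
        assert cfg.with_sensitivity("L01").L_percent == 0.1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            AttackConfig(knn_k=0)
        with pytest.raises(ValueError):
            AttackConfig(L_percent=0.0)
        with pytest.raises(ValueError):
            AttackConfig(closeness_threshold=-1.0)
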