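"""Counting, the likelihood-ratio operator, smoothing, variant scoring and
top-k prediction, checked against hand-computed values on the toy corpus."""

import math

import pytest

from dxrank import (
    CooccurrenceModel,
    MedicalRecord,
    VariantConfig,
    fit,
    oversample_balanced,
    table_variants,
)

NONE_CFG = VariantConfig(prior_mode="none")


class TestFit:
    def test_toy_counts(self, toy_model):
        m = toy_model
        assert m.n_records == 4
        assert m.disease_counts == {"A": 2, "B": 2}
        assert m.symptom_counts == {"s1": 2, "s2": 2, "s3": 3}
        assert m.pair_counts[("A", "s1")] == 2
        assert ("B", "s1") not in m.pair_counts
        assert m.diseases == ("A", "B")
        assert m.vocabulary == ("s1", "s2", "s3")

    def test_singleton(self):
        m = fit([MedicalRecord("A", ("s1", "s2"))])
        assert m.n_records == 1
        assert m.pair_counts[("A", "s1")] == 1
        assert m.pair_counts[("A", "s2")] == 1

    def test_duplicated_corpus_doubles_counts(self, toy_records, toy_model):
        doubled = fit(toy_records + toy_records)
        assert doubled.n_records == 2 * toy_model.n_records
        for key, n in toy_model.pair_counts.items():
            assert doubled.pair_counts[key] == 2 * n

    def test_count_consistency_invariants(self, toy_model):
        m = toy_model
        assert sum(m.disease_counts.values()) == m.n_records
        for s, n_s in m.symptom_counts.items():
            assert n_s == sum(
                m.pair_counts.get((d, s), 0) for d in m.diseases
            )
        for (d, s), n_ds in m.pair_counts.items():
            assert 0 <= n_ds <= min(m.disease_counts[d], m.symptom_counts[s])

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit([])


class TestProbabilities:
    @pytest.mark.parametrize(
        "s,d,expected", [("s1", "A", 1.0), ("s1", "B", 0.0), ("s3", "B", 1.0)]
    )
    def test_conditional(self, toy_model, s, d, expected):
        assert toy_model.conditional_prob(s, d) == expected

    def test_conditional_unknown_disease(self, toy_model):
        with pytest.raises(KeyError):
            toy_model.conditional_prob("s1", "Z")

    def test_marginal_empirical(self, toy_model):
        assert toy_model.marginal_prob("s3") == 0.75

    def test_marginal_uniform_balanced_matches_empirical(self, toy_model):
        assert toy_model.marginal_prob("s3", "uniform") == 0.75

    def test_marginal_uniform_differs_on_skewed_corpus(self):
        # 3 records of A all with s, 1 record of B without it
        m = fit(
            [
                MedicalRecord("A", ("s",)),
                MedicalRecord("A", ("s",)),
                MedicalRecord("A", ("s", "t")),
                MedicalRecord("B", ("t",)),
            ]
        )
        assert m.marginal_prob("s") == 0.75
        assert m.marginal_prob("s", "uniform") == 0.5

    def test_marginal_unknown_symptom(self, toy_model):
        with pytest.raises(KeyError):
            toy_model.marginal_prob("sX")


class TestOperator:
    def test_cooccurring(self, toy_model):
        assert toy_model.operator("s1", "A", NONE_CFG) == 2.0
        assert toy_model.operator("s2", "A", NONE_CFG) == 1.0

    def test_smoothed_non_cooccurring(self, toy_model):
        # alpha/(N(B) + alpha*|V|) / P(s1) = (1/5)/0.5
        assert toy_model.operator("s1", "B", NONE_CFG) == pytest.approx(0.4)

    def test_smoothed_below_cooccurring_for_same_symptom(self, toy_model):
        assert toy_model.operator("s1", "B", NONE_CFG) < toy_model.operator(
            "s1", "A", NONE_CFG
        )


class TestCandidates:
    @pytest.mark.parametrize(
        "symptoms,expected",
        [(["s1"], {"A"}), (["s2"], {"A", "B"}), (["unknown"], set())],
    )
    def test_candidates(self, toy_model, symptoms, expected):
        assert toy_model.candidate_diseases(symptoms) == expected


class TestScore:
    def test_unweighted_product(self, toy_model):
        assert toy_model.score(["s1", "s2"], "A", NONE_CFG) == 2.0
        assert toy_model.score(["s1", "s2"], "B", NONE_CFG) == pytest.approx(0.4)

    def test_weighted_gating(self, toy_model):
        cfg = VariantConfig(prior_mode="none", weighted=True, weight=2.0)
        assert toy_model.score(["s1", "s2"], "A", cfg) == 8.0
        # (B, s1) has no cooccurrence -> no weight on s1, weight on s2
        assert toy_model.score(["s1", "s2"], "B", cfg) == pytest.approx(0.8)

    def test_prior_modes(self, toy_model):
        base = toy_model.score(["s1", "s2"], "A", NONE_CFG)
        emp = toy_model.score(
            ["s1", "s2"], "A", VariantConfig(prior_mode="empirical")
        )
        uni = toy_model.score(
            ["s1", "s2"], "A", VariantConfig(prior_mode="uniform")
        )
        assert emp == base * 0.5  # P(A) = 2/4
        assert uni == base * 0.5  # 1/|D| = 1/2, balanced corpus

    def test_log_form_matches_log_of_product(self, toy_model):
        cfg = VariantConfig(prior_mode="empirical", form="log")
        prod = toy_model.score(
            ["s1", "s2"], "A", VariantConfig(prior_mode="empirical")
        )
        assert toy_model.score(["s1", "s2"], "A", cfg) == pytest.approx(
            math.log(prod)
        )

    def test_non_candidate_rejected(self, toy_model):
        with pytest.raises(ValueError):
            toy_model.score(["s1"], "B", NONE_CFG)


class TestPredictTopk:
    def test_ranking(self, toy_model):
        pred = toy_model.predict_topk(["s1", "s2"], NONE_CFG)
        assert pred.status == "ok"
        assert [d for d, _ in pred.ranked] == ["A", "B"]
        assert pred.ranked[0][1] == 2.0
        assert pred.ranked[1][1] == pytest.approx(0.4)

    def test_unknown_only_gives_no_candidates(self, toy_model):
        pred = toy_model.predict_topk(["mystery"], NONE_CFG)
        assert pred.status == "no_candidates"
        assert pred.ranked == ()
        assert pred.unknown_symptoms == ("mystery",)

    def test_tie_broken_lexicographically(self, toy_model):
        pred = toy_model.predict_topk(["s2"], NONE_CFG)
        assert pred.ranked[0][0] == "A"
        assert pred.ranked[0][1] == pred.ranked[1][1] == 1.0

    def test_truncation_and_dedup(self, toy_model):
        cfg = VariantConfig(prior_mode="none", top_k=1)
        pred = toy_model.predict_topk(["s1", "s1", "s2"], cfg)
        assert len(pred.ranked) == 1
        assert pred.candidates_considered == 2

    def test_scores_non_increasing(self, toy_model):
        for cfg in table_variants().values():
            pred = toy_model.predict_topk(["s2", "s3"], cfg)
            scores = [s for _, s in pred.ranked]
            assert scores == sorted(scores, reverse=True)


class TestSerialization:
    def test_roundtrip_exact(self, toy_model, tmp_path):
        p = tmp_path / "model.json"
        toy_model.save(p)
        back = CooccurrenceModel.load(p)
        assert back.n_records == toy_model.n_records
        assert back.disease_counts == toy_model.disease_counts
        assert back.symptom_counts == toy_model.symptom_counts
        assert back.pair_counts == toy_model.pair_counts
        assert back.predict_topk(["s1", "s2"], NONE_CFG) == toy_model.predict_topk(
            ["s1", "s2"], NONE_CFG
        )


class TestOversampling:
    def test_balances_classes(self):
        records = [
            MedicalRecord("A", ("s",)),
            MedicalRecord("A", ("s",)),
            MedicalRecord("A", ("s", "t")),
            MedicalRecord("B", ("t",)),
        ]
        balanced = oversample_balanced(records)
        m = fit(balanced)
        assert len(set(m.disease_counts.values())) == 1

    def test_realizes_uniform_marginal_exactly(self):
        records = [
            MedicalRecord("A", ("s",)),
            MedicalRecord("A", ("s",)),
            MedicalRecord("A", ("s", "t")),
            MedicalRecord("B", ("t",)),
        ]
        original = fit(records)
        balanced = fit(oversample_balanced(records))
        for s in original.vocabulary:
            assert balanced.marginal_prob(s) == original.marginal_prob(s, "uniform")
        # and the empirical prior of the balanced corpus is 1/|D|
        for d in balanced.diseases:
            assert balanced.disease_counts[d] / balanced.n_records == 0.5

    def test_size_limit(self):
        records = [MedicalRecord("A", ("s",))] * 97 + [
            MedicalRecord(f"B{i}", ("t",)) for i in range(89)
        ]
        with pytest.raises(ValueError):
            oversample_balanced(records, limit=1000)
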