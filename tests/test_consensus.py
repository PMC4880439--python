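import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snvconsensus import calibration
from snvconsensus.consensus import (
    calibrate_consensus,
    consensus_score,
    predict,
    select_consensus_subset,
    train_bundle,
)
from snvconsensus.core_io import (
    DELETERIOUS,
    NEUTRAL,
    LabeledDataset,
    ScoreTable,
    ToolSpec,
    Variant,
)
from snvconsensus.synthetic_data import ClassParams, ScoreSimSpec, simulate_scores

vote = st.tuples(st.sampled_from(["D", "N"]), st.integers(0, 99))


class TestConsensusScore:
    def test_weighted_vote_arithmetic(self):
        s = consensus_score([("D", 80), ("D", 60), ("N", 70)])
        assert s == pytest.approx((0.8 + 0.6 - 0.7) / 2.1)

    def test_single_vote_is_that_tool(self):
        assert consensus_score([("N", 90)]) == -1.0

    def test_even_split_scores_zero(self):
        assert consensus_score([("D", 50), ("N", 50)]) == 0.0

    def test_all_zero_confidence_scores_zero(self):
        assert consensus_score([("D", 0), ("N", 0)]) == 0.0

    def test_empty_votes_error(self):
        with pytest.raises(ValueError):
            consensus_score([])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(vote, min_size=1, max_size=8))
    def test_bounded_permutation_symmetric_and_sign_flips(self, votes):
        s = consensus_score(votes)
        assert -1.0 <= s <= 1.0
        assert consensus_score(list(reversed(votes))) == pytest.approx(s)
        flipped = [("N" if p == "D" else "D", c) for p, c in votes]
        assert consensus_score(flipped) == pytest.approx(-s)

    def test_equal_confidences_reduce_to_majority_vote(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(1, 10))
            preds = ["D" if rng.uniform() < 0.5 else "N" for _ in range(n)]
            votes = [(p, 70) for p in preds]
            s = consensus_score(votes)
            margin = preds.count("D") - preds.count("N")
            assert ("D" if s >= 0 else "N") == ("D" if margin >= 0 else "N")


class TestEnsembleGain:
    def test_independent_tools_reach_binomial_majority_accuracy(self):
        """5 conditionally independent tools at balanced accuracy 0.7 give
        a majority consensus near the binomial value P(X>=3), X~Bin(5,0.7)."""
        rng = np.random.default_rng(99)
        n = 10_000
        truth = np.array(["D"] * (n // 2) + ["N"] * (n // 2))
        correct = rng.uniform(size=(n, 5)) < 0.7
        single_acc = correct.mean(axis=0)
        cons_correct = 0
        for i in range(n):
            votes = [(truth[i] if c else ("N" if truth[i] == "D" else "D"), 50)
                     for c in correct[i]]
            pred = "D" if consensus_score(votes) >= 0 else "N"
            cons_correct += pred == truth[i]
        cons_acc = cons_correct / n
        from scipy.stats import binom
        expected = binom.sf(2, 5, 0.7)  # P(at least 3 of 5 correct)
        assert cons_acc == pytest.approx(expected, abs=0.02)
        assert cons_acc > single_acc.max()


def _make_votes(rng, accs, n):
    """Per-tool calibrated-vote fixtures with given per-tool accuracies."""
    labels = ["D"] * (n // 2) + ["N"] * (n - n // 2)
    votes = {}
    for name, acc in accs.items():
        col = []
        for lab in labels:
            correct = rng.uniform() < acc
            p = "D" if lab == "D" else "N"
            if not correct:
                p = "N" if p == "D" else "D"
            conf = int(rng.integers(40, 95))
            col.append((p, conf))
        votes[name] = col
    return votes, labels


class TestSubsetSelection:
    def test_all_subsets_of_size_two_plus_evaluated(self):
        rng = np.random.default_rng(0)
        votes, labels = _make_votes(
            rng, {t: 0.7 for t in "abcde"}, 200)
        cm = select_consensus_subset(votes, labels, "missense", n_bins=10)
        assert len(cm.subset_report) == 26  # 2^5 - 5 - 1

    def test_identical_tools_tie_break_to_two_lexicographic(self):
        rng = np.random.default_rng(1)
        base, labels = _make_votes(rng, {"a": 0.8}, 200)
        votes = {t: list(base["a"]) for t in ["c", "a", "b"]}
        cm = select_consensus_subset(votes, labels, "missense", n_bins=10)
        assert cm.tools == ["a", "b"]

    def test_noise_tools_excluded_from_best_subset(self):
        """One strong tool + two label-independent noise tools: the chosen
        subset drops at least one noise tool and never beats its own
        training accuracy by adding them back."""
        rng = np.random.default_rng(5)
        n = 1000
        labels = ["D"] * (n // 2) + ["N"] * (n // 2)
        votes = {}
        strong = []
        for lab in labels:
            correct = rng.uniform() < 0.92
            p = lab if correct else ("N" if lab == "D" else "D")
            strong.append((p, int(rng.integers(85, 99))))
        votes["strong"] = strong
        for noise in ("noise1", "noise2"):
            votes[noise] = [("D" if rng.uniform() < 0.5 else "N",
                             int(rng.integers(40, 60))) for _ in labels]
        cm = select_consensus_subset(votes, labels, "regulatory", n_bins=10)
        assert "strong" in cm.tools
        assert len([t for t in cm.tools if t.startswith("noise")]) < 2
        all_tools_nacc = dict(
            (tuple(sorted(s)), a) for s, a in cm.subset_report
        )[("noise1", "noise2", "strong")]
        assert cm.training_normalized_accuracy >= all_tools_nacc

    def test_selected_subset_at_least_all_tools_consensus(self, sim_data):
        spec, datasets, _ = sim_data
        bundle = train_bundle({c: d["train"] for c, d in datasets.items()},
                              spec.tools)
        for cat, cm in bundle.consensus.items():
            full = tuple(sorted(t.name for t in spec.tools))
            report = {tuple(sorted(s)): a for s, a in cm.subset_report}
            if full in report:
                assert cm.training_normalized_accuracy >= report[full]

    def test_fewer_than_two_tools_is_error(self):
        with pytest.raises(Exception):
            select_consensus_subset({"a": [("D", 50)] * 4},
                                    ["D", "D", "N", "N"], "missense")


class TestCalibrateConsensus:
    def test_separable_consensus_scores(self):
        scores = [-0.9, -0.8, -0.7, -0.6, 0.6, 0.7, 0.8, 0.9]
        labels = ["N"] * 4 + ["D"] * 4
        thr, nacc, curve = calibrate_consensus(scores, labels, n_bins=4)
        assert nacc == 1.0
        assert -0.6 < thr <= 0.6

    def test_constant_scores_are_degenerate(self):
        with pytest.raises(ValueError):
            calibrate_consensus([0.2] * 8, ["D"] * 4 + ["N"] * 4)


class TestPredict:
    @pytest.fixture()
    def trained(self, sim_data):
        spec, datasets, table = sim_data
        bundle = train_bundle({c: d["train"] for c, d in datasets.items()},
                              spec.tools)
        return spec, datasets, table, bundle

    def test_end_to_end_equals_hand_pipeline(self, trained):
        """Predictions decompose exactly into transform -> vote -> calibrate."""
        spec, datasets, table, bundle = trained
        test = datasets["splicing"]["test"]
        preds = predict(test.variants[:50], table, bundle)
        cm = bundle.consensus["splicing"]
        for p in preds:
            votes = {}
            for tool in cm.tools:
                raw = table.get(p.variant, tool)
                if math.isnan(raw):
                    continue
                curve = bundle.curves[(tool, "splicing")]
                votes[tool] = calibration.transform_score(
                    curve, raw, bundle.thresholds.polarity(tool))
            assert votes == p.tool_votes
            s = consensus_score(list(votes.values()))
            assert s == pytest.approx(p.consensus_score)
            ep, ec = calibration.transform_score(cm.consensus_curve, s)
            assert (ep, ec) == (p.consensus_prediction, p.consensus_confidence)

    def test_missing_tools_renormalize(self, trained):
        spec, datasets, table, bundle = trained
        test = datasets["missense"]["test"]
        v = test.variants[0]
        cm = bundle.consensus["missense"]
        # knock out one selected tool's score
        partial = ScoreTable(spec.tools)
        vec = np.array(table.entries[v.key], dtype=float)
        idx = [t.name for t in spec.tools].index(cm.tools[0])
        vec[idx] = np.nan
        partial.entries[v.key] = vec
        p = predict([v], partial, bundle)[0]
        assert cm.tools[0] not in p.tool_votes
        assert len(p.tool_votes) == len(cm.tools) - 1
        assert p.consensus_score == pytest.approx(
            consensus_score(list(p.tool_votes.values())))

    def test_no_scores_flagged(self, trained):
        spec, datasets, table, bundle = trained
        v = Variant(chrom="9", pos=1, ref="A", alt="G", category="missense")
        p = predict([v], table, bundle)[0]
        assert p.no_scores and p.consensus_prediction is None

    def test_unknown_category_is_error(self, trained):
        spec, datasets, table, bundle = trained
        v = datasets["missense"]["test"].variants[0]
        bad = Variant(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                      category=None)
        with pytest.raises(ValueError):
            predict([bad], table, bundle)
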