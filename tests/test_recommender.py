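"""Meta-model: training, recommendation, LOO protocol, similarity gate,
semi-simulated augmentation and the determinism contracts."""

import numpy as np
import pytest

from svrec.calleval import CallerPerformance
from svrec.errors import ValidationError
from svrec.recommender import (
    CallerRecommender,
    CorpusEntry,
    HistoricalCorpus,
    RecommenderResults,
    augment_semisimulated,
    count_similar,
)
from svrec.sigscan import FEATURE_ORDER, MetaFeatureVector
from svrec.synthdata import (
    CorpusConfig,
    LabelRule,
    RuleClause,
    simulate_corpus,
)


def mf(depth=50.0, large=0.2, **over):
    vals = dict(
        avg_read_length=8000.0,
        avg_depth=depth,
        prop_sv_tr=0.3,
        prop_short=0.5 - large / 2,
        prop_middle=0.5 - large / 2,
        prop_large=large,
        rvb=1.0,
        prop_high_rvb=0.1,
    )
    vals.update(over)
    return MetaFeatureVector(**vals)


def entry(dataset_id, features, best, callers=("A", "B"), spread=0.4):
    perfs = {}
    for c in callers:
        v = 0.9 if c == best else 0.9 - spread
        perfs[c] = CallerPerformance(dataset_id, c, v, v, v)
    return CorpusEntry(dataset_id, features, perfs)


def threshold_corpus(n=60, seed=0):
    """best caller = A iff avg_depth > 50 else B, noiseless."""
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n):
        depth = float(rng.uniform(10, 150))
        entries.append(
            entry(f"d{i:03d}", mf(depth=depth), "A" if depth > 50 else "B")
        )
    return HistoricalCorpus(entries)


class TestTraining:
    def test_learns_a_clean_threshold_rule(self):
        corpus = threshold_corpus(200)
        results = CallerRecommender(corpus, n_trees=100, seed=42).fit()
        caller, scores = results.recommend(mf(depth=100.0))
        assert caller == "A"
        caller, _ = results.recommend(mf(depth=15.0))
        assert caller == "B"
        assert sum(scores.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_class_corpus_predicts_that_class(self):
        entries = [entry(f"d{i}", mf(depth=10.0 * (i + 1)), "C", callers=("B", "C"))
                   for i in range(5)]
        results = CallerRecommender(HistoricalCorpus(entries), n_trees=20).fit()
        caller, scores = results.recommend(mf(depth=77.0))
        assert caller == "C"
        assert scores["C"] == 1.0

    def test_corpus_of_one_entry_rejected(self):
        with pytest.raises(ValidationError):
            CallerRecommender(HistoricalCorpus([entry("d0", mf(), "A")]))

    def test_non_finite_feature_names_dataset(self):
        entries = [
            entry("good", mf(), "A"),
            entry("nanset", mf(avg_depth=float("nan")), "B"),
        ]
        with pytest.raises(ValidationError, match="nanset"):
            CallerRecommender(HistoricalCorpus(entries), n_trees=10).fit()

    def test_refit_is_deterministic_on_probe_set(self):
        corpus = threshold_corpus(60)
        probes = [mf(depth=d) for d in (12.0, 43.0, 77.0, 140.0)]
        a = CallerRecommender(corpus, n_trees=50, seed=9).fit()
        b = CallerRecommender(corpus, n_trees=50, seed=9).fit()
        for p in probes:
            assert a.recommend(p) == b.recommend(p)

    def test_model_round_trip_preserves_predictions(self, tmp_path):
        corpus = threshold_corpus(60)
        results = CallerRecommender(corpus, n_trees=50, seed=1).fit()
        path = tmp_path / "model.bin"
        results.save(path)
        loaded = RecommenderResults.load(path)
        for d in (15.0, 60.0, 130.0):
            assert loaded.recommend(mf(depth=d)) == results.recommend(mf(depth=d))


class TestLOO:
    def test_needs_three_entries(self):
        entries = [entry("d0", mf(depth=10.0), "A"), entry("d1", mf(depth=90.0), "B")]
        with pytest.raises(ValidationError):
            CallerRecommender(HistoricalCorpus(entries)).loo()

    def test_all_callers_tied_gives_ra_one_everywhere(self):
        entries = [
            entry(f"d{i}", mf(depth=10.0 + i * 10), "A", spread=0.0)
            for i in range(8)
        ]
        loo = CallerRecommender(HistoricalCorpus(entries), n_trees=20).loo()
        assert (loo.table["ra"] == 1.0).all()
        assert loo.mean_ra == 1.0

    def test_ra_values_lie_in_unit_interval(self, small_corpus):
        loo = CallerRecommender(small_corpus, n_trees=30, seed=3).loo()
        assert ((loo.table["ra"] >= 0) & (loo.table["ra"] <= 1)).all()

    def test_fixed_pick_of_true_optimal_has_ra_one(self, small_corpus):
        loo = CallerRecommender(small_corpus, n_trees=30, seed=3).loo()
        for _, row in loo.table.iterrows():
            assert row[f"{row['optimal']}.ra"] == pytest.approx(1.0)
            worst_ra = min(row[f"{c}.ra"] for c in small_corpus.callers)
            assert worst_ra == pytest.approx(0.0)

    def test_entry_order_does_not_change_loo(self, small_corpus):
        base = CallerRecommender(small_corpus, n_trees=30, seed=3).loo()
        rng = np.random.default_rng(5)
        shuffled_entries = list(small_corpus.entries)
        rng.shuffle(shuffled_entries)
        shuffled = CallerRecommender(
            HistoricalCorpus(shuffled_entries), n_trees=30, seed=3
        ).loo()
        assert abs(base.mean_ra - shuffled.mean_ra) < 1e-12

    def test_wdl_rows_total_dataset_count(self, small_corpus):
        loo = CallerRecommender(small_corpus, n_trees=30, seed=3).loo()
        wdl = loo.win_draw_loss_table()
        assert (wdl[["wins", "draws", "losses"]].sum(axis=1) == len(small_corpus)).all()


class TestCorpusTable:
    def test_corpus_round_trip(self, tmp_path, small_corpus):
        path = tmp_path / "corpus.tsv"
        small_corpus.save(path)
        back = HistoricalCorpus.load(path)
        assert back.callers == small_corpus.callers
        assert len(back) == len(small_corpus)
        for a, b in zip(small_corpus, back):
            assert a.dataset_id == b.dataset_id
            assert a.features.as_tuple() == pytest.approx(b.features.as_tuple())
            for c in small_corpus.callers:
                assert a.performances[c].f_measure == pytest.approx(
                    b.performances[c].f_measure
                )

    def test_duplicate_ids_rejected(self):
        e = entry("dup", mf(), "A")
        with pytest.raises(ValidationError):
            HistoricalCorpus([e, e])

    def test_caller_set_must_agree(self):
        with pytest.raises(ValidationError):
            HistoricalCorpus(
                [entry("d0", mf(), "A"), entry("d1", mf(), "C", callers=("B", "C"))]
            )


class TestSimilarityGate:
    def test_empty_corpus(self):
        count, needs = count_similar(HistoricalCorpus([]), mf())
        assert (count, needs) == (0, True)

    def test_identical_entries_are_neighbours(self):
        entries = [entry(f"d{i}", mf(depth=60.0), "A") for i in range(150)]
        count, needs = count_similar(HistoricalCorpus(entries), mf(depth=60.0))
        assert count == 150 and needs is False

    def test_rule_fires_at_exactly_one_hundred(self):
        entries = [entry(f"d{i}", mf(depth=60.0), "A") for i in range(100)]
        count, needs = count_similar(HistoricalCorpus(entries), mf(depth=60.0))
        assert count == 100 and needs is True  # "greater than 100" is strict


class TestAugmentation:
    @staticmethod
    def provider(features, dataset_id):
        best = "A" if features.avg_depth > 50 else "B"
        return {
            c: CallerPerformance(
                dataset_id, c, *(3 * [0.9 if c == best else 0.5])
            )
            for c in ("A", "B")
        }

    def test_generates_exactly_n_entries(self, small_corpus):
        got = augment_semisimulated(
            small_corpus, small_corpus.entries[0].features,
            self.provider, n=100, seed=4,
        )
        assert len(got) == 100
        for e in got:
            triple = (
                e.features.prop_short + e.features.prop_middle + e.features.prop_large
            )
            assert triple == pytest.approx(1.0, abs=1e-9)

    def test_seeded_determinism(self, small_corpus):
        q = small_corpus.entries[3].features
        a = augment_semisimulated(small_corpus, q, self.provider, n=20, seed=9)
        b = augment_semisimulated(small_corpus, q, self.provider, n=20, seed=9)
        assert [e.features.as_tuple() for e in a] == [
            e.features.as_tuple() for e in b
        ]

    def test_missing_provider_explains_contract(self, small_corpus):
        with pytest.raises(ValidationError, match="performance_provider"):
            augment_semisimulated(
                small_corpus, small_corpus.entries[0].features, None
            )

    def test_augmented_corpus_is_trainable(self, small_corpus):
        extra = augment_semisimulated(
            small_corpus, small_corpus.entries[0].features,
            lambda f, d: {
                c: CallerPerformance(d, c, 0.7, 0.7, 0.7)
                for c in small_corpus.callers
            },
            n=30,
            seed=2,
        )
        bigger = small_corpus.extended(extra)
        assert len(bigger) == len(small_corpus) + 30
        CallerRecommender(bigger, n_trees=20).fit()
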