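"""The meta-model: from historical corpus to caller recommendations.

The central object is :class:`CallerRecommender`, a model built from a
:class:`HistoricalCorpus` (meta-feature vectors paired with per-caller
performances over many datasets). ``fit()`` trains a bagged decision-tree
ensemble (a random forest) mapping the eight meta-features to the
best-performing caller under a chosen metric and returns a
:class:`RecommenderResults` carrying the trained ensemble, its training
summary and prediction methods. ``loo()`` runs the leave-one-out evaluation
protocol and returns an :class:`LOOResults` with per-dataset recommendation
accuracies and win/draw/loss comparisons against the fixed-pick and
random-pick baselines.

Recommendations are deterministic: the per-fold ensemble seed is derived
from the held-out dataset id, training rows are ordered by dataset id, and
vote ties fall to the lexicographically smaller caller name.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import formats
from .calleval import (
    METRICS,
    CallerPerformance,
    MetaTargetLabel,
    WinDrawLossCount,
    identify_meta_target,
    recommendation_accuracy,
    win_draw_loss,
)
from .errors import ModelLoadError, ValidationError
from .sigscan import FEATURE_ORDER, MetaFeatureVector

_SEED_MASK = 0x7FFFFFFF


@dataclass(frozen=True)
class CorpusEntry:
    """One historical dataset: its meta-features and per-caller performances."""

    dataset_id: str
    features: MetaFeatureVector
    performances: Mapping[str, CallerPerformance]  # caller -> performance

    def meta_target(self, metric: str) -> MetaTargetLabel:
        return identify_meta_target(self.performances.values(), metric)


class HistoricalCorpus:
    """The meta-learning training corpus.

    Every entry must cover the same caller set and dataset ids are unique.
    """

    def __init__(self, entries: Iterable[CorpusEntry]):
        self.entries: list[CorpusEntry] = list(entries)
        ids = [e.dataset_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate dataset ids in corpus")
        caller_sets = {frozenset(e.performances) for e in self.entries}
        if len(caller_sets) > 1:
            raise ValidationError("corpus entries disagree on the caller set")
        self.callers: tuple[str, ...] = (
            tuple(sorted(next(iter(caller_sets)))) if self.entries else ()
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def feature_matrix(self) -> np.ndarray:
        return np.array([e.features.as_tuple() for e in self.entries], dtype=float)

    def labels(self, metric: str) -> list[str]:
        return [e.meta_target(metric).best_caller for e in self.entries]

    def extended(self, extra: Iterable[CorpusEntry]) -> "HistoricalCorpus":
        return HistoricalCorpus([*self.entries, *extra])

    # ---- tabular round trip -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one row per dataset: features then per-caller metrics."""
        rows = []
        for e in self.entries:
            row: dict = {"dataset_id": e.dataset_id}
            row.update(e.features.as_dict())
            for caller in self.callers:
                perf = e.performances[caller]
                for m in METRICS:
                    row[f"{caller}.{m}"] = perf.metric(m)
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HistoricalCorpus":
        feature_cols = list(FEATURE_ORDER)
        missing = [c for c in ("dataset_id", *feature_cols) if c not in df.columns]
        if missing:
            raise ValidationError(f"corpus table missing columns {missing}")
        callers = sorted(
            {c.rsplit(".", 1)[0] for c in df.columns if c.endswith(".f_measure")}
        )
        if not callers:
            raise ValidationError("corpus table has no <caller>.f_measure columns")
        entries = []
        for _, row in df.iterrows():
            mf = MetaFeatureVector(**{c: float(row[c]) for c in feature_cols})
            perfs = {}
            for caller in callers:
                perfs[caller] = CallerPerformance(
                    dataset_id=str(row["dataset_id"]),
                    caller=caller,
                    precision=float(row[f"{caller}.precision"]),
                    recall=float(row[f"{caller}.recall"]),
                    f_measure=float(row[f"{caller}.f_measure"]),
                )
            entries.append(
                CorpusEntry(str(row["dataset_id"]), mf, perfs)
            )
        return cls(entries)

    def save(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "HistoricalCorpus":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"))


def _check_finite(X: np.ndarray, ids: Sequence[str]) -> None:
    bad = ~np.isfinite(X)
    if bad.any():
        i = int(np.argwhere(bad.any(axis=1))[0][0])
        raise ValidationError(f"non-finite meta-feature in dataset {ids[i]}")


def _fold_seed(dataset_id: str, seed: int) -> int:
    """Stable per-fold ensemble seed, independent of corpus entry order."""
    return (zlib.crc32(dataset_id.encode()) ^ seed) & _SEED_MASK


@dataclass
class RecommenderConfig:
    """Ensemble configuration: tree count and base seed."""

    n_trees: int = 500
    seed: int = 42


class CallerRecommender:
    """Meta-model recommending an SV caller from dataset meta-features.

    Parameters
    ----------
    corpus:
        Historical corpus of (meta-features, per-caller performances).
    metric:
        The meta-target metric — ``f_measure``, ``precision`` or ``recall``.
    n_trees, seed:
        Size and seed of the bagged decision-tree ensemble.
    """

    def __init__(
        self,
        corpus: HistoricalCorpus,
        metric: str = "f_measure",
        n_trees: int = 500,
        seed: int = 42,
    ):
        if metric not in METRICS:
            raise ValidationError(f"unknown metric {metric!r}")
        if len(corpus) < 2:
            raise ValidationError("training needs a corpus of >= 2 entries")
        self.corpus = corpus
        self.metric = metric
        self.config = RecommenderConfig(n_trees=n_trees, seed=seed)

    def fit(
        self, seed: Optional[int] = None, compute_oob: bool = True
    ) -> "RecommenderResults":
        """Train the ensemble on the whole corpus.

        ``compute_oob`` controls whether the out-of-bag accuracy is
        estimated for the training summary; per-fold refits in ``loo()``
        skip it since the fold summaries are never read.
        """
        entries = sorted(self.corpus.entries, key=lambda e: e.dataset_id)
        ids = [e.dataset_id for e in entries]
        X = np.array([e.features.as_tuple() for e in entries], dtype=float)
        _check_finite(X, ids)
        y = [e.meta_target(self.metric).best_caller for e in entries]
        rf_seed = self.config.seed if seed is None else seed
        use_oob = compute_oob and self.config.n_trees >= 10 and len(set(y)) > 1
        ensemble = RandomForestClassifier(
            n_estimators=self.config.n_trees,
            random_state=rf_seed,
            oob_score=use_oob,
            bootstrap=True,
        )
        ensemble.fit(X, y)
        training_summary = {
            "n_datasets": len(entries),
            "n_classes": len(set(y)),
            "oob_accuracy": float(ensemble.oob_score_) if use_oob else float("nan"),
        }
        return RecommenderResults(
            metric=self.metric,
            feature_order=tuple(FEATURE_ORDER),
            caller_labels=self.corpus.callers,
            ensemble=ensemble,
            seed=rf_seed,
            training_summary=training_summary,
        )

    def loo(self) -> "LOOResults":
        """Leave-one-out evaluation against fixed-pick and random-pick.

        Each dataset is held out in turn; the ensemble is retrained on the
        rest (seeded per held-out dataset) and its recommendation is scored
        with the recommendation-accuracy statistic on the held-out dataset's
        realized per-caller performances.
        """
        corpus, metric = self.corpus, self.metric
        if len(corpus) < 3:
            raise ValidationError("leave-one-out needs >= 3 corpus entries")
        callers = corpus.callers
        rows = []
        for held in corpus.entries:
            rest = HistoricalCorpus(
                [e for e in corpus.entries if e.dataset_id != held.dataset_id]
            )
            model = CallerRecommender(
                rest, metric, self.config.n_trees, self.config.seed
            ).fit(
                seed=_fold_seed(held.dataset_id, self.config.seed),
                compute_oob=False,
            )
            recommended, _ = model.recommend(held.features)
            perf = {c: held.performances[c].metric(metric) for c in callers}
            p_opt, p_worst = max(perf.values()), min(perf.values())
            row = {
                "dataset_id": held.dataset_id,
                "recommended": recommended,
                "optimal": held.meta_target(metric).best_caller,
                "p_recommended": perf[recommended],
                "p_optimal": p_opt,
                "p_worst": p_worst,
                "ra": recommendation_accuracy(perf[recommended], p_opt, p_worst),
                "random_pick_metric": float(np.mean(list(perf.values()))),
                "random_pick_ra": float(
                    np.mean(
                        [recommendation_accuracy(v, p_opt, p_worst)
                         for v in perf.values()]
                    )
                ),
            }
            for c in callers:
                row[f"{c}.metric"] = perf[c]
                row[f"{c}.ra"] = recommendation_accuracy(perf[c], p_opt, p_worst)
            rows.append(row)
        table = pd.DataFrame(rows)
        return LOOResults(metric=metric, callers=callers, table=table)


@dataclass
class RecommenderResults:
    """A trained recommendation model.

    Carries the fitted ensemble, the feature ordering it expects, the caller
    label set and the training summary; provides prediction and persistence.
    """

    metric: str
    feature_order: tuple[str, ...]
    caller_labels: tuple[str, ...]
    ensemble: RandomForestClassifier
    seed: int
    training_summary: dict

    def recommend(self, mf: MetaFeatureVector) -> tuple[str, dict[str, float]]:
        """Recommend a caller; returns (caller, per-caller vote fractions).

        The winner is the caller with the largest vote fraction, ties going
        to the lexicographically smaller name. Fractions sum to 1.
        """
        x = np.array([mf.as_tuple()], dtype=float)
        _check_finite(x, ["<query>"])
        try:
            proba = self.ensemble.predict_proba(x)[0]
        except Exception as exc:
            raise ModelLoadError(f"model ensemble is not usable: {exc}") from exc
        classes = list(self.ensemble.classes_)
        scores = {c: 0.0 for c in self.caller_labels}
        for c, p in zip(classes, proba):
            scores[c] = float(p)
        best = max(sorted(scores), key=lambda c: scores[c])
        return best, scores

    def summary(self) -> str:
        s = self.training_summary
        lines = [
            "Caller recommendation model",
            "=" * 40,
            f"meta-target metric : {self.metric}",
            f"callers            : {', '.join(self.caller_labels)}",
            f"trees              : {self.ensemble.n_estimators}",
            f"seed               : {self.seed}",
            f"training datasets  : {s['n_datasets']}",
            f"target classes     : {s['n_classes']}",
            f"out-of-bag accuracy: {s['oob_accuracy']:.4f}",
        ]
        return "\n".join(lines)

    def save(self, path: str | os.PathLike) -> None:
        formats.write_model(
            {
                "metric": self.metric,
                "feature_order": self.feature_order,
                "caller_labels": self.caller_labels,
                "ensemble": self.ensemble,
                "seed": self.seed,
                "training_summary": self.training_summary,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RecommenderResults":
        env = formats.read_model(path)
        try:
            return cls(
                metric=env["metric"],
                feature_order=tuple(env["feature_order"]),
                caller_labels=tuple(env["caller_labels"]),
                ensemble=env["ensemble"],
                seed=env["seed"],
                training_summary=env["training_summary"],
            )
        except KeyError as exc:
            raise ModelLoadError(f"{path}: incomplete model envelope: {exc}") from exc


@dataclass
class LOOResults:
    """Leave-one-out evaluation results.

    ``table`` has one row per dataset with the recommendation, its RA, the
    per-caller fixed-pick RA columns (``<caller>.ra``) and the random-pick
    expectation columns.
    """

    metric: str
    callers: tuple[str, ...]
    table: pd.DataFrame

    @property
    def mean_ra(self) -> float:
        return float(self.table["ra"].mean())

    @property
    def fixed_pick_ra(self) -> dict[str, float]:
        return {c: float(self.table[f"{c}.ra"].mean()) for c in self.callers}

    @property
    def random_pick_ra(self) -> float:
        return float(self.table["random_pick_ra"].mean())

    def random_pick_realized_ra(self, seed: int = 42) -> float:
        """Mean RA of one realized uniform random draw per dataset."""
        rng = np.random.default_rng(seed & _SEED_MASK)
        picks = rng.integers(0, len(self.callers), len(self.table))
        vals = [
            float(self.table.iloc[i][f"{self.callers[k]}.ra"])
            for i, k in enumerate(picks)
        ]
        return float(np.mean(vals))

    def win_draw_loss_vs(self, strategy: str) -> WinDrawLossCount:
        """WDL of the recommendation against a baseline on realized metrics.

        ``strategy`` is a caller name (fixed-pick) or ``"random"`` (uniform
        expectation over callers).
        """
        rec = self.table["p_recommended"].tolist()
        if strategy == "random":
            other = self.table["random_pick_metric"].tolist()
        elif strategy in self.callers:
            other = self.table[f"{strategy}.metric"].tolist()
        else:
            raise ValidationError(f"unknown strategy {strategy!r}")
        return win_draw_loss(rec, other)

    def win_draw_loss_table(self) -> pd.DataFrame:
        rows = []
        for strategy in [*self.callers, "random"]:
            wdl = self.win_draw_loss_vs(strategy)
            rows.append(
                {
                    "versus": strategy,
                    "wins": wdl.wins,
                    "draws": wdl.draws,
                    "losses": wdl.losses,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Leave-one-out evaluation ({self.metric}, n={len(self.table)})",
            "=" * 48,
            f"mean RA (recommended): {self.mean_ra:.4f}",
            f"mean RA (random-pick): {self.random_pick_ra:.4f}",
        ]
        for c, v in self.fixed_pick_ra.items():
            lines.append(f"mean RA (fixed {c}): {v:.4f}")
        lines.append("")
        lines.append("Win/Draw/Loss of the recommendation on realized "
                     f"{self.metric}:")
        for _, row in self.win_draw_loss_table().iterrows():
            lines.append(
                f"  vs {row['versus']:<12} {row['wins']:>4} / "
                f"{row['draws']:>4} / {row['losses']:>4}"
            )
        return "\n".join(lines)


# ---- similarity gate and semi-simulated augmentation ------------------------

def count_similar(
    corpus: HistoricalCorpus, mf: MetaFeatureVector, radius: float = 1.0
) -> tuple[int, bool]:
    """Count corpus entries with meta-features similar to ``mf``.

    Features are standardized to zero mean / unit variance over the corpus;
    a neighbour is an entry within Euclidean distance ``radius`` in that
    space. Augmentation is needed unless the count strictly exceeds 100.
    """
    if len(corpus) == 0:
        return 0, True
    X = corpus.feature_matrix()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    z = (np.array(mf.as_tuple(), dtype=float) - mu) / sd
    dist = np.sqrt(((Z - z) ** 2).sum(axis=1))
    count = int((dist <= radius).sum())
    return count, count <= 100


PerformanceProvider = Callable[[MetaFeatureVector, str], Mapping[str, CallerPerformance]]

_PROPORTION_TRIPLE = ("prop_short", "prop_middle", "prop_large")


def augment_semisimulated(
    corpus: HistoricalCorpus,
    mf: MetaFeatureVector,
    performance_provider: Optional[PerformanceProvider],
    n: int = 100,
    seed: int = 42,
) -> list[CorpusEntry]:
    """Generate semi-simulated corpus entries around a query feature vector.

    Each entry perturbs ``mf`` with Gaussian noise (sd = 5% of the per-feature
    corpus sd; the size-class proportion triple is re-clipped to [0,1] and
    renormalized) and is labelled by the injected ``performance_provider``,
    which maps a feature vector to per-caller performances — the stand-in for
    actually running the SV callers on semi-simulated reads.
    """
    if performance_provider is None:
        raise ValidationError(
            "augment_semisimulated needs a performance_provider: obtaining "
            "per-caller performances for semi-simulated data (normally done "
            "by running the callers) is delegated to the caller of this API"
        )
    if len(corpus) == 0:
        raise ValidationError("augmentation needs a non-empty corpus")
    rng = np.random.default_rng(seed & _SEED_MASK)
    X = corpus.feature_matrix()
    sd = X.std(axis=0) * 0.05
    base = np.array(mf.as_tuple(), dtype=float)
    entries: list[CorpusEntry] = []
    prop_idx = [FEATURE_ORDER.index(p) for p in _PROPORTION_TRIPLE]
    for i in range(n):
        vec = base + rng.normal(0.0, 1.0, base.shape) * sd
        vec[0] = max(vec[0], 1.0)  # read length stays positive
        vec[1] = max(vec[1], 0.0)  # depth stays non-negative
        tr_i = FEATURE_ORDER.index("prop_sv_tr")
        vec[tr_i] = float(np.clip(vec[tr_i], 0.0, 1.0))
        hi_i = FEATURE_ORDER.index("prop_high_rvb")
        vec[hi_i] = float(np.clip(vec[hi_i], 0.0, 1.0))
        vec[FEATURE_ORDER.index("rvb")] = max(vec[FEATURE_ORDER.index("rvb")], 0.0)
        triple = np.clip(vec[prop_idx], 0.0, 1.0)
        if triple.sum() > 0:
            triple = triple / triple.sum()
        vec[prop_idx] = triple
        new_mf = MetaFeatureVector(**dict(zip(FEATURE_ORDER, map(float, vec))))
        dataset_id = f"semisim_{i:04d}"
        perfs = performance_provider(new_mf, dataset_id)
        entries.append(CorpusEntry(dataset_id, new_mf, dict(perfs)))
    return entries
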