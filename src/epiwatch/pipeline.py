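"""End-to-end orchestration: reliable sources -> features -> classifier ->
publisher elimination -> early-warning indicators, plus the ablation harness.

``run_identification`` executes the identification stage on a labelled
corpus: score the link graph, build co-occurrence statistics, extract the
nine-feature table, train the boosted classifier on a stratified split,
evaluate held-out accuracy, update each publisher's false-history
probability from the classifier's output, and eliminate publishers at the
threshold theta.  The surviving messages are the *effective corpus* fed to
``run_warning``, which computes the five daily indicators.

``run_ablation_benchmark`` sweeps training fractions and compares the full
feature system against a model without subject relevance (F1) and the
regulatory feature (F9), optionally against classical baselines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import boosting, features, reliability, warning as warn_mod
from .corpus import Corpus, write_corpus
from .features import FEATURE_NAMES
from .warning import WarningConfig

__all__ = [
    "PipelineConfig",
    "IdentificationReport",
    "run_identification",
    "run_warning",
    "run_ablation_benchmark",
]

logger = logging.getLogger("epiwatch")


@dataclass(frozen=True)
class PipelineConfig:
    theta: float = 0.5
    train_fraction: float = 0.8
    classifier: boosting.TrainConfig = field(default_factory=boosting.TrainConfig)
    warning: WarningConfig = field(default_factory=WarningConfig)
    ablation: frozenset[str] = frozenset()       # feature names to drop, e.g. {"f1","f9"}
    use_f9_in_classifier: bool = False           # F9 is regulatory by default
    classify_threshold: float = 0.5
    pmi_smoothing: float = 1e-9
    damping: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0,1)")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0,1]")
        unknown = set(self.ablation) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown ablation features: {sorted(unknown)}")


@dataclass
class IdentificationReport:
    accuracy: float
    confusion: dict[str, int]            # tp/fp/tn/fn on the held-out set
    importance: pd.DataFrame             # 9 rows: feature, gain
    n_train: int
    n_test: int
    n_messages: int
    n_effective: int
    n_reliable_pages: int
    dropped_features: tuple[str, ...]
    model: boosting.BoostedModel
    effective_corpus: Corpus
    predictions: pd.Series               # message_id -> predicted label


def _classifier_columns(config: PipelineConfig) -> list[str]:
    cols = list(FEATURE_NAMES[:8])
    if config.use_f9_in_classifier:
        cols.append("f9")
    return [c for c in cols if c not in config.ablation]


def build_stats_for_corpus(
    corpus: Corpus,
    feature_words: Sequence[str],
    reliable_pages: set[int] | None = None,
) -> features.CorpusStats:
    """Document-level co-occurrence statistics for PMI.

    Documents are the messages' token sets; when the corpus carries pages
    and a reliable-page set is given, the reliable pages' texts are included
    as additional documents (the reliable-source corpus).
    """
    docs: list[list[str]] = [[t for t, _ in m.tokens()] for m in corpus.messages]
    if corpus.pages is not None and reliable_pages:
        for p in corpus.pages:
            if p.page_id in reliable_pages and p.text:
                docs.append(p.text.split())
    vocab = set(w for d in docs for w in d)
    return features.build_corpus_stats(docs, vocabulary=vocab)


def run_identification(
    corpus: Corpus,
    feature_words: Sequence[str],
    config: PipelineConfig = PipelineConfig(),
    output_dir: str | Path | None = None,
) -> IdentificationReport:
    """Identification stage on a labelled corpus (ground truth on messages).

    Steps: reliable-source selection (when a link graph is present) ->
    corpus statistics -> nine-feature extraction -> seeded stratified
    80/20-style split -> boosted-tree training -> held-out accuracy ->
    classification of the whole corpus -> publisher false-history update ->
    theta elimination.  Writes the filtered corpus, model and metrics when
    ``output_dir`` is given.
    """
    labels = [m.label for m in corpus.messages]
    if any(lab is None for lab in labels):
        raise ValueError("identification requires a fully labelled corpus")

    n_reliable = 0
    reliable: set[int] = set()
    if corpus.pages:
        tm = reliability.build_transfer_matrix(corpus.pages)
        scores = reliability.score_pages(tm, damping=config.damping)
        reliable = reliability.select_reliable(scores)
        n_reliable = len(reliable)
        logger.info("reliable sources: %d of %d pages", n_reliable, len(corpus.pages))

    stats = build_stats_for_corpus(corpus, feature_words, reliable)
    table = features.feature_matrix(
        corpus, feature_words, stats, smoothing=config.pmi_smoothing
    )
    cols = _classifier_columns(config)
    X = table[cols].to_numpy(dtype=float)
    y = np.array([1 if lab == "false_info" else 0 for lab in labels])

    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=config.train_fraction,
        stratify=y,
        random_state=config.seed,
    )
    model = boosting.train(X[train_idx], y[train_idx], config.classifier)
    test_probs = boosting.predict(model, X[test_idx])
    test_pred = (test_probs >= config.classify_threshold).astype(int)
    acc = float((test_pred == y[test_idx]).mean())
    confusion = {
        "tp": int(((test_pred == 1) & (y[test_idx] == 1)).sum()),
        "fp": int(((test_pred == 1) & (y[test_idx] == 0)).sum()),
        "tn": int(((test_pred == 0) & (y[test_idx] == 0)).sum()),
        "fn": int(((test_pred == 0) & (y[test_idx] == 1)).sum()),
    }

    # classify the whole corpus, update publisher regulatory state, eliminate
    all_probs = boosting.predict(model, X)
    predicted = boosting.classify(all_probs, config.classify_threshold)
    by_publisher: dict[str, list[str]] = {}
    for m, lab in zip(corpus.messages, predicted):
        by_publisher.setdefault(m.publisher_id, []).append(lab)
    new_pubs = {
        pid: features.update_false_history(pub, by_publisher.get(pid, []))
        for pid, pub in corpus.publishers.items()
    }
    updated = corpus.with_publishers(new_pubs)
    kept = [
        m for m, lab in zip(updated.messages, predicted) if lab == "true_info"
    ]
    effective = features.eliminate_publishers(
        updated.with_messages(kept), config.theta
    )

    gain = model.feature_importance()
    importance = pd.DataFrame(
        {
            "feature": list(FEATURE_NAMES),
            "gain": [
                gain.get(cols.index(f), 0.0) if f in cols else 0.0
                for f in FEATURE_NAMES
            ],
        }
    )
    report = IdentificationReport(
        accuracy=acc,
        confusion=confusion,
        importance=importance,
        n_train=len(train_idx),
        n_test=len(test_idx),
        n_messages=len(corpus.messages),
        n_effective=len(effective.messages),
        n_reliable_pages=n_reliable,
        dropped_features=tuple(sorted(config.ablation)),
        model=model,
        effective_corpus=effective,
        predictions=pd.Series(
            predicted, index=[m.message_id for m in corpus.messages], name="predicted"
        ),
    )
    if output_dir is not None:
        _write_identification(report, config, Path(output_dir))
    return report


def _config_manifest(config: PipelineConfig) -> dict:
    cfg = dataclasses.asdict(config)
    cfg["ablation"] = sorted(config.ablation)
    blob = json.dumps(cfg, sort_keys=True, default=str)
    return {
        "config": cfg,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
    }


def _write_identification(
    report: IdentificationReport, config: PipelineConfig, outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_corpus(report.effective_corpus, outdir / "effective_corpus.jsonl")
    boosting.save_model(report.model, outdir / "model.json")
    report.importance.to_csv(outdir / "importance.csv", index=False)
    metrics = {
        "accuracy": report.accuracy,
        "confusion": report.confusion,
        "n_train": report.n_train,
        "n_test": report.n_test,
        "n_messages": report.n_messages,
        "n_effective": report.n_effective,
        "n_reliable_pages": report.n_reliable_pages,
        "dropped_features": list(report.dropped_features),
    }
    (outdir / "metrics.json").write_text(
        json.dumps(metrics, indent=2), encoding="utf-8"
    )
    (outdir / "manifest.json").write_text(
        json.dumps(_config_manifest(config), indent=2), encoding="utf-8"
    )


def run_warning(
    corpus_or_windows,
    gazetteer: dict[str, str],
    feature_words: Sequence[str],
    config: PipelineConfig = PipelineConfig(),
    output_path: str | Path | None = None,
) -> pd.DataFrame:
    """Compute the daily indicator series for an effective corpus.

    Accepts either a Corpus (grouped into daily windows by timestamp) or an
    explicit list of (date, messages) windows.  Returns a DataFrame with
    columns date, i1..i5; undefined indicators are NaN.
    """
    if isinstance(corpus_or_windows, Corpus):
        corpus = corpus_or_windows
        if not corpus.messages:
            logger.warning("empty effective corpus: no indicators to compute")
            return pd.DataFrame(columns=["date", "i1", "i2", "i3", "i4", "i5"])
        by_day: dict = {}
        for m in corpus.messages:
            by_day.setdefault(m.timestamp, []).append(m)
        windows = sorted(by_day.items())
        all_messages = corpus.messages
    else:
        windows = list(corpus_or_windows)
        all_messages = [m for _, msgs in windows for m in msgs]
        if not all_messages:
            logger.warning("empty windows: no indicators to compute")
            return pd.DataFrame(columns=["date", "i1", "i2", "i3", "i4", "i5"])

    stats = features.build_corpus_stats(
        ([t for t, _ in m.tokens()] for m in all_messages)
    )
    wcfg = dataclasses.replace(config.warning, pmi_smoothing=config.pmi_smoothing)
    records = warn_mod.compute_indicator_series(windows, gazetteer, stats, wcfg)
    for r in records:
        if not r.i1_defined:
            logger.info("window %s: I1 undefined (no base count)", r.window_date)
    df = pd.DataFrame([r.as_dict() for r in records])
    if output_path is not None:
        df.to_csv(output_path, index=False)
    return df


def run_ablation_benchmark(
    corpus: Corpus,
    feature_words: Sequence[str],
    config: PipelineConfig = PipelineConfig(),
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    ablation: frozenset[str] = frozenset({"f1", "f9"}),
    include_baselines: bool = False,
    output_path: str | Path | None = None,
) -> pd.DataFrame:
    """Accuracy of full vs ablated model across training-set fractions.

    Returns a tidy long-format table (model, train_fraction, accuracy).
    ``include_baselines`` adds naive Bayes, KNN and SVM reference
    classifiers from scikit-learn — oracles for comparison, not part of the
    method.
    """
    stats = build_stats_for_corpus(corpus, feature_words)
    table = features.feature_matrix(
        corpus, feature_words, stats, smoothing=config.pmi_smoothing
    )
    y = np.array(
        [1 if m.label == "false_info" else 0 for m in corpus.messages]
    )

    variants: dict[str, list[str]] = {
        "full": _classifier_columns(config),
        "ablated": [
            c for c in _classifier_columns(config) if c not in ablation
        ],
    }
    rows = []
    for frac in fractions:
        idx = np.arange(len(y))
        train_idx, test_idx = train_test_split(
            idx, train_size=frac, stratify=y, random_state=config.seed
        )
        for name, cols in variants.items():
            X = table[cols].to_numpy(dtype=float)
            model = boosting.train(X[train_idx], y[train_idx], config.classifier)
            pred = (
                boosting.predict(model, X[test_idx]) >= config.classify_threshold
            ).astype(int)
            rows.append(
                {
                    "model": name,
                    "train_fraction": frac,
                    "accuracy": float((pred == y[test_idx]).mean()),
                }
            )
        if include_baselines:
            from sklearn.naive_bayes import GaussianNB
            from sklearn.neighbors import KNeighborsClassifier
            from sklearn.svm import SVC

            X = table[variants["full"]].to_numpy(dtype=float)
            for name, clf in (
                ("naive_bayes", GaussianNB()),
                ("knn", KNeighborsClassifier()),
                ("svm", SVC(random_state=config.seed)),
            ):
                clf.fit(X[train_idx], y[train_idx])
                rows.append(
                    {
                        "model": name,
                        "train_fraction": frac,
                        "accuracy": float(
                            (clf.predict(X[test_idx]) == y[test_idx]).mean()
                        ),
                    }
                )
    df = pd.DataFrame(rows)
    if output_path is not None:
        df.to_csv(output_path, index=False)
    return df
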