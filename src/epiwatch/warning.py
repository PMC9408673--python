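"""Five public-opinion early-warning indicators over daily message windows.

Computed per unit time (one calendar day) on the *effective* corpus — the
messages surviving false-information filtering:

* I1 change rate Qr = (l2 - l1) / l1 of the message count vs the previous
  day (undefined on the first day or after an empty day);
* I2 regional coverage Ac = p_l / P: distinct provinces mentioned, over the
  P provincial administrative regions of the gazetteer;
* I3 emotional tendency Et: mean per-message emotional intensity P/(P+R);
* I4 subject concentration Tc = n/c: messages per topic cluster, where the
  clusters come from adaptive agglomerative clustering of the day's
  subject (noun-list) matrix under pairwise PMI similarity;
* I5 new subjects Nt: current clusters with low PMI relevance to every
  cluster of the previous day.

High concentration means attention focused on few subjects; a burst of new
subjects signals that the epidemic conversation has shifted.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from datetime import date
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .corpus import Message
from .features import CorpusStats, f5_emotional_intensity, pmi

__all__ = [
    "SubjectMatrix",
    "Clustering",
    "IndicatorRecord",
    "WarningConfig",
    "i1_change_rate",
    "i2_region_coverage",
    "i3_emotional_tendency",
    "cluster_subjects",
    "i4_concentration",
    "i5_new_subjects",
    "compute_indicator_series",
]

#: provincial administrative regions of China (the paper's country P)
DEFAULT_TOTAL_PROVINCES = 34


@dataclass(frozen=True)
class SubjectMatrix:
    """Per-message ordered noun lists of one window (ragged rows)."""

    rows: tuple[tuple[str, ...], ...]

    @classmethod
    def from_messages(cls, messages: Sequence[Message]) -> "SubjectMatrix":
        return cls(tuple(tuple(m.nouns()) for m in messages))

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class Clustering:
    """Assignment of a window's messages to topic clusters."""

    assignments: tuple[int, ...]
    n_clusters: int
    representatives: tuple[tuple[str, ...], ...]  # per-cluster noun multiset

    @classmethod
    def empty(cls) -> "Clustering":
        return cls((), 0, ())


@dataclass(frozen=True)
class WarningConfig:
    tau: float = 0.5
    tau_new: float | None = None  # defaults to tau
    total_provinces: int = DEFAULT_TOTAL_PROVINCES
    pmi_smoothing: float = 0.0

    @property
    def effective_tau_new(self) -> float:
        return self.tau if self.tau_new is None else self.tau_new


@dataclass(frozen=True)
class IndicatorRecord:
    """I1..I5 of one time window; undefined indicators are NaN + flag."""

    window_date: date
    i1_change_rate: float
    i2_region_coverage: float
    i3_emotional_tendency: float
    i4_concentration: float
    i5_new_subjects: int
    i1_defined: bool = True
    i3_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "date": self.window_date.isoformat(),
            "i1": self.i1_change_rate,
            "i2": self.i2_region_coverage,
            "i3": self.i3_emotional_tendency,
            "i4": self.i4_concentration,
            "i5": self.i5_new_subjects,
        }


def i1_change_rate(l1: int, l2: int) -> float:
    """Qr = (l2 - l1)/l1; NaN (undefined) when the base count l1 is 0."""
    if l1 <= 0:
        return math.nan
    return (l2 - l1) / l1


def i2_region_coverage(
    messages: Sequence[Message],
    gazetteer: Mapping[str, str],
    total_provinces: int = DEFAULT_TOTAL_PROVINCES,
) -> float:
    """Ac = p_l / P: share of provinces touched by the window's place mentions.

    Place names map to provinces through the gazetteer; unmapped places are
    ignored with a warning.
    """
    if total_provinces <= 0:
        raise ValueError("total_provinces must be > 0")
    if not gazetteer:
        raise ValueError("gazetteer must be nonempty")
    provinces: set[str] = set()
    unmapped: set[str] = set()
    for m in messages:
        for place in m.places:
            prov = gazetteer.get(place)
            if prov is None:
                unmapped.add(place)
            else:
                provinces.add(prov)
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} place name(s) not in gazetteer: "
            f"{sorted(unmapped)[:5]}...",
            stacklevel=2,
        )
    return len(provinces) / total_provinces


def i3_emotional_tendency(intensities: Sequence[float]) -> float:
    """Et: mean per-message emotional intensity; NaN for an empty window."""
    if len(intensities) == 0:
        return math.nan
    return float(np.mean(intensities))


def _mean_positive_pmi(
    nouns_a: Sequence[str],
    nouns_b: Sequence[str],
    stats: CorpusStats,
    smoothing: float,
) -> float:
    """Mean of max(PMI, 0) over the cross product of two noun lists.

    Computed over distinct-noun pairs weighted by multiplicity, which equals
    the full cross-product mean at far lower cost for repetitive lists.
    """
    if not nouns_a or not nouns_b:
        return 0.0
    ca, cb = Counter(nouns_a), Counter(nouns_b)
    total = 0.0
    for a, na in ca.items():
        for b, nb in cb.items():
            v = pmi(a, b, stats, smoothing)
            if v > 0:
                total += na * nb * v
    return total / (len(nouns_a) * len(nouns_b))


def _normalize_similarities(sim: np.ndarray) -> np.ndarray:
    """Scale pairwise similarities onto [0,1] by the window's maximum.

    Division by the largest off-diagonal relevance keeps the *ratios*
    between pairs: a window dominated by one topic normalizes to uniformly
    high similarity (and stays one cluster), while full min-max rescaling
    would stretch its internal noise across [0,1] and shatter it.  A window
    with no positive relevance at all maps to all-zero (nothing related).
    """
    n = sim.shape[0]
    if n < 2:
        return sim
    off = sim[~np.eye(n, dtype=bool)]
    hi = off.max()
    if hi <= 0:
        out = np.zeros_like(sim)
    else:
        out = sim / hi
    np.fill_diagonal(out, 1.0)
    return np.clip(out, 0.0, 1.0)


def cluster_subjects(
    matrix: SubjectMatrix,
    stats: CorpusStats,
    tau: float = 0.5,
    smoothing: float = 0.0,
) -> Clustering:
    """Adaptive topic clustering of a window's subject matrix.

    Pairwise message relevance is the mean positive PMI between their noun
    lists, min-max normalized; average-linkage agglomerative merging
    continues while the linkage similarity is at least ``tau``, so the
    cluster count c emerges from the data rather than being preset.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0,1], got {tau}")
    n = len(matrix)
    if n == 0:
        return Clustering.empty()
    if n == 1:
        return Clustering((0,), 1, (matrix.rows[0],))

    sim = np.zeros((n, n))
    for i in range(n):
        sim[i, i] = 1.0
        for j in range(i + 1, n):
            s = _mean_positive_pmi(matrix.rows[i], matrix.rows[j], stats, smoothing)
            sim[i, j] = sim[j, i] = s
    sim = _normalize_similarities(sim)

    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    # merge while similarity >= tau  <=>  cut the dendrogram at distance 1 - tau
    labels = fcluster(Z, t=1.0 - tau, criterion="distance")
    labels = labels - labels.min()
    n_clusters = int(labels.max()) + 1
    reps: list[list[str]] = [[] for _ in range(n_clusters)]
    for row, lab in zip(matrix.rows, labels):
        reps[lab].extend(row)
    return Clustering(tuple(int(x) for x in labels), n_clusters,
                      tuple(tuple(r) for r in reps))


def i4_concentration(n: int, c: int) -> float:
    """Tc = n/c: average messages per topic cluster."""
    if c < 1:
        raise ValueError("cluster count must be >= 1")
    if n < c:
        raise ValueError("message count must be >= cluster count")
    return n / c


def i5_new_subjects(
    current: Clustering,
    previous: Clustering,
    stats: CorpusStats,
    tau_new: float = 0.5,
    smoothing: float = 0.0,
) -> int:
    """Nt: current clusters with low relevance to every previous cluster.

    Cross-window relevance is the mean positive PMI between cluster noun
    multisets, normalized by the largest cross-relevance so identical
    windows score 1.  A current cluster counts as new when its best
    relevance to the previous window falls below ``tau_new``; when there is
    no previous window every current cluster is new.
    """
    if current.n_clusters == 0:
        return 0
    if previous.n_clusters == 0:
        return current.n_clusters
    rel = np.zeros((current.n_clusters, previous.n_clusters))
    for i, cur in enumerate(current.representatives):
        for j, prev in enumerate(previous.representatives):
            rel[i, j] = _mean_positive_pmi(cur, prev, stats, smoothing)
    hi = rel.max()
    if hi > 0:
        rel = rel / hi
    best = rel.max(axis=1)
    return int((best < tau_new).sum())


def compute_indicator_series(
    windows: Sequence[tuple[date, Sequence[Message]]],
    gazetteer: Mapping[str, str],
    stats: CorpusStats,
    config: WarningConfig = WarningConfig(),
) -> list[IndicatorRecord]:
    """One IndicatorRecord per chronologically ordered daily window.

    I1 is flagged undefined on the first window (no base count).  Results
    are independent of message order within a window.
    """
    if not windows:
        return []
    dates = [d for d, _ in windows]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("windows must be strictly chronologically ordered")

    records: list[IndicatorRecord] = []
    prev_count: int | None = None
    prev_clustering = Clustering.empty()
    for day, msgs in windows:
        msgs = sorted(msgs, key=lambda m: m.message_id)  # order invariance
        n = len(msgs)
        qr = math.nan if prev_count is None else i1_change_rate(prev_count, n)
        ac = i2_region_coverage(msgs, gazetteer, config.total_provinces)
        et = i3_emotional_tendency([f5_emotional_intensity(m) for m in msgs])
        if n > 0:
            clustering = cluster_subjects(
                SubjectMatrix.from_messages(msgs), stats, config.tau,
                config.pmi_smoothing,
            )
            tc = i4_concentration(n, clustering.n_clusters)
            nt = i5_new_subjects(
                clustering, prev_clustering, stats, config.effective_tau_new,
                config.pmi_smoothing,
            )
        else:
            clustering = Clustering.empty()
            tc, nt = math.nan, 0
        records.append(
            IndicatorRecord(
                window_date=day,
                i1_change_rate=qr,
                i2_region_coverage=ac,
                i3_emotional_tendency=et,
                i4_concentration=tc,
                i5_new_subjects=nt,
                i1_defined=not math.isnan(qr),
                i3_defined=not math.isnan(et),
            )
        )
        prev_count = n
        prev_clustering = clustering
    return records
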