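"""Utility metrics comparing a synthetic cohort against the real one.

Eight metrics, grouped by what they probe:

* marginals — APD (binary prevalence differences), AWD (normalized 1-D
  Wasserstein distances for continuous features), and their combined
  dimension-wise score;
* pairwise structure — correlation distance between Pearson matrices;
* joint structure — latent-cluster deviation after PCA + k-means;
* record-level consistency — gender-exclusive-code violation rate and
  medical-concept abundance distance;
* downstream modelling — TSTR/TRTS AUROC and important-feature agreement.

All distance-style metrics are lower-better; AUROC and feature agreement are
higher-better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

from .cohort_io import PatientMatrix, ValidationError

__all__ = [
    "MetricValue",
    "LatentClusterResult",
    "AbundanceHistogram",
    "apd",
    "awd",
    "dimension_wise_score",
    "correlation_distance",
    "elbow_k",
    "latent_deviation",
    "gender_exclusive_codes",
    "knowledge_violation_rate",
    "abundance_distance",
    "outcome_auroc",
    "feature_agreement",
    "LightGBMLearner",
]

LOWER_BETTER = "lower_better"
HIGHER_BETTER = "higher_better"


@dataclass
class MetricValue:
    metric_id: str
    dataset_id: str
    value: float
    direction: str
    extras: dict = field(default_factory=dict)


@dataclass
class LatentClusterResult:
    k: int
    n_total: np.ndarray  # per-cluster total points
    n_real: np.ndarray  # per-cluster real points
    deviation: float  # may be -inf under perfect mixing


@dataclass
class AbundanceHistogram:
    m: int
    edges: np.ndarray
    h_real: np.ndarray
    h_synth: np.ndarray
    n: int


def _check_shared_schema(real: PatientMatrix, synth: PatientMatrix) -> None:
    if real.schema != synth.schema:
        raise ValidationError("real and synthetic schemas differ")


# ---------------------------------------------------------------------------
# dimension-wise distribution


def apd(real: PatientMatrix, synth: PatientMatrix) -> float:
    """Average absolute prevalence difference over binary features."""
    _check_shared_schema(real, synth)
    cols = real.schema.binary_names
    if not cols:
        raise ValidationError("no binary features")
    pr = real.values[cols].mean().to_numpy()
    ps = synth.values[cols].mean().to_numpy()
    return float(np.abs(pr - ps).mean())


def _raw_wasserstein(real: PatientMatrix, synths: Sequence[PatientMatrix]
                     ) -> np.ndarray:
    cols = real.schema.continuous_names
    out = np.zeros((len(synths), len(cols)))
    for j, c in enumerate(cols):
        rv = real.values[c].to_numpy(dtype=float)
        for i, s in enumerate(synths):
            out[i, j] = wasserstein_distance(rv, s.values[c].to_numpy(dtype=float))
    return out


def _normalized_wasserstein(real: PatientMatrix, synths: Sequence[PatientMatrix]
                            ) -> np.ndarray:
    """Per-feature distances divided by the per-feature maximum across the
    candidate set (0 where every candidate's distance is 0)."""
    raw = _raw_wasserstein(real, synths)
    denom = raw.max(axis=0)
    norm = np.zeros_like(raw)
    nz = denom > 0
    norm[:, nz] = raw[:, nz] / denom[nz]
    return norm


def awd(real: PatientMatrix, candidate_synths: Sequence[PatientMatrix]
        ) -> dict[str, float]:
    """Average normalized Wasserstein distance per candidate dataset.

    The Wasserstein distance is unbounded, so each continuous feature's
    distances are normalized by the maximum across all candidates under
    assessment; the per-dataset AWD is the mean over continuous features.
    """
    if not real.schema.continuous_names:
        raise ValidationError("no continuous features")
    for s in candidate_synths:
        _check_shared_schema(real, s)
    norm = _normalized_wasserstein(real, list(candidate_synths))
    return {s.dataset_id: float(norm[i].mean())
            for i, s in enumerate(candidate_synths)}


def dimension_wise_score(real: PatientMatrix,
                         candidate_synths: Sequence[PatientMatrix],
                         scale: float = 1000.0) -> dict[str, float]:
    """Combined marginal-fidelity score per candidate.

    ``scale × (Σ_binary |Δprevalence| + Σ_continuous normalized WD) / D``
    where D is the total feature count.  The factor (1000 by default) keeps
    the averages legible; purely binary schemas reduce to ``scale × APD``.
    """
    synths = list(candidate_synths)
    for s in synths:
        _check_shared_schema(real, s)
    bcols = real.schema.binary_names
    ccols = real.schema.continuous_names
    d_total = len(bcols) + len(ccols)
    if d_total == 0:
        raise ValidationError("empty feature set")
    sums = np.zeros(len(synths))
    if bcols:
        pr = real.values[bcols].mean().to_numpy()
        for i, s in enumerate(synths):
            sums[i] += np.abs(pr - s.values[bcols].mean().to_numpy()).sum()
    if ccols:
        sums += _normalized_wasserstein(real, synths).sum(axis=1)
    return {s.dataset_id: float(scale * sums[i] / d_total)
            for i, s in enumerate(synths)}


# ---------------------------------------------------------------------------
# column-wise correlation


def _corr_matrix(df: pd.DataFrame) -> np.ndarray:
    """Pearson matrix with entries involving constant columns set to 0
    off-diagonal (Pearson is undefined there) and 1 on the diagonal, so a
    rare code absent from one dataset keeps the matrices comparable."""
    x = df.to_numpy(dtype=float)
    sd = x.std(axis=0)
    const = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c = np.atleast_2d(c)
    c[const, :] = 0.0
    c[:, const] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


def correlation_distance(real: PatientMatrix, synth: PatientMatrix,
                         scale: float = 1e6) -> float:
    """Mean absolute cell-wise difference of Pearson matrices, × scale."""
    _check_shared_schema(real, synth)
    if real.n_features < 2:
        raise ValidationError("need at least 2 features")
    cr = _corr_matrix(real.values)
    cs = _corr_matrix(synth.values)
    return float(np.abs(cr - cs).mean() * scale)


# ---------------------------------------------------------------------------
# latent cluster analysis


def _kmeans(points: np.ndarray, k: int, seed: int) -> KMeans:
    return KMeans(n_clusters=k, n_init=10, random_state=seed).fit(points)


def elbow_k(points: np.ndarray, k_max: int = 10, seed: int = 0) -> int:
    """Elbow heuristic: the k (2..k_max-1) maximizing the second difference
    of the within-cluster sum of squares over k = 1..k_max; ties break to
    the smallest k."""
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    points = np.asarray(points, dtype=float)
    if len(points) <= k_max:
        raise ValidationError("need more points than k_max")
    wcss = np.empty(k_max + 1)
    wcss[0] = np.nan
    centroid = points.mean(axis=0)
    wcss[1] = float(((points - centroid) ** 2).sum())
    for k in range(2, k_max + 1):
        wcss[k] = _kmeans(points, k, seed).inertia_
    if k_max == 2:
        return 2
    ks = np.arange(2, k_max)
    curvature = wcss[ks - 1] - 2 * wcss[ks] + wcss[ks + 1]
    return int(ks[np.argmax(curvature)])


def deviation_from_counts(n_real: np.ndarray, n_total: np.ndarray) -> float:
    """log(mean_i (n_i^R / n_i − 1/2)²); −inf under perfect mixing."""
    n_real = np.asarray(n_real, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    mean_sq = float((((n_real / n_total) - 0.5) ** 2).mean())
    return math.log(mean_sq) if mean_sq > 0 else -math.inf


def latent_deviation(real: PatientMatrix, synth: PatientMatrix,
                     k: int | None = None, seed: int = 0,
                     variance_target: float = 0.80,
                     k_max: int = 10) -> LatentClusterResult:
    """Cluster-mixing deviation of synthetic from real data in latent space.

    Real and synthetic records are stacked, reduced by PCA to the smallest
    dimension count explaining >= ``variance_target`` of the variance, and
    clustered with k-means (k from the elbow heuristic unless given).  The
    deviation is ``log(mean_i (n_i^R / n_i - 1/2)^2)`` (natural log): 0.5
    real in every cluster means perfect mixing and the deviation diverges to
    -inf, which is accepted as the best possible value.
    """
    _check_shared_schema(real, synth)
    if real.n_records != synth.n_records:
        raise ValidationError("latent deviation requires equal-size datasets")
    stacked = np.vstack([real.array(), synth.array()])
    n_real = real.n_records
    pca = PCA(random_state=seed).fit(stacked)
    cum = np.cumsum(pca.explained_variance_ratio_)
    d = int(np.searchsorted(cum, variance_target) + 1)
    proj = pca.transform(stacked)[:, :d]
    if k is None:
        k = elbow_k(proj, k_max=min(k_max, len(proj) - 1), seed=seed)
    labels = _kmeans(proj, k, seed).labels_
    n_tot = np.bincount(labels, minlength=k).astype(float)
    n_r = np.bincount(labels[:n_real], minlength=k).astype(float)
    return LatentClusterResult(k=k, n_total=n_tot, n_real=n_r,
                               deviation=deviation_from_counts(n_r, n_tot))


# ---------------------------------------------------------------------------
# clinical knowledge violation


def gender_exclusive_codes(real: PatientMatrix, top_n: int = 3
                           ) -> dict[int, list[str]]:
    """Per gender value, the most prevalent concepts exclusive to it.

    A code is exclusive to a gender when it has at least one carrier of that
    gender and none of the other in the real data.  Up to ``top_n`` codes
    per gender are kept, ranked by prevalence.
    """
    gname = real.schema.gender_name
    if gname is None:
        raise ValidationError("schema has no gender feature")
    g = real.values[gname].to_numpy()
    out: dict[int, list[str]] = {}
    for gval in (0, 1):
        rows_this, rows_other = g == gval, g != gval
        scored = []
        for code in real.schema.concept_names:
            col = real.values[code].to_numpy()
            if col[rows_this].sum() >= 1 and col[rows_other].sum() == 0:
                scored.append((float(col.mean()), code))
        scored.sort(key=lambda t: (-t[0], t[1]))
        out[gval] = [code for _, code in scored[:top_n]]
    return out


def knowledge_violation_rate(synth: PatientMatrix,
                             codes: dict[int, list[str]]) -> float:
    """Mean fraction of synthetic code carriers with the impossible gender.

    For each gender-exclusive code, the fraction of synthetic records
    positive for it whose gender is the opposite of the code's exclusive
    gender (0 when no synthetic record carries the code), averaged over all
    selected codes.
    """
    all_codes = [(gval, c) for gval, cs in codes.items() for c in cs]
    if not all_codes:
        raise ValidationError("no gender-exclusive codes selected")
    gname = synth.schema.gender_name
    g = synth.values[gname].to_numpy()
    fracs = []
    for gval, code in all_codes:
        carriers = synth.values[code].to_numpy() == 1
        n_car = int(carriers.sum())
        fracs.append(0.0 if n_car == 0 else float((g[carriers] != gval).mean()))
    return float(np.mean(fracs))


# ---------------------------------------------------------------------------
# medical concept abundance


def abundance_histogram(m: PatientMatrix, bins: int) -> tuple[np.ndarray, np.ndarray]:
    cols = m.schema.concept_names
    counts = m.values[cols].to_numpy().sum(axis=1)
    edges = np.linspace(0, len(cols), bins + 1)
    h, _ = np.histogram(counts, bins=edges)
    return h, edges


def abundance_distance(real: PatientMatrix, synth: PatientMatrix,
                       m: int = 20) -> float:
    """Normalized Manhattan distance between distinct-concept-count
    histograms: ``Σ_i |h_r(i) − h_s(i)| / (2N)`` over ``m`` equal-width bins
    spanning [0, number of concepts]; lies in [0, 1]."""
    _check_shared_schema(real, synth)
    if real.n_records != synth.n_records:
        raise ValidationError("abundance distance requires equal record counts")
    if not real.schema.concept_names:
        raise ValidationError("no concept features")
    h_r, edges = abundance_histogram(real, m)
    h_s, _ = abundance_histogram(synth, m)
    n = real.n_records
    return float(np.abs(h_r - h_s).sum() / (2 * n))


# ---------------------------------------------------------------------------
# prediction performance (TSTR / TRTS) and important features


class LightGBMLearner:
    """Default gradient-boosted-trees learner (LightGBM) behind a minimal
    fit/predict_proba/importance interface so alternatives can be plugged in."""

    def __init__(self, seed: int = 0, n_estimators: int = 100):
        self.seed = seed
        self.n_estimators = n_estimators
        self._model = None

    @staticmethod
    def _frame(X: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LightGBMLearner":
        from lightgbm import LGBMClassifier

        self._model = LGBMClassifier(
            n_estimators=self.n_estimators,
            random_state=self.seed,
            deterministic=True,
            n_jobs=1,
            verbose=-1,
        ).fit(self._frame(X), y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._model.predict_proba(self._frame(X))[:, 1]

    def shap_importance(self, X: np.ndarray) -> np.ndarray:
        """Mean |SHAP value| per feature via LightGBM's exact TreeSHAP."""
        contrib = self._model.predict(self._frame(X), pred_contrib=True)
        return np.abs(contrib[:, :-1]).mean(axis=0)  # last column is the bias


LearnerFactory = Callable[[int], LightGBMLearner]


def _xy(m: PatientMatrix, feature_names: Sequence[str] | None = None
        ) -> tuple[np.ndarray, np.ndarray]:
    out = m.schema.outcome_name
    names = [n for n in (feature_names or m.schema.names) if n != out]
    return m.array(names), m.values[out].to_numpy(dtype=int)


def outcome_auroc(train_set: PatientMatrix, test_set: PatientMatrix,
                  seed: int = 0, n_boot: int = 1000,
                  learner_factory: LearnerFactory = LightGBMLearner
                  ) -> MetricValue:
    """AUROC of a gradient-boosted classifier trained on one set, tested on
    the other, with a percentile bootstrap 95% CI over test records.

    TSTR is ``outcome_auroc(synth, real_eval)``; TRTS is
    ``outcome_auroc(real_train, synth)``.
    """
    _check_shared_schema(train_set, test_set)
    Xtr, ytr = _xy(train_set)
    Xte, yte = _xy(test_set)
    if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
        raise ValidationError("both sets must contain both outcome classes")
    model = learner_factory(seed).fit(Xtr, ytr)
    scores = model.predict_proba(Xte)
    auc = float(roc_auc_score(yte, scores))
    rng = np.random.default_rng(seed)
    boots = []
    n = len(yte)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(yte[idx])) < 2:
            continue
        boots.append(roc_auc_score(yte[idx], scores[idx]))
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (auc, auc))
    return MetricValue(
        metric_id="auroc",
        dataset_id=train_set.dataset_id,
        value=auc,
        direction=HIGHER_BETTER,
        extras={"ci95": (float(lo), float(hi)), "n_boot": len(boots)},
    )


def _auroc_of(train_set: PatientMatrix, test_set: PatientMatrix, seed: int,
              feature_names: Sequence[str] | None,
              learner_factory: LearnerFactory) -> float:
    Xtr, ytr = _xy(train_set, feature_names)
    Xte, yte = _xy(test_set, feature_names)
    model = learner_factory(seed).fit(Xtr, ytr)
    return float(roc_auc_score(yte, model.predict_proba(Xte)))


def _importance_ranking(train_set: PatientMatrix, seed: int,
                        learner_factory: LearnerFactory) -> list[str]:
    out = train_set.schema.outcome_name
    names = [n for n in train_set.schema.names if n != out]
    X, y = _xy(train_set)
    model = learner_factory(seed).fit(X, y)
    imp = model.shap_importance(X)
    order = sorted(range(len(names)), key=lambda i: (-imp[i], names[i]))
    return [names[i] for i in order]


def feature_agreement(real_train: PatientMatrix, real_eval: PatientMatrix,
                      synth: PatientMatrix, seed: int = 0,
                      learner_factory: LearnerFactory = LightGBMLearner,
                      m_override: int | None = None) -> float:
    """Overlap of top important features between real- and synthetic-trained
    models, as a proportion of the top-list size M.

    Features are ranked by mean absolute SHAP attribution.  M is the
    smallest k such that a model retrained on the real data's top-k features
    reaches >= 90% of the full real model's AUROC on real evaluation data
    (M defaults to 1 if the full model is no better than chance).  The
    returned value is |top-M(real) ∩ top-M(synth)| / M in [0, 1].
    """
    real_rank = _importance_ranking(real_train, seed, learner_factory)
    synth_rank = _importance_ranking(synth, seed, learner_factory)
    if m_override is not None:
        m = m_override
    else:
        full_auc = _auroc_of(real_train, real_eval, seed, None, learner_factory)
        if full_auc <= 0.5:
            m = 1
        else:
            m = len(real_rank)
            for k in range(1, len(real_rank) + 1):
                sub_auc = _auroc_of(real_train, real_eval, seed,
                                    real_rank[:k], learner_factory)
                if sub_auc >= 0.9 * full_auc:
                    m = k
                    break
    shared = set(real_rank[:m]) & set(synth_rank[:m])
    return float(len(shared) / m)
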