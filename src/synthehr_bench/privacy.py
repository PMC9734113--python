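"""Privacy attack simulations against a synthetic cohort.

Four risks, each in [0, 1] (lower is safer), under the standard assumption
that the adversary holds the synthetic data but not the generator:

* attribute inference — k-nearest-neighbour imputation of sensitive
  attributes from known demographics/common codes, scored as an
  entropy-weighted sum of per-attribute F1 (binary) or closeness accuracy
  (continuous);
* membership inference — claim a target is in the training data when some
  synthetic record lies within a Euclidean distance threshold; scored as F1
  with members as the positive class;
* meaningful identity disclosure — a marketer-risk-style linkage between
  synthetic, real and population data over quasi-identifiers, adjusted for
  adversary error and for whether anything sensitive and non-obvious would
  actually be learned;
* nearest-neighbour adversarial accuracy (NNAA) — the gap between
  synthetic-vs-evaluation and synthetic-vs-training discriminability, a
  direct overfitting probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import f1_score
from sklearn.neighbors import NearestNeighbors

from .cohort_io import PatientMatrix, ValidationError

__all__ = [
    "AttackConfig",
    "entropy_weights",
    "attribute_inference_risk",
    "membership_inference_risk",
    "required_qualifying_count",
    "rs_indicator",
    "identity_disclosure_risk",
    "adversarial_accuracy",
    "nnaa_risk",
]


@dataclass
class AttackConfig:
    """Adversary knowledge and attack parameters.

    ``lambda_spec`` holds two (min, mode, max) triples for the triangular
    error-rate distributions entering the identity-disclosure adjustment
    λ_s = (1 − e1)(1 − e2); ``lambda_override`` pins λ_s for tests.
    """

    knn_k: int = 1
    closeness_threshold: float = 0.1
    membership_distance_threshold: float = 2.0
    known_attributes: list[str] = field(default_factory=list)
    L_percent: float = 1.0
    lambda_spec: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.0, 0.1, 0.2),
        (0.0, 0.1, 0.2),
    )
    lambda_override: float | None = None
    nnaa_repeats: int = 5
    rs_kmeans_k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.closeness_threshold <= 0 or self.membership_distance_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.L_percent <= 100.0:
            raise ValueError("L_percent must lie in (0, 100]")

    # Sensitivity presets mirroring the supplementary attack variants.
    def with_sensitivity(self, variant: str) -> "AttackConfig":
        presets = {
            "knn10": {"knn_k": 10},
            "membership_t5": {"membership_distance_threshold": 5.0},
            "L01": {"L_percent": 0.1},
        }
        if variant not in presets:
            raise KeyError(f"unknown sensitivity variant {variant!r}")
        return replace(self, **presets[variant])


# ---------------------------------------------------------------------------
# attribute inference


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * math.log(p) - (1 - p) * math.log(1 - p)


def entropy_weights(real: PatientMatrix, attributes: list[str],
                    n_bins: int = 20) -> dict[str, float]:
    """Per-attribute weights proportional to empirical information entropy.

    Binary attributes use the Bernoulli entropy of their prevalence;
    continuous attributes use the entropy of a fixed-width ``n_bins``
    discretization of [0, 1].  Weights sum to one.
    """
    ent = {}
    for name in attributes:
        if name not in real.schema:
            raise ValidationError(f"unknown attribute {name!r}")
        col = real.values[name].to_numpy(dtype=float)
        if real.schema[name].kind == "binary":
            ent[name] = _binary_entropy(float(col.mean()))
        else:
            h, _ = np.histogram(col, bins=n_bins, range=(0.0, 1.0))
            p = h[h > 0] / h.sum()
            ent[name] = float(-(p * np.log(p)).sum())
    total = sum(ent.values())
    if total == 0:
        raise ValidationError("all attribute entropies are zero; nothing to infer")
    return {k: v / total for k, v in ent.items()}


def attribute_inference_risk(synth: PatientMatrix, targets: PatientMatrix,
                             cfg: AttackConfig) -> float:
    """Entropy-weighted attribute-inference success against real targets.

    For each target the adversary takes its ``knn_k`` nearest synthetic
    records by Euclidean distance on the known attributes and predicts every
    unknown sensitive attribute — majority vote for binary, neighbour mean
    for continuous.  Binary attributes score an F1 (presence positive, 0
    when no target is positive); continuous attributes score the fraction of
    predictions within ``closeness_threshold`` of the truth.
    """
    schema = synth.schema
    known = list(cfg.known_attributes)
    for name in known:
        if name not in schema:
            raise ValidationError(f"known attribute {name!r} not in schema")
    unknown = [n for n in schema.sensitive_names if n not in known]
    if not unknown:
        raise ValidationError("no sensitive attributes left to infer")
    if cfg.knn_k > synth.n_records:
        raise ValidationError("knn_k exceeds synthetic dataset size")
    nn = NearestNeighbors(n_neighbors=cfg.knn_k).fit(synth.array(known))
    _, idx = nn.kneighbors(targets.array(known))
    try:
        weights = entropy_weights(targets, unknown)
    except ValidationError:
        # every inferable attribute is constant in the targets; weight them
        # uniformly so degenerate fixtures still score their raw F1/accuracy
        weights = {n: 1.0 / len(unknown) for n in unknown}
    risk = 0.0
    for name in unknown:
        true = targets.values[name].to_numpy(dtype=float)
        neigh_vals = synth.values[name].to_numpy(dtype=float)[idx]
        if schema[name].kind == "binary":
            pred = (neigh_vals.mean(axis=1) >= 0.5).astype(int)
            score = f1_score(true.astype(int), pred, zero_division=0)
        else:
            pred = neigh_vals.mean(axis=1)
            score = float((np.abs(pred - true) <= cfg.closeness_threshold).mean())
        risk += weights[name] * score
    return float(risk)


# ---------------------------------------------------------------------------
# membership inference


def membership_inference_risk(synth: PatientMatrix,
                              member_targets: PatientMatrix,
                              nonmember_targets: PatientMatrix,
                              cfg: AttackConfig) -> float:
    """F1 of the distance-threshold membership attack (members positive).

    A target is claimed to be a training member when at least one synthetic
    record lies strictly within ``membership_distance_threshold`` in
    Euclidean distance over all attributes (normalized scale).
    """
    if member_targets.n_records == 0 or nonmember_targets.n_records == 0:
        raise ValidationError("member and non-member target sets must be non-empty")
    s = synth.array()
    claims, truth = [], []
    for tm, is_member in ((member_targets, 1), (nonmember_targets, 0)):
        d = cdist(tm.array(), s).min(axis=1)
        claims.append(d < cfg.membership_distance_threshold)
        truth.append(np.full(tm.n_records, is_member))
    y_pred = np.concatenate(claims).astype(int)
    y_true = np.concatenate(truth)
    return float(f1_score(y_true, y_pred, zero_division=0))


# ---------------------------------------------------------------------------
# meaningful identity disclosure


def required_qualifying_count(L_percent: float, n_sensitive: int) -> int:
    """Sensitive attributes that must qualify for the adversary to have
    meaningfully learned something: ceil(L% of the sensitive attributes)."""
    return int(math.ceil(L_percent / 100.0 * n_sensitive))


def _univariate_clusters(col: np.ndarray, k: int, seed: int) -> np.ndarray:
    k = min(k, len(np.unique(col)))
    if k < 2:
        return np.zeros(len(col), dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(col.reshape(-1, 1))


def rs_indicator(real_record: pd.Series, synth_record: pd.Series,
                 real: PatientMatrix, synth: PatientMatrix,
                 sensitive: list[str], L_percent: float = 1.0,
                 n_clusters: int = 3, mad_floor: float = 1e-9,
                 seed: int = 0) -> int:
    """Would the adversary learn something new from this matched pair?

    A categorical (binary) sensitive attribute qualifies iff (a) at least
    one synthetic record matches at least one real record on that attribute
    and (b) the real-data share of the record's value is below 0.5 (common
    values teach the adversary nothing).  A continuous attribute qualifies
    iff ``p_s × |X_s − Y_t| < 1.48 × MAD`` where p_s is the real-data share
    of the record's cluster under univariate k-means on that attribute and
    MAD its median absolute deviation (floored at ``mad_floor`` when zero).
    Returns 1 iff at least ceil(L% × |sensitive|) attributes qualify.
    """
    if not sensitive:
        raise ValidationError("empty sensitive attribute list")
    qualifying = 0
    for name in sensitive:
        rv = real.values[name].to_numpy(dtype=float)
        x = float(real_record[name])
        if real.schema[name].kind == "binary":
            synth_vals = set(synth.values[name].unique())
            real_vals = set(real.values[name].unique())
            if not (synth_vals & real_vals):
                continue
            p_j = float((rv == x).mean())
            if p_j < 0.5:
                qualifying += 1
        else:
            labels = _univariate_clusters(rv, n_clusters, seed)
            own = labels[np.argmin(np.abs(rv - x))]
            p_s = float((labels == own).mean())
            med = np.median(rv)
            mad = float(np.median(np.abs(rv - med)))
            mad = max(mad, mad_floor)
            y = float(synth_record[name])
            if p_s * abs(x - y) < 1.48 * mad:
                qualifying += 1
    need = required_qualifying_count(L_percent, len(sensitive))
    return int(qualifying >= need)


def _qid_keys(m: PatientMatrix, qids: list[str]) -> pd.Series:
    return pd.Series(list(map(tuple, m.values[qids].to_numpy())), index=m.values.index)


def _draw_lambda(cfg: AttackConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.lambda_override is not None:
        return np.full(n, float(cfg.lambda_override))
    (a1, m1, b1), (a2, m2, b2) = cfg.lambda_spec
    e1 = rng.triangular(a1, m1, b1, size=n)
    e2 = rng.triangular(a2, m2, b2, size=n)
    return (1.0 - e1) * (1.0 - e2)


def identity_disclosure_risk(synth: PatientMatrix, real: PatientMatrix,
                             population: PatientMatrix, cfg: AttackConfig) -> float:
    """Marketer-style re-identification risk adjusted for inference error
    and meaningfulness.

    For each real record s: f_s counts real records sharing its exact
    quasi-identifier values, F_s counts population records sharing them,
    I_s flags an exact quasi-identifier match to some synthetic record, and
    R_s (see :func:`rs_indicator`) flags that matching would teach the
    adversary something sensitive and non-obvious.  The risk is the larger
    of the population-normalized and sample-normalized averaged sums of
    ``(1/f_s or 1/F_s) × (1+λ_s)/2 × I_s × R_s``.
    """
    qids = real.schema.qid_names
    if not qids:
        raise ValidationError("no quasi-identifiers flagged in schema")
    sensitive = real.schema.sensitive_names
    n = real.n_records
    n_pop = population.n_records
    rng = np.random.default_rng(cfg.seed)
    lam = _draw_lambda(cfg, n, rng)

    real_keys = _qid_keys(real, qids)
    f_counts = real_keys.value_counts()
    pop_counts = _qid_keys(population, qids).value_counts()
    synth_keys = _qid_keys(synth, qids)
    first_synth_match: dict[tuple, int] = {}
    for i, key in enumerate(synth_keys):
        first_synth_match.setdefault(key, i)
    match_idx = np.array([first_synth_match.get(k, -1) for k in real_keys])

    # R_s for every real record at once (vectorized rs_indicator)
    need = required_qualifying_count(cfg.L_percent, len(sensitive))
    qual = np.zeros(n, dtype=int)
    bin_sens = [a for a in sensitive if real.schema[a].kind == "binary"]
    cont_sens = [a for a in sensitive if real.schema[a].kind == "continuous"]
    if bin_sens:
        xb = real.values[bin_sens].to_numpy(dtype=float)
        p1 = xb.mean(axis=0)
        share = np.where(xb == 1, p1, 1.0 - p1)
        has_match = np.array([
            bool(set(synth.values[a].unique()) & set(real.values[a].unique()))
            for a in bin_sens
        ])
        qual += ((share < 0.5) & has_match).sum(axis=1)
    if cont_sens:
        matched = match_idx >= 0
        for a in cont_sens:
            rv = real.values[a].to_numpy(dtype=float)
            labels = _univariate_clusters(rv, cfg.rs_kmeans_k, cfg.seed)
            cl_share = np.bincount(labels).astype(float) / n
            p_s = cl_share[labels]
            mad = max(float(np.median(np.abs(rv - np.median(rv)))), 1e-9)
            y = np.zeros(n)
            y[matched] = synth.values[a].to_numpy(dtype=float)[match_idx[matched]]
            qual += ((p_s * np.abs(rv - y) < 1.48 * mad) & matched).astype(int)
    r_s = qual >= need

    active = (match_idx >= 0) & r_s
    adj = (1.0 + lam) / 2.0
    f = np.array([f_counts[k] for k in real_keys], dtype=float)
    big_f = np.array([pop_counts.get(k, 0) for k in real_keys], dtype=float)
    term_pop = float((adj[active] / f[active]).sum()) / n_pop
    ok = active & (big_f > 0)
    term_sample = float((adj[ok] / big_f[ok]).sum()) / n
    return float(max(term_pop, term_sample))


# ---------------------------------------------------------------------------
# nearest neighbour adversarial accuracy


def _min_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return cdist(a, b).min(axis=1)


def _min_self(a: np.ndarray) -> np.ndarray:
    d = cdist(a, a)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def adversarial_accuracy(a: np.ndarray, b: np.ndarray) -> float:
    """Nearest-neighbour adversarial accuracy between two equal-size point
    sets: ½ [ P(nearest-B farther than nearest-other-A) + symmetric term ].

    0 when B duplicates A exactly; 1 when the sets are far apart relative to
    their internal spacing; ≈ 0.5 for independent draws from one
    distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a, b = a.reshape(-1, 1), b.reshape(-1, 1)
    if len(a) != len(b):
        raise ValidationError("adversarial accuracy needs equal-size sets")
    if len(a) < 2:
        raise ValidationError("need at least 2 points per set")
    term_a = float((_min_cross(a, b) > _min_self(a)).mean())
    term_b = float((_min_cross(b, a) > _min_self(b)).mean())
    return 0.5 * (term_a + term_b)


def nnaa_risk(train: PatientMatrix, synth: PatientMatrix,
              eval_set: PatientMatrix, cfg: AttackConfig) -> float:
    """Overfitting loss AA_ES − AA_TS, averaged over seeded subsamples.

    The three point sets must be equal-sized, so the training and synthetic
    data are repeatedly subsampled to the evaluation size and the risk
    averaged over ``nnaa_repeats`` repeats.  Raw values lie in [−1, 1];
    negatives are reported as computed.
    """
    n = eval_set.n_records
    if n < 2:
        raise ValidationError("evaluation set too small")
    if train.n_records < n or synth.n_records < n:
        raise ValidationError("train and synth must be at least evaluation-sized")
    rng = np.random.default_rng(cfg.seed)
    e = eval_set.array()
    t_full, s_full = train.array(), synth.array()
    vals = []
    for _ in range(cfg.nnaa_repeats):
        t = t_full[rng.permutation(len(t_full))[:n]]
        s = s_full[rng.permutation(len(s_full))[:n]]
        vals.append(adversarial_accuracy(e, s) - adversarial_accuracy(t, s))
    return float(np.mean(vals))
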