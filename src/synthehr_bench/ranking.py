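"""Rank aggregation: tie-averaged dataset ranks per metric, rank-derived
model scores, use-case weighted final scores, replicate filtering and risk
categorization.

Lower rank = better dataset; lower final score = better model.  Ranking in
place of raw values makes the aggregation invariant to each metric's scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .cohort_io import PatientMatrix, ValidationError
from .utility import HIGHER_BETTER, LOWER_BETTER, dimension_wise_score

__all__ = [
    "METRIC_SLOTS",
    "RANKING_METRICS",
    "METRIC_DIRECTIONS",
    "RankTable",
    "WeightProfile",
    "rank_with_ties",
    "model_rank_scores",
    "final_model_scores",
    "builtin_weight_profiles",
    "select_top_replicates",
    "risk_category",
]

# The 11 weight slots of a use-case profile: seven utility (TSTR and TRTS
# share the single model-performance slot) and four privacy.
METRIC_SLOTS = (
    "dimension_wise",
    "correlation",
    "latent_cluster",
    "knowledge_violation",
    "concept_abundance",
    "model_performance",
    "feature_agreement",
    "attribute_inference",
    "membership_inference",
    "identity_disclosure",
    "nnaa",
)

PRIVACY_SLOTS = METRIC_SLOTS[-4:]

# The 12 ranking lists: the model-performance slot expands to TSTR and TRTS,
# each carrying half the slot's weight.
RANKING_METRICS = (
    "dimension_wise",
    "correlation",
    "latent_cluster",
    "knowledge_violation",
    "concept_abundance",
    "tstr_auroc",
    "trts_auroc",
    "feature_agreement",
    "attribute_inference",
    "membership_inference",
    "identity_disclosure",
    "nnaa",
)

METRIC_DIRECTIONS = {
    "dimension_wise": LOWER_BETTER,
    "correlation": LOWER_BETTER,
    "latent_cluster": LOWER_BETTER,
    "knowledge_violation": LOWER_BETTER,
    "concept_abundance": LOWER_BETTER,
    "tstr_auroc": HIGHER_BETTER,
    "trts_auroc": HIGHER_BETTER,
    "feature_agreement": HIGHER_BETTER,
    "attribute_inference": LOWER_BETTER,
    "membership_inference": LOWER_BETTER,
    "identity_disclosure": LOWER_BETTER,
    "nnaa": LOWER_BETTER,
}


@dataclass
class RankTable:
    metric_id: str
    dataset_ids: list[str]
    ranks: dict[str, float]
    direction: str

    def rank_sum(self) -> float:
        return float(sum(self.ranks.values()))


@dataclass
class WeightProfile:
    """Metric-slot → weight map summing to 1 (a use case)."""

    name: str
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(METRIC_SLOTS)
        if unknown:
            raise ValueError(f"unknown metric slots {sorted(unknown)}")
        missing = set(METRIC_SLOTS) - set(self.weights)
        if missing:
            raise ValueError(f"missing metric slots {sorted(missing)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def per_ranking_metric(self) -> dict[str, float]:
        """Expand the model-performance slot over TSTR and TRTS (half each)."""
        out = {}
        for slot, w in self.weights.items():
            if slot == "model_performance":
                out["tstr_auroc"] = w / 2.0
                out["trts_auroc"] = w / 2.0
            else:
                out[slot] = w
        return out


def rank_with_ties(values: dict[str, float], direction: str,
                   metric_id: str = "metric") -> RankTable:
    """Tie-averaged ranks, best first.

    Tied datasets share the mean of the sorted positions they occupy, so
    three datasets tied at positions 3–5 each receive rank 4 and the rank
    sum is always n(n+1)/2.  −inf is a legal best value for lower-better
    metrics; NaN is rejected.
    """
    if not values:
        raise ValidationError("no values to rank")
    ids = sorted(values)
    vals = np.array([values[i] for i in ids], dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("NaN metric value cannot be ranked")
    if direction == HIGHER_BETTER:
        vals = -vals
    elif direction != LOWER_BETTER:
        raise ValueError(f"unknown direction {direction!r}")
    ranks = rankdata(vals, method="average")
    return RankTable(metric_id=metric_id, dataset_ids=ids,
                     ranks={i: float(r) for i, r in zip(ids, ranks)},
                     direction=direction)


def model_rank_scores(table: RankTable,
                      model_map: dict[str, list[str]]) -> dict[str, float]:
    """Per-model mean of its replicate datasets' ranks."""
    assigned = [d for reps in model_map.values() for d in reps]
    if sorted(assigned) != sorted(table.dataset_ids):
        raise ValidationError("model map does not partition the ranked datasets")
    return {m: float(np.mean([table.ranks[d] for d in reps]))
            for m, reps in model_map.items()}


def final_model_scores(scores: dict[str, dict[str, float]],
                       profile: WeightProfile
                       ) -> list[tuple[str, float]]:
    """Weighted sum of rank-derived scores; models ordered best (lowest)
    first with lexicographic tie-break on model id.

    ``scores`` maps ranking-metric id → {model → rank-derived score} and
    must cover all 12 ranking lists.
    """
    weights = profile.per_ranking_metric()
    missing = set(RANKING_METRICS) - set(scores)
    if missing:
        raise ValidationError(f"missing ranking lists {sorted(missing)}")
    models = sorted(scores[RANKING_METRICS[0]])
    for mid in RANKING_METRICS:
        if sorted(scores[mid]) != models:
            raise ValidationError(f"metric {mid!r} missing some models")
    final = {
        m: float(sum(weights[mid] * scores[mid][m] for mid in RANKING_METRICS))
        for m in models
    }
    return sorted(final.items(), key=lambda kv: (kv[1], kv[0]))


def _uniform_profile() -> dict[str, float]:
    return {slot: 1.0 / len(METRIC_SLOTS) for slot in METRIC_SLOTS}


def builtin_weight_profiles() -> dict[str, WeightProfile]:
    """The default and three use-case profiles.

    education emphasizes statistical resemblance and clinical consistency;
    medical_ai emphasizes prediction performance with substantial privacy
    weight; system_dev emphasizes privacy plus data shape/sparsity.
    """
    education = {slot: 0.05 for slot in METRIC_SLOTS}
    education.update({
        "dimension_wise": 0.25,
        "correlation": 0.15,
        "knowledge_violation": 0.15,
        "concept_abundance": 0.10,
    })

    medical_ai = {slot: 0.2 / 6.0 for slot in METRIC_SLOTS}
    medical_ai["model_performance"] = 0.5
    for slot in PRIVACY_SLOTS:
        medical_ai[slot] = 0.3 / 4.0

    system_dev = {slot: 0.04 for slot in METRIC_SLOTS}
    system_dev.update({"dimension_wise": 0.15, "concept_abundance": 0.15})
    for slot in PRIVACY_SLOTS:
        system_dev[slot] = 0.5 / 4.0

    return {
        "default": WeightProfile("default", _uniform_profile()),
        "education": WeightProfile("education", education),
        "medical_ai": WeightProfile("medical_ai", medical_ai),
        "system_dev": WeightProfile("system_dev", system_dev),
    }


def select_top_replicates(candidates: list[PatientMatrix], real: PatientMatrix,
                          keep: int = 3) -> list[PatientMatrix]:
    """Keep the replicates that best preserve the dimension-wise
    distribution of the real data (lowest score first; ties by dataset id).

    This is the generate-five-keep-three filter: datasets that poorly
    capture first-moment feature statistics are dropped before benchmarking.
    """
    if len(candidates) < keep:
        raise ValidationError("fewer candidates than replicates to keep")
    scores = dimension_wise_score(real, candidates)
    order = sorted(candidates, key=lambda c: (scores[c.dataset_id], c.dataset_id))
    return order[:keep]


def risk_category(value: float) -> str:
    """Equal thirds of [0, 1]: low below 1/3, median below 2/3, else high."""
    if not 0.0 <= value <= 1.0:
        raise ValueError("risk value must lie in [0, 1]")
    if value < 1.0 / 3.0:
        return "low"
    if value < 2.0 / 3.0:
        return "median"
    return "high"
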