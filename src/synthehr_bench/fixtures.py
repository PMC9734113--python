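"""Fixture generators: a parametric "real" cohort with known structure, the
marginal-sampling Baseline generator, a deliberately leaky memorizing
generator, and the combined/separated synthesis-paradigm orchestrations.

The parametric cohort emulates structured EHR extracts used for outcome
prediction: a few thousand patients, a few hundred sparse binary concept
columns (diagnoses/medications/procedures), binary gender plus a one-hot
race block, a handful of vitals on a normalized [0, 1] scale, and a rare
binary outcome (~4% positive).  Latent patient classes induce cross-feature
correlation; a small set of gender-exclusive codes (e.g. pregnancy or
prostate phecodes) encodes clinical knowledge the violation metric probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort_io import Feature, FeatureSchema, PatientMatrix, ValidationError

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "ParadigmConfig",
    "default_cohort_spec",
    "generate_cohort",
    "sample_baseline",
    "perturbation_copier",
    "exact_copy",
    "make_copier",
    "synthesize_with_paradigm",
    "BUILTIN_GENERATORS",
]

# A generator procedure maps (training matrix, output size, seed) -> synthetic matrix.
GeneratorFn = Callable[[PatientMatrix, int, int], PatientMatrix]

_VITALS = [
    ("diastolic_pressure", (40.0, 120.0)),
    ("systolic_pressure", (80.0, 200.0)),
    ("pulse", (40.0, 180.0)),
    ("temperature", (35.0, 41.0)),
    ("pulse_oximetry", (70.0, 100.0)),
    ("respirations", (8.0, 40.0)),
    ("body_mass_index", (12.0, 60.0)),
]

_RACES = ["white", "black", "asian", "other", "unknown"]


@dataclass
class OutcomeModel:
    """Logistic outcome on a named feature subset.

    ``intercept=None`` means calibrate per realization so the population
    positive rate hits ``target_rate``.
    """

    coefficients: Mapping[str, float]
    intercept: float | None = None
    target_rate: float = 0.04


@dataclass
class CohortSpec:
    n_records: int
    n_binary_concepts: int
    n_continuous: int
    n_latent_classes: int
    class_mixing: Sequence[float]
    class_prevalence_profiles: np.ndarray  # (K, n_binary_concepts)
    gender_exclusive_codes: Mapping[int, Sequence[str]]  # gender value -> code names
    outcome_model: OutcomeModel
    vitals_means: np.ndarray  # (K, n_continuous), normalized scale
    vitals_sds: np.ndarray  # (K, n_continuous)
    seed: int = 0
    female_rate: float = 0.55
    race_probs: Sequence[float] = (0.65, 0.09, 0.02, 0.04, 0.20)
    n_qid_concepts: int = 4

    def validate(self) -> None:
        mix = np.asarray(self.class_mixing, dtype=float)
        if mix.shape != (self.n_latent_classes,) or not np.isclose(mix.sum(), 1.0):
            raise ValidationError("class mixing proportions must sum to 1")
        prof = np.asarray(self.class_prevalence_profiles, dtype=float)
        if prof.shape != (self.n_latent_classes, self.n_binary_concepts):
            raise ValidationError("profile shape mismatch")
        if prof.min() < 0 or prof.max() > 1:
            raise ValidationError("profile probabilities must lie in [0,1]")
        if not 0.0 < self.outcome_model.target_rate < 1.0:
            raise ValidationError("outcome positive rate must lie in (0,1)")
        if self.n_continuous != self.vitals_means.shape[1]:
            raise ValidationError("vitals parameter shape mismatch")


@dataclass
class GroundTruth:
    """What the generator knows, returned for recovery tests."""

    class_labels: np.ndarray
    class_mixing: np.ndarray
    class_prevalence_profiles: np.ndarray
    informative_features: list[str]
    intercept: float
    positive_rate: float


@dataclass
class ParadigmConfig:
    paradigm: str = "combined"  # {"combined", "separated"}
    n_models: int = 1
    n_keep: int = 1
    n_paradigms: int = 1

    def __post_init__(self) -> None:
        if self.paradigm not in ("combined", "separated"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if min(self.n_models, self.n_keep, self.n_paradigms) < 1:
            raise ValueError("paradigm counts must be >= 1")

    @property
    def n_datasets(self) -> int:
        """Number of synthetic datasets entering every metric ranking list."""
        return self.n_models * self.n_keep * self.n_paradigms


def _concept_name(i: int) -> str:
    return f"code_{i:04d}"


def default_cohort_spec(n_records: int = 2000, n_binary_concepts: int = 200,
                        n_latent_classes: int = 3, seed: int = 0) -> CohortSpec:
    """A class-structured sparse cohort with the study's data shape.

    Concept prevalences are mostly rare (median a few percent), three latent
    classes modulate disjoint concept blocks to create strong cross-feature
    correlation, three codes per gender are gender-exclusive, and the outcome
    is a rare (4%) logistic function of ten concepts plus one vital.
    """
    rng = np.random.default_rng(seed)
    K, D = n_latent_classes, n_binary_concepts
    base = rng.beta(1.2, 18.0, size=D) * 0.6  # sparse marginals, median ~3%
    profiles = np.tile(base, (K, 1))
    # each class enriches its own third of the concept space
    block = D // K
    for k in range(K):
        sl = slice(k * block, (k + 1) * block if k < K - 1 else D)
        profiles[k, sl] = np.clip(profiles[k, sl] * 6.0 + 0.05, 0.0, 0.9)
    names = [_concept_name(i) for i in range(D)]
    # last six codes are gender-exclusive, three per gender, boosted so they
    # are prevalent enough to be picked up
    female_codes = names[D - 6 : D - 3]
    male_codes = names[D - 3 :]
    profiles[:, D - 6 :] = np.clip(profiles[:, D - 6 :] + 0.15, 0.0, 0.9)
    n_inf = min(10, D - 6)
    informative = list(rng.choice(names[: D - 6], size=n_inf, replace=False))
    coefs = {name: float(c) for name, c in
             zip(informative, rng.normal(1.6, 0.4, size=n_inf))}
    coefs["pulse"] = 2.0
    mixing = rng.dirichlet(np.full(K, 8.0))
    vit_means = np.clip(rng.normal(0.5, 0.12, size=(K, len(_VITALS))), 0.1, 0.9)
    vit_sds = np.full((K, len(_VITALS)), 0.08)
    return CohortSpec(
        n_records=n_records,
        n_binary_concepts=D,
        n_continuous=len(_VITALS),
        n_latent_classes=K,
        class_mixing=mixing,
        class_prevalence_profiles=profiles,
        gender_exclusive_codes={1: female_codes, 0: male_codes},
        outcome_model=OutcomeModel(coefficients=coefs),
        vitals_means=vit_means,
        vitals_sds=vit_sds,
        seed=seed,
    )


def _build_schema(spec: CohortSpec, concept_prev: np.ndarray) -> FeatureSchema:
    feats = [Feature("gender_female", "binary", role="gender", qid=True)]
    for r in _RACES:
        feats.append(Feature(f"race_{r}", "binary", role="demographic", qid=True))
    # the most frequent concepts double as phenotypic quasi-identifiers
    exclusive = {c for codes in spec.gender_exclusive_codes.values() for c in codes}
    order = np.argsort(-concept_prev)
    qid_codes = set()
    for i in order:
        name = _concept_name(i)
        if name not in exclusive:
            qid_codes.add(name)
        if len(qid_codes) >= spec.n_qid_concepts:
            break
    for i in range(spec.n_binary_concepts):
        name = _concept_name(i)
        feats.append(Feature(name, "binary", role="concept",
                             qid=name in qid_codes, sensitive=name not in qid_codes))
    for (vname, bounds) in _VITALS[: spec.n_continuous]:
        feats.append(Feature(vname, "continuous", role="concept", sensitive=True,
                             bounds=bounds))
    feats.append(Feature("outcome", "binary", role="outcome"))
    return FeatureSchema(feats)


def generate_cohort(spec: CohortSpec, dataset_id: str = "real"
                    ) -> tuple[PatientMatrix, GroundTruth]:
    """Draw a cohort from the spec; returns the matrix and its ground truth.

    Per record: latent class ~ mixing; binary concepts independent Bernoulli
    given the class profile; vitals per-class truncated normals on [0, 1];
    gender-exclusive codes zeroed in the opposite gender; outcome from a
    logistic model whose intercept is calibrated to the target positive rate.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, K, D = spec.n_records, spec.n_latent_classes, spec.n_binary_concepts
    mixing = np.asarray(spec.class_mixing, dtype=float)
    profiles = np.asarray(spec.class_prevalence_profiles, dtype=float)

    classes = rng.choice(K, size=n, p=mixing)
    gender = (rng.random(n) < spec.female_rate).astype(int)
    race_idx = rng.choice(len(_RACES), size=n, p=np.asarray(spec.race_probs))
    race = np.zeros((n, len(_RACES)), dtype=int)
    race[np.arange(n), race_idx] = 1
    concepts = (rng.random((n, D)) < profiles[classes]).astype(int)

    name_to_col = {_concept_name(i): i for i in range(D)}
    for gval, codes in spec.gender_exclusive_codes.items():
        mask = gender != gval
        for code in codes:
            concepts[mask, name_to_col[code]] = 0

    C = spec.n_continuous
    vit_mu = spec.vitals_means[classes]
    vit_sd = spec.vitals_sds[classes]
    a, b = (0.0 - vit_mu) / vit_sd, (1.0 - vit_mu) / vit_sd
    vitals = truncnorm.rvs(a, b, loc=vit_mu, scale=vit_sd,
                           size=(n, C), random_state=rng)

    om = spec.outcome_model
    lp = np.zeros(n)
    vital_names = [v[0] for v in _VITALS[:C]]
    for fname, coef in om.coefficients.items():
        if fname in name_to_col:
            lp += coef * concepts[:, name_to_col[fname]]
        elif fname in vital_names:
            lp += coef * vitals[:, vital_names.index(fname)]
        else:
            raise ValidationError(f"outcome coefficient on unknown feature {fname!r}")
    if om.intercept is None:
        lo, hi = -60.0, 60.0
        if not (expit(lp + lo).mean() < om.target_rate < expit(lp + hi).mean()):
            raise ValidationError("requested outcome positive rate is infeasible")
        intercept = brentq(lambda b0: expit(lp + b0).mean() - om.target_rate, lo, hi)
    else:
        intercept = om.intercept
    p_out = expit(lp + intercept)
    outcome = (rng.random(n) < p_out).astype(int)

    schema = _build_schema(spec, concepts.mean(axis=0))
    df = pd.DataFrame(
        np.column_stack([gender, race, concepts, vitals, outcome]),
        columns=schema.names,
    )
    for name in schema.binary_names:
        df[name] = df[name].astype(int)
    matrix = PatientMatrix(schema=schema, values=df, dataset_id=dataset_id,
                           normalized=True)
    truth = GroundTruth(
        class_labels=classes,
        class_mixing=mixing,
        class_prevalence_profiles=profiles,
        informative_features=list(om.coefficients),
        intercept=float(intercept),
        positive_rate=float(outcome.mean()),
    )
    return matrix, truth


def _demographic_block(schema: FeatureSchema) -> list[str]:
    return schema.names_where(kind="binary", role="demographic")


def sample_baseline(train: PatientMatrix, n_out: int, seed: int = 0,
                    dataset_id: str = "baseline") -> PatientMatrix:
    """The sampling Baseline: independent draws from the training marginals.

    Binary columns are coin flips at the training prevalence; continuous
    columns are resampled from the training column's empirical values.  The
    one-hot demographic block (race) is resampled jointly, i.e. as a
    categorical draw from its empirical distribution, so one-hot validity is
    preserved; all other columns are mutually independent.
    """
    if n_out < 1:
        raise ValidationError("n_out must be >= 1")
    rng = np.random.default_rng(seed)
    schema = train.schema
    block = _demographic_block(schema)
    block_rows = None
    if block:
        rows = train.values.loc[:, block].to_numpy(dtype=int)
        block_rows = rows[rng.integers(0, len(rows), size=n_out)]
    cols = {}
    bi = 0
    for feat in schema:
        if feat.name in block:
            cols[feat.name] = block_rows[:, bi]
            bi += 1
        elif feat.kind == "binary":
            p = train.values[feat.name].mean()
            cols[feat.name] = (rng.random(n_out) < p).astype(int)
        else:
            col = train.values[feat.name].to_numpy(dtype=float)
            cols[feat.name] = col[rng.integers(0, len(col), size=n_out)]
    df = pd.DataFrame(cols)
    return PatientMatrix(schema=schema, values=df, dataset_id=dataset_id,
                         normalized=train.normalized)


def perturbation_copier(train: PatientMatrix, copy_fraction: float = 1.0,
                        flip_rate: float = 0.0, seed: int = 0,
                        n_out: int | None = None,
                        dataset_id: str = "copier") -> PatientMatrix:
    """A leaky generator: near-copies of training records plus baseline fill.

    ``copy_fraction`` of the output rows are sampled training records with
    each binary value flipped with probability ``flip_rate`` and continuous
    values jittered uniformly by ±``flip_rate`` on the normalized scale; the
    remaining rows come from :func:`sample_baseline`.  An overfit generator
    the privacy metrics must flag.
    """
    if not (0.0 <= copy_fraction <= 1.0 and 0.0 <= flip_rate <= 1.0):
        raise ValidationError("copy_fraction and flip_rate must lie in [0,1]")
    if n_out is None:
        n_out = train.n_records
    seq = np.random.SeedSequence([int(seed), 0x9E37])
    rng = np.random.default_rng(seq)
    n_copy = int(round(copy_fraction * n_out))
    parts = []
    if n_copy:
        if n_copy <= train.n_records:
            idx = rng.permutation(train.n_records)[:n_copy]
        else:
            idx = rng.integers(0, train.n_records, size=n_copy)
        part = train.values.iloc[idx].reset_index(drop=True).copy()
        if flip_rate > 0:
            for name in train.schema.binary_names:
                flips = rng.random(n_copy) < flip_rate
                part[name] = np.where(flips, 1 - part[name], part[name])
            for name in train.schema.continuous_names:
                jitter = rng.uniform(-flip_rate, flip_rate, size=n_copy)
                part[name] = np.clip(part[name].to_numpy(dtype=float) + jitter,
                                     0.0, 1.0)
        parts.append(part)
    if n_out - n_copy:
        fill = sample_baseline(train, n_out - n_copy,
                               seed=int(rng.integers(0, 2**31)))
        parts.append(fill.values)
    df = pd.concat(parts, ignore_index=True)
    return PatientMatrix(schema=train.schema, values=df, dataset_id=dataset_id,
                         normalized=train.normalized)


def exact_copy(train: PatientMatrix, n_out: int, seed: int = 0,
               dataset_id: str = "copy") -> PatientMatrix:
    """Row-sample the training data verbatim (a worst-case memorizer)."""
    rng = np.random.default_rng(seed)
    if n_out <= train.n_records:
        idx = rng.permutation(train.n_records)[:n_out]
    else:
        idx = rng.integers(0, train.n_records, size=n_out)
    return PatientMatrix(schema=train.schema,
                         values=train.values.iloc[idx].reset_index(drop=True),
                         dataset_id=dataset_id, normalized=train.normalized)


def make_copier(copy_fraction: float, flip_rate: float) -> GeneratorFn:
    def gen(train: PatientMatrix, n_out: int, seed: int) -> PatientMatrix:
        return perturbation_copier(train, copy_fraction=copy_fraction,
                                   flip_rate=flip_rate, seed=seed, n_out=n_out)
    return gen


def _baseline_gen(train: PatientMatrix, n_out: int, seed: int) -> PatientMatrix:
    return sample_baseline(train, n_out, seed=seed)


BUILTIN_GENERATORS: dict[str, GeneratorFn] = {
    "baseline": _baseline_gen,
    "memorizer": make_copier(1.0, 0.0),
    "copier_light": make_copier(1.0, 0.05),
    "copier_noisy": make_copier(1.0, 0.20),
    "copier_half": make_copier(0.5, 0.05),
    "exact_copy": exact_copy,
}


def synthesize_with_paradigm(generator: GeneratorFn, train: PatientMatrix,
                             paradigm: str = "combined", seed: int = 0,
                             dataset_id: str | None = None) -> PatientMatrix:
    """Run a generator under the combined or separated synthesis paradigm.

    combined: one generator pass over all features including the outcome.
    separated: one pass per outcome stratum with the stratum's exact real
    size, outputs concatenated — the synthetic outcome distribution equals
    the real one by construction.
    """
    out_name = train.schema.outcome_name
    if paradigm == "combined":
        result = generator(train, train.n_records, seed)
    elif paradigm == "separated":
        seq = np.random.SeedSequence([int(seed), 0x5E9A])
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(2)]
        parts = []
        for j, val in enumerate((0, 1)):
            stratum = train.values[train.values[out_name] == val]
            if len(stratum) == 0:
                raise ValidationError(
                    f"separated paradigm: outcome stratum {val} is empty"
                )
            sub = train.replace_values(stratum, dataset_id=f"{train.dataset_id}_y{val}")
            piece = generator(sub, len(stratum), child_seeds[j])
            vals = piece.values.copy()
            vals[out_name] = val
            parts.append(vals)
        df = pd.concat(parts, ignore_index=True)
        result = PatientMatrix(schema=train.schema, values=df,
                               dataset_id="separated", normalized=train.normalized)
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    if dataset_id is not None:
        result.dataset_id = dataset_id
    return result
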