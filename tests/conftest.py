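"""Shared fixtures: tiny hand-checkable matrices plus a seeded class-structured
cohort with its train/eval split and generator outputs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import synthehr_bench as sb
from synthehr_bench.cohort_io import Feature, FeatureSchema, PatientMatrix


def make_pm(columns: dict[str, list], kinds: dict[str, str] | None = None,
            roles: dict[str, str] | None = None,
            qids: set[str] | None = None, sensitive: set[str] | None = None,
            outcome: str | None = None, dataset_id: str = "toy",
            normalized: bool = True) -> PatientMatrix:
    """Build a small matrix; the outcome column is appended as zeros unless a
    supplied column is named."""
    kinds = kinds or {}
    roles = roles or {}
    qids = qids or set()
    sensitive = sensitive or set()
    data = {k: list(v) for k, v in columns.items()}
    if outcome is None:
        outcome = "outcome"
        n = len(next(iter(data.values())))
        data[outcome] = [0] * (n - 1) + [1] if n else []
    feats = []
    for name in data:
        feats.append(Feature(
            name=name,
            kind=kinds.get(name, "binary"),
            role="outcome" if name == outcome else roles.get(name, "concept"),
            qid=name in qids,
            sensitive=name in sensitive,
        ))
    return PatientMatrix(schema=FeatureSchema(feats), values=pd.DataFrame(data),
                         dataset_id=dataset_id, normalized=normalized)


@pytest.fixture(scope="session")
def cohort():
    spec = sb.default_cohort_spec(n_records=600, n_binary_concepts=60, seed=1)
    matrix, truth = sb.generate_cohort(spec)
    return matrix, truth


@pytest.fixture(scope="session")
def split(cohort):
    matrix, _ = cohort
    return sb.split_train_eval(matrix, 0.7, seed=2)


@pytest.fixture(scope="session")
def train(split):
    return split[0]


@pytest.fixture(scope="session")
def eval_set(split):
    return split[1]


@pytest.fixture(scope="session")
def baseline(train):
    return sb.sample_baseline(train, train.n_records, seed=3, dataset_id="baseline")


@pytest.fixture(scope="session")
def memorizer(train):
    return sb.perturbation_copier(train, copy_fraction=1.0, flip_rate=0.0,
                                  seed=3, dataset_id="memorizer")


@pytest.fixture(scope="session")
def attack_cfg(train):
    return sb.AttackConfig(known_attributes=train.schema.qid_names,
                           nnaa_repeats=3, lambda_override=1.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
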