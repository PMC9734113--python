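"""Patient-level cohort matrices: schema, validation, I/O, normalization, splitting.

A cohort is a rectangular records-by-features table.  Binary columns encode
presence/absence of medical concepts (phecodes, procedure categories,
medication ingredients) or demographic indicators (gender, one-hot race);
continuous columns are vitals/labs, stored either on their original scale or
min-max normalized to [0, 1].  Exactly one binary column is the prediction
outcome.  The schema carries per-feature kind/role plus the quasi-identifier
and sensitive flags that drive privacy-attack applicability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Feature",
    "FeatureSchema",
    "PatientMatrix",
    "DatasetBundle",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "normalize_continuous",
    "denormalize_continuous",
    "split_train_eval",
]

KINDS = ("binary", "continuous")
ROLES = ("concept", "demographic", "outcome", "gender")


class SchemaError(ValueError):
    """Schema is malformed or inconsistent with the data it describes."""


class ValidationError(ValueError):
    """Matrix values violate the schema's invariants."""


@dataclass(frozen=True)
class Feature:
    """One column: its kind, role, privacy flags and (continuous) bounds."""

    name: str
    kind: str
    role: str = "concept"
    qid: bool = False
    sensitive: bool = False
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for feature {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for feature {self.name!r}")
        if self.qid and self.sensitive:
            raise SchemaError(
                f"feature {self.name!r} flagged both quasi-identifier and sensitive"
            )
        if self.bounds is not None:
            lo, hi = self.bounds
            if not lo < hi:
                raise SchemaError(f"degenerate bounds {self.bounds} for {self.name!r}")


class FeatureSchema:
    """An ordered collection of :class:`Feature` with uniqueness checks.

    Invariants enforced at construction: unique names, exactly one binary
    outcome, at most one gender feature.
    """

    def __init__(self, features: Sequence[Feature]):
        names = [f.name for f in features]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names")
        outcomes = [f for f in features if f.role == "outcome"]
        if len(outcomes) != 1:
            raise SchemaError(f"need exactly one outcome feature, got {len(outcomes)}")
        if outcomes[0].kind != "binary":
            raise SchemaError("outcome feature must be binary")
        if sum(f.role == "gender" for f in features) > 1:
            raise SchemaError("at most one gender feature")
        self.features: tuple[Feature, ...] = tuple(features)
        self._by_name = {f.name: f for f in self.features}

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, name: str) -> Feature:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureSchema) and self.features == other.features

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def names_where(self, **flags) -> list[str]:
        out = []
        for f in self.features:
            if all(getattr(f, k) == v for k, v in flags.items()):
                out.append(f.name)
        return out

    @property
    def binary_names(self) -> list[str]:
        return self.names_where(kind="binary")

    @property
    def continuous_names(self) -> list[str]:
        return self.names_where(kind="continuous")

    @property
    def concept_names(self) -> list[str]:
        return self.names_where(role="concept", kind="binary")

    @property
    def outcome_name(self) -> str:
        return self.names_where(role="outcome")[0]

    @property
    def gender_name(self) -> str | None:
        names = self.names_where(role="gender")
        return names[0] if names else None

    @property
    def qid_names(self) -> list[str]:
        return self.names_where(qid=True)

    @property
    def sensitive_names(self) -> list[str]:
        return self.names_where(sensitive=True)

    def with_bounds(self, bounds: dict[str, tuple[float, float]]) -> "FeatureSchema":
        feats = [
            replace(f, bounds=tuple(bounds[f.name])) if f.name in bounds else f
            for f in self.features
        ]
        return FeatureSchema(feats)

    def to_json(self) -> list[dict]:
        out = []
        for f in self.features:
            d = {"name": f.name, "kind": f.kind, "role": f.role,
                 "qid": f.qid, "sensitive": f.sensitive}
            if f.bounds is not None:
                d["bounds"] = list(f.bounds)
            out.append(d)
        return out

    @classmethod
    def from_json(cls, obj: Iterable[dict]) -> "FeatureSchema":
        feats = []
        for d in obj:
            feats.append(
                Feature(
                    name=d["name"],
                    kind=d["kind"],
                    role=d.get("role", "concept"),
                    qid=bool(d.get("qid", False)),
                    sensitive=bool(d.get("sensitive", False)),
                    bounds=tuple(d["bounds"]) if d.get("bounds") else None,
                )
            )
        return cls(feats)


@dataclass
class PatientMatrix:
    """A validated records-by-features table with its schema.

    ``values`` is a pandas DataFrame whose columns follow schema order.
    Row order carries no identity: a synthetic record is never linked to a
    real record by index.
    """

    schema: FeatureSchema
    values: pd.DataFrame
    dataset_id: str = "cohort"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = self.values.loc[:, self.schema.names].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.values
        if list(df.columns) != self.schema.names:
            raise SchemaError("matrix columns do not match schema")
        if len(df) < 1:
            raise ValidationError("matrix must contain at least one record")
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise ValidationError(f"missing values in columns {bad}; no imputation")
        for name in self.schema.binary_names:
            col = df[name].to_numpy()
            if not np.isin(col, (0, 1)).all():
                raise ValidationError(f"binary column {name!r} has values outside {{0,1}}")
        if self.normalized:
            for name in self.schema.continuous_names:
                col = df[name].to_numpy(dtype=float)
                if col.min() < -1e-12 or col.max() > 1 + 1e-12:
                    raise ValidationError(
                        f"normalized continuous column {name!r} outside [0,1]"
                    )

    @property
    def n_records(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return len(self.schema)

    def array(self, columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.schema.names
        return self.values.loc[:, cols].to_numpy(dtype=float)

    def replace_values(self, df: pd.DataFrame, dataset_id: str | None = None,
                       normalized: bool | None = None) -> "PatientMatrix":
        return PatientMatrix(
            schema=self.schema,
            values=df,
            dataset_id=self.dataset_id if dataset_id is None else dataset_id,
            normalized=self.normalized if normalized is None else normalized,
        )


@dataclass
class DatasetBundle:
    """Real train/eval split plus per-model synthetic replicates."""

    real_train: PatientMatrix
    real_eval: PatientMatrix
    candidates: dict[str, list[PatientMatrix]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        schema = self.real_train.schema
        if self.real_eval.schema != schema:
            raise SchemaError("real train/eval schemas differ")
        for model_id, reps in self.candidates.items():
            if len(reps) < 1:
                raise ValidationError(f"model {model_id!r} has no replicates")
            for rep in reps:
                if rep.schema != schema:
                    raise SchemaError(f"replicate of {model_id!r} has mismatched schema")

    @property
    def model_ids(self) -> list[str]:
        return sorted(self.candidates)


def read_cohort(matrix_path: str | Path, schema_path: str | Path,
                dataset_id: str | None = None) -> PatientMatrix:
    """Read a header-bearing CSV matrix and its JSON schema sidecar."""
    schema = FeatureSchema.from_json(json.loads(Path(schema_path).read_text()))
    df = pd.read_csv(matrix_path, float_precision="round_trip")
    if list(df.columns) != schema.names:
        raise SchemaError(
            "CSV header does not match schema: "
            f"{list(df.columns)[:5]}... vs {schema.names[:5]}..."
        )
    if dataset_id is None:
        dataset_id = Path(matrix_path).stem
    # Normalized state is recoverable: continuous columns inside [0,1] with
    # recorded bounds outside that range were written normalized.
    meta_path = Path(str(matrix_path) + ".meta.json")
    normalized = False
    if meta_path.exists():
        normalized = bool(json.loads(meta_path.read_text()).get("normalized", False))
    return PatientMatrix(schema=schema, values=df, dataset_id=dataset_id,
                         normalized=normalized)


def write_cohort(m: PatientMatrix, matrix_path: str | Path,
                 schema_path: str | Path) -> None:
    """Write CSV + JSON schema sidecar; repeated writes are byte-identical."""
    matrix_path, schema_path = Path(matrix_path), Path(schema_path)
    df = m.values.copy()
    for name in m.schema.binary_names:
        df[name] = df[name].astype(int)
    # %.17g round-trips any double exactly and is byte-stable across writes
    df.to_csv(matrix_path, index=False, lineterminator="\n",
              float_format="%.17g")
    schema_path.write_text(json.dumps(m.schema.to_json(), indent=1) + "\n")
    meta = {"dataset_id": m.dataset_id, "normalized": m.normalized}
    Path(str(matrix_path) + ".meta.json").write_text(
        json.dumps(meta, sort_keys=True) + "\n"
    )


def normalize_continuous(m: PatientMatrix) -> PatientMatrix:
    """Min-max map each continuous column into [0, 1].

    Schema bounds take precedence; otherwise the observed min/max are used
    and recorded back into the returned matrix's schema so that
    :func:`denormalize_continuous` inverts exactly.  A constant column with
    no schema bounds has no recoverable scale and is rejected.
    """
    if m.normalized:
        raise ValidationError("matrix is already normalized")
    df = m.values.copy()
    new_bounds: dict[str, tuple[float, float]] = {}
    for name in m.schema.continuous_names:
        feat = m.schema[name]
        col = df[name].to_numpy(dtype=float)
        if feat.bounds is not None:
            lo, hi = feat.bounds
        else:
            lo, hi = float(col.min()), float(col.max())
            if lo == hi:
                raise ValidationError(
                    f"constant continuous column {name!r} without schema bounds"
                )
            new_bounds[name] = (lo, hi)
        df[name] = np.clip((col - lo) / (hi - lo), 0.0, 1.0)
    schema = m.schema.with_bounds(new_bounds) if new_bounds else m.schema
    return PatientMatrix(schema=schema, values=df, dataset_id=m.dataset_id,
                         normalized=True)


def denormalize_continuous(m: PatientMatrix) -> PatientMatrix:
    """Invert :func:`normalize_continuous` using the recorded schema bounds."""
    if not m.normalized:
        raise ValidationError("matrix is not normalized")
    df = m.values.copy()
    for name in m.schema.continuous_names:
        feat = m.schema[name]
        if feat.bounds is None:
            raise SchemaError(f"no recorded bounds for continuous column {name!r}")
        lo, hi = feat.bounds
        df[name] = df[name].to_numpy(dtype=float) * (hi - lo) + lo
    return PatientMatrix(schema=m.schema, values=df, dataset_id=m.dataset_id,
                         normalized=False)


def split_train_eval(m: PatientMatrix, train_fraction: float = 0.7,
                     seed: int = 0, stratify: bool = False
                     ) -> tuple[PatientMatrix, PatientMatrix]:
    """Seeded disjoint-and-exhaustive split into (train, eval).

    Train size is ``floor(train_fraction * N)``; the remainder goes to eval.
    With ``stratify=True`` the outcome rate is preserved across the two parts
    (per-stratum floor split, remainder records assigned to keep global
    train size exact).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = m.n_records
    if n < 2:
        raise ValidationError("need at least 2 records to split")
    n_train = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(seed)
    if stratify:
        y = m.values[m.schema.outcome_name].to_numpy()
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        rng.shuffle(pos)
        rng.shuffle(neg)
        n_pos_train = int(np.floor(train_fraction * len(pos)))
        n_neg_train = n_train - n_pos_train
        train_idx = np.concatenate([pos[:n_pos_train], neg[:n_neg_train]])
        eval_idx = np.concatenate([pos[n_pos_train:], neg[n_neg_train:]])
    else:
        perm = rng.permutation(n)
        train_idx, eval_idx = perm[:n_train], perm[n_train:]
    train_idx, eval_idx = np.sort(train_idx), np.sort(eval_idx)
    tr = m.replace_values(m.values.iloc[train_idx], dataset_id=m.dataset_id + "_train")
    ev = m.replace_values(m.values.iloc[eval_idx], dataset_id=m.dataset_id + "_eval")
    return tr, ev
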