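"""Feature-matrix container shared by the stats and biometrics modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .features import FEATURE_NAMES

__all__ = ["FeatureDataset"]


@dataclass
class FeatureDataset:
    """n subjects x b trials x F features, one row per blink.

    Every subject must contribute the same number of trials ``b`` and no
    value may be missing; this balanced layout is what the per-subject
    statistics and the stratified cross-validation assume.
    """

    X: np.ndarray = field(repr=False)
    subjects: np.ndarray = field(repr=False)
    trials: np.ndarray = field(repr=False)
    feature_names: list = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.subjects = np.asarray(self.subjects)
        self.trials = np.asarray(self.trials)
        if self.X.ndim != 2:
            raise InvalidInputError("feature matrix must be 2-D")
        if len(self.subjects) != self.X.shape[0] or len(self.trials) != self.X.shape[0]:
            raise InvalidInputError("labels must match the number of rows")
        if self.X.shape[1] != len(self.feature_names):
            raise InvalidInputError(
                f"matrix has {self.X.shape[1]} columns but "
                f"{len(self.feature_names)} feature names"
            )
        if np.isnan(self.X).any():
            raise InvalidInputError("feature matrix contains missing values")
        _, counts = np.unique(self.subjects, return_counts=True)
        if len(counts) and counts.min() != counts.max():
            raise InvalidInputError(
                "every subject must have the same number of trials "
                f"(got {counts.min()}..{counts.max()})"
            )

    @property
    def B(self) -> int:
        return self.X.shape[0]

    @property
    def F(self) -> int:
        return self.X.shape[1]

    @property
    def subject_labels(self) -> np.ndarray:
        return np.unique(self.subjects)

    @property
    def n(self) -> int:
        return len(self.subject_labels)

    @property
    def b(self) -> int:
        return self.B // max(self.n, 1)

    def rows_of(self, subject) -> np.ndarray:
        return np.flatnonzero(self.subjects == subject)

    @classmethod
    def from_vectors(cls, vectors) -> "FeatureDataset":
        if not vectors:
            raise InvalidInputError("no feature vectors supplied")
        X = np.vstack([v.values for v in vectors])
        return cls(
            X=X,
            subjects=np.array([v.subject_id for v in vectors]),
            trials=np.array([v.trial_id for v in vectors]),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "trial", self.trials)
        df.insert(0, "subject", self.subjects)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "FeatureDataset":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in ("subject", "trial"):
            if col not in df.columns:
                raise InvalidInputError(f"feature CSV missing column '{col}'")
        names = [c for c in df.columns if c not in ("subject", "trial")]
        return cls(
            X=df[names].to_numpy(float),
            subjects=df["subject"].astype(str).to_numpy(),
            trials=df["trial"].astype(str).to_numpy(),
            feature_names=names,
        )
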