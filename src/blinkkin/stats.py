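"""Summary statistics, coefficient-of-variation screening and feature discard.

Per-feature mean and sample standard deviation are taken over all B = n * b
blinks.  The coefficient of variation (CV = std / mean) measures a feature's
discriminative potential: a feature whose CV is near zero both within and
across subjects (in the study, the three normalized magnitudes that sit at
their ceiling of 1 in ~96% of blinks) carries no identity information and is
discarded before classification.  Boxplot normalization expresses each value
as a fractional deviation from the feature mean,
M'_{j,k}(f) = (M_{j,k}(f) - mean(f)) / mean(f).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureDataset
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "FeatureSummary",
    "summarize",
    "discard_low_cv",
    "DEFAULT_DISCARD",
]

#: 1-based canonical indices of the near-constant normalized magnitudes
#: |P̂(t3P)|, |â(t2a)| and |v̂(t2P)|.
DEFAULT_DISCARD = (10, 21, 26)


def _tukey_quartiles(x: np.ndarray) -> tuple:
    """Quartiles by the inclusive median-of-halves (Tukey hinge) convention."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    med = float(np.median(x))
    half = (n + 1) // 2  # include the median point in both halves when n odd
    q1 = float(np.median(x[:half]))
    q3 = float(np.median(x[n - half:]))
    return q1, med, q3


@dataclass
class FeatureSummary:
    """Per-feature summary: mean, std, CVs, normalized matrix, quartiles."""

    mean: np.ndarray
    std: np.ndarray
    cv_overall: np.ndarray
    cv_by_subject: pd.DataFrame = field(repr=False)
    normalized: np.ndarray = field(repr=False)
    quartiles: pd.DataFrame = field(repr=False)
    feature_names: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "mean": self.mean,
                "std": self.std,
                "cv": self.cv_overall,
            }
        )


def _safe_cv(std: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """std/mean with an undefined marker (NaN) where the mean is zero."""
    cv = np.full_like(std, np.nan)
    nz = mean != 0
    cv[nz] = std[nz] / np.abs(mean[nz])
    return cv


def summarize(ds: FeatureDataset) -> FeatureSummary:
    """Mean, sample std (B-1 denominator), overall and per-subject CV,
    mean-normalized matrix M', and Tukey quartiles of M' per feature."""
    if ds.B < 2:
        raise InvalidInputError("need at least 2 rows to summarize")
    mean = ds.X.mean(axis=0)
    std = ds.X.std(axis=0, ddof=1)
    cv_overall = _safe_cv(std, mean)

    rows = {}
    for subj in ds.subject_labels:
        Xs = ds.X[ds.rows_of(subj)]
        if Xs.shape[0] < 2:
            raise InvalidInputError(f"subject {subj} has fewer than 2 trials")
        rows[subj] = _safe_cv(Xs.std(axis=0, ddof=1), Xs.mean(axis=0))
    cv_by_subject = pd.DataFrame.from_dict(
        rows, orient="index", columns=ds.feature_names
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(mean != 0, (ds.X - mean) / mean, np.nan)
    quart = pd.DataFrame(
        [_tukey_quartiles(normalized[:, f]) for f in range(ds.F)],
        columns=["q1", "median", "q3"],
        index=ds.feature_names,
    )
    return FeatureSummary(
        mean=mean,
        std=std,
        cv_overall=cv_overall,
        cv_by_subject=cv_by_subject,
        normalized=normalized,
        quartiles=quart,
        feature_names=list(ds.feature_names),
    )


def discard_low_cv(
    ds: FeatureDataset, indices=DEFAULT_DISCARD
) -> tuple:
    """Drop low-variability features by 1-based canonical index.

    Returns ``(reduced_dataset, index_map)`` where ``index_map`` maps each
    surviving old 1-based index to its new 1-based position (canonical order
    is preserved).  The defaults remove the three near-ceiling normalized
    magnitudes, reducing 29 features to 26.
    """
    indices = list(indices)
    if len(set(indices)) != len(indices):
        raise InvalidParameterError(f"duplicate discard indices: {indices}")
    for i in indices:
        if not 1 <= i <= ds.F:
            raise InvalidParameterError(
                f"discard index {i} outside 1..{ds.F}"
            )
    keep = [f for f in range(ds.F) if (f + 1) not in indices]
    index_map = {old + 1: new + 1 for new, old in enumerate(keep)}
    reduced = FeatureDataset(
        X=ds.X[:, keep],
        subjects=ds.subjects.copy(),
        trials=ds.trials.copy(),
        feature_names=[ds.feature_names[f] for f in keep],
    )
    return reduced, index_map
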