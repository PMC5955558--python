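"""Train-set-fitted feature scaling.

Classifier performance degrades badly when features span several orders of
magnitude (intensity vs. shape features), so tables are rescaled before
filtering and classification.  The transform parameters are always
estimated on the training data only and then applied unchanged to any
later data (validation folds, test sets, unlabeled kinetics tables) —
fitting them on anything else would leak information into evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feature_table import FeatureTable

__all__ = ["ScalingParams", "fit_scaler", "apply_scaler"]

_MODES = ("standardize", "normalize", "none")


@dataclass
class ScalingParams:
    """Per-feature affine transform ``(x - location) / scale``.

    ``standardize`` uses mean and sample standard deviation (ddof=1);
    ``normalize`` uses minimum and range; ``none`` is the identity.
    Features constant on the training data are flagged and given scale 1,
    so they map to 0 wherever the query value equals the training value.
    """

    mode: str
    feature_names: list[str]
    location: np.ndarray
    scale: np.ndarray
    constant: np.ndarray

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "feature_names": list(self.feature_names),
            "location": self.location.tolist(),
            "scale": self.scale.tolist(),
            "constant": self.constant.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(
            mode=d["mode"],
            feature_names=list(d["feature_names"]),
            location=np.asarray(d["location"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            constant=np.asarray(d["constant"], dtype=bool),
        )


def fit_scaler(train: FeatureTable, mode: str = "standardize") -> ScalingParams:
    """Estimate scaling parameters from a training table.

    Requires at least two rows (one row has no spread to estimate).
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    if train.m < 2:
        raise ValueError("need >= 2 rows to fit a scaler")
    X = train.values
    n = train.n
    if mode == "standardize":
        location = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
    elif mode == "normalize":
        location = X.min(axis=0)
        scale = X.max(axis=0) - location
    else:
        location = np.zeros(n)
        scale = np.ones(n)
    constant = scale <= 0
    scale = np.where(constant, 1.0, scale)
    return ScalingParams(
        mode=mode,
        feature_names=list(train.feature_names),
        location=np.asarray(location, dtype=float),
        scale=np.asarray(scale, dtype=float),
        constant=constant,
    )


def apply_scaler(table: FeatureTable, params: ScalingParams) -> FeatureTable:
    """Apply fitted scaling to a table with the same feature schema.

    Values outside the training range are deliberately not clipped under
    ``normalize`` (clipping would distort distances for KNN/SVM), so
    transformed values may fall outside [0, 1].
    """
    if list(table.feature_names) != list(params.feature_names):
        raise ValueError("feature names do not match the scaler's fitting table")
    X = (table.values - params.location) / params.scale
    return FeatureTable(
        values=X,
        feature_names=list(table.feature_names),
        sample_ids=list(table.sample_ids) if table.sample_ids else None,
        labels=table.labels.copy() if table.labels is not None else None,
        class_names=list(table.class_names),
    )
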