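"""Model scoring: q², external r², and acceptance rules.

q² is the correlation coefficient 1 - SSE/SST computed on the fitted set:
1 at a perfect fit, 0 for the mean predictor, negative when the model is
worse than predicting the mean. r² is the squared Pearson correlation
between observed and predicted activities on the external test set — the
standard external-validation statistic in QSAR. The two are deliberately
different: r² is blind to systematic bias (affine-invariant), q² is not,
and no ordering between them is assumed anywhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ValidationError


@dataclass
class ModelReport:
    """Summary of one trained model for acceptance and audit."""

    q2_train: float
    q2_test: float
    r2_test: float
    n_train: int
    n_test: int
    descriptors: list[str] = field(default_factory=list)
    stopping_epoch: int = 0
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        return (
            f"q2_train={self.q2_train:.4f} q2_test={self.q2_test:.4f} "
            f"r2_test={self.r2_test:.4f} n_train={self.n_train} "
            f"n_test={self.n_test} stop_epoch={self.stopping_epoch}"
        )


def q_squared(y, h) -> float:
    """q² = 1 - sum((h - y)²) / sum((y - mean(y))²). May be negative."""
    y = np.asarray(y, dtype=float)
    h = np.asarray(h, dtype=float)
    if y.shape != h.shape:
        raise ValidationError("observed and predicted must have equal length")
    if len(y) < 2:
        raise ValidationError("need at least 2 observations")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise ValidationError("constant activities: q2 undefined")
    return float(1.0 - np.sum((h - y) ** 2) / sst)


def r_squared(y, h, mode: str = "pearson", y_train_mean: float | None = None) -> float:
    """External r².

    ``mode="pearson"`` (default): squared Pearson correlation between y and
    h, in [0, 1]; a constant h degenerates to 0 with a warning.
    ``mode="about_train_mean"``: coefficient of determination about the
    training-set activity mean (requires ``y_train_mean``) — an alternative
    external-validation convention.
    """
    y = np.asarray(y, dtype=float)
    h = np.asarray(h, dtype=float)
    if y.shape != h.shape:
        raise ValidationError("observed and predicted must have equal length")
    if len(y) < 3:
        raise ValidationError("need at least 3 observations")
    if np.var(y) == 0:
        raise ValidationError("constant activities: r2 undefined")
    if mode == "about_train_mean":
        if y_train_mean is None:
            raise ValidationError("about_train_mean mode requires y_train_mean")
        denom = float(np.sum((y - y_train_mean) ** 2))
        if denom <= 0:
            raise ValidationError("degenerate denominator")
        return float(1.0 - np.sum((h - y) ** 2) / denom)
    if mode != "pearson":
        raise ValidationError(f"unknown r2 mode {mode!r}")
    if np.var(h) == 0:
        warnings.warn("constant predictions: r2 degenerates to 0")
        return 0.0
    r = np.corrcoef(y, h)[0, 1]
    return float(r * r)


def accept_model(
    report: ModelReport,
    q2_threshold: float = 0.60,
    r2_threshold: float = 0.55,
) -> bool:
    """A model is acceptable iff q2_train >= q2_threshold and
    r2_test >= r2_threshold (both inclusive)."""
    return report.q2_train >= q2_threshold and report.r2_test >= r2_threshold
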