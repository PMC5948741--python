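"""Validation statistics for estimated-versus-actual trait values.

Estimates are validated by ordinary least squares of the estimated
values on the actual (ground-truth) values — actual on the x axis —
together with Pearson's r, RMSE in the trait's units, and percentage
errors.  Because deviations can be systematically signed (a model that
under-reconstructs leaf tips under-estimates area), both the signed mean
percentage error (MPE) and the mean absolute percentage error (MAPE) are
reported and labelled distinctly.  p-values of the regression are
descriptive output with a significance flag at p < 0.01; no
multiple-testing correction is applied across traits or species.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, InputError

__all__ = [
    "PairedSample",
    "ValidationReport",
    "pearson_r",
    "linear_fit",
    "rmse",
    "percentage_errors",
    "validation_report",
]


@dataclass
class PairedSample:
    """Actual (ground truth) and estimated trait values, same units."""

    actual: np.ndarray
    estimated: np.ndarray
    labels: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.actual = np.asarray(self.actual, dtype=np.float64).ravel()
        self.estimated = np.asarray(self.estimated, dtype=np.float64).ravel()
        if len(self.actual) != len(self.estimated):
            raise InputError("actual and estimated must have equal length")
        if self.labels is not None and len(self.labels) != len(self.actual):
            raise InputError("labels must match the number of pairs")

    def __len__(self) -> int:
        return len(self.actual)


@dataclass
class ValidationReport:
    """Summary statistics of one estimated-versus-actual comparison."""

    n: int
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    rmse: float
    mpe_pct: float
    mape_pct: float
    p_value: float
    significant_p01: bool

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        return cls(**json.loads(text))


def _as_pairs(pairs) -> PairedSample:
    if isinstance(pairs, PairedSample):
        return pairs
    actual, estimated = pairs
    return PairedSample(np.asarray(actual), np.asarray(estimated))


def pearson_r(pairs) -> float:
    """Product-moment correlation between estimated and actual values."""
    p = _as_pairs(pairs)
    if len(p) < 2:
        raise InputError("correlation needs at least 2 pairs")
    if p.actual.std() == 0 or p.estimated.std() == 0:
        raise DegenerateInputError("zero variance in one of the series")
    return float(sps.pearsonr(p.actual, p.estimated).statistic)


def linear_fit(pairs) -> Tuple[float, float, float]:
    """OLS of estimated on actual: returns (slope, intercept, r_squared)."""
    p = _as_pairs(pairs)
    if len(p) < 2:
        raise InputError("regression needs at least 2 pairs")
    if p.actual.std() == 0:
        raise DegenerateInputError("zero variance in actual values")
    res = sps.linregress(p.actual, p.estimated)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def rmse(pairs) -> float:
    """Root mean square error, in the units of the input series."""
    p = _as_pairs(pairs)
    if len(p) < 1:
        raise InputError("rmse needs at least 1 pair")
    return float(np.sqrt(np.mean((p.estimated - p.actual) ** 2)))


def percentage_errors(pairs) -> Tuple[float, float]:
    """(MPE, MAPE) in percent.

    Per-pair error is ``100 * (estimated - actual) / actual``; MPE is
    its signed mean (negative when the model under-estimates), MAPE the
    mean of absolute values.
    """
    p = _as_pairs(pairs)
    if len(p) < 1:
        raise InputError("percentage errors need at least 1 pair")
    zero = p.actual == 0
    if zero.any():
        which = (
            [p.labels[i] for i in np.flatnonzero(zero)]
            if p.labels is not None
            else list(np.flatnonzero(zero))
        )
        raise DegenerateInputError(
            f"actual value is zero for {which}; percentage error undefined"
        )
    e = 100.0 * (p.estimated - p.actual) / p.actual
    return float(e.mean()), float(np.abs(e).mean())


def validation_report(pairs) -> ValidationReport:
    """Compute the full per-trait validation summary."""
    p = _as_pairs(pairs)
    r = pearson_r(p)
    res = sps.linregress(p.actual, p.estimated)
    mpe, mape = percentage_errors(p)
    return ValidationReport(
        n=len(p),
        pearson_r=r,
        r_squared=float(r**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        rmse=rmse(p),
        mpe_pct=mpe,
        mape_pct=mape,
        p_value=float(res.pvalue),
        significant_p01=bool(res.pvalue < 0.01),
    )
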