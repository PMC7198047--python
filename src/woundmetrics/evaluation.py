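"""Measurement-quality statistics.

The assessment protocol scores each wound parameter with four statistics:

* **accuracy** — signed relative deviation from the reference value,
  ``(measured - true)/true * 100`` (%);
* **precision** — coefficient of variation, ``CV = sigma / |mean|`` of
  repeated measurements (sample SD);
* **inter-rater reliability** — ICC(2,1), the two-way random-effects
  single-measure intraclass correlation over an n-subjects x k-raters table;
* **repeatability** — 2.77 x within-subject SD from one-way ANOVA over
  replicate series, the bound expected to cover 95% of test-retest
  differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DegenerateInputError, DomainError


@dataclass
class RaterStudy:
    """Measurements of one parameter: subjects (phantoms) x raters."""

    matrix: np.ndarray  # (n_subjects, k_raters)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
            raise DomainError("need >= 2 subjects and >= 2 raters")
        if not np.all(np.isfinite(m)):
            raise DomainError("ICC requires a complete table (no missing cells)")
        self.matrix = m


def accuracy_pct(measured: float, truth: float) -> float:
    """Signed relative deviation from the true value, in percent."""
    if truth == 0:
        raise DomainError("true value must be nonzero")
    return float((measured - truth) / truth * 100.0)


def cv(values: np.ndarray) -> float:
    """Coefficient of variation sigma/|mean| (unitless; multiply by 100 for %).

    Uses the sample standard deviation (ddof=1).
    """
    v = np.asarray(values, float)
    if v.size < 2:
        raise DomainError("CV needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise DomainError("CV undefined for zero mean")
    return float(v.std(ddof=1) / abs(mean))


def icc21(matrix: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    From the two-way ANOVA mean squares (rows = subjects, columns = raters):
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.
    """
    m = RaterStudy(np.asarray(matrix, float)).matrix
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-30:
        raise DegenerateInputError("zero total variance: ICC undefined")
    return float((msr - mse) / denom)


def repeatability_coeff(replicates: np.ndarray, multiplier: float = 2.77
                        ) -> float:
    """Repeatability = 2.77 x within-subject SD from one-way ANOVA.

    ``replicates`` is (n_subjects, m_repeats); the within-subject SD is the
    square root of the residual mean square, and 2.77 = 1.96 * sqrt(2) bounds
    95% of differences between two measurements on the same subject.
    """
    r = np.asarray(replicates, float)
    if r.ndim != 2 or r.shape[1] < 2:
        raise DomainError("repeatability needs >= 2 replicates per subject")
    n, m = r.shape
    resid = r - r.mean(axis=1, keepdims=True)
    ms_within = np.sum(resid ** 2) / (n * (m - 1))
    return float(multiplier * np.sqrt(ms_within))


def summarize_study(measurements: dict[str, np.ndarray],
                    truths: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    """Per-parameter accuracy/precision/ICC table for a full rater study.

    ``measurements[param]`` is (n_phantoms, k_raters); ``truths[param]`` the
    per-phantom reference values.  Accuracy is aggregated as the mean of
    absolute per-measurement relative deviations; precision as the mean CV
    across phantoms.
    """
    out: dict[str, dict[str, float]] = {}
    for param, mat in measurements.items():
        truth = np.asarray(truths[param], float)
        rel = np.abs((mat - truth[:, None]) / truth[:, None]) * 100
        cvs = [cv(row) for row in mat]
        out[param] = {
            "accuracy_pct": float(rel.mean()),
            "precision_cv_pct": float(np.mean(cvs) * 100),
            "icc21": icc21(mat),
        }
    return out
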