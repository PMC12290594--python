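"""Test-retest reliability of microstate metrics.

Reliability between two sessions is quantified with the intraclass
correlation coefficient in its two-way random, single-measure,
*absolute-agreement* form (ICC(A,1) in McGraw & Wong terms), which
penalizes systematic session offsets - more stringent than consistency.
With n subjects and k = 2 sessions and the usual two-way ANOVA mean
squares (MSR rows/subjects, MSC columns/sessions, MSE residual):

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

Per-cell ICCs (one per template per metric, one per transition cell) are
aggregated by Fisher z-transform, averaged, and back-transformed.  In
small samples parametric confidence intervals are uninformative, so
significance of each mean ICC comes from a permutation test: the subject
order of one session is shuffled, breaking the pairing, and the observed
mean is compared to the null distribution (one-sided, add-one p).

Mean ICCs are labelled poor (< .50), moderate ([.50, .75)), good
([.75, .90)) or excellent (>= .90).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .microstate import MicrostateMetrics
from .preprocess import ParameterError

METRICS = ("duration", "occurrence", "coverage", "transition")


@dataclass
class PairedMetrics:
    subjects: list[str]
    session_a: list[MicrostateMetrics]
    session_b: list[MicrostateMetrics]
    pairing_label: str = ""

    def __post_init__(self) -> None:
        n = len(self.subjects)
        if not (len(self.session_a) == len(self.session_b) == n):
            raise ParameterError("sessions must cover the same subjects")
        if n == 0:
            raise ParameterError("no subjects")
        labels = self.session_a[0].labels
        for m in self.session_a + self.session_b:
            if m.labels != labels:
                raise ParameterError("template labels differ across metrics")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def cell_matrix(self, metric: str) -> np.ndarray:
        """n_subjects x n_cells x 2 array of paired metric values."""
        a = np.stack([m.as_vector(metric) for m in self.session_a])
        b = np.stack([m.as_vector(metric) for m in self.session_b])
        return np.stack([a, b], axis=-1)


@dataclass
class ReliabilityReport:
    pairing_label: str
    n_subjects: int
    icc: dict[str, np.ndarray]          # per metric: per-cell ICC (nan = undefined)
    mean_icc: dict[str, float]
    p_perm: dict[str, float]
    category: dict[str, str]
    seed: int | None = None


# ---------------------------------------------------------------------
# ICC machinery
# ---------------------------------------------------------------------

def icc_a1(x: np.ndarray) -> float:
    """Two-way random, single-measure, absolute-agreement ICC for an
    n x 2 paired matrix.  Returns nan (flagged missing) when either
    column is constant, since agreement is then undefined."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ParameterError("expected an n x 2 matrix")
    n, k = x.shape
    if n < 3:
        raise ParameterError("need at least 3 subjects")
    if np.ptp(x[:, 0]) == 0 or np.ptp(x[:, 1]) == 0:
        return float("nan")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def fisher_mean(iccs) -> float:
    """tanh(mean(atanh(values))) over non-missing values; values at or
    beyond +/-1 are clamped just inside the open interval."""
    vals = np.asarray([v for v in np.ravel(iccs) if np.isfinite(v)], dtype=float)
    if len(vals) == 0:
        return float("nan")
    vals = np.clip(vals, -1 + 1e-6, 1 - 1e-6)
    return float(np.tanh(np.mean(np.arctanh(vals))))


def classify_icc(value: float) -> str:
    """Reliability category; boundaries are closed on the left."""
    if not np.isfinite(value):
        return "undefined"
    if value < 0.50:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value < 0.90:
        return "good"
    return "excellent"


def _mean_icc_from_cells(cells: np.ndarray) -> float:
    """Fisher-z mean of per-cell ICCs of an n x cells x 2 array."""
    iccs = [icc_a1(cells[:, c, :]) for c in range(cells.shape[1])]
    return fisher_mean(iccs)


def permutation_test(pair: PairedMetrics, metric: str, reps: int = 1000,
                     seed: int | None = None) -> float:
    """One-sided permutation p for the mean ICC of one metric.

    Session A keeps its subject order; session B's order is shuffled
    ``reps`` times; p = (1 + #{null >= observed}) / (1 + reps).
    """
    if pair.n_subjects < 5:
        raise ParameterError("need at least 5 subjects for a permutation test")
    cells = pair.cell_matrix(metric)
    observed = _mean_icc_from_cells(cells)
    if not np.isfinite(observed):
        return float("nan")
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    n = pair.n_subjects
    for r in range(reps):
        perm = rng.permutation(n)
        shuffled = np.stack([cells[:, :, 0], cells[perm, :, 1]], axis=-1)
        null[r] = _mean_icc_from_cells(shuffled)
    return float((1 + np.sum(null >= observed)) / (1 + reps))


def pair_reliability(pair: PairedMetrics, reps: int = 1000,
                     seed: int | None = None,
                     permutation: bool = True) -> ReliabilityReport:
    """Per-cell ICCs, Fisher-z means, permutation p-values and categories
    for duration, occurrence, coverage and (pooled) transitions."""
    icc: dict[str, np.ndarray] = {}
    mean_icc: dict[str, float] = {}
    p_perm: dict[str, float] = {}
    category: dict[str, str] = {}
    for metric in METRICS:
        cells = pair.cell_matrix(metric)
        vals = np.array([icc_a1(cells[:, c, :]) for c in range(cells.shape[1])])
        icc[metric] = vals
        mean_icc[metric] = fisher_mean(vals)
        category[metric] = classify_icc(mean_icc[metric])
        if permutation:
            p_perm[metric] = permutation_test(pair, metric, reps=reps, seed=seed)
        else:
            p_perm[metric] = float("nan")
    return ReliabilityReport(pairing_label=pair.pairing_label,
                             n_subjects=pair.n_subjects, icc=icc,
                             mean_icc=mean_icc, p_perm=p_perm,
                             category=category, seed=seed)
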