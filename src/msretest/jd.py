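"""Joint decorrelation (JD) of residual heartbeat-locked artifacts.

The ballistocardiogram (BCG) artifact that survives temporal and hardware
corrections is heartbeat-locked and spatially stereotyped.  JD exploits
this: epochs around ECG R-peaks are averaged in consecutive blocks of N
to suppress ongoing brain activity relative to the phase-locked artifact,
the same is done for randomly placed reference triggers, and the two
stacked-average spatial covariances C_art and C_ref are contrasted by a
generalized eigendecomposition

    C_art W = C_ref W diag(lambda),     W' C_ref W = I.

A generalized eigenvalue lambda_i is the ratio of heartbeat-locked to
reference variance captured by component i.  Because block averaging of
N independent epochs divides non-locked variance by roughly N, the raw
eigenvalues are rescaled by the empirically measured noise-reduction
ratio gamma_bar (the mean diagonal of W' C_ref_raw W, where C_ref_raw is
the covariance of the *unaveraged* reference epochs):

    lambda~_i = (lambda_i - 1) / gamma_bar + 1.

lambda~_i = 1 means a component gains nothing from heartbeat locking
beyond what random averaging explains; components with lambda~_i above a
chosen threshold are projected out of the recording.  At threshold 1.00
about half of all components are expected to be rejected on artifact-free
data (sampling noise alone puts half the eigenvalues above 1), which is
why practical thresholds sit in the 1.05-1.20 range.

Reference triggers are random, so the procedure is replicated with
several seeds; :func:`run_bcg_reduction` wraps that loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .core import EventSelection, Recording
from .preprocess import ParameterError


@dataclass
class EpochTensor:
    """Channels x epochs x samples-per-epoch block of trigger-locked data."""

    data: np.ndarray
    offset_s: float
    rate: float

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]


@dataclass
class StackedAverages:
    """Block averages of N consecutive epochs, concatenated along time."""

    data: np.ndarray    # C x (T * n_groups)
    n_avg: int
    n_groups: int


@dataclass
class JDModel:
    filters: np.ndarray          # W, columns sorted by descending eigenvalue
    patterns: np.ndarray         # A = C_ref W  (so A W' = I)
    eigvals: np.ndarray
    rescaled: np.ndarray
    gamma_bar: float
    cov_art: np.ndarray
    cov_ref_avg: np.ndarray
    cov_ref_raw: np.ndarray
    seed: int
    ch_names: list[str]


@dataclass
class RejectionResult:
    rejected_indices: np.ndarray
    threshold: float
    cleaned: Recording


# ---------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------

def epoch_around(rec: Recording, triggers: EventSelection,
                 offset_s: float = -0.2, duration_s: float = 0.7,
                 channels: np.ndarray | None = None) -> EpochTensor:
    """Cut fixed-length epochs around trigger samples.

    Epoch k, column j holds ``data[:, trigger_k + round(offset*rate) + j]``
    for j in [0, round(duration*rate)).  Triggers whose epoch would leave
    the recording are dropped.
    """
    if duration_s <= 0:
        raise ParameterError("duration must be positive")
    off = int(round(offset_s * rec.rate))
    T = int(round(duration_s * rec.rate))
    if channels is None:
        channels = rec.eeg_indices
    usable = [t for t in triggers.indices if t + off >= 0 and t + off + T <= rec.n_samples]
    if not usable:
        raise ParameterError("zero triggers give a full epoch inside the recording")
    data = np.stack(
        [rec.data[np.ix_(channels, np.arange(t + off, t + off + T))] for t in usable],
        axis=1,
    )
    return EpochTensor(data=data, offset_s=offset_s, rate=rec.rate)


def average_consecutive(X: EpochTensor, n_avg: int = 25) -> StackedAverages:
    """Average disjoint consecutive blocks of ``n_avg`` epochs and stack
    the averages along time; leftover epochs are discarded."""
    E = X.n_epochs
    if E < n_avg:
        raise ParameterError(
            f"{E} epochs < n_avg = {n_avg}; use a smaller averaging block")
    G = E // n_avg
    C, _, T = X.data.shape
    blocks = X.data[:, : G * n_avg].reshape(C, G, n_avg, T).mean(axis=2)
    return StackedAverages(data=blocks.reshape(C, G * T), n_avg=n_avg, n_groups=G)


def random_triggers(rec: Recording, count: int, offset_s: float = -0.2,
                    duration_s: float = 0.7, seed: int | None = None,
                    rng: np.random.Generator | None = None) -> EventSelection:
    """Uniform random trigger samples whose epochs fit the recording."""
    if count < 1:
        raise ParameterError("count must be >= 1")
    off = int(round(offset_s * rec.rate))
    T = int(round(duration_s * rec.rate))
    lo = max(0, -off)
    hi = rec.n_samples - (off + T)
    if hi - lo < count:
        raise ParameterError(
            f"recording supports at most {max(hi - lo, 0)} random triggers, need {count}")
    if rng is None:
        rng = np.random.default_rng(seed)
    picks = rng.choice(hi - lo, size=count, replace=False) + lo
    return EventSelection(label_pattern="<random>", indices=np.sort(picks))


# ---------------------------------------------------------------------
# model estimation
# ---------------------------------------------------------------------

def _spatial_cov(stacked: np.ndarray) -> np.ndarray:
    X = stacked - stacked.mean(axis=1, keepdims=True)
    return X @ X.T / (X.shape[1] - 1)


def _demean_epochs(X: EpochTensor) -> EpochTensor:
    return EpochTensor(data=X.data - X.data.mean(axis=2, keepdims=True),
                       offset_s=X.offset_s, rate=X.rate)


def fit_jd(rec: Recording, r_peaks: EventSelection, n_avg: int = 25,
           offset_s: float = -0.2, duration_s: float = 0.7,
           seed: int = 0, shrinkage: float = 1e-6,
           demean_epochs: bool = True) -> JDModel:
    """Estimate the JD model from R-peak-locked and random-reference epochs.

    The reference-epoch count equals the artifact-epoch count.  A small
    shrinkage toward the scaled identity keeps C_ref invertible for
    average-referenced (rank C-1) data.
    """
    Xart = epoch_around(rec, r_peaks, offset_s, duration_s)
    E = Xart.n_epochs
    ref = random_triggers(rec, E, offset_s, duration_s, seed=seed)
    Xref = epoch_around(rec, ref, offset_s, duration_s)
    if demean_epochs:
        Xart, Xref = _demean_epochs(Xart), _demean_epochs(Xref)

    Sart = average_consecutive(Xart, n_avg)
    Sref = average_consecutive(Xref, n_avg)
    C = Sart.data.shape[0]
    cov_art = _spatial_cov(Sart.data)
    cov_ref = _spatial_cov(Sref.data)
    if shrinkage:
        cov_ref = (1 - shrinkage) * cov_ref + shrinkage * np.trace(cov_ref) / C * np.eye(C)

    cond = np.linalg.cond(cov_ref)
    if not np.isfinite(cond) or cond > 1e12:
        raise ParameterError(
            "reference covariance is rank deficient; increase shrinkage")

    lam, W = linalg.eigh(cov_art, cov_ref)     # ascending, W' cov_ref W = I
    order = np.argsort(lam)[::-1]
    lam, W = lam[order], W[:, order]
    lam = np.clip(lam, 0.0, None)

    raw = Xref.data.reshape(C, -1)
    cov_ref_raw = _spatial_cov(raw)
    gamma_bar = float(np.mean(np.diag(W.T @ cov_ref_raw @ W)))
    rescaled = rescale_eigenvalues(lam, gamma_bar)
    patterns = cov_ref @ W

    return JDModel(filters=W, patterns=patterns, eigvals=lam, rescaled=rescaled,
                   gamma_bar=gamma_bar, cov_art=cov_art, cov_ref_avg=cov_ref,
                   cov_ref_raw=cov_ref_raw, seed=seed,
                   ch_names=[rec.ch_names[i] for i in rec.eeg_indices])


def rescale_eigenvalues(eigvals: np.ndarray, gamma_bar: float) -> np.ndarray:
    """lambda~ = (lambda - 1) / gamma_bar + 1, order preserved."""
    if gamma_bar <= 0:
        raise ParameterError("gamma_bar must be positive")
    return (np.asarray(eigvals, dtype=float) - 1.0) / gamma_bar + 1.0


def apply_jd(rec: Recording, model: JDModel, threshold: float) -> RejectionResult:
    """Project out all components with rescaled eigenvalue above threshold.

    cleaned = X - A_rej (W_rej' X); ties at the threshold are kept.
    """
    eeg = rec.eeg_indices
    if len(eeg) != model.filters.shape[0]:
        raise ParameterError("model channel count does not match recording")
    rej = np.where(model.rescaled > threshold)[0]
    out = rec.data.copy()
    if len(rej):
        W = model.filters[:, rej]
        A = model.patterns[:, rej]
        X = rec.data[eeg]
        out[eeg] = X - A @ (W.T @ X)
    cleaned = rec.with_data(
        out, f"jd rejection threshold={threshold}: {len(rej)}/{model.filters.shape[1]} components")
    return RejectionResult(rejected_indices=rej, threshold=threshold, cleaned=cleaned)


def run_bcg_reduction(rec: Recording, r_peaks: EventSelection, threshold: float,
                      n_avg: int = 25, replicates: int = 10, base_seed: int = 0,
                      **fit_kwargs) -> list[RejectionResult]:
    """Replicate fit+apply with seeds ``base_seed ... base_seed+replicates-1``.

    The random reference periods make single runs non-deterministic given
    different seeds; replicates expose that variability.
    """
    results = []
    for k in range(replicates):
        model = fit_jd(rec, r_peaks, n_avg=n_avg, seed=base_seed + k, **fit_kwargs)
        results.append(apply_jd(rec, model, threshold))
    return results
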