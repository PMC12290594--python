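"""Three-step reliability-driven evaluation of noise reduction.

Step 1 establishes that microstate metrics are reliable between two
artifact-free sessions.  Step 2 sweeps the JD rejection threshold
(default grid 1.05 ... 1.20 in steps of 0.01, plus a "none" control with
the JD step disabled) over several random-reference replicates, scoring
each (threshold, replicate) cell by the Fisher-z mean ICC between the
cleaned in-scanner metrics and the reference (outside) metrics; cells
where duration, occurrence and coverage all reach ICC >= 0.5 pass.
Step 3 crosses the surviving candidates of two recording days and picks
the passing combination with the most similar (ideally identical)
thresholds.

Also here: Welch PSD and baseline-corrected evoked responses (ERP) used
as conventional data-quality checks on the cleaned recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import EventSelection, Recording
from .jd import apply_jd, fit_jd
from .microstate import MicrostateMetrics, MicrostateTemplates, backfit, metrics
from .preprocess import ParameterError
from .reliability import PairedMetrics, ReliabilityReport, pair_reliability

PASS_METRICS = ("duration", "occurrence", "coverage")
DEFAULT_GRID = [round(t, 2) for t in np.arange(1.05, 1.201, 0.01)]


@dataclass
class SweepResult:
    thresholds: list            # numeric grid values plus "none"
    replicate_seeds: list[int]
    table: pd.DataFrame         # threshold, replicate, metric, mean_icc
    pass_mask: dict             # (threshold, replicate) -> bool
    metrics_by_cell: dict = field(default_factory=dict)
    # (threshold, replicate) -> list[MicrostateMetrics] per subject


def _sweep_grid(grid) -> list[float]:
    numeric = [t for t in grid if t != "none"]
    if any(np.diff(numeric) <= 0):
        raise ParameterError("threshold grid must be strictly increasing")
    return numeric


def threshold_sweep(inside: list[tuple[Recording, EventSelection]],
                    outside_metrics: list[MicrostateMetrics],
                    templates: MicrostateTemplates,
                    grid=None, replicates: int = 10, seed: int = 0,
                    n_avg: int = 25, smooth_window_ms: float = 20.0,
                    penalty: float = 1.0) -> SweepResult:
    """Mean ICC versus outside metrics for every threshold x replicate.

    ``inside`` holds one (recording, R-peak selection) pair per subject,
    matched by position to ``outside_metrics``.  For each replicate a JD
    model is fitted once per subject (the random reference periods are
    the replicate's source of variability) and applied at every grid
    threshold; "none" skips the JD step entirely.
    """
    if grid is None:
        grid = ["none"] + DEFAULT_GRID
    numeric = _sweep_grid(grid)
    if len(inside) != len(outside_metrics):
        raise ParameterError("inside recordings and outside metrics must pair up")
    n_subj = len(inside)
    replicate_seeds = [seed + r for r in range(replicates)]

    rows = []
    pass_mask: dict = {}
    metrics_by_cell: dict = {}

    none_metrics = None
    if "none" in grid:
        none_metrics = [metrics(backfit(rec, templates, smooth_window_ms, penalty),
                                labels=templates.labels)
                        for rec, _ in inside]

    for r, rseed in enumerate(replicate_seeds):
        models = None
        if numeric:
            models = [fit_jd(rec, rp, n_avg=n_avg, seed=rseed * 10007 + s)
                      for s, (rec, rp) in enumerate(inside)]
        for thr in grid:
            if thr == "none":
                cell = none_metrics
            else:
                cell = []
                for (rec, _), model in zip(inside, models):
                    cleaned = apply_jd(rec, model, thr).cleaned
                    seq = backfit(cleaned, templates, smooth_window_ms, penalty)
                    cell.append(metrics(seq, labels=templates.labels))
            pair = PairedMetrics(subjects=[f"S{i}" for i in range(n_subj)],
                                 session_a=outside_metrics, session_b=cell,
                                 pairing_label=f"thr={thr} rep={r}")
            rep = pair_reliability(pair, permutation=False)
            for m, v in rep.mean_icc.items():
                rows.append({"threshold": thr, "replicate": r,
                             "metric": m, "mean_icc": v})
            passed = all(rep.mean_icc[m] >= 0.5 for m in PASS_METRICS)
            pass_mask[(thr, r)] = bool(passed)
            metrics_by_cell[(thr, r)] = cell
    table = pd.DataFrame(rows)
    return SweepResult(thresholds=list(grid), replicate_seeds=replicate_seeds,
                       table=table, pass_mask=pass_mask,
                       metrics_by_cell=metrics_by_cell)


def select_candidates(sweep: SweepResult) -> list[tuple[float, int]]:
    """Passing (threshold, replicate) cells, ranked by how wide and
    contiguous each replicate's passing threshold range is.

    Replicates are ordered by longest contiguous run of passing grid
    thresholds, ties broken by total passes, then by replicate index;
    within a replicate candidates keep grid order.  The "none" control
    never becomes a candidate.
    """
    numeric = [t for t in sweep.thresholds if t != "none"]
    ranked = []
    for r in range(len(sweep.replicate_seeds)):
        passes = [sweep.pass_mask.get((t, r), False) for t in numeric]
        longest = cur = 0
        for p in passes:
            cur = cur + 1 if p else 0
            longest = max(longest, cur)
        ranked.append((-longest, -sum(passes), r))
    ranked.sort()
    out = []
    for _, _, r in ranked:
        for t in numeric:
            if sweep.pass_mask.get((t, r), False):
                out.append((t, r))
    return out


def cross_day_select(day1_candidates: list[tuple[float, int]],
                     day2_candidates: list[tuple[float, int]],
                     day1_metrics: dict, day2_metrics: dict,
                     subjects: list[str] | None = None,
                     ) -> tuple[tuple | None, dict]:
    """Cross every day-1 candidate with every day-2 candidate.

    ``dayN_metrics`` maps (threshold, replicate) to the per-subject
    metrics of that day's cleaned recordings.  A combination passes when
    the duration/occurrence/coverage mean ICCs between the two days all
    reach 0.5; among passing combinations the pick minimizes the
    threshold difference, ties resolved toward lower thresholds.
    Returns ``(pick, reports)`` with pick None when nothing passes.
    """
    if not day1_candidates or not day2_candidates:
        raise ParameterError("candidate lists must be non-empty")
    reports: dict = {}
    passing = []
    for c1 in day1_candidates:
        for c2 in day2_candidates:
            m1, m2 = day1_metrics[c1], day2_metrics[c2]
            subj = subjects or [f"S{i}" for i in range(len(m1))]
            pair = PairedMetrics(subjects=subj, session_a=m1, session_b=m2,
                                 pairing_label=f"day1 {c1} vs day2 {c2}")
            rep = pair_reliability(pair, permutation=False)
            reports[(c1, c2)] = rep
            if all(rep.mean_icc[m] >= 0.5 for m in PASS_METRICS):
                passing.append((abs(c1[0] - c2[0]), c1[0], c2[0], (c1, c2)))
    if not passing:
        return None, reports
    passing.sort()
    return passing[0][3], reports


# ---------------------------------------------------------------------
# data-quality checks
# ---------------------------------------------------------------------

@dataclass
class PSDResult:
    freqs: np.ndarray
    mean: np.ndarray            # channel-averaged power, uV^2/Hz
    sd: np.ndarray              # SD over channels


@dataclass
class ERPResult:
    times: np.ndarray           # s, relative to the event
    data: np.ndarray            # channels x time, baseline-corrected mean
    n_epochs: int
    baseline: tuple[float, float]


def welch_psd(rec: Recording, window_s: float = 2.0,
              overlap: float = 0.5) -> PSDResult:
    """Channel-averaged Welch power spectral density of the EEG channels."""
    nper = int(round(window_s * rec.rate))
    if nper > rec.n_samples:
        raise ParameterError("window longer than recording")
    freqs, psd = signal.welch(rec.eeg_data(), fs=rec.rate, nperseg=nper,
                              noverlap=int(round(nper * overlap)), axis=1)
    return PSDResult(freqs=freqs, mean=psd.mean(axis=0), sd=psd.std(axis=0))


def erp(rec: Recording, events: EventSelection,
        window: tuple[float, float] = (-0.1, 0.6),
        baseline: tuple[float, float] = (-0.1, 0.0)) -> ERPResult:
    """Event-locked average, each channel referenced to its mean over the
    baseline window; epochs extending past the recording are dropped."""
    a = int(round(window[0] * rec.rate))
    b = int(round(window[1] * rec.rate))
    usable = [t for t in events.indices if t + a >= 0 and t + b <= rec.n_samples]
    if not usable:
        raise ParameterError("zero usable events")
    eeg = rec.eeg_data()
    epochs = np.stack([eeg[:, t + a: t + b] for t in usable])
    times = np.arange(a, b) / rec.rate
    bsel = (times >= baseline[0]) & (times <= baseline[1])
    epochs = epochs - epochs[:, :, bsel].mean(axis=2, keepdims=True)
    return ERPResult(times=times, data=epochs.mean(axis=0),
                     n_epochs=len(usable), baseline=baseline)
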