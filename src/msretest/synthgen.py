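"""Ground-truthed synthetic EEG for exercising every pipeline stage.

The generator emulates the signal and artifact structure the pipeline
assumes, with full ground truth recorded:

* microstate-structured EEG: a semi-Markov sequence of K smooth,
  average-referenced template topographies, gamma-distributed dwell
  times, modulated by a rectified low-pass-noise GFP envelope, plus
  white sensor noise;
* a heartbeat-locked (BCG-like) artifact: an R-peak train at ~1 Hz with
  jittered RR intervals, each beat spawning a few damped-oscillation
  component waveforms (delayed from the R-peak) mixed through fixed
  spatial patterns - the spatially stereotyped, phase-locked structure
  the joint-decorrelation method targets;
* optionally a large periodic gradient-like artifact with volume
  triggers, and carbon-wire-loop channels that share a motion source
  with the EEG;
* twin-session cohorts in which the subject-level mean dwell time
  carries a known share of the between- plus within-subject variance,
  so the true test-retest ICC of duration-type metrics is known by
  construction.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import signal

from .core import Recording
from .preprocess import ParameterError

# 10-20 labels used for synthetic montages, roughly uniform scalp coverage
_MONTAGE_NAMES = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "PO4", "PO8", "O1", "Oz", "O2",
    "AF3", "AF4", "F5", "F1", "F2", "F6", "FT7", "FC3", "FC4", "FT8",
    "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO9", "POz", "PO10", "F9", "F10", "AF7",
    "AF8", "Fpz",
]


@lru_cache(maxsize=8)
def _cached_positions(n_channels: int) -> tuple[tuple[str, ...], bytes]:
    import warnings

    import mne
    names = tuple(_MONTAGE_NAMES[:n_channels])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1020")
    pos_map = montage.get_positions()["ch_pos"]
    P = np.array([pos_map[n] for n in names])
    P = P - P.mean(axis=0)
    P /= np.linalg.norm(P, axis=1, keepdims=True)
    return names, P.tobytes()


def standard_positions(n_channels: int) -> tuple[list[str], np.ndarray]:
    """First ``n_channels`` 10-20 labels with unit-sphere positions."""
    if n_channels > len(_MONTAGE_NAMES):
        raise ParameterError(f"at most {len(_MONTAGE_NAMES)} channels supported")
    names, raw = _cached_positions(n_channels)
    return list(names), np.frombuffer(raw).reshape(n_channels, 3).copy()


@dataclass
class SynthConfig:
    n_channels: int = 32
    rate: float = 250.0
    duration_s: float = 120.0
    k_templates: int = 4
    mean_state_duration_ms: float = 80.0
    state_duration_cv: float = 0.5
    gfp_mean_uv: float = 10.0
    heart_rate_hz: float = 1.0
    rr_jitter_sd_s: float = 0.05
    n_bcg_components: int = 3
    bcg_snr: float = 0.0              # BCG RMS relative to EEG signal RMS
    bcg_delay_s: float = 0.21         # artifact lag after the R-peak
    noise_sd_uv: float = 2.0
    ga_period_s: float | None = None
    ga_amplitude_uv: float = 0.0
    cwl_coupling: float | None = None
    n_cwl: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.duration_s <= 0 or self.heart_rate_hz <= 0:
            raise ParameterError("rates and durations must be positive")
        if not (2 <= self.k_templates <= 8):
            raise ParameterError("k_templates must be in [2, 8]")


@dataclass
class GroundTruth:
    state_labels: np.ndarray
    r_peaks: np.ndarray
    template_maps: np.ndarray
    bcg_patterns: np.ndarray | None = None
    bcg_waveforms: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------

def _smooth_map(P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random smooth scalp map: polynomial field of position up to
    degree 3 (a spherical-harmonic-like basis of 13 functions)."""
    x, y, z = P.T
    basis = np.stack([
        x, y, z,
        x * x - y * y, 3 * z * z - 1, x * y, y * z, x * z,
        x ** 3, y ** 3, z ** 3, x * y * z, (x * x - y * y) * z,
    ])
    m = rng.normal(size=basis.shape[0]) @ basis
    m = m - m.mean()
    return m * np.sqrt(len(m)) / np.linalg.norm(m)


def _bcg_pattern_set(n_channels: int, k: int, seed: int,
                     positions: np.ndarray) -> np.ndarray:
    """Spatial patterns of the heartbeat-locked artifact: a smooth field
    plus an electrode-level rough component.  Wire and electrode motion
    couples less smoothly across the scalp than neural sources, which
    also keeps artifact topographies from collapsing onto the microstate
    template subspace."""
    rng = np.random.default_rng(seed)
    out = np.empty((k, n_channels))
    for i in range(k):
        smooth = _smooth_map(positions, rng)
        rough = rng.normal(size=n_channels)
        rough -= rough.mean()
        rough *= np.sqrt(n_channels) / np.linalg.norm(rough)
        m = smooth + 0.7 * rough
        m -= m.mean()
        out[i] = m * np.sqrt(n_channels) / np.linalg.norm(m)
    return out


def make_templates(n_channels: int, k: int, seed: int,
                   max_abs_corr: float = 0.5,
                   positions: np.ndarray | None = None) -> np.ndarray:
    """k smooth, average-referenced, unit-GFP maps with pairwise
    |correlation| below ``max_abs_corr`` (rejection sampled)."""
    if k > n_channels - 1:
        raise ParameterError("k must be below the average-referenced rank")
    if positions is None:
        _, positions = standard_positions(n_channels)
    rng = np.random.default_rng(seed)
    maps: list[np.ndarray] = []
    for _ in range(2000):
        cand = _smooth_map(positions, rng)
        if all(abs(cand @ m) / (np.linalg.norm(cand) * np.linalg.norm(m))
               < max_abs_corr for m in maps):
            maps.append(cand)
            if len(maps) == k:
                return np.array(maps)
    raise ParameterError("rejection sampling failed; relax max_abs_corr")


def simulate_state_sequence(cfg: SynthConfig,
                            rng: np.random.Generator | None = None,
                            mean_duration_ms: float | None = None) -> np.ndarray:
    """Semi-Markov state labels per sample: gamma dwell times with the
    configured mean/CV, next state uniform over the other k-1 states."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mean_ms = cfg.mean_state_duration_ms if mean_duration_ms is None else mean_duration_ms
    mean_samples = np.broadcast_to(
        np.asarray(mean_ms, dtype=float) / 1000.0 * cfg.rate, (cfg.k_templates,))
    n = int(round(cfg.duration_s * cfg.rate))
    cv = cfg.state_duration_cv
    labels = np.empty(n, dtype=int)
    state = int(rng.integers(cfg.k_templates))
    t = 0
    while t < n:
        if cv <= 0:
            dwell = max(1, int(round(mean_samples[state])))
        else:
            shape = 1.0 / cv ** 2
            dwell = max(1, int(round(rng.gamma(shape, mean_samples[state] * cv ** 2))))
        labels[t: t + dwell] = state
        t += dwell
        step = int(rng.integers(cfg.k_templates - 1))
        state = (state + 1 + step) % cfg.k_templates
    return labels


def _gfp_envelope(n: int, rate: float, mean_uv: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Rectified alpha-band noise, scaled to the requested mean level.

    The 4-12 Hz band makes GFP maxima occur every few tens of
    milliseconds, like the dense GFP-peak structure of band-passed
    resting EEG, so peak-based backfitting sees one or more peaks per
    microstate."""
    w = rng.normal(size=n)
    sos = signal.butter(2, [4.0, 12.0], btype="bandpass", fs=rate, output="sos")
    env = np.abs(signal.sosfiltfilt(sos, w)) + 0.05
    env *= mean_uv / max(env.mean(), 1e-12)
    return env


def _r_peak_train(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    rr_mean = 1.0 / cfg.heart_rate_hz
    t, peaks = 0.3, []
    while t < cfg.duration_s - 0.1:
        peaks.append(int(round(t * cfg.rate)))
        rr = rr_mean + rng.normal(0, cfg.rr_jitter_sd_s)
        t += max(rr, 0.3)
    return np.array(peaks, dtype=int)


def _bcg_component_waveforms(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Stereotyped damped oscillations, one per component, delayed from
    the R-peak; length 0.5 s."""
    T = int(round(0.5 * cfg.rate))
    tt = np.arange(T) / cfg.rate
    waves = np.empty((cfg.n_bcg_components, T))
    for i in range(cfg.n_bcg_components):
        f = rng.uniform(3.0, 8.0)
        phase = rng.uniform(0, 2 * np.pi)
        tau = rng.uniform(0.1, 0.2)
        waves[i] = np.exp(-tt / tau) * np.sin(2 * np.pi * f * tt + phase)
    return waves


# ---------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------

def simulate_recording(cfg: SynthConfig,
                       mean_duration_ms: float | None = None,
                       ) -> tuple[Recording, GroundTruth]:
    """One synthetic recording with complete ground truth.

    The BCG, gradient and CWL terms are additive, so setting their
    amplitudes to zero reproduces the clean recording bit-for-bit under
    the same seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.rate))
    names, P = standard_positions(cfg.n_channels)

    templates = make_templates(cfg.n_channels, cfg.k_templates,
                               seed=int(rng.integers(2 ** 31)), positions=P)
    labels = simulate_state_sequence(cfg, rng, mean_duration_ms=mean_duration_ms)
    env = _gfp_envelope(n, cfg.rate, cfg.gfp_mean_uv, rng)
    eeg = templates[labels].T * env[None, :]
    signal_rms = float(np.sqrt(np.mean(eeg ** 2)))
    eeg = eeg + rng.normal(0, cfg.noise_sd_uv, size=eeg.shape)

    # heartbeat-locked artifact (always drawn so the RNG stream is stable)
    r_peaks = _r_peak_train(cfg, rng)
    waves = _bcg_component_waveforms(cfg, rng)
    patterns = _bcg_pattern_set(cfg.n_channels, cfg.n_bcg_components,
                                seed=int(rng.integers(2 ** 31)), positions=P)
    gains = rng.uniform(0.5, 1.0, size=cfg.n_bcg_components)
    delay = int(round(cfg.bcg_delay_s * cfg.rate))
    bcg_src = np.zeros((cfg.n_bcg_components, n))
    T = waves.shape[1]
    for p in r_peaks:
        a = p + delay
        b = min(a + T, n)
        if a < n:
            bcg_src[:, a:b] += waves[:, : b - a]
    bcg = (patterns.T * gains) @ bcg_src
    bcg_rms = float(np.sqrt(np.mean(bcg ** 2)))
    if cfg.bcg_snr > 0 and bcg_rms > 0:
        eeg = eeg + bcg * (cfg.bcg_snr * signal_rms / bcg_rms)

    events = [(int(p), "R") for p in r_peaks]

    # gradient-like periodic artifact + volume triggers
    if cfg.ga_period_s and cfg.ga_amplitude_uv > 0:
        period = int(round(cfg.ga_period_s * cfg.rate))
        tt = np.arange(period) / cfg.rate
        ga_wave = signal.sawtooth(2 * np.pi * 20 * tt) * cfg.ga_amplitude_uv
        ga_pattern = np.abs(_smooth_map(P, rng)) + 0.5
        starts = np.arange(0, n - period + 1, period)
        for s in starts:
            eeg[:, s:s + period] += ga_pattern[:, None] * ga_wave[None, :]
            events.append((int(s), "V"))

    data, ch_names, ch_types = eeg, list(names), ["eeg"] * cfg.n_channels
    positions = P
    if cfg.cwl_coupling is not None:
        sos = signal.butter(2, 8.0, btype="lowpass", fs=cfg.rate, output="sos")
        motion = signal.sosfiltfilt(sos, rng.normal(size=(cfg.n_cwl, n)), axis=1)
        motion *= cfg.gfp_mean_uv / np.sqrt(np.mean(motion ** 2))
        coupling = rng.normal(0, 1.0, size=(cfg.n_channels, cfg.n_cwl))
        data = eeg + cfg.cwl_coupling * coupling @ motion
        cwl = motion + rng.normal(0, 0.01 * cfg.gfp_mean_uv, size=motion.shape)
        data = np.vstack([data, cwl])
        ch_names = ch_names + [f"CWL{i + 1}" for i in range(cfg.n_cwl)]
        ch_types = ch_types + ["cwl"] * cfg.n_cwl
        positions = np.vstack([P, np.zeros((cfg.n_cwl, 3))])

    events.sort(key=lambda e: e[0])
    rec = Recording(data=data, rate=cfg.rate, ch_names=ch_names,
                    ch_types=ch_types, events=events, positions=positions,
                    meta=[f"synthetic seed={cfg.seed}"])
    truth = GroundTruth(state_labels=labels, r_peaks=r_peaks,
                        template_maps=templates, bcg_patterns=patterns,
                        bcg_waveforms=waves,
                        extra={"signal_rms": signal_rms})
    return rec, truth


# ---------------------------------------------------------------------
# cohorts with known reliability
# ---------------------------------------------------------------------

def paired_subject_means(n_subjects: int, icc_target: float,
                         mu_pop: float, sigma_total: float,
                         rng: np.random.Generator,
                         n_sessions: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Subject means and per-session means with a known variance split.

    sigma_between^2 = icc_target * sigma_total^2 and sigma_within^2 the
    complement, so the true ICC of the session means is ``icc_target``.
    """
    if not (0 <= icc_target < 1):
        raise ParameterError("icc_target must be in [0, 1)")
    sb = sigma_total * np.sqrt(icc_target)
    sw = sigma_total * np.sqrt(1 - icc_target)
    mu_subj = mu_pop + rng.normal(0, sb, size=n_subjects)
    mu_sess = mu_subj[:, None] + rng.normal(0, sw, size=(n_subjects, n_sessions))
    return mu_subj, mu_sess


@dataclass
class Cohort:
    subjects: list[str]
    recordings: list[list[Recording]]       # [subject][session]
    truths: list[list[GroundTruth]]
    mu_subj: np.ndarray
    mu_sess: np.ndarray
    icc_target: float
    template_maps: np.ndarray


def simulate_cohort(cfg: SynthConfig, n_subjects: int, icc_target: float,
                    n_sessions: int = 2,
                    subject_sd_frac: float = 0.2,
                    session_overrides: list[dict] | None = None) -> Cohort:
    """Twin-session cohort whose duration-type metrics have a known ICC.

    The subject/session mean dwell times come from
    :func:`paired_subject_means` with total SD ``subject_sd_frac`` of the
    population mean; every session is then simulated independently given
    its mean.  ``session_overrides`` patches the config per session (for
    instance giving session 2 a nonzero ``bcg_snr`` to emulate in-scanner
    recordings).  All subjects share one template set (the group truth).
    """
    rng = np.random.default_rng(cfg.seed)
    mu_pop = cfg.mean_state_duration_ms
    # independent subject/session effects per template, so duration-type
    # metrics (and coverage, via the dwell-share nonlinearity) all carry
    # subject-level signal
    per_template = [paired_subject_means(n_subjects, icc_target, mu_pop,
                                         subject_sd_frac * mu_pop, rng, n_sessions)
                    for _ in range(cfg.k_templates)]
    mu_subj = np.stack([p[0] for p in per_template], axis=-1)   # subj x k
    mu_sess = np.stack([p[1] for p in per_template], axis=-1)   # subj x sess x k
    mu_sess = np.clip(mu_sess, 0.3 * mu_pop, None)
    template_seed = int(rng.integers(2 ** 31))

    recordings: list[list[Recording]] = []
    truths: list[list[GroundTruth]] = []
    for s in range(n_subjects):
        recs, trs = [], []
        for j in range(n_sessions):
            sess_cfg = replace(cfg, seed=int(rng.integers(2 ** 31)))
            if session_overrides is not None:
                sess_cfg = replace(sess_cfg, **session_overrides[j])
            rec, truth = _recording_with_fixed_templates(
                sess_cfg, template_seed, mean_duration_ms=mu_sess[s, j])
            truth.extra.update(subject=s, session=j,
                               mu_subj=mu_subj[s].copy(),
                               mu_sess=mu_sess[s, j].copy())
            recs.append(rec)
            trs.append(truth)
        recordings.append(recs)
        truths.append(trs)
    template_maps = truths[0][0].template_maps
    return Cohort(subjects=[f"S{s:03d}" for s in range(n_subjects)],
                  recordings=recordings, truths=truths,
                  mu_subj=mu_subj, mu_sess=mu_sess,
                  icc_target=icc_target, template_maps=template_maps)


def _recording_with_fixed_templates(cfg: SynthConfig, template_seed: int,
                                    mean_duration_ms,
                                    ) -> tuple[Recording, GroundTruth]:
    """Like :func:`simulate_recording` but with a cohort-shared template
    set, so sessions and subjects are comparable."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.rate))
    names, P = standard_positions(cfg.n_channels)
    templates = make_templates(cfg.n_channels, cfg.k_templates,
                               seed=template_seed, positions=P)
    labels = simulate_state_sequence(cfg, rng, mean_duration_ms=mean_duration_ms)
    env = _gfp_envelope(n, cfg.rate, cfg.gfp_mean_uv, rng)
    eeg = templates[labels].T * env[None, :]
    signal_rms = float(np.sqrt(np.mean(eeg ** 2)))
    eeg = eeg + rng.normal(0, cfg.noise_sd_uv, size=eeg.shape)

    r_peaks = _r_peak_train(cfg, rng)
    waves = _bcg_component_waveforms(cfg, rng)
    patterns = _bcg_pattern_set(cfg.n_channels, cfg.n_bcg_components,
                                seed=template_seed + 1, positions=P)
    gains = rng.uniform(0.5, 1.0, size=cfg.n_bcg_components)
    delay = int(round(cfg.bcg_delay_s * cfg.rate))
    bcg_src = np.zeros((cfg.n_bcg_components, n))
    T = waves.shape[1]
    for p in r_peaks:
        a = p + delay
        b = min(a + T, n)
        if a < n:
            bcg_src[:, a:b] += waves[:, : b - a]
    bcg = (patterns.T * gains) @ bcg_src
    bcg_rms = float(np.sqrt(np.mean(bcg ** 2)))
    if cfg.bcg_snr > 0 and bcg_rms > 0:
        eeg = eeg + bcg * (cfg.bcg_snr * signal_rms / bcg_rms)

    rec = Recording(data=eeg, rate=cfg.rate, ch_names=list(names),
                    ch_types=["eeg"] * cfg.n_channels,
                    events=sorted([(int(p), "R") for p in r_peaks]),
                    positions=P, meta=[f"synthetic cohort seed={cfg.seed}"])
    truth = GroundTruth(state_labels=labels, r_peaks=r_peaks,
                        template_maps=templates, bcg_patterns=patterns,
                        bcg_waveforms=waves, extra={"signal_rms": signal_rms})
    return rec, truth
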