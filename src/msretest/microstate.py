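"""EEG microstate segmentation and metrics.

Microstates model multichannel EEG as a sequence of a few quasi-stable
scalp topographies, each dominating for tens of milliseconds.  The
workflow here follows the classic GFP-peak / clustering / backfitting
recipe:

1. Topography maps are sampled at peaks of global field power (GFP, the
   spatial standard deviation across average-referenced channels), where
   topographic signal-to-noise is highest, ignoring polarity.
2. Maps are clustered with the atomize-and-agglomerate hierarchical
   clustering (AAHC), chosen for being deterministic: repeatedly dissolve
   the cluster contributing least global explained variance (GEV) and
   reassign its members to the best-correlated surviving cluster.
   Two-level clustering (per subject, then across subject mean maps)
   yields group templates.
3. Templates are ordered against canonical reference maps (Hungarian
   assignment on absolute spatial correlation) and backfitted to the
   recording: each GFP peak takes the best-matching template, non-peak
   samples inherit the nearest peak's label, and segments shorter than a
   smoothing window are absorbed into their neighbors.

From the resulting label sequence the standard metrics are computed:
mean duration (ms), occurrence (segments/s), coverage (%) and the
cross-type transition probability matrix.  All steps treat a map and its
negation as identical (polarity invariance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import Recording
from .preprocess import ParameterError

DEFAULT_LABELS = [chr(ord("A") + i) for i in range(26)]


# ---------------------------------------------------------------------
# types
# ---------------------------------------------------------------------

@dataclass
class TopographySet:
    maps: np.ndarray            # M x C, average-referenced
    gfp: np.ndarray             # per-map GFP
    source: str = ""

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        self.gfp = np.asarray(self.gfp, dtype=float)
        if np.any(self.gfp < 0):
            raise ParameterError("gfp must be nonnegative")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]


@dataclass
class MicrostateTemplates:
    maps: np.ndarray            # K x C, unit GFP
    labels: list[str]
    gev: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.maps.shape[0]


@dataclass
class MicrostateSequence:
    labels: np.ndarray          # per-sample template index, -1 = unassigned
    rate: float
    gfp: np.ndarray
    fit: np.ndarray             # per-sample |spatial corr| to assigned template
    k: int


@dataclass
class MicrostateMetrics:
    labels: list[str]
    duration_ms: np.ndarray     # per template
    occurrence_hz: np.ndarray
    coverage_pct: np.ndarray
    transition: np.ndarray      # K x K, diagonal 0

    def as_vector(self, metric: str) -> np.ndarray:
        """Flatten one metric to a vector (transitions: row-major off-diagonal)."""
        if metric == "transition":
            K = len(self.labels)
            mask = ~np.eye(K, dtype=bool)
            return self.transition[mask]
        return getattr(self, {"duration": "duration_ms",
                              "occurrence": "occurrence_hz",
                              "coverage": "coverage_pct"}[metric])


# ---------------------------------------------------------------------
# GFP
# ---------------------------------------------------------------------

def _avg_ref(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=0, keepdims=True)


def gfp_curve(rec: Recording) -> np.ndarray:
    """Per-sample GFP: population SD across average-referenced EEG channels."""
    eeg = rec.eeg_data()
    if eeg.shape[0] < 2:
        raise ParameterError("need at least 2 EEG channels")
    return _avg_ref(eeg).std(axis=0)


def gfp_peaks(rec: Recording, min_separation_ms: float = 0.0) -> TopographySet:
    """Topography maps at strict local maxima of the GFP curve."""
    g = gfp_curve(rec)
    idx = np.where((g[1:-1] > g[:-2]) & (g[1:-1] > g[2:]))[0] + 1
    if len(idx) == 0:
        raise ParameterError("no GFP peaks (constant or monotone GFP)")
    if min_separation_ms > 0:
        min_sep = int(round(min_separation_ms / 1000 * rec.rate))
        keep: list[int] = []
        for i in idx[np.argsort(g[idx])[::-1]]:   # larger peaks first
            if all(abs(i - j) >= min_sep for j in keep):
                keep.append(int(i))
        idx = np.array(sorted(keep), dtype=int)
    maps = _avg_ref(rec.eeg_data())[:, idx].T
    return TopographySet(maps=maps, gfp=g[idx], source=f"{len(idx)} gfp peaks")


def spatial_corr(map1: np.ndarray, map2: np.ndarray,
                 ignore_polarity: bool = True) -> float:
    """Pearson correlation across channels of two average-referenced maps."""
    a = np.asarray(map1, float) - np.mean(map1)
    b = np.asarray(map2, float) - np.mean(map2)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ParameterError("zero-variance map")
    r = float(a @ b / (na * nb))
    return abs(r) if ignore_polarity else r


# ---------------------------------------------------------------------
# AAHC clustering
# ---------------------------------------------------------------------

def _principal_map(S: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of a map outer-product sum, unit GFP scaled."""
    vals, vecs = np.linalg.eigh(S)
    v = vecs[:, -1]
    v = v - v.mean()
    C = len(v)
    n = np.linalg.norm(v)
    if n == 0:
        raise ParameterError("degenerate cluster prototype")
    return v * np.sqrt(C) / n


def aahc(topos: TopographySet, k_target: int,
         max_maps: int | None = None) -> MicrostateTemplates:
    """Atomize-and-agglomerate hierarchical clustering, polarity invariant.

    Starts from singleton clusters and repeatedly dissolves the cluster
    with the smallest GEV contribution, reassigning each freed map to the
    cluster whose prototype it correlates with most strongly (squared
    correlation, so sign-free).  Prototypes are the dominant eigenvector
    of the member outer-product sum.  ``max_maps`` evenly subsamples the
    input maps beforehand to bound runtime on long recordings.
    """
    maps, gfp = topos.maps, topos.gfp
    if max_maps is not None and topos.n_maps > max_maps:
        pick = np.linspace(0, topos.n_maps - 1, max_maps).round().astype(int)
        maps, gfp = maps[pick], gfp[pick]
    M, C = maps.shape
    if M < k_target:
        raise ParameterError(f"{M} maps < k_target = {k_target}")

    U = _avg_ref(maps.T).T
    norms = np.linalg.norm(U, axis=1)
    if np.any(norms == 0):
        raise ParameterError("zero-variance map in input")
    U = U / norms[:, None]                    # unit-norm centered maps
    gfp2_total = float(np.sum(gfp ** 2))
    if gfp2_total == 0:
        gfp2_total = 1.0

    members: list[list[int]] = [[i] for i in range(M)]
    S = [np.outer(U[i], U[i]) for i in range(M)]
    protos = np.array([_principal_map(s) for s in S])
    pn = protos / np.linalg.norm(protos, axis=1, keepdims=True)

    def contribution(ci: int) -> float:
        mem = members[ci]
        corr = U[mem] @ pn[ci]
        return float(np.sum((gfp[mem] * np.abs(corr)) ** 2)) / gfp2_total

    contrib = np.array([contribution(i) for i in range(M)])
    alive = list(range(M))

    while len(alive) > k_target:
        worst = alive[int(np.argmin(contrib[alive]))]
        freed = members[worst]
        alive.remove(worst)
        corr2 = (U[freed] @ pn[alive].T) ** 2        # freed x alive
        dest = np.argmax(corr2, axis=1)
        changed = set()
        for m, d in zip(freed, dest):
            ci = alive[d]
            members[ci].append(m)
            S[ci] = S[ci] + np.outer(U[m], U[m])
            changed.add(ci)
        for ci in changed:
            protos[ci] = _principal_map(S[ci])
            pn[ci] = protos[ci] / np.linalg.norm(protos[ci])
            contrib[ci] = contribution(ci)

    order = np.argsort(contrib[alive])[::-1]
    alive = [alive[i] for i in order]
    return MicrostateTemplates(
        maps=protos[alive],
        labels=DEFAULT_LABELS[: len(alive)],
        gev=contrib[alive].copy(),
    )


def two_level_templates(per_subject: list[TopographySet],
                        k_subject_range: range | list[int] = range(4, 7),
                        k_group_range: range | list[int] = range(4, 7),
                        max_maps: int | None = 1000,
                        ) -> dict[int, MicrostateTemplates]:
    """First-level AAHC per subject, second-level AAHC over the pooled
    subject mean maps; one template set per group-level k."""
    pooled_maps = []
    for topos in per_subject:
        for k in k_subject_range:
            tmpl = aahc(topos, k, max_maps=max_maps)
            pooled_maps.append(tmpl.maps)
    pooled = np.vstack(pooled_maps)
    pool = TopographySet(maps=pooled, gfp=np.ones(len(pooled)), source="subject means")
    return {kg: aahc(pool, kg) for kg in k_group_range}


# ---------------------------------------------------------------------
# ordering against canonical maps
# ---------------------------------------------------------------------

def canonical_templates(positions: np.ndarray) -> MicrostateTemplates:
    """Four analytic reference maps on given sensor positions (unit sphere,
    x right / y anterior / z up): two oblique dipolar maps (left-posterior
    to right-anterior and its mirror), an anterior-posterior gradient, and
    a fronto-central radial blob.  Used only as a stable ordering anchor."""
    P = np.asarray(positions, dtype=float)
    d_a = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
    d_b = np.array([-1.0, 1.0, 0.0]) / np.sqrt(2)
    d_c = np.array([0.0, 1.0, 0.0])
    r0 = np.array([0.0, 0.45, 0.9])
    r0 /= np.linalg.norm(r0)
    maps = np.stack([
        P @ d_a,
        P @ d_b,
        P @ d_c,
        np.exp(-np.linalg.norm(P - r0, axis=1) ** 2 / 0.8 ** 2),
    ])
    maps = _avg_ref(maps.T).T
    maps *= np.sqrt(maps.shape[1]) / np.linalg.norm(maps, axis=1, keepdims=True)
    return MicrostateTemplates(maps=maps, labels=["A", "B", "C", "D"])


def order_templates(tmpl: MicrostateTemplates,
                    canonical: MicrostateTemplates) -> MicrostateTemplates:
    """Relabel templates by optimal assignment to canonical maps.

    The Hungarian method maximizes the summed absolute spatial
    correlation; surplus templates (k above the canonical count) keep
    fresh labels, ordered by GEV when known.
    """
    K, Kc = tmpl.k, canonical.k
    corr = np.zeros((K, Kc))
    for i in range(K):
        for j in range(Kc):
            corr[i, j] = spatial_corr(tmpl.maps[i], canonical.maps[j])
    rows, cols = linear_sum_assignment(-corr)
    labels: list[str | None] = [None] * K
    for r, c in zip(rows, cols):
        labels[r] = canonical.labels[c]
    surplus = [i for i in range(K) if labels[i] is None]
    if tmpl.gev is not None:
        surplus.sort(key=lambda i: -tmpl.gev[i])
    used = set(canonical.labels)
    fresh = iter(l for l in DEFAULT_LABELS if l not in used)
    for i in surplus:
        labels[i] = next(fresh)
    order = np.argsort([labels[i] for i in range(K)])
    return MicrostateTemplates(
        maps=tmpl.maps[order],
        labels=[labels[i] for i in order],
        gev=None if tmpl.gev is None else tmpl.gev[order],
    )


# ---------------------------------------------------------------------
# backfitting
# ---------------------------------------------------------------------

def backfit(rec: Recording, tmpl: MicrostateTemplates,
            smooth_window_ms: float = 20.0, penalty: float = 1.0,
            ) -> MicrostateSequence:
    """Assign each sample to a template, peak-wise, then smooth.

    GFP-peak maps take the template with the highest absolute spatial
    correlation; every other sample inherits the label of its nearest
    peak (ties to the earlier peak).  Smoothing then absorbs segments
    shorter than ``smooth_window_ms``: a short segment keeps its label
    only if its mean fit beats the best neighboring label's mean fit
    over the same samples by at least ``penalty`` (so penalty 1 means
    unconditional absorption into the better-fitting neighbor).
    """
    eeg = _avg_ref(rec.eeg_data())
    n = eeg.shape[1]
    g = eeg.std(axis=0)

    T = _avg_ref(tmpl.maps.T).T
    T = T / np.linalg.norm(T, axis=1, keepdims=True)
    Xc = eeg - eeg.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(Xc, axis=0)
    xn[xn == 0] = 1.0
    corr_all = np.abs(T @ (Xc / xn))      # K x n

    peaks = np.where((g[1:-1] > g[:-2]) & (g[1:-1] > g[2:]))[0] + 1
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(g))])
    peak_labels = np.argmax(corr_all[:, peaks], axis=0)

    # nearest-peak interpolation, ties to the earlier peak
    labels = np.empty(n, dtype=int)
    pos = np.searchsorted(peaks, np.arange(n))
    left = np.clip(pos - 1, 0, len(peaks) - 1)
    right = np.clip(pos, 0, len(peaks) - 1)
    dl = np.abs(np.arange(n) - peaks[left])
    dr = np.abs(np.arange(n) - peaks[right])
    use_left = dl <= dr
    labels[use_left] = peak_labels[left[use_left]]
    labels[~use_left] = peak_labels[right[~use_left]]

    # temporal smoothing: absorb short segments
    min_len = max(1, int(round(smooth_window_ms / 1000 * rec.rate)))
    for _ in range(n):   # bounded iteration; converges much earlier
        segs = _segments(labels)
        short = [(b - a, a, b, lab) for a, b, lab in segs if b - a < min_len]
        if not short:
            break
        short.sort()
        changed = False
        for _, a, b, lab in short:
            neighbors = []
            if a > 0:
                neighbors.append(labels[a - 1])
            if b < n:
                neighbors.append(labels[b])
            neighbors = [nb for nb in dict.fromkeys(neighbors) if nb != lab]
            if not neighbors:
                continue
            fits = [corr_all[nb, a:b].mean() for nb in neighbors]
            best = neighbors[int(np.argmax(fits))]
            own = corr_all[lab, a:b].mean()
            if own < max(fits) + penalty:
                labels[a:b] = best
                changed = True
        if not changed:
            break

    fit = corr_all[labels, np.arange(n)]
    return MicrostateSequence(labels=labels, rate=rec.rate, gfp=g, fit=fit, k=tmpl.k)


def _segments(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs as (start, stop, label), half-open."""
    n = len(labels)
    out = []
    a = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[a]:
            out.append((a, i, int(labels[a])))
            a = i
    return out


# ---------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------

def metrics(seq: MicrostateSequence,
            labels: list[str] | None = None) -> MicrostateMetrics:
    """Duration, occurrence, coverage and transition probabilities.

    Unassigned samples (label -1) are excluded from the total-time
    denominators and break segment runs without counting as transitions.
    """
    if len(seq.labels) == 0:
        raise ParameterError("empty sequence")
    K = seq.k
    if labels is None:
        labels = DEFAULT_LABELS[:K]
    segs = [(a, b, l) for a, b, l in _segments(seq.labels) if l >= 0]
    ms_per_sample = 1000.0 / seq.rate
    total_assigned_s = sum(b - a for a, b, _ in segs) / seq.rate

    duration = np.zeros(K)
    occurrence = np.zeros(K)
    coverage = np.zeros(K)
    counts = np.zeros((K, K))
    for k in range(K):
        lens = [b - a for a, b, l in segs if l == k]
        if lens:
            duration[k] = np.mean(lens) * ms_per_sample
            occurrence[k] = len(lens) / total_assigned_s
            coverage[k] = sum(lens) / (total_assigned_s * seq.rate) * 100.0
    for (a1, b1, l1), (a2, b2, l2) in zip(segs[:-1], segs[1:]):
        if b1 == a2:           # adjacent runs = a genuine transition
            counts[l1, l2] += 1
    np.fill_diagonal(counts, 0.0)
    row = counts.sum(axis=1, keepdims=True)
    transition = np.divide(counts, row, out=np.zeros_like(counts), where=row > 0)
    return MicrostateMetrics(labels=list(labels), duration_ms=duration,
                             occurrence_hz=occurrence, coverage_pct=coverage,
                             transition=transition)
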