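"""Oligomer classification from molecular brightness and photobleaching.

A membrane-bound particle carrying two mature fluorophores is roughly
twice as bright as a single-fluorophore monomer, so a fixed intensity
threshold (instrument-specific; 8200 A.U. on the reference setup)
separates apparent dimers from monomers.  Stepwise photobleaching gives an
orthogonal readout: a dimer with two mature chromophores bleaches in two
discrete steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "DIMER_THRESHOLD_DEFAULT",
    "BrightnessSample",
    "StepCountResult",
    "dimer_fraction",
    "auto_dimer_threshold",
    "count_bleach_steps",
    "dimer_fraction_timecourse",
    "attachment_vs_equilibrium_brightness",
]

#: reference-instrument particle-intensity threshold for calling a dimer
DIMER_THRESHOLD_DEFAULT = 8200.0


@dataclass
class BrightnessSample:
    """Per-particle intensity snapshot with a fixed dimer threshold."""

    intensities: np.ndarray
    acquisition_window: float = 0.0
    dimer_threshold: float = DIMER_THRESHOLD_DEFAULT

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.intensities = self.intensities[np.isfinite(self.intensities)]


@dataclass
class StepCountResult:
    n_steps: int
    step_times: np.ndarray      # seconds
    step_sizes: np.ndarray      # signed; negative = bleaching

    def __post_init__(self):
        assert self.n_steps == len(self.step_times) == len(self.step_sizes)


def dimer_fraction(sample: BrightnessSample) -> float:
    """Fraction of particles at or above the dimer intensity threshold."""
    n = sample.intensities.size
    if n < 100:
        raise ValueError(f"need >= 100 particles, got {n}")
    return float(np.mean(sample.intensities >= sample.dimer_threshold))


def auto_dimer_threshold(intensities) -> float:
    """Antimode between fitted 1- and 2-fluorophore Gaussian components.

    Fits a two-Gaussian mixture with the second mean constrained to twice
    the first (two independent fluorophores) and returns the intensity at
    which the two weighted components are equally likely.
    """
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x)]
    lo, hi = np.percentile(x, [1, 99])
    grid = np.linspace(lo, hi, 256)
    kde = stats.gaussian_kde(x)(grid)

    def two_gauss(g, w, mu, sd1, sd2):
        return (w * stats.norm.pdf(g, mu, sd1)
                + (1 - w) * stats.norm.pdf(g, 2 * mu, sd2))

    mu0 = np.median(x) * 0.8
    sd0 = x.std() / 2
    popt, _ = curve_fit(two_gauss, grid, kde,
                        p0=[0.6, mu0, sd0, sd0],
                        bounds=([0.01, lo / 2, 1e-6, 1e-6],
                                [0.99, hi, hi, hi]), maxfev=20000)
    w, mu, sd1, sd2 = popt
    between = np.linspace(mu, 2 * mu, 512)
    diff = (w * stats.norm.pdf(between, mu, sd1)
            - (1 - w) * stats.norm.pdf(between, 2 * mu, sd2))
    sign_change = np.nonzero(np.diff(np.sign(diff)))[0]
    if sign_change.size:
        return float(between[sign_change[0]])
    return float(1.5 * mu)


# ---------------------------------------------------------------------------
# change-point step counting
# ---------------------------------------------------------------------------

def _best_split(y: np.ndarray, min_seg: int) -> tuple[int | None, float]:
    """Index minimizing the two-segment RSS, or None if no valid split."""
    n = y.size
    if n < 2 * min_seg:
        return None, 0.0
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csum2 = np.concatenate([[0.0], np.cumsum(y ** 2)])

    def rss(i, j):  # [i, j)
        s, s2, m = csum[j] - csum[i], csum2[j] - csum2[i], j - i
        return s2 - s * s / m

    total = rss(0, n)
    best_k, best_gain = None, 0.0
    for k in range(min_seg, n - min_seg + 1):
        gain = total - rss(0, k) - rss(k, n)
        if gain > best_gain:
            best_k, best_gain = k, gain
    return best_k, best_gain


def _segment(y: np.ndarray, min_seg: int = 2) -> list[int]:
    """Offline binary segmentation with a BIC stopping rule.

    Returns sorted internal breakpoints of the piecewise-constant fit.
    """
    n = y.size
    breaks: list[int] = []

    def bic(bps: list[int]) -> float:
        bounds = [0] + sorted(bps) + [n]
        rss = 0.0
        for i, j in zip(bounds[:-1], bounds[1:]):
            seg = y[i:j]
            rss += float(np.sum((seg - seg.mean()) ** 2))
        k = 2 * len(bps) + 1      # level + location per break, + base level
        return n * np.log(max(rss, 1e-12) / n) + k * np.log(n)

    while True:
        current = bic(breaks)
        best = None
        bounds = [0] + sorted(breaks) + [n]
        for i, j in zip(bounds[:-1], bounds[1:]):
            k, gain = _best_split(y[i:j], min_seg)
            if k is None:
                continue
            cand = sorted(breaks + [i + k])
            b = bic(cand)
            if b < current and (best is None or b < best[0]):
                best = (b, i + k)
        if best is None:
            return sorted(breaks)
        breaks.append(best[1])


def count_bleach_steps(trace, times=None, noise_sd: float = None,
                       min_separation: int = 2) -> StepCountResult:
    """Count discrete intensity change points in a single-particle trace.

    Change points are located by piecewise-constant segmentation (binary
    splitting, BIC stopping) and gated at magnitude >= 3 x ``noise_sd``
    and >= ``min_separation`` frames apart.  Step sizes are signed;
    photobleaching steps are negative.
    """
    y = np.asarray(trace, dtype=float)
    y = y[np.isfinite(y)]
    if y.size < 10:
        raise ValueError("trace must have >= 10 finite points")
    if noise_sd is None or noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if times is None:
        times = np.arange(y.size, dtype=float)
    else:
        times = np.asarray(times, dtype=float)

    breaks = _segment(y)
    bounds = [0] + breaks + [y.size]
    levels = [float(y[i:j].mean()) for i, j in zip(bounds[:-1], bounds[1:])]

    step_times, step_sizes = [], []
    last_kept = -np.inf
    for b, (lv0, lv1) in zip(breaks, zip(levels[:-1], levels[1:])):
        size = lv1 - lv0
        if abs(size) >= 3.0 * noise_sd and b - last_kept >= min_separation:
            step_times.append(times[b])
            step_sizes.append(size)
            last_kept = b
    return StepCountResult(len(step_times), np.asarray(step_times),
                           np.asarray(step_sizes))


# ---------------------------------------------------------------------------
# time-resolved dimer fraction
# ---------------------------------------------------------------------------

def dimer_fraction_timecourse(
    traces: np.ndarray,
    frame_interval: float,
    window: float = 1.0,
    threshold: float = DIMER_THRESHOLD_DEFAULT,
    detect_threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Dimer fraction per acquisition window during photobleaching.

    Per window, particles visible there (window-mean intensity above
    ``detect_threshold``; default half the dimer threshold / 1.5, i.e. a
    one-fluorophore level) are classified against ``threshold``.  New
    arrivals (NaN before their arrival frame) enter the denominator from
    the window in which they appear.
    """
    traces = np.asarray(traces, dtype=float)
    n_frames = traces.shape[1]
    w = max(1, int(round(window / frame_interval)))
    if detect_threshold is None:
        detect_threshold = threshold / 3.0
    t_out, frac_out = [], []
    for start in range(0, n_frames - w + 1, w):
        block = traces[:, start:start + w]
        finite = np.isfinite(block)
        n_fin = finite.sum(axis=1)
        mean_i = np.where(
            n_fin > 0,
            np.where(finite, block, 0.0).sum(axis=1) / np.maximum(n_fin, 1),
            np.nan)
        visible = np.isfinite(mean_i) & (mean_i >= detect_threshold)
        if visible.sum() == 0:
            continue
        t_out.append((start + 0.5 * w) * frame_interval)
        frac_out.append(float(np.mean(mean_i[visible] >= threshold)))
    return np.asarray(t_out), np.asarray(frac_out)


def attachment_vs_equilibrium_brightness(
    tracks, rng=None, n_sample_frames: int = 20,
    threshold: float = DIMER_THRESHOLD_DEFAULT,
) -> tuple[BrightnessSample, BrightnessSample]:
    """First-attachment vs equilibrium brightness samples from tracks.

    The attachment sample takes each track's first-frame intensity (the
    molecular brightness the species arrives with from solution); the
    equilibrium sample pools the intensities of all particles present in
    ``n_sample_frames`` randomly chosen movie frames, so membrane-resident
    oligomers are weighted by occupancy.
    """
    rng = np.random.default_rng(rng)
    first = np.array([tr.intensity[0] for tr in tracks], dtype=float)

    all_frames = np.unique(np.concatenate([tr.frames for tr in tracks]))
    chosen = rng.choice(all_frames, size=min(n_sample_frames,
                                             all_frames.size), replace=False)
    chosen_set = set(int(f) for f in chosen)
    eq = []
    for tr in tracks:
        mask = np.isin(tr.frames, list(chosen_set))
        eq.extend(tr.intensity[mask].tolist())
    return (BrightnessSample(first, dimer_threshold=threshold),
            BrightnessSample(np.asarray(eq), dimer_threshold=threshold))
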