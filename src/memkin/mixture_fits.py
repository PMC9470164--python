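"""Survival and displacement mixture-model fits.

Dwell times are fit in log10(1 - CDF) (log-survival) space to one- or
two-component exponential decays, exactly as the single-molecule
membrane-binding literature does:

    f(t) = e^(-t/tau)                         (single species)
    f(t) = a e^(-t/tau1) + (1-a) e^(-t/tau2)  (two species, tau1 <= tau2)

with alpha the fraction of the fast-dissociating (tau1) component.

Step sizes (per-frame 2D displacements r) are binned at 0.01 um, converted
to probability density, and fit to the Brownian (Rayleigh-form) density

    f(r) = r/(2 D tau) e^(-r^2 / 4 D tau)

or the two-species mixture, with alpha the fraction of the slow (D1)
component and tau the frame interval.

Model selection fits both models and escalates to two components only when
the nested-model F-test is significant at ``f_pvalue`` AND the fitted
mixture is non-degenerate: a two-component fit whose minor fraction is
below ``min_fraction`` or whose components differ by less than a factor
``min_ratio`` collapses to the single-species model.  (A naive R^2 gate on
the log-survival line is insensitive here: the long single-exponential
tail of a well-separated mixture dominates the variance and keeps R^2 high
even when the head is visibly curved.)

Fits are inverse-variance weighted using Poisson counting errors
propagated into the fitted space; this is what makes the fast component of
a dwell mixture recoverable, since uniform weights drown the short-time
bins in the long tail.

An independent maximum-likelihood mixture fit (:func:`fit_dwell_mle`) is
provided as a cross-check; the weighted log-survival least-squares fit is
the default and the procedure of record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DwellFitResult",
    "StepFitResult",
    "fit_dwell",
    "fit_dwell_mle",
    "correct_bleaching",
    "fit_steps",
]


@dataclass
class DwellFitResult:
    n_components: int
    tau1: float
    tau2: float | None
    alpha: float            # fraction of the fast (tau1) component
    n_molecules: int
    fit_quality: float      # R^2 in log10-survival space
    tau_corrected: tuple | None = None

    def __post_init__(self):
        if self.tau1 <= 0 or (self.tau2 is not None and self.tau2 <= 0):
            raise ValueError("tau must be > 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.tau2 is not None and self.tau1 > self.tau2:
            raise ValueError("component order must satisfy tau1 <= tau2")

    def to_dict(self) -> dict:
        return {"n_components": self.n_components, "tau1": self.tau1,
                "tau2": self.tau2, "alpha": self.alpha,
                "N": self.n_molecules, "fit_quality": self.fit_quality,
                "tau_corrected": self.tau_corrected}


@dataclass
class StepFitResult:
    n_components: int
    D1: float
    D2: float | None
    alpha: float            # fraction of the slow (D1) component
    frame_interval: float
    n_steps: int
    fit_quality: float      # R^2 in density space
    at_bound: bool = False

    def __post_init__(self):
        if self.D1 <= 0 or (self.D2 is not None and self.D2 <= 0):
            raise ValueError("D must be > 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.D2 is not None and self.D1 > self.D2:
            raise ValueError("component order must satisfy D1 <= D2")

    def to_dict(self) -> dict:
        return {"n_components": self.n_components, "D1": self.D1,
                "D2": self.D2, "alpha": self.alpha,
                "frame_interval": self.frame_interval,
                "steps": self.n_steps, "fit_quality": self.fit_quality}


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def _f_test(rss1: float, rss2: float, n: int, extra: int, p2: int) -> float:
    """p-value of the nested-model F-test (model 2 has p2 parameters)."""
    df2 = n - p2
    if df2 <= 0 or rss2 <= 0:
        return 0.0
    f = ((rss1 - rss2) / extra) / (rss2 / df2)
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, extra, df2))


# component-degeneracy guards for the two-species fits
_MIN_FRACTION = 0.10
_MIN_RATIO = 2.0


def _degenerate(v1: float, v2: float, alpha: float,
                min_ratio: float = _MIN_RATIO,
                min_fraction: float = _MIN_FRACTION) -> bool:
    lo, hi = (v1, v2) if v1 <= v2 else (v2, v1)
    if hi / lo < min_ratio:
        return True
    minor = min(alpha, 1.0 - alpha)
    return minor <= min_fraction


# ---------------------------------------------------------------------------
# dwell times
# ---------------------------------------------------------------------------

def _survival_points(dwells: np.ndarray, dt: float, min_survival: float):
    """Empirical log-survival binned at the frame interval.

    Dwells below one frame are unobservable, so the curve is fit from the
    second bin onward; points where survival decays below ``min_survival``
    are dropped.  Returns (t, survival, n).
    """
    n = dwells.size
    kmax = int(np.ceil(dwells.max() / dt))
    t = np.arange(1, kmax) * dt
    surv = np.array([(dwells > ti).sum() / n for ti in t])
    keep = surv >= max(min_survival, 2.0 / n)
    t, surv = t[keep], surv[keep]
    # leading bins at survival 1 carry no decay information (left
    # truncation, e.g. a minimum-track-length filter); fit starts one bin
    # past the first decaying point
    start = int(np.argmax(surv < 1.0)) + 1
    return t[start:], surv[start:], n


def _model1_log(t, log_c, tau):
    return log_c - t / (tau * math.log(10.0))


def _model2_log(t, log_c, alpha, tau1, tau2):
    s = alpha * np.exp(-t / tau1) + (1.0 - alpha) * np.exp(-t / tau2)
    return log_c + np.log10(np.clip(s, 1e-300, None))


def fit_dwell(
    dwells,
    frame_interval: float,
    max_components: int = 2,
    f_pvalue: float = 0.01,
    min_survival: float = 1e-3,
) -> DwellFitResult:
    """Fit the dwell-time survival curve in log10(1-CDF) space.

    A free amplitude absorbs the truncation of sub-frame dwells, so the
    decay constants are recovered without bias from the first-bin cut.
    Points are weighted by their Poisson counting error propagated into
    log10 space: sigma_i = sqrt((1-S_i)/(n S_i)) / ln 10.
    """
    dwells = np.asarray(dwells, dtype=float)
    if dwells.size < 50:
        raise ValueError(f"need >= 50 dwells, got {dwells.size}")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    t, surv, n = _survival_points(dwells, frame_interval, min_survival)
    if t.size < 6:
        raise ValueError("too few survival points to fit "
                         "(dwells too short for the frame interval?)")
    y = np.log10(surv)
    sigma = np.sqrt((1.0 - surv) / (n * surv)) / math.log(10.0)
    sigma = np.clip(sigma, 1e-6, None)

    tau0 = float(np.mean(dwells))
    popt1, _ = optimize.curve_fit(_model1_log, t, y, p0=[0.0, tau0],
                                  sigma=sigma, absolute_sigma=True,
                                  maxfev=10000)
    tau_single = float(abs(popt1[1]))
    y1 = _model1_log(t, *popt1)
    rss1 = float(np.sum(((y - y1) / sigma) ** 2))

    single = DwellFitResult(1, tau_single, None, 1.0, dwells.size,
                            _r2(y, y1))
    if max_components == 1:
        return single

    tau_lo = frame_interval / 10.0
    tau_hi = 100.0 * float(np.max(dwells))
    best = None
    for a0 in (0.2, 0.5, 0.8):
        try:
            popt, _ = optimize.curve_fit(
                _model2_log, t, y,
                p0=[popt1[0], a0, 0.5 * tau_single, 2.0 * tau_single],
                bounds=([-2.0, 0.0, tau_lo, tau_lo],
                        [2.0, 1.0, tau_hi, tau_hi]),
                sigma=sigma, absolute_sigma=True, maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum(((y - _model2_log(t, *popt)) / sigma) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        return single
    rss2, popt = best
    if _f_test(rss1, rss2, t.size, 2, 4) >= f_pvalue:
        return single

    _, alpha, tau_a, tau_b = popt
    if tau_a > tau_b:
        tau_a, tau_b = tau_b, tau_a
        alpha = 1.0 - alpha
    if _degenerate(tau_a, tau_b, alpha):
        return single
    y2 = _model2_log(t, *popt)
    return DwellFitResult(2, float(tau_a), float(tau_b), float(alpha),
                          dwells.size, _r2(y, y2))


def fit_dwell_mle(dwells, frame_interval: float,
                  n_components: int = 2, n_iter: int = 2000) -> DwellFitResult:
    """EM maximum-likelihood exponential-mixture fit (cross-check oracle).

    Works on the raw (left-truncated at one frame) dwell sample; the
    truncation is handled by shifting each dwell by the minimum observed
    value, which is exact for exponential mixtures (memorylessness changes
    only the mixing weights, recomputed below).
    """
    dwells = np.asarray(dwells, dtype=float)
    t0 = dwells.min()
    z = dwells - t0
    n = z.size
    if n_components == 1:
        return DwellFitResult(1, float(z.mean()), None, 1.0, n, math.nan)
    tau = np.array([0.5, 2.0]) * max(z.mean(), frame_interval)
    w = np.array([0.5, 0.5])
    for _ in range(n_iter):
        dens = w / tau * np.exp(-np.outer(z, 1.0 / tau))     # (n, 2)
        resp = dens / np.clip(dens.sum(axis=1, keepdims=True), 1e-300, None)
        w_new = resp.mean(axis=0)
        tau_new = (resp * z[:, None]).sum(axis=0) / np.maximum(
            resp.sum(axis=0), 1e-12)
        done = np.allclose(tau_new, tau, rtol=1e-9) and np.allclose(
            w_new, w, rtol=1e-9)
        tau, w = tau_new, w_new
        if done:
            break
    # undo the truncation shift in the weights: observing past t0 favors
    # the slow component by e^(t0/tau_i)
    w_orig = w * np.exp(-t0 / tau)
    w_orig = w_orig / w_orig.sum()
    order = np.argsort(tau)
    tau, w_orig = tau[order], w_orig[order]
    return DwellFitResult(2, float(tau[0]), float(tau[1]), float(w_orig[0]),
                          n, math.nan)


def correct_bleaching(fit: DwellFitResult, tau_bleach: float) -> DwellFitResult:
    """Competing-exponentials bleach correction.

    The observed off-rate is the sum of the true unbinding rate and the
    photobleaching rate, so tau_true = 1 / (1/tau_obs - 1/tau_bleach) per
    component.  Requires tau_obs < tau_bleach.
    """
    if tau_bleach <= 0:
        raise ValueError("tau_bleach must be > 0")

    def _corr(tau_obs: float) -> float:
        if tau_obs >= tau_bleach:
            raise ValueError(
                f"observed dwell tau ({tau_obs:g} s) >= bleaching tau "
                f"({tau_bleach:g} s): unbinding slower than bleaching "
                "cannot be resolved")
        return 1.0 / (1.0 / tau_obs - 1.0 / tau_bleach)

    corrected = (_corr(fit.tau1),
                 _corr(fit.tau2) if fit.tau2 is not None else None)
    return DwellFitResult(fit.n_components, fit.tau1, fit.tau2, fit.alpha,
                          fit.n_molecules, fit.fit_quality,
                          tau_corrected=corrected)


# ---------------------------------------------------------------------------
# step sizes
# ---------------------------------------------------------------------------

def rayleigh_density(r, D: float, tau: float):
    """Brownian 2D step-size density r/(2 D tau) exp(-r^2 / 4 D tau)."""
    r = np.asarray(r, dtype=float)
    return r / (2.0 * D * tau) * np.exp(-(r ** 2) / (4.0 * D * tau))


def _step_hist(steps: np.ndarray, bin_width: float):
    """Probability-density histogram (frequency / bin width) at bin centers."""
    edges = np.arange(0.0, steps.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(steps, bins=edges)
    density = counts / (steps.size * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    # Poisson error on the density
    sigma = np.sqrt(counts[keep]) / (steps.size * bin_width)
    return centers[keep], density[keep], sigma


_D_LO, _D_HI = 1e-6, 100.0


def fit_steps(
    steps,
    frame_interval: float,
    bin_width: float = 0.01,
    max_components: int = 2,
    f_pvalue: float = 0.01,
) -> StepFitResult:
    """Fit the step-size probability-density histogram (bin 0.01 um).

    Trust-region least squares (Poisson-weighted) with multi-start over
    the mixing fraction (alpha in {0.2, 0.5, 0.8}); ties broken by lowest
    residual then lowest component count.  A fit pinned at a parameter
    bound is flagged.
    """
    steps = np.asarray(steps, dtype=float)
    if steps.size < 1000:
        raise ValueError(f"need >= 1000 steps, got {steps.size}")
    if np.all(steps == 0):
        raise ValueError("all steps are zero")
    tau = frame_interval
    r, dens, sigma = _step_hist(steps, bin_width)
    sigma = np.clip(sigma, sigma[sigma > 0].min(), None)
    D_mom = float(np.mean(steps ** 2) / (4.0 * tau))   # moment estimator

    def model1(r_, D):
        return rayleigh_density(r_, D, tau)

    popt1, _ = optimize.curve_fit(model1, r, dens, p0=[D_mom],
                                  sigma=sigma, absolute_sigma=True,
                                  bounds=(_D_LO, _D_HI), maxfev=10000)
    D_single = float(popt1[0])
    y1 = model1(r, D_single)
    rss1 = float(np.sum(((dens - y1) / sigma) ** 2))
    at_bound1 = D_single <= 1.5 * _D_LO or D_single >= 0.99 * _D_HI

    single = StepFitResult(1, D_single, None, 1.0, tau, steps.size,
                           _r2(dens, y1), at_bound=at_bound1)
    if max_components == 1:
        return single

    def model2(r_, a, D1, D2):
        return (a * rayleigh_density(r_, D1, tau)
                + (1.0 - a) * rayleigh_density(r_, D2, tau))

    best = None
    for a0 in (0.2, 0.5, 0.8):
        try:
            popt, _ = optimize.curve_fit(
                model2, r, dens, p0=[a0, 0.4 * D_mom, 2.0 * D_mom],
                bounds=([0.0, _D_LO, _D_LO], [1.0, _D_HI, _D_HI]),
                sigma=sigma, absolute_sigma=True, maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum(((dens - model2(r, *popt)) / sigma) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        return single
    rss2, popt = best
    if _f_test(rss1, rss2, r.size, 2, 3) >= f_pvalue:
        return single

    a, D_a, D_b = popt
    if D_a > D_b:
        D_a, D_b = D_b, D_a
        a = 1.0 - a
    if _degenerate(D_a, D_b, a):
        return single
    y2 = model2(r, *popt)
    at_bound = (D_a <= 1.5 * _D_LO or D_b >= 0.99 * _D_HI)
    return StepFitResult(2, float(D_a), float(D_b), float(a), tau,
                         steps.size, _r2(dens, y2), at_bound=at_bound)
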