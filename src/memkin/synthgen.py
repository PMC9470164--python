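"""Synthetic single-molecule and kinetic data generator.

Emulates the statistical structure of single-molecule TIRF observables on
supported lipid bilayers so every downstream analysis stage is testable
without microscopy data:

* :func:`simulate_tracks` — Poisson membrane arrivals, exponential-mixture
  dwell times, 2D Brownian motion with oligomer-state-dependent diffusivity,
  monomer<->dimer Markov switching, chromophore maturation, photobleaching,
  localization noise and camera-noise intensities.
* :func:`simulate_brightness` — per-particle intensity traces for monomers
  or dimers under stepwise photobleaching.
* :func:`simulate_isotherm` — Hill-cooperative titration tables.
* :func:`simulate_reaction` — deterministic ODE or exact stochastic corral
  simulation of the kinase(-phosphatase) reaction.

All randomness is drawn from per-purpose streams derived from one root
seed, so with a fixed seed every output is bit-identical across runs and
the stages are independently reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from ._gillespie import simulate_corral
from .config import ReactionSimConfig, SimConfig

__all__ = [
    "simulate_tracks",
    "simulate_brightness",
    "simulate_isotherm",
    "simulate_reaction",
    "write_tracks",
    "write_ground_truth",
    "TRACK_COLUMNS",
]

TRACK_COLUMNS = ["TRACK_ID", "FRAME", "POSITION_T",
                 "POSITION_X", "POSITION_Y", "INTENSITY"]

_STREAMS = {"tracks": 1, "brightness": 2, "isotherm": 3, "reaction": 4}


def _rng(seed: int, purpose: str) -> np.random.Generator:
    """Independent child stream per purpose, derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence(seed,
                                                        spawn_key=(_STREAMS[purpose],)))


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def _draw_dwells(rng, cfg: SimConfig, n: int) -> np.ndarray:
    comp = rng.choice(len(cfg.dwell_taus), size=n, p=cfg.dwell_fractions)
    return rng.exponential(np.asarray(cfg.dwell_taus)[comp])


def simulate_tracks(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a single-particle-tracking movie.

    Returns
    -------
    tracks : DataFrame
        Long-format table with TrackMate-style columns
        ``TRACK_ID, FRAME, POSITION_T, POSITION_X, POSITION_Y, INTENSITY``.
        Frames are 1-based; times and positions are seconds and um.
    truth : dict
        Every generating parameter plus per-particle ground truth
        (arrival time, true dwell, bleach draw, maturation, frame count).
    """
    warns = config.validate()
    for w in warns:
        warnings.warn(w, stacklevel=2)
    rng = _rng(config.seed, "tracks")
    dt = config.frame_interval
    t_total = config.n_frames * dt
    n_particles = rng.poisson(config.arrival_rate * config.area * t_total)

    arrivals = rng.uniform(0.0, t_total, size=n_particles)
    x0 = rng.uniform(0.0, config.field_size[0], size=n_particles)
    y0 = rng.uniform(0.0, config.field_size[1], size=n_particles)
    dwells = _draw_dwells(rng, config, n_particles)
    if math.isinf(config.bleach_tau):
        bleach = np.full(n_particles, np.inf)
    else:
        bleach = rng.exponential(config.bleach_tau, size=n_particles)
    mature = rng.random(n_particles) < config.maturation_prob
    lifetimes = np.minimum(dwells, bleach)

    two_state = len(config.diff_coeffs) == 2 and config.dimer_on_rate > 0
    p_on = 1.0 - math.exp(-config.dimer_on_rate * dt) if two_state else 0.0
    p_off = 1.0 - math.exp(-config.dimer_off_rate * dt) if two_state else 0.0

    rows_id, rows_frame, rows_x, rows_y, rows_i = [], [], [], [], []
    n_frames_obs = np.zeros(n_particles, dtype=int)
    tid = 0
    for p in range(n_particles):
        if not mature[p]:
            continue
        a, life = arrivals[p], lifetimes[p]
        # frame j (1-based) samples time (j-1)*dt
        j0 = int(math.ceil(a / dt)) + 1
        j1 = int(math.floor((a + life) / dt)) + 1
        j1 = min(j1, config.n_frames)
        if j1 < j0:
            continue
        nfr = j1 - j0 + 1
        n_frames_obs[p] = nfr
        tid += 1
        frames = np.arange(j0, j1 + 1)

        if not two_state:
            sd = math.sqrt(2.0 * config.diff_coeffs[0] * dt)
            xs = x0[p] + np.concatenate(
                [[0.0], np.cumsum(rng.normal(0.0, sd, nfr - 1))])
            ys = y0[p] + np.concatenate(
                [[0.0], np.cumsum(rng.normal(0.0, sd, nfr - 1))])
            nf = np.ones(nfr)
        else:
            # initial oligomer state: switching equilibrium by default
            # (steady-state imaging; a binder can also join an existing
            # membrane-bound partner on arrival), or forced monomeric
            # arrival via initial_dimer_prob=0
            p_dimer0 = config.initial_dimer_prob
            if p_dimer0 is None:
                p_dimer0 = config.dimer_on_rate / (config.dimer_on_rate
                                                   + config.dimer_off_rate)
            state = 1 if rng.random() < p_dimer0 else 0
            xs = np.empty(nfr)
            ys = np.empty(nfr)
            nf = np.empty(nfr)
            x, y = x0[p], y0[p]
            for i in range(nfr):
                xs[i], ys[i] = x, y
                nf[i] = 2.0 if state == 1 else 1.0
                sd = math.sqrt(2.0 * config.diff_coeffs[state] * dt)
                x += rng.normal(0.0, sd)
                y += rng.normal(0.0, sd)
                if state == 0 and rng.random() < p_on:
                    state = 1
                elif state == 1 and rng.random() < p_off:
                    state = 0
        xs_obs = xs + rng.normal(0.0, config.localization_sigma, nfr)
        ys_obs = ys + rng.normal(0.0, config.localization_sigma, nfr)
        inten = nf * config.monomer_intensity_mean + rng.normal(
            0.0, config.monomer_intensity_sd, nfr)

        rows_id.append(np.full(nfr, tid))
        rows_frame.append(frames)
        rows_x.append(xs_obs)
        rows_y.append(ys_obs)
        rows_i.append(inten)

    if tid == 0:
        tracks = pd.DataFrame({c: [] for c in TRACK_COLUMNS})
    else:
        frame_all = np.concatenate(rows_frame)
        tracks = pd.DataFrame({
            "TRACK_ID": np.concatenate(rows_id).astype(int),
            "FRAME": frame_all.astype(int),
            "POSITION_T": (frame_all - 1) * dt,
            "POSITION_X": np.concatenate(rows_x),
            "POSITION_Y": np.concatenate(rows_y),
            "INTENSITY": np.concatenate(rows_i),
        })

    truth = {
        "config": config.to_dict(),
        "warnings": warns,
        "n_particles": int(n_particles),
        "n_tracks": int(tid),
        "arrival_time": arrivals.tolist(),
        "true_dwell": dwells.tolist(),
        "bleach_draw": [None if math.isinf(b) else float(b) for b in bleach],
        "mature": mature.tolist(),
        "n_frames_observed": n_frames_obs.tolist(),
    }
    return tracks, truth


def write_tracks(tracks: pd.DataFrame, path: str | Path) -> None:
    tracks.to_csv(path, index=False, columns=TRACK_COLUMNS)


def write_ground_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# brightness
# ---------------------------------------------------------------------------

def simulate_brightness(
    config: SimConfig,
    oligomer_state: Literal["monomer", "dimer"] = "dimer",
    n_particles: int = 1000,
    observe_bleaching: bool = True,
    arrival_window: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-particle intensity traces under (optional) stepwise bleaching.

    Each dimer carries two fluorophores, each independently mature with
    ``maturation_prob`` and bleaching with rate 1/``bleach_tau`` from
    illumination start.  Per-frame intensity is (live mature fluorophores)
    x monomer intensity plus Gaussian camera noise.  If ``arrival_window``
    > 0, particle arrival times are uniform in it and frames before
    arrival are NaN (new binding events during acquisition).

    Returns (traces [n_particles x n_frames], truth table).
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    rng = _rng(config.seed, "brightness")
    n_fluor = 2 if oligomer_state == "dimer" else 1
    dt = config.frame_interval
    nfr = config.n_frames
    t_frames = np.arange(nfr) * dt

    mature = rng.random((n_particles, n_fluor)) < config.maturation_prob
    if observe_bleaching and not math.isinf(config.bleach_tau):
        bleach_t = rng.exponential(config.bleach_tau, (n_particles, n_fluor))
    else:
        bleach_t = np.full((n_particles, n_fluor), np.inf)
    if arrival_window > 0:
        t_arr = rng.uniform(0.0, arrival_window, n_particles)
    else:
        t_arr = np.zeros(n_particles)

    # live fluorophores at each frame (bleach clock starts at arrival)
    rel_t = t_frames[None, :] - t_arr[:, None]            # (n, nfr)
    live = (
        mature[:, None, :]
        & (rel_t[:, :, None] < bleach_t[:, None, :])
    ).sum(axis=2)
    traces = live * config.monomer_intensity_mean + rng.normal(
        0.0, config.monomer_intensity_sd, (n_particles, nfr))
    traces[rel_t < 0] = np.nan

    truth = pd.DataFrame({
        "particle_id": np.arange(n_particles),
        "n_mature": mature.sum(axis=1),
        "arrival_time": t_arr,
        "first_bleach": bleach_t.min(axis=1),
        "last_bleach": bleach_t.max(axis=1),
    })
    return traces, truth


# ---------------------------------------------------------------------------
# isotherm
# ---------------------------------------------------------------------------

def hill(conc, bmax: float, kd: float, n_h: float):
    """Concerted-cooperativity (Hill) isotherm: Bmax c^n / (Kd^n + c^n)."""
    conc = np.asarray(conc, dtype=float)
    cn = conc ** n_h
    return bmax * cn / (kd ** n_h + cn)


def simulate_isotherm(
    bmax: float, kd: float, n_h: float, concs,
    noise_cv: float = 0.0, seed: int = 0,
) -> pd.DataFrame:
    """Titration table of solution concentration vs membrane surface density.

    density_i = Hill(c_i) * (1 + eps), eps ~ N(0, noise_cv); clipped at 0.
    """
    if kd <= 0 or n_h <= 0:
        raise ValueError("Kd and n_H must be > 0")
    rng = _rng(seed, "isotherm")
    concs = np.asarray(concs, dtype=float)
    dens = hill(concs, bmax, kd, n_h)
    if noise_cv > 0:
        dens = dens * (1.0 + rng.normal(0.0, noise_cv, concs.size))
    return pd.DataFrame({"conc_nM": concs,
                         "density": np.clip(dens, 0.0, None)})


# ---------------------------------------------------------------------------
# reaction
# ---------------------------------------------------------------------------

@dataclass
class ReactionTrace:
    """A product time series for one membrane field or corral.

    ``P`` is the product surface density (lipids/um^2), ``S0`` the total
    PIP lipid density; ``E`` an optional kinase surface density series and
    ``n_kinase`` the raw stochastic copy-number trace.
    """

    t: np.ndarray
    P: np.ndarray
    S0: float
    E: np.ndarray | None = None
    n_kinase: np.ndarray | None = None

    @property
    def x(self) -> np.ndarray:
        return self.P / self.S0

    def to_frame(self) -> pd.DataFrame:
        d = {"t_s": self.t, "P_density": self.P}
        if self.E is not None:
            d["E_density"] = self.E
        return pd.DataFrame(d)


def reaction_rhs(x: float, k_coeffs, phosphatase_coeffs) -> float:
    """dx/dt = k(x)(1-x) - (p0 + p1(1-x)) x."""
    k0, k1, k2 = k_coeffs
    p0, p1 = phosphatase_coeffs
    return (k0 + k1 * x + k2 * x * x) * (1.0 - x) - (p0 + p1 * (1.0 - x)) * x


def simulate_reaction(
    config: ReactionSimConfig,
    mode: Literal["deterministic", "stochastic"] = "deterministic",
) -> ReactionTrace:
    """Integrate or stochastically simulate the corral reaction.

    Deterministic mode solves the ODE above; stochastic mode runs the exact
    event-driven simulation over {kinase arrival, departure, single-lipid
    phosphorylation, single-lipid dephosphorylation} (see
    :mod:`memkin._gillespie`).
    """
    t_rec = np.arange(0.0, config.t_end + 1e-9, config.dt_record)
    if mode == "deterministic":
        sol = solve_ivp(
            lambda t, y: [reaction_rhs(min(max(y[0], 0.0), 1.0),
                                       config.k_coeffs,
                                       config.phosphatase_coeffs)],
            (0.0, config.t_end), [config.x0], t_eval=t_rec,
            method="LSODA", rtol=1e-9, atol=1e-12)
        x = np.clip(sol.y[0], 0.0, 1.0)
        return ReactionTrace(t=sol.t, P=x * config.S0, S0=config.S0)
    if mode != "stochastic":
        raise ValueError("mode must be 'deterministic' or 'stochastic'")

    if config.lipid_count < 100:
        raise ValueError(
            f"stochastic mode requires S0*corral_area >= 100 lipids "
            f"(got {config.lipid_count})")
    lam = config.kinase_kon * config.kinase_solution_conc * config.corral_area
    n_p2_0 = int(round(config.x0 * config.lipid_count))
    t, x, n_kin = simulate_corral(
        seed=config.seed, lipid_count=config.lipid_count, n_p2_0=n_p2_0,
        k_coeffs=config.k_coeffs,
        phosphatase_coeffs=config.phosphatase_coeffs,
        lam_arrive=lam, dwell_tau=config.kinase_dwell_tau,
        t_end=config.t_end, dt_record=config.dt_record,
        recruitment_coupling=config.recruitment_coupling)
    E = n_kin / config.corral_area
    return ReactionTrace(t=t, P=x * config.S0, S0=config.S0,
                         E=E, n_kinase=n_kin)
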