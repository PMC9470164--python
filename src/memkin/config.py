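"""Simulation configuration objects.

Two configs drive the synthetic-data generator: :class:`SimConfig` for
single-molecule TIRF observables (membrane binding, diffusion, brightness)
and :class:`ReactionSimConfig` for the kinase reaction in a membrane field
or corral.  Both are plain dataclasses with explicit validation and YAML
round-trip helpers, so configs can be versioned next to the data they
produced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

__all__ = ["SimConfig", "ReactionSimConfig", "load_config", "dump_config"]


@dataclass
class SimConfig:
    """Parameters of the single-molecule membrane-binding simulation.

    Defaults reflect the dilute-labeled lipid-kinase imaging conditions the
    analyses were designed for: ~50 ms frames, sub-second mean dwell,
    D ~ 0.15 um^2/s for the monomeric kinase, ~80% chromophore maturation
    and a ~27 s photobleaching time constant for the stable dye.

    Parameters
    ----------
    seed : int
        Root seed.  Independent per-purpose streams (tracks, brightness,
        isotherm, reaction) are derived from it, so each stage is
        reproducible on its own.
    frame_interval : float
        Camera frame interval in seconds.
    n_frames : int
        Movie length in frames.
    field_size : (float, float)
        Field of view in um (x, y), origin at a corner.
    arrival_rate : float
        Membrane association rate in particles/um^2/s.
    dwell_taus, dwell_fractions : sequences
        Exponential dwell-time mixture (seconds; fractions sum to 1).
    diff_coeffs : sequence
        Diffusion coefficients in um^2/s keyed by oligomer state:
        ``[D_monomer]`` or ``[D_monomer, D_dimer]``.
    dimer_on_rate, dimer_off_rate : float
        Monomer<->dimer two-state switching rates (1/s).  ``dimer_on_rate=0``
        gives a purely monomeric (dimerization-deficient) species.
    maturation_prob : float
        Probability that a fluorescent-protein chromophore is mature
        (fluorescent) at all.
    bleach_tau : float
        Per-fluorophore photobleaching time constant (s); ``math.inf``
        disables bleaching.
    monomer_intensity_mean, monomer_intensity_sd : float
        Single-fluorophore camera intensity (arbitrary units) and per-frame
        Gaussian noise.
    localization_sigma : float
        Per-axis localization error in um, added independently every frame.
    """

    seed: int = 0
    frame_interval: float = 0.05
    n_frames: int = 1000
    field_size: tuple[float, float] = (40.0, 40.0)
    arrival_rate: float = 0.05
    dwell_taus: Sequence[float] = (0.453,)
    dwell_fractions: Sequence[float] = (1.0,)
    diff_coeffs: Sequence[float] = (0.148,)
    dimer_on_rate: float = 0.0
    dimer_off_rate: float = 0.5
    maturation_prob: float = 0.8
    bleach_tau: float = 26.7
    monomer_intensity_mean: float = 5500.0
    monomer_intensity_sd: float = 900.0
    localization_sigma: float = 0.02
    #: probability a particle is dimeric at its first observed frame;
    #: None = switching equilibrium on/(on+off) (steady-state imaging),
    #: 0.0 = all particles arrive from solution as monomers
    initial_dimer_prob: float | None = None

    def __post_init__(self) -> None:
        self.dwell_taus = tuple(float(t) for t in self.dwell_taus)
        self.dwell_fractions = tuple(float(f) for f in self.dwell_fractions)
        self.diff_coeffs = tuple(float(d) for d in self.diff_coeffs)
        self.field_size = tuple(float(v) for v in self.field_size)
        self.validate()

    def validate(self) -> list[str]:
        """Raise on invalid parameters; return a list of warning strings."""
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if any(v <= 0 for v in self.field_size):
            raise ValueError("field_size must be positive")
        if self.arrival_rate < 0:
            raise ValueError("arrival_rate must be >= 0")
        if len(self.dwell_taus) != len(self.dwell_fractions):
            raise ValueError("dwell_taus and dwell_fractions length mismatch")
        if any(t <= 0 for t in self.dwell_taus):
            raise ValueError("dwell_taus must be > 0")
        if abs(sum(self.dwell_fractions) - 1.0) > 1e-9:
            raise ValueError("dwell_fractions must sum to 1 within 1e-9")
        if any(f < 0 for f in self.dwell_fractions):
            raise ValueError("dwell_fractions must be >= 0")
        if not self.diff_coeffs or any(d <= 0 for d in self.diff_coeffs):
            raise ValueError("diff_coeffs must be positive and non-empty")
        if len(self.diff_coeffs) > 2:
            raise ValueError("diff_coeffs supports at most two states "
                             "(monomer, dimer)")
        if self.dimer_on_rate < 0 or self.dimer_off_rate <= 0:
            raise ValueError("dimer rates must be >= 0 (off rate > 0)")
        if not 0.0 <= self.maturation_prob <= 1.0:
            raise ValueError("maturation_prob must be in [0, 1]")
        if self.bleach_tau <= 0:
            raise ValueError("bleach_tau must be > 0 (use math.inf to disable)")
        if self.monomer_intensity_mean <= 0 or self.monomer_intensity_sd < 0:
            raise ValueError("intensity parameters must be positive")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be >= 0")
        if self.initial_dimer_prob is not None and not (
                0.0 <= self.initial_dimer_prob <= 1.0):
            raise ValueError("initial_dimer_prob must be in [0, 1] or None")
        warnings: list[str] = []
        if self.frame_interval >= min(self.dwell_taus) / 5.0:
            warnings.append(
                "undersampling: frame_interval >= min(dwell_tau)/5; "
                "short dwells will be poorly resolved"
            )
        return warnings

    @property
    def area(self) -> float:
        return self.field_size[0] * self.field_size[1]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dwell_taus"] = list(self.dwell_taus)
        d["dwell_fractions"] = list(self.dwell_fractions)
        d["diff_coeffs"] = list(self.diff_coeffs)
        d["field_size"] = list(self.field_size)
        if math.isinf(d["bleach_tau"]):
            d["bleach_tau"] = ".inf"
        return d


@dataclass
class ReactionSimConfig:
    """Parameters of the kinase-phosphatase reaction simulation.

    The reaction coordinate is x = product / total PIP lipid.  Kinase
    catalysis follows dx/dt = k(x)(1-x) with k(x) = k0 + k1 x + k2 x^2;
    the opposing phosphatase removes product at (p0 + p1(1-x)) x (its
    feedback is driven by product binding of the substrate-regenerating
    species, i.e. by 1-x).

    ``S0`` is the total PIP lipid surface density (default 55,555
    lipids/um^2: 4 mol% at a 0.72 nm^2 lipid footprint).  In stochastic
    mode individual lipids in a corral of ``corral_area`` are converted by
    discrete events, and kinase copies arrive at
    ``kinase_kon * kinase_solution_conc * corral_area`` per second and
    depart at 1/``kinase_dwell_tau`` each.
    """

    seed: int = 0
    S0: float = 55_555.0
    k_coeffs: tuple[float, float, float] = (0.001, 0.02, 0.3)
    phosphatase_coeffs: tuple[float, float] = (0.0, 0.0)
    corral_area: float = 25.0
    kinase_kon: float = 0.02
    kinase_solution_conc: float = 10.0
    kinase_dwell_tau: float = 2.0
    dt_record: float = 2.0
    t_end: float = 600.0
    x0: float = 0.0
    recruitment_coupling: float = 0.0

    def __post_init__(self) -> None:
        self.k_coeffs = tuple(float(k) for k in self.k_coeffs)
        self.phosphatase_coeffs = tuple(float(p) for p in self.phosphatase_coeffs)
        self.validate()

    def validate(self) -> None:
        if self.S0 <= 0:
            raise ValueError("S0 must be > 0")
        if len(self.k_coeffs) != 3 or any(k < 0 for k in self.k_coeffs):
            raise ValueError("k_coeffs must be three non-negative numbers")
        if len(self.phosphatase_coeffs) != 2 or any(
            p < 0 for p in self.phosphatase_coeffs
        ):
            raise ValueError("phosphatase_coeffs must be two non-negative numbers")
        if self.corral_area <= 0:
            raise ValueError("corral_area must be > 0")
        if self.kinase_kon < 0 or self.kinase_solution_conc < 0:
            raise ValueError("kinase arrival parameters must be >= 0")
        if self.kinase_dwell_tau <= 0:
            raise ValueError("kinase_dwell_tau must be > 0")
        if self.dt_record <= 0 or self.t_end <= 0:
            raise ValueError("dt_record and t_end must be > 0")
        if not 0.0 <= self.x0 <= 1.0:
            raise ValueError("x0 must be in [0, 1]")
        if self.recruitment_coupling < 0:
            raise ValueError("recruitment_coupling must be >= 0")

    @property
    def lipid_count(self) -> int:
        return int(round(self.S0 * self.corral_area))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_coeffs"] = list(self.k_coeffs)
        d["phosphatase_coeffs"] = list(self.phosphatase_coeffs)
        return d


_KINDS = {"tracks": SimConfig, "brightness": SimConfig,
          "isotherm": SimConfig, "reaction": ReactionSimConfig}


def load_config(path: str | Path, kind: str = "tracks"):
    """Load a :class:`SimConfig` or :class:`ReactionSimConfig` from YAML."""
    cls = _KINDS.get(kind)
    if cls is None:
        raise ValueError(f"unknown config kind {kind!r}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "bleach_tau" in raw and raw["bleach_tau"] in (".inf", "inf", None):
        raw["bleach_tau"] = math.inf
    return cls(**raw)


def dump_config(cfg: SimConfig | ReactionSimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
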