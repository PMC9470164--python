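"""Surface-density calibration and cooperative binding isotherms.

Fluorescence intensity is converted to absolute molecules/um^2 via a
lipid-dye standard curve: membranes doped with known mole fractions of a
calibrated fluorescent lipid give intensity-vs-density standards, and a
solution-brightness scaling factor corrects for the brightness difference
between the standard dye and the protein label.  Calibrated isotherms are
fit with the concerted-cooperativity (Hill) model

    rho(c) = Bmax c^nH / (Kd^nH + c^nH).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model
from scipy import stats

from .synthgen import hill

__all__ = [
    "AREA_PER_LIPID_NM2",
    "lipid_density",
    "CalibrationCurve",
    "build_calibration",
    "BindingIsotherm",
    "fit_hill",
]

#: DOPC lipid footprint used for mole-fraction -> density conversion (nm^2)
AREA_PER_LIPID_NM2 = 0.72


def lipid_density(mole_fraction: float,
                  area_per_lipid: float = AREA_PER_LIPID_NM2) -> float:
    """Lipids/um^2 at a given mole fraction of the target lipid.

    Uses the total-composition-per-membrane-area convention (no leaflet
    factor of two): density = mole_fraction / area_per_lipid.  At 4 mol%
    and 0.72 nm^2 per lipid this gives 55,555 lipids/um^2.
    """
    if not 0.0 <= mole_fraction <= 1.0:
        raise ValueError("mole_fraction must be in [0, 1]")
    if area_per_lipid <= 0:
        raise ValueError("area_per_lipid must be > 0")
    return mole_fraction / (area_per_lipid * 1e-6)   # nm^2 -> um^2


@dataclass
class CalibrationCurve:
    """Linear intensity-vs-density standard with a dye-brightness scale.

    density(I) = (I - intercept) / (slope * scaling_factor), where
    scaling_factor = probe solution slope / standard solution slope.
    """

    standard_densities: np.ndarray
    standard_intensities: np.ndarray
    slope: float
    intercept: float
    scaling_factor: float = 1.0

    def density(self, intensity):
        return (np.asarray(intensity, dtype=float) - self.intercept) / (
            self.slope * self.scaling_factor)

    def intensity(self, density):
        return (np.asarray(density, dtype=float)
                * self.slope * self.scaling_factor + self.intercept)

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "scaling_factor": self.scaling_factor,
                "standard_densities": list(self.standard_densities),
                "standard_intensities": list(self.standard_intensities)}


def build_calibration(
    standard_densities,
    standard_intensities,
    probe_solution_slope: float | None = None,
    standard_solution_slope: float | None = None,
) -> CalibrationCurve:
    """Least-squares standard line plus the solution-brightness scaling.

    The intercept is fit, not forced through zero (background fluorescence
    exists).  If the two solution slopes are omitted the dyes are assumed
    identical (scaling factor 1).
    """
    dens = np.asarray(standard_densities, dtype=float)
    inten = np.asarray(standard_intensities, dtype=float)
    if dens.size < 3:
        raise ValueError("need >= 3 standard points")
    order = np.argsort(dens)
    if not np.all(np.diff(inten[order]) > 0):
        raise ValueError("standards must be monotone in density")
    res = stats.linregress(dens, inten)
    if res.slope <= 0:
        raise ValueError("standard slope must be > 0")
    if probe_solution_slope is None or standard_solution_slope is None:
        sf = 1.0
    else:
        sf = probe_solution_slope / standard_solution_slope
        if sf <= 0:
            raise ValueError("scaling factor must be > 0")
    return CalibrationCurve(dens, inten, float(res.slope),
                            float(res.intercept), float(sf))


@dataclass
class BindingIsotherm:
    """Titration data with fitted concerted-cooperativity parameters."""

    concentrations: np.ndarray
    densities: np.ndarray
    Bmax: float
    Kd: float
    n_H: float
    stderr: dict = field(default_factory=dict)
    pip2_fraction: float | None = None
    extrapolated: bool = False

    def predicted(self, conc=None):
        c = self.concentrations if conc is None else np.asarray(conc)
        return hill(c, self.Bmax, self.Kd, self.n_H)

    def to_dict(self) -> dict:
        return {"Bmax": self.Bmax, "Kd": self.Kd, "n_H": self.n_H,
                "stderr": self.stderr, "pip2_fraction": self.pip2_fraction,
                "extrapolated": self.extrapolated}


def fit_hill(concentrations, densities, sd=None,
             pip2_fraction: float | None = None) -> BindingIsotherm:
    """Weighted least-squares Hill fit with parameter standard errors.

    Weights are inverse-variance when replicate SDs are provided, else
    uniform.  A fit whose data never reach 70% of the fitted Bmax is
    flagged as extrapolated.
    """
    c = np.asarray(concentrations, dtype=float)
    rho = np.asarray(densities, dtype=float)
    if c.size < 5:
        raise ValueError("need >= 5 concentrations")
    model = Model(hill, independent_vars=["conc"])
    params = model.make_params(
        bmax=dict(value=float(rho.max()), min=1e-12),
        kd=dict(value=float(np.median(c[c > 0])) or 1.0, min=1e-12),
        n_h=dict(value=1.5, min=1e-3, max=20.0),
    )
    weights = None
    if sd is not None:
        sd = np.asarray(sd, dtype=float)
        weights = 1.0 / np.clip(sd, np.finfo(float).tiny, None)
    out = model.fit(rho, params, conc=c, weights=weights)
    bmax = float(out.params["bmax"].value)
    err = {k: (float(out.params[k].stderr)
               if out.params[k].stderr is not None else None)
           for k in ("bmax", "kd", "n_h")}
    return BindingIsotherm(
        concentrations=c, densities=rho, Bmax=bmax,
        Kd=float(out.params["kd"].value), n_H=float(out.params["n_h"].value),
        stderr=err, pip2_fraction=pip2_fraction,
        extrapolated=bool(rho.max() < 0.7 * bmax))
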