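#!/usr/bin/env python
"""Single-molecule membrane binding: dwell times and diffusion.

Simulates single-particle tracking movies at the two kinase-density
regimes, runs the full filter -> extract -> mixture-fit pipeline, applies
the photobleaching correction, and writes a summary table of the
fitted binding parameters.

Dilute regime: monomeric binding, single-exponential dwell (~0.45 s),
one diffusive species (~0.148 um^2/s).  Dense regime: membrane-mediated
dimerization produces a second, long-dwelling (~2 s) and slow-diffusing
(~0.043 um^2/s) population.
"""

from pathlib import Path

import pandas as pd

from memkin import (
    SimConfig,
    correct_bleaching,
    extract_dwells,
    extract_steps,
    filter_tracks,
    fit_dwell,
    fit_steps,
    simulate_tracks,
    tracks_from_frame,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
TAU_BLEACH = 26.7
DT = 0.05

CONDITIONS = {
    "dilute_monomer": dict(
        arrival_rate=0.035, dwell_taus=(0.453,), dwell_fractions=(1.0,),
        diff_coeffs=(0.148,)),
    "dense_dimerizing": dict(
        arrival_rate=0.03, dwell_taus=(0.787, 2.08),
        dwell_fractions=(0.70, 0.30), diff_coeffs=(0.142, 0.043),
        dimer_on_rate=0.851, dimer_off_rate=0.5),
}


def run_condition(name: str, seed: int, **kw) -> dict:
    cfg = SimConfig(seed=seed, frame_interval=DT, n_frames=5000,
                    field_size=(40.0, 40.0), bleach_tau=TAU_BLEACH,
                    maturation_prob=1.0, localization_sigma=0.01, **kw)
    table, _ = simulate_tracks(cfg)
    kept, report = filter_tracks(tracks_from_frame(table), cfg.n_frames,
                                 cfg.field_size)
    dwells = extract_dwells(kept, DT)
    dfit = correct_bleaching(fit_dwell(dwells, DT), TAU_BLEACH)
    steps, n_gapped = extract_steps(kept)
    sfit = fit_steps(steps, DT)
    print(f"[{name}] {report.n_input} tracks -> {report.n_output} after "
          f"filters; {dfit.n_components}-component dwell fit, "
          f"{sfit.n_components}-component step fit")
    return {
        "condition": name,
        "N": dfit.n_molecules,
        "tau1_s": round(dfit.tau_corrected[0], 3),
        "tau2_s": (round(dfit.tau_corrected[1], 3)
                   if dfit.n_components == 2 else None),
        "dwell_alpha": round(dfit.alpha, 3),
        "steps": sfit.n_steps,
        "D1_um2_s": round(sfit.D1, 4),
        "D2_um2_s": round(sfit.D2, 4) if sfit.n_components == 2 else None,
        "step_alpha": round(sfit.alpha, 3),
    }


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = [run_condition(name, seed=100 + i, **kw)
            for i, (name, kw) in enumerate(CONDITIONS.items())]
    df = pd.DataFrame(rows)
    out = RESULTS / "single_molecule_binding_fits.csv"
    df.to_csv(out, index=False)
    print(df.to_string(index=False))
    print(f"\nDense-regime binding shows the dimerization signature: a "
          f"second dwell component and a slow diffusive state.\n-> {out}")


if __name__ == "__main__":
    main()
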