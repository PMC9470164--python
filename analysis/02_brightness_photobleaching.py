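#!/usr/bin/env python
"""Oligomer brightness and stepwise photobleaching.

A constitutive dimer carrying two fluorescent-protein tags is limited by
chromophore maturation (~80%): among detectable particles, only
p^2/(1-(1-p)^2) = 67% show two-fluorophore brightness.  Under continuous
illumination the two-visible fraction decays as the conditional survival
e^(-2t/tau_b) / (2e^(-t/tau_b) - e^(-2t/tau_b)), and individual dimers
bleach in two discrete steps.
"""

import json
from pathlib import Path

import numpy as np

from memkin import SimConfig, count_bleach_steps, dimer_fraction_timecourse
from memkin import simulate_brightness

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    # maturation-limited two-visible fraction
    cfg = SimConfig(seed=201, maturation_prob=0.8, n_frames=3)
    _, truth = simulate_brightness(cfg, "dimer", 100_000,
                                   observe_bleaching=False)
    nm = truth.n_mature.to_numpy()
    frac_two = float((nm == 2).sum() / (nm >= 1).sum())
    print(f"two-visible fraction among detectable dimers (p=0.8): "
          f"{frac_two:.4f} (binomial expectation 0.6667)")

    # bleaching time course of the dimer fraction
    cfg_b = SimConfig(seed=202, maturation_prob=1.0, bleach_tau=5.0,
                      n_frames=200, monomer_intensity_sd=300.0)
    traces, _ = simulate_brightness(cfg_b, "dimer", 20_000,
                                    observe_bleaching=True)
    t, frac = dimer_fraction_timecourse(traces, cfg_b.frame_interval,
                                        window=1.0)
    s = np.exp(-t / 5.0)
    analytic = s ** 2 / (2 * s - s ** 2)
    dev = float(np.max(np.abs(frac - analytic)))
    print(f"dimer-fraction decay vs conditional-survival curve: "
          f"max deviation {dev:.3f} over {t.size} windows")

    # stepwise photobleaching
    cfg_s = SimConfig(seed=203, maturation_prob=1.0, bleach_tau=3.0,
                      n_frames=400, monomer_intensity_sd=550.0)
    traces_s, _ = simulate_brightness(cfg_s, "dimer", 500,
                                      observe_bleaching=True)
    counts = [count_bleach_steps(tr, noise_sd=550.0).n_steps
              for tr in traces_s]
    frac_two_step = float(np.mean(np.asarray(counts) == 2))
    print(f"dimer traces photobleaching in exactly two steps: "
          f"{100 * frac_two_step:.1f}%")

    out = RESULTS / "brightness_summary.json"
    out.write_text(json.dumps({
        "two_visible_fraction_detectable": round(frac_two, 4),
        "timecourse_max_dev_from_analytic": round(dev, 4),
        "fraction_two_step_bleaching": round(frac_two_step, 3),
        "timecourse": {"t_s": t.tolist(),
                       "dimer_fraction": frac.tolist()},
    }, indent=2) + "\n")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
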