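"""Exact event-driven (Gillespie) kernel for the corral reaction.

State: (n_P2, N) — product lipid count and membrane-bound kinase copies in
one corral of S lipids.  Events and propensities:

* kinase arrival      : lam_arrive                     (solution-coupled)
* kinase departure    : N / dwell_tau
* phosphorylation     : (N / N_ss) * k(x) * (S - n_P2)
* dephosphorylation   : (p0 + p1*(1 - x)) * n_P2

with x = n_P2 / S and k(x) = k0 + k1 x + k2 x^2.  The N/N_ss scaling makes
the mean-field limit equal the deterministic ODE dx/dt = k(x)(1-x) -
(p0 + p1(1-x))x while kinase copy-number fluctuations modulate the rate.
All propensities are constant between events, so the direct method is exact.

Compiled with numba; the pure shape of the loop (one uniform pair per
event) keeps multi-million-event ensembles tractable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_corral"]


@njit(cache=True)
def _kernel(seed, S, n_p2_0, k0, k1, k2, p0, p1,
            lam_arrive, dep_rate, n_ss, coupling,
            t_end, dt_rec):  # pragma: no cover
    np.random.seed(seed)
    n_rec = int(t_end / dt_rec) + 1
    x_rec = np.empty(n_rec, dtype=np.float64)
    n_rec_arr = np.empty(n_rec, dtype=np.int64)

    n_p2 = n_p2_0
    # start the kinase pool at its stationary mean (Poisson) so ensembles
    # equilibrate immediately; 0 if there is no arrival flux
    if lam_arrive > 0.0 and n_ss > 0.0:
        n_kin = np.random.poisson(n_ss)
    else:
        n_kin = 0

    t = 0.0
    i_rec = 0
    while True:
        x = n_p2 / S
        a_arr = lam_arrive * (1.0 + coupling * x)
        a_dep = n_kin * dep_rate
        if n_ss > 0.0:
            a_phos = (n_kin / n_ss) * (k0 + k1 * x + k2 * x * x) * (S - n_p2)
        else:
            a_phos = 0.0
        a_dephos = (p0 + p1 * (1.0 - x)) * n_p2
        a_tot = a_arr + a_dep + a_phos + a_dephos

        if a_tot <= 0.0:
            # frozen state: fill remaining records and stop
            while i_rec < n_rec:
                x_rec[i_rec] = x
                n_rec_arr[i_rec] = n_kin
                i_rec += 1
            break

        dt = -np.log(np.random.random()) / a_tot
        t_next = t + dt
        while i_rec < n_rec and i_rec * dt_rec <= t_next:
            x_rec[i_rec] = n_p2 / S
            n_rec_arr[i_rec] = n_kin
            i_rec += 1
        if i_rec >= n_rec:
            break
        t = t_next

        u = np.random.random() * a_tot
        if u < a_arr:
            n_kin += 1
        elif u < a_arr + a_dep:
            n_kin -= 1
        elif u < a_arr + a_dep + a_phos:
            n_p2 += 1
        else:
            n_p2 -= 1

    return x_rec, n_rec_arr


def simulate_corral(seed: int, lipid_count: int, n_p2_0: int,
                    k_coeffs, phosphatase_coeffs,
                    lam_arrive: float, dwell_tau: float,
                    t_end: float, dt_record: float,
                    recruitment_coupling: float = 0.0):
    """Run one corral; returns (t, x, n_kinase) arrays sampled at dt_record."""
    k0, k1, k2 = (float(v) for v in k_coeffs)
    p0, p1 = (float(v) for v in phosphatase_coeffs)
    n_ss = lam_arrive * dwell_tau
    x, n = _kernel(np.uint32(seed % (2**32)), float(lipid_count), int(n_p2_0),
                   k0, k1, k2, p0, p1, float(lam_arrive), 1.0 / dwell_tau,
                   float(n_ss), float(recruitment_coupling),
                   float(t_end), float(dt_record))
    t = np.arange(x.size) * dt_record
    return t, x, n
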