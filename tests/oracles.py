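"""Independent optimization oracles and generators for the test suite.

These deliberately share no code with the package's NLP solver: growth
rates are written out in closed form from the model parameters, and the
optima are located by exhaustive grid search plus golden-section / nested
grid refinement.
"""

import numpy as np

GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def mu_minimal(kcat_t, K_t, kcat_r, K_r, rho, a, xi_r):
    """Closed-form growth rate of the 2-reaction self-replicator at
    ribosome allocation ``xi_r`` (the density constraint pins xi_t = rho)."""
    c_C = rho - xi_r
    if xi_r <= 0 or c_C <= 0:
        return -1.0
    tau_t = (1.0 + K_t / a) / kcat_t
    tau_r = (1.0 + K_r / c_C) / kcat_r
    return xi_r / (rho * tau_t + xi_r * tau_r)


def solve_minimal_oracle(kcat_t, K_t, kcat_r, K_r, rho, a):
    """1-D oracle: 1000-point grid then golden-section refinement."""
    def f(x):
        return mu_minimal(kcat_t, K_t, kcat_r, K_r, rho, a, x)

    grid = np.linspace(1e-9, rho * (1 - 1e-9), 1001)
    vals = np.array([f(x) for x in grid])
    i = int(np.argmax(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    while hi - lo > 1e-13 * rho:
        x1 = hi - GOLDEN * (hi - lo)
        x2 = lo + GOLDEN * (hi - lo)
        if f(x1) < f(x2):
            lo = x1
        else:
            hi = x2
    xr = 0.5 * (lo + hi)
    return f(xr), xr


def mu_chain3(model, rho, a, xi_e, xi_r):
    """Closed-form growth rate of the 3-reaction chain
    t: x -> C1, e: C1 -> C2, r: C2 -> P (xi_t = rho forced)."""
    kcat_t, kcat_e, kcat_r = (float(k) for k in model.kcat_f)
    K = np.asarray(model.K, dtype=float)
    K_t, K_e, K_r = K[0, 0], K[1, 1], K[2, 2]
    c1 = rho - xi_e
    c2 = xi_e - xi_r
    if c1 <= 0 or c2 <= 0 or xi_r <= 0:
        return -1.0
    tau_t = (1.0 + K_t / a) / kcat_t
    tau_e = (1.0 + K_e / c1) / kcat_e
    tau_r = (1.0 + K_r / c2) / kcat_r
    return xi_r / (rho * tau_t + xi_e * tau_e + xi_r * tau_r)


def solve_chain3_oracle(model, rho, a, n_grid=101, passes=3):
    """2-D oracle: nested grid refinement (each pass zooms ~50x)."""
    lo_e, hi_e = 0.0, rho
    lo_r, hi_r = 0.0, rho
    best = (-1.0, 0.0, 0.0)
    for _ in range(passes):
        es = np.linspace(lo_e, hi_e, n_grid)
        rs = np.linspace(lo_r, hi_r, n_grid)
        for xe in es:
            for xr in rs:
                v = mu_chain3(model, rho, a, xe, xr)
                if v > best[0]:
                    best = (v, xe, xr)
        de = 2.0 * (hi_e - lo_e) / (n_grid - 1)
        dr = 2.0 * (hi_r - lo_r) / (n_grid - 1)
        lo_e, hi_e = best[1] - de, best[1] + de
        lo_r, hi_r = best[2] - dr, best[2] + dr
    return best[0], best[1], best[2]


def random_conservative_stoichiometry(seed, n_species=None, n_rxn=None):
    """Random mol-based stoichiometry (S, w) satisfying w @ S = 0 exactly
    enough: negative coefficients are drawn freely and the positive side is
    scaled so each column's mass balances."""
    rng = np.random.default_rng(seed)
    n_species = n_species or int(rng.integers(3, 8))
    n_rxn = n_rxn or int(rng.integers(2, 6))
    w = rng.uniform(1.0, 500.0, n_species)
    S = np.zeros((n_species, n_rxn))
    for j in range(n_rxn):
        perm = rng.permutation(n_species)
        n_sub = int(rng.integers(1, max(2, n_species // 2 + 1)))
        n_prod = int(rng.integers(1, max(2, n_species - n_sub)))
        subs = perm[:n_sub]
        prods = perm[n_sub:n_sub + n_prod]
        S[subs, j] = -rng.uniform(0.5, 3.0, n_sub)
        raw = rng.uniform(0.5, 3.0, n_prod)
        mass_in = -np.sum(w[subs] * S[subs, j])
        S[prods, j] = raw * mass_in / np.sum(w[prods] * raw)
    return S, w
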