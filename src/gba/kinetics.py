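"""Convenience-kinetics evaluation: specific rates, turnover times, and the
catalyst-protein demand of a flux.

The specific rate of reaction ``alpha`` (per unit mass of its catalyst, 1/h)
is

    k_a = reg_a * (kcat_f * prod_s x_s/K_s  -  kcat_b * prod_p x_p/K_p)
          / (prod_s (1 + x_s/K_s) + prod_p (1 + x_p/K_p) - 1)

where ``s`` ranges over substrates (negative entries in column ``alpha`` of
M), ``p`` over products (positive entries), ``x`` is the reactant
concentration (external or internal as the row dictates), and

    reg_a = prod_{KA>0} c/(KA + c) * prod_{KI>0} KI/(KI + c).

For an irreversible reaction (``kcat_b == 0``) the product-side terms are
dropped, which reduces a single-substrate reaction without regulation to
plain Michaelis-Menten kinetics ``kcat * x / (K + x)``.

The turnover time is ``tau_a = 1 / k_a`` (hours of catalyst mass per unit
flux); protein demand is ``p_a = v_a * tau_a``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import GBAModel

__all__ = ["TurnoverContext", "specific_rate", "turnover_time",
           "turnover_times", "protein_demand", "regulation_factor",
           "CONCENTRATION_FLOOR"]

#: concentrations are clamped at this floor (g/L) so that rates and turnover
#: times stay finite-valued for gradient-based optimization
CONCENTRATION_FLOOR = 1e-12


@dataclass
class TurnoverContext:
    """The (a, c) concentration pair at which kinetics are evaluated.

    ``a``: external concentrations (g/L), order matching the x_ rows of M.
    ``c``: internal concentrations (g/L), last entry = total protein P.
    Values are clamped at :data:`CONCENTRATION_FLOOR` on construction.
    """

    a: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        self.a = np.maximum(np.asarray(self.a, dtype=float), CONCENTRATION_FLOOR)
        self.c = np.maximum(np.asarray(self.c, dtype=float), CONCENTRATION_FLOOR)


def _concentration(model: GBAModel, row: int, ctx: TurnoverContext) -> float:
    n_ext = model.n_external
    return float(ctx.a[row]) if row < n_ext else float(ctx.c[row - n_ext])


def regulation_factor(model: GBAModel, alpha: int, ctx: TurnoverContext) -> float:
    """Multiplicative activation/inhibition prefactor, in (0, 1]."""
    reg = 1.0
    KA = np.asarray(model.KA)[:, alpha]
    KI = np.asarray(model.KI)[:, alpha]
    for i in np.nonzero(KA > 0)[0]:
        ci = float(ctx.c[i])
        reg *= ci / (KA[i] + ci)
    for i in np.nonzero(KI > 0)[0]:
        ci = float(ctx.c[i])
        reg *= KI[i] / (KI[i] + ci)
    return reg


def specific_rate(model: GBAModel, alpha: int, ctx: TurnoverContext) -> float:
    """Signed per-catalyst-mass rate of reaction ``alpha`` (1/h).

    Negative when a reversible reaction runs net backward; zero exactly at
    the numerator's equilibrium point.
    """
    M = np.asarray(model.M)
    K = np.asarray(model.K)
    col = M[:, alpha]
    subs = np.nonzero(col < 0)[0]
    prods = np.nonzero(col > 0)[0]
    kf = float(model.kcat_f[alpha])
    kb = float(model.kcat_b[alpha])

    fwd = 1.0
    den_s = 1.0
    for i in subs:
        ratio = _concentration(model, i, ctx) / K[i, alpha]
        fwd *= ratio
        den_s *= 1.0 + ratio
    num = kf * fwd
    den = den_s
    if kb > 0.0:
        bwd = 1.0
        den_p = 1.0
        for i in prods:
            ratio = _concentration(model, i, ctx) / K[i, alpha]
            bwd *= ratio
            den_p *= 1.0 + ratio
        num -= kb * bwd
        den = den_s + den_p - 1.0
    return regulation_factor(model, alpha, ctx) * num / den


def turnover_time(model: GBAModel, alpha: int, ctx: TurnoverContext) -> float:
    """Turnover time tau_alpha = 1 / specific rate (hours).

    May be +inf (zero rate) or negative (reversible reaction whose net
    direction is backward at this context).
    """
    k = specific_rate(model, alpha, ctx)
    if k == 0.0:
        return np.inf
    return 1.0 / k


def turnover_times(model: GBAModel, ctx: TurnoverContext) -> np.ndarray:
    """Vector of turnover times for all reactions at one context."""
    return np.array([turnover_time(model, alpha, ctx)
                     for alpha in range(model.n_reactions)])


def protein_demand(model: GBAModel, alpha: int, v_alpha: float,
                   ctx: TurnoverContext) -> float:
    """Catalyst mass concentration p_a = v_a * tau_a (g/L) needed to carry
    flux ``v_alpha``.

    A negative result means the flux points against the net thermodynamic
    direction and must be treated as infeasible by the caller.
    """
    tau = turnover_time(model, alpha, ctx)
    if v_alpha == 0.0 and np.isfinite(tau):
        return 0.0
    return v_alpha * tau
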