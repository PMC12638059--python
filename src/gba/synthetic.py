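"""Random model generation, the minimal self-replicator fixture, and
parameter-lumping helpers for coarse-graining.

``generate_model`` builds structurally valid models by construction: column
supports are drawn first, then magnitudes are normalized so positive entries
sum to +1 and negative entries to -1, which satisfies the mass-fraction sum
rule without rejection sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (EXTERNAL_PREFIX, PROTEIN_LABEL, RIBOSOME_LABEL,
                         ConditionSet, GBAModel)

__all__ = ["ModelSpec", "generate_model", "minimal_model",
           "lump_kcat", "lump_km"]


@dataclass
class ModelSpec:
    """Recipe for a random GBA model."""

    n_rxn: int = 5
    n_ext: int = 1
    n_int: int | None = None        # default: n_rxn - n_ext + 1, min 2
    reversible_fraction: float = 0.0
    regulation_density: float = 0.0
    seed: int = 0
    n_conditions: int = 1
    kcat_range: tuple[float, float] = (1.0, 100.0)
    km_range: tuple[float, float] = (0.1, 10.0)
    rho_range: tuple[float, float] = (200.0, 400.0)
    a_range: tuple[float, float] = (0.1, 10.0)

    def __post_init__(self):
        if self.n_int is None:
            self.n_int = max(2, self.n_rxn - self.n_ext + 1)
        if self.n_rxn < 2:
            raise ValueError("n_rxn must be >= 2 (a transport plus the ribosome)")
        if self.n_int < 2:
            raise ValueError("n_int must be >= 2 (a metabolite plus P)")
        if self.n_ext < 1:
            raise ValueError("n_ext must be >= 1")
        if self.n_rxn < self.n_ext + 1:
            raise ValueError("need n_rxn >= n_ext + 1 (one transport per "
                             "external reactant plus the ribosome)")


def generate_model(spec: ModelSpec) -> tuple[GBAModel, ConditionSet]:
    """Deterministic (given ``spec.seed``) random model that always passes
    the full validation pipeline with no repairs.

    Topology: every external reactant is imported by its own transport
    column into the first metabolite; enzymatic columns form a conversion
    chain ``C1 -> C2 -> ...`` (extras draw random internal conversions); the
    ribosome consumes the chain's last reachable metabolite and produces
    ``P`` with mass fraction 1.
    """
    rng = np.random.default_rng(spec.seed)
    n_ext, n_int, n_rxn = spec.n_ext, spec.n_int, spec.n_rxn
    n_met = n_int - 1
    n_enz = n_rxn - n_ext - 1

    reactant_labels = ([f"{EXTERNAL_PREFIX}{i}" for i in range(1, n_ext + 1)]
                       + [f"C{i}" for i in range(1, n_met + 1)]
                       + [PROTEIN_LABEL])
    reaction_labels = ([f"t{i}" for i in range(1, n_ext + 1)]
                       + [f"e{i}" for i in range(1, n_enz + 1)]
                       + [RIBOSOME_LABEL])

    n_rct = n_ext + n_int
    M = np.zeros((n_rct, n_rxn))
    # transports: x_i -> C1
    for i in range(n_ext):
        M[i, i] = -1.0
        M[n_ext, i] = 1.0
    # enzymatic chain, then random conversions for any surplus columns
    chain_len = min(n_enz, n_met - 1)
    for j in range(chain_len):
        col = n_ext + j
        M[n_ext + j, col] = -1.0
        M[n_ext + j + 1, col] = 1.0
    for j in range(chain_len, n_enz):
        col = n_ext + j
        if n_met < 2:
            # single metabolite: the only conserving conversion is C1 -> P
            M[n_ext, col] = -1.0
            M[-1, col] = 1.0
            continue
        mets = rng.permutation(n_met)
        n_sub = 1 + int(rng.integers(0, min(2, n_met - 1)))
        n_prod = min(1 + int(rng.integers(0, 2)), n_met - n_sub)
        subs, prods = mets[:n_sub], mets[n_sub:n_sub + max(n_prod, 1)]
        sub_w = rng.uniform(0.2, 1.0, len(subs))
        prod_w = rng.uniform(0.2, 1.0, len(prods))
        M[n_ext + subs, col] = -sub_w / sub_w.sum()
        M[n_ext + prods, col] = prod_w / prod_w.sum()
    # ribosome: last reachable chain metabolite -> P
    last_met = n_ext + min(chain_len, n_met - 1)
    M[last_met, -1] = -1.0
    M[-1, -1] = 1.0

    K = np.where(M != 0.0, rng.uniform(*spec.km_range, M.shape), 0.0)
    kcat_f = rng.uniform(*spec.kcat_range, n_rxn)
    kcat_b = np.zeros(n_rxn)
    for j in range(n_ext, n_rxn - 1):     # only enzymatic columns reverse
        if rng.uniform() < spec.reversible_fraction:
            kcat_b[j] = kcat_f[j] * rng.uniform(0.01, 0.5)
            # reversible rate law needs product Kms as well
            prod_rows = np.nonzero(M[:, j] > 0)[0]
            K[prod_rows, j] = np.where(K[prod_rows, j] == 0.0,
                                       rng.uniform(*spec.km_range,
                                                   len(prod_rows)),
                                       K[prod_rows, j])
    KA = np.zeros((n_int, n_rxn))
    KI = np.zeros((n_int, n_rxn))
    mask = rng.uniform(size=KA.shape) < spec.regulation_density
    KA[mask] = rng.uniform(*spec.km_range, int(mask.sum()))
    mask = rng.uniform(size=KI.shape) < spec.regulation_density
    KI[mask] = rng.uniform(*spec.km_range, int(mask.sum()))

    model = GBAModel(reactant_labels, reaction_labels, M, K, KA, KI,
                     kcat_f, kcat_b)
    cond_labels = [f"cond{k + 1}" for k in range(spec.n_conditions)]
    rho = rng.uniform(*spec.rho_range, spec.n_conditions)
    a = rng.uniform(*spec.a_range, (n_ext, spec.n_conditions))
    conditions = ConditionSet(cond_labels, rho, a,
                              external_labels=reactant_labels[:n_ext])
    return model, conditions


def minimal_model(kcat_t: float, K_t: float, kcat_r: float, K_r: float,
                  rho: float, a: float) -> tuple[GBAModel, ConditionSet]:
    """The 2-reaction self-replicator: a transporter ``t`` importing ``x_s``
    into metabolite ``C`` and a ribosome ``r`` converting ``C`` into ``P``,
    both irreversible Michaelis-Menten.

    The density constraint forces ``xi_t = rho``, so optimizing this model
    is a one-dimensional search over ``xi_r`` — the closed-form oracle used
    to certify the NLP solver.
    """
    for name, val in (("kcat_t", kcat_t), ("K_t", K_t), ("kcat_r", kcat_r),
                      ("K_r", K_r), ("rho", rho), ("a", a)):
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    M = np.array([[-1.0, 0.0],
                  [1.0, -1.0],
                  [0.0, 1.0]])
    K = np.array([[K_t, 0.0],
                  [0.0, K_r],
                  [0.0, 0.0]])
    model = GBAModel(
        reactant_labels=["x_s", "C", PROTEIN_LABEL],
        reaction_labels=["t", RIBOSOME_LABEL],
        M=M, K=K,
        KA=np.zeros((2, 2)), KI=np.zeros((2, 2)),
        kcat_f=np.array([kcat_t, kcat_r]), kcat_b=np.zeros(2))
    conditions = ConditionSet(["cond1"], np.array([rho]),
                              np.array([[a]]), external_labels=["x_s"])
    return model, conditions


def lump_kcat(kcats, mode: str) -> float:
    """Effective turnover number when lumping reactions.

    ``parallel`` -> arithmetic mean; ``series`` -> harmonic mean.
    """
    kcats = np.asarray(kcats, dtype=float).ravel()
    if kcats.size == 0:
        raise ValueError("kcats must be nonempty")
    if np.any(kcats <= 0):
        raise ValueError("kcats must all be positive")
    if mode == "parallel":
        return float(np.mean(kcats))
    if mode == "series":
        return float(len(kcats) / np.sum(1.0 / kcats))
    raise ValueError(f"mode must be 'parallel' or 'series', got {mode!r}")


def lump_km(substrate_concentrations) -> float:
    """Effective Michaelis constant for a lumped reaction: half of the
    summed substrate concentrations (typical enzyme saturation)."""
    x = np.asarray(substrate_concentrations, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("substrate_concentrations must be nonempty")
    if np.any(x < 0):
        raise ValueError("substrate concentrations must be non-negative")
    return float(np.sum(x) / 2.0)
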