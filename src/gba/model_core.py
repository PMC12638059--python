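"""Domain types for GBA models, template/example construction, and the
stoichiometry-to-mass-fraction conversion.

Conventions throughout the package:

* reactants are matrix rows, reactions are columns;
* external reactants carry the ``x_`` label prefix and come first;
* the last internal row is total protein ``P``; the last column is the
  protein-producing ribosome reaction ``r``;
* concentrations, densities and Michaelis constants are in g/L, turnover
  numbers in 1/h (mass of product per mass of catalyst per hour).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import MassConservationError

__all__ = [
    "GBAModel",
    "ConditionSet",
    "StoichiometryInput",
    "EXTERNAL_PREFIX",
    "PROTEIN_LABEL",
    "RIBOSOME_LABEL",
    "mass_fraction_from_stoichiometry",
    "write_template",
    "build_example_model",
]

EXTERNAL_PREFIX = "x_"
PROTEIN_LABEL = "P"
RIBOSOME_LABEL = "r"

#: absolute tolerance for the +-1 column-sum rule of M
COLUMN_SUM_TOL = 1e-9


def _coerce(x) -> np.ndarray:
    """Convert to a float ndarray; object arrays (possibly holding text or
    None from a raw file) are passed through for the integrity check."""
    arr = np.asarray(x)
    if arr.dtype == object:
        return arr
    return arr.astype(float)


@dataclass
class GBAModel:
    """A coarse-grained self-replicator model in mass-fraction form.

    Parameters
    ----------
    reactant_labels
        External reactants (``x_`` prefix) first, then internal reactants;
        the last internal reactant is total protein ``P``.
    reaction_labels
        Transport reactions first, then enzymatic, last the ribosome ``r``.
    M
        Mass-fraction matrix, shape ``(n_reactants, n_reactions)``,
        dimensionless.  Negative entries consume, positive entries produce.
    K
        Michaelis constants, same shape as ``M``, g/L.
    KA, KI
        Activation / inhibition constants over *internal* rows only, shape
        ``(n_internal, n_reactions)``, g/L; 0 means "no effect".
    kcat_f, kcat_b
        Forward / backward turnover numbers per reaction, 1/h; a backward
        value of 0 marks the reaction irreversible.
    """

    reactant_labels: list[str]
    reaction_labels: list[str]
    M: np.ndarray
    K: np.ndarray
    KA: np.ndarray
    KI: np.ndarray
    kcat_f: np.ndarray
    kcat_b: np.ndarray

    def __post_init__(self):
        # Shapes are deliberately NOT enforced here: the validation module
        # must be able to inspect models whose tabs disagree on dimensions.
        self.reactant_labels = list(self.reactant_labels)
        self.reaction_labels = list(self.reaction_labels)
        self.M = _coerce(self.M)
        self.K = _coerce(self.K)
        self.KA = _coerce(self.KA)
        self.KI = _coerce(self.KI)
        self.kcat_f = _coerce(self.kcat_f)
        self.kcat_b = _coerce(self.kcat_b)

    # ---- derived structure -------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_labels)

    @property
    def n_reactants(self) -> int:
        return len(self.reactant_labels)

    @property
    def n_external(self) -> int:
        return sum(1 for lbl in self.reactant_labels
                   if lbl.startswith(EXTERNAL_PREFIX))

    @property
    def n_internal(self) -> int:
        return self.n_reactants - self.n_external

    @property
    def external_labels(self) -> list[str]:
        return self.reactant_labels[: self.n_external]

    @property
    def internal_labels(self) -> list[str]:
        return self.reactant_labels[self.n_external:]

    @property
    def M_ext(self) -> np.ndarray:
        """External rows of M, shape (n_external, n_reactions)."""
        return self.M[: self.n_external, :]

    @property
    def M_int(self) -> np.ndarray:
        """Internal rows of M, shape (n_internal, n_reactions)."""
        return self.M[self.n_external:, :]

    @property
    def K_ext(self) -> np.ndarray:
        return self.K[: self.n_external, :]

    @property
    def K_int(self) -> np.ndarray:
        return self.K[self.n_external:, :]

    @property
    def irreversible(self) -> np.ndarray:
        """Boolean mask of irreversible reactions (kcat_b == 0)."""
        return np.asarray(self.kcat_b) == 0.0

    def copy(self) -> "GBAModel":
        return replace(
            self,
            reactant_labels=list(self.reactant_labels),
            reaction_labels=list(self.reaction_labels),
            M=np.array(self.M, copy=True),
            K=np.array(self.K, copy=True),
            KA=np.array(self.KA, copy=True),
            KI=np.array(self.KI, copy=True),
            kcat_f=np.array(self.kcat_f, copy=True),
            kcat_b=np.array(self.kcat_b, copy=True),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GBAModel):
            return NotImplemented
        return (
            self.reactant_labels == other.reactant_labels
            and self.reaction_labels == other.reaction_labels
            and np.array_equal(self.M, other.M)
            and np.array_equal(self.K, other.K)
            and np.array_equal(self.KA, other.KA)
            and np.array_equal(self.KI, other.KI)
            and np.array_equal(self.kcat_f, other.kcat_f)
            and np.array_equal(self.kcat_b, other.kcat_b)
        )


@dataclass
class ConditionSet:
    """Growth conditions: cell density rho plus external concentrations.

    ``a`` rows follow the order of the ``x_``-prefixed rows of the model's M.
    """

    condition_labels: list[str]
    rho: np.ndarray
    a: np.ndarray
    #: labels of the external-concentration rows; defaults to None, meaning
    #: "trust positional order against the model's x_ rows"
    external_labels: list[str] | None = None

    def __post_init__(self):
        self.condition_labels = list(self.condition_labels)
        n_cond = len(self.condition_labels)
        self.rho = _coerce(self.rho)
        a = _coerce(self.a)
        if a.dtype != object:
            a = a.reshape(-1, n_cond) if a.size else a.reshape(0, n_cond)
        self.a = a

    @property
    def n_conditions(self) -> int:
        return len(self.condition_labels)

    @property
    def n_external(self) -> int:
        return self.a.shape[0]

    def condition(self, k: int) -> tuple[float, np.ndarray]:
        """Return (rho, a) for condition index ``k``."""
        return float(self.rho[k]), np.array(self.a[:, k], copy=True)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConditionSet):
            return NotImplemented
        labels_ok = (self.external_labels is None
                     or other.external_labels is None
                     or self.external_labels == other.external_labels)
        return (
            labels_ok
            and self.condition_labels == other.condition_labels
            and np.array_equal(self.rho, other.rho)
            and np.array_equal(self.a, other.a)
        )


@dataclass
class StoichiometryInput:
    """A mol-based stoichiometric matrix S with molecular weights w (g/mol).

    Mass conservation requires ``w @ S == 0`` column-wise.
    """

    S: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.w = np.asarray(self.w, dtype=float).ravel()
        if self.S.shape[0] != self.w.shape[0]:
            raise ValueError("w length must equal the number of rows of S")
        if np.any(self.w <= 0):
            raise ValueError("molecular weights must be strictly positive")


def mass_fraction_from_stoichiometry(
    inp: StoichiometryInput, *, tol: float = 1e-9
) -> np.ndarray:
    """Convert a mol-based stoichiometric matrix to mass fractions.

    Each row of S is scaled by its molecular weight and each column is then
    normalized so positive entries sum to 1 (and, because mass is conserved,
    negative entries to -1).

    Raises
    ------
    MassConservationError
        If a column has ``w @ S != 0`` beyond ``tol`` (relative to the mass
        throughput), or is all-zero.
    """
    S, w = inp.S, inp.w
    WS = w[:, None] * S
    M = np.zeros_like(WS)
    for j in range(S.shape[1]):
        col = WS[:, j]
        pos = col[col > 0].sum()
        neg = col[col < 0].sum()
        if pos == 0 and neg == 0:
            raise MassConservationError(
                f"column {j} is all-zero", column=j)
        scale = max(pos, -neg)
        if abs(pos + neg) > tol * max(scale, 1.0):
            raise MassConservationError(
                f"column {j} violates mass conservation: w.S = {pos + neg:g}",
                column=j)
        M[:, j] = col / pos
    return M


# ---------------------------------------------------------------------------
# template + packaged example
# ---------------------------------------------------------------------------

def make_template(n_reactants: int, n_reactions: int) -> tuple[GBAModel, ConditionSet]:
    """Build a structurally valid skeleton model.

    One external reactant ``x_1``, internal reactants ``C1..``, trailing
    ``P`` row; one transport column ``t1``, enzymatic columns ``e1..``,
    trailing ``r`` column.  A linear conversion chain is pre-filled where the
    shapes allow; remaining cells are zero.
    """
    if n_reactants < 2:
        raise ValueError("n_reactants must be >= 2 (one metabolite plus P)")
    if n_reactions < 2:
        raise ValueError("n_reactions must be >= 2 (a transport plus the ribosome)")

    n_int = n_reactants - 1                      # one external by convention
    reactant_labels = ([f"{EXTERNAL_PREFIX}1"]
                       + [f"C{i}" for i in range(1, n_int)]
                       + [PROTEIN_LABEL])
    reaction_labels = (["t1"] + [f"e{i}" for i in range(1, n_reactions - 1)]
                       + [RIBOSOME_LABEL])

    M = np.zeros((n_reactants, n_reactions))
    n_met = n_int - 1                            # internal metabolites before P
    if n_met >= 1:
        M[0, 0], M[1, 0] = -1.0, 1.0             # t1: x_1 -> C1
        # enzymatic chain C_j -> C_{j+1} while both columns and rows remain
        for j in range(1, n_reactions - 1):
            if j < n_met:
                M[j, j], M[j + 1, j] = -1.0, 1.0
        # ribosome: last reachable metabolite -> P
        last_met = min(n_met, n_reactions - 1)
        M[last_met, -1], M[-1, -1] = -1.0, 1.0

    K = np.where(M != 0.0, 0.5, 0.0)
    KA = np.zeros((n_int, n_reactions))
    KI = np.zeros((n_int, n_reactions))
    kcat_f = np.full(n_reactions, 10.0)
    kcat_b = np.zeros(n_reactions)

    model = GBAModel(reactant_labels, reaction_labels, M, K, KA, KI, kcat_f, kcat_b)
    conditions = ConditionSet(["cond1"], np.array([300.0]),
                              np.ones((1, 1)))
    return model, conditions


def write_template(n_reactants: int, n_reactions: int, path,
                   dialect: str | None = None) -> None:
    """Write a skeleton model file (see :func:`make_template`)."""
    from .io import write_model
    model, conditions = make_template(n_reactants, n_reactions)
    write_model(model, conditions, path, dialect=dialect)


def build_example_model() -> tuple[GBAModel, ConditionSet]:
    """The packaged 5-reaction example: one transporter, three enzymes, and
    the ribosome, all irreversible Michaelis-Menten (no regulation).

    Topology::

        t : x_s -> A
        e1: A -> B
        e2: A -> C
        e3: 0.5 B + 0.5 C -> D
        r : D -> P

    Parameter values are package fixtures chosen in biologically plausible
    ranges; three growth conditions sweep the external nutrient level.
    """
    reactant_labels = ["x_s", "A", "B", "C", "D", "P"]
    reaction_labels = ["t", "e1", "e2", "e3", "r"]

    M = np.array([
        # t     e1    e2    e3    r
        [-1.0,  0.0,  0.0,  0.0,  0.0],   # x_s
        [1.0,  -1.0, -1.0,  0.0,  0.0],   # A
        [0.0,   1.0,  0.0, -0.5,  0.0],   # B
        [0.0,   0.0,  1.0, -0.5,  0.0],   # C
        [0.0,   0.0,  0.0,  1.0, -1.0],   # D
        [0.0,   0.0,  0.0,  0.0,  1.0],   # P
    ])
    K = np.array([
        [0.5, 0.0, 0.0, 0.0, 0.0],
        [3.0, 1.0, 2.0, 0.0, 0.0],
        [0.0, 2.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 1.5, 0.8, 0.0],
        [0.0, 0.0, 0.0, 5.0, 2.0],
        [0.0, 0.0, 0.0, 0.0, 10.0],
    ])
    n_int, n_rxn = 5, 5
    KA = np.zeros((n_int, n_rxn))
    KI = np.zeros((n_int, n_rxn))
    kcat_f = np.array([180.0, 120.0, 150.0, 90.0, 25.0])
    kcat_b = np.zeros(n_rxn)

    model = GBAModel(reactant_labels, reaction_labels, M, K, KA, KI,
                     kcat_f, kcat_b)
    conditions = ConditionSet(
        ["low", "medium", "high"],
        rho=np.array([340.0, 340.0, 340.0]),
        a=np.array([[0.2, 2.0, 20.0]]),
    )
    return model, conditions
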