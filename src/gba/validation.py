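"""The "check model" pipeline: data integrity, dimensional consistency,
non-negativity, mass conservation, Michaelis-constant repair, and the
model-size limit.

Checks report failures as results, never exceptions, so every structurally
possible check runs and the report aggregates maximal diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ConditionSet, GBAModel

__all__ = [
    "CheckResult", "ValidationReport",
    "check_data_integrity", "check_dimensions", "check_nonnegativity",
    "check_mass_conservation", "repair_km_defaults", "check_model",
    "DEFAULT_KM", "MAX_REACTIONS", "COLUMN_SUM_TOL",
]

#: default Michaelis constant (g/L) assigned to substrate entries whose K is 0
DEFAULT_KM = 0.1
#: largest model size accepted by default
MAX_REACTIONS = 20
#: absolute tolerance on the +1 / -1 column sums of M
COLUMN_SUM_TOL = 1e-6


@dataclass
class CheckResult:
    name: str
    status: str  # "pass" | "fail" | "repaired"
    messages: list[str] = field(default_factory=list)


@dataclass
class ValidationReport:
    checks: list[CheckResult]
    repaired_model: GBAModel | None = None

    @property
    def is_valid(self) -> bool:
        return not any(c.status == "fail" for c in self.checks)

    @property
    def repairs(self) -> list[str]:
        out = []
        for c in self.checks:
            if c.status == "repaired":
                out.extend(c.messages)
        return out

    def summary(self) -> str:
        lines = []
        for c in self.checks:
            lines.append(f"[{c.status.upper():8s}] {c.name}")
            lines.extend(f"    {m}" for m in c.messages)
        verdict = "VALID" if self.is_valid else "INVALID"
        lines.append(f"model is {verdict}")
        return "\n".join(lines)


def _is_number(v) -> bool:
    try:
        return np.isfinite(float(v))
    except (TypeError, ValueError):
        return False


def _bad_cells(arr, row_labels, col_labels) -> list[tuple]:
    """(row_label, col_label) coordinates of missing / non-numeric cells."""
    arr = np.atleast_2d(np.asarray(arr, dtype=object))
    bad = []
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            if not _is_number(arr[i, j]):
                rl = row_labels[i] if i < len(row_labels) else i
                cl = col_labels[j] if j < len(col_labels) else j
                bad.append((rl, cl))
    return bad


def _numeric(arr) -> bool:
    a = np.asarray(arr)
    return a.dtype != object and bool(np.all(np.isfinite(a)))


def check_data_integrity(model: GBAModel, conditions: ConditionSet) -> CheckResult:
    """Every cell of every tab must hold a finite number."""
    msgs = []
    tabs = [
        ("M", model.M, model.reactant_labels, model.reaction_labels),
        ("K", model.K, model.reactant_labels, model.reaction_labels),
        ("KA", model.KA, model.internal_labels, model.reaction_labels),
        ("KI", model.KI, model.internal_labels, model.reaction_labels),
        ("kcat", np.vstack([np.atleast_1d(np.asarray(model.kcat_f, dtype=object)),
                            np.atleast_1d(np.asarray(model.kcat_b, dtype=object))]),
         ["kcat_f", "kcat_b"], model.reaction_labels),
        ("conditions", np.atleast_2d(np.asarray(conditions.rho, dtype=object)),
         ["rho"], conditions.condition_labels),
    ]
    if np.asarray(conditions.a).size:
        ext = conditions.external_labels or [f"a[{i}]" for i in
                                             range(np.atleast_2d(conditions.a).shape[0])]
        tabs.append(("conditions", conditions.a, ext, conditions.condition_labels))
    for tab, arr, rl, cl in tabs:
        for r, c in _bad_cells(arr, rl, cl):
            msgs.append(f"missing or non-numeric value in {tab!r} at ({r!r}, {c!r})")
    return CheckResult("data_integrity", "fail" if msgs else "pass", msgs)


def check_dimensions(model: GBAModel, conditions: ConditionSet) -> CheckResult:
    """All tabs must agree with M on reactant / reaction / external counts."""
    msgs = []
    M = np.atleast_2d(np.asarray(model.M))
    n_rct, n_rxn = len(model.reactant_labels), len(model.reaction_labels)
    if M.shape != (n_rct, n_rxn):
        msgs.append(f"M has shape {M.shape}, labels imply ({n_rct}, {n_rxn})")
    K = np.atleast_2d(np.asarray(model.K))
    if K.shape != M.shape:
        msgs.append(f"K has shape {K.shape}, M has {M.shape}")
    n_int = model.n_internal
    for name, arr in (("KA", model.KA), ("KI", model.KI)):
        arr = np.atleast_2d(np.asarray(arr))
        if arr.shape != (n_int, n_rxn):
            msgs.append(f"{name} has shape {arr.shape}, expected ({n_int}, {n_rxn})")
    for name, vec in (("kcat_f", model.kcat_f), ("kcat_b", model.kcat_b)):
        vec = np.atleast_1d(np.asarray(vec))
        if vec.shape != (n_rxn,):
            msgs.append(f"{name} has length {vec.shape[0]}, expected {n_rxn}")
    a = np.atleast_2d(np.asarray(conditions.a)) if np.asarray(conditions.a).size \
        else np.zeros((0, conditions.n_conditions))
    if a.shape[0] != model.n_external:
        msgs.append(f"conditions has {a.shape[0]} external rows, "
                    f"M has {model.n_external} 'x_' reactants")
    if conditions.external_labels is not None:
        missing = [lbl for lbl in conditions.external_labels
                   if lbl not in model.external_labels]
        for lbl in missing:
            msgs.append(f"conditions row {lbl!r} is not an external reactant of M")
    return CheckResult("dimensions", "fail" if msgs else "pass", msgs)


def check_nonnegativity(model: GBAModel, conditions: ConditionSet) -> CheckResult:
    """External concentrations must be >= 0 and cell density > 0."""
    msgs = []
    rho = np.atleast_1d(np.asarray(conditions.rho))
    a = np.atleast_2d(np.asarray(conditions.a)) if np.asarray(conditions.a).size \
        else np.zeros((0, conditions.n_conditions))
    for k, label in enumerate(conditions.condition_labels):
        if k < rho.shape[0] and _is_number(rho[k]) and float(rho[k]) <= 0:
            msgs.append(f"condition {label!r}: cell density rho = {rho[k]} "
                        "must be positive")
        for i in range(a.shape[0]):
            if k < a.shape[1] and _is_number(a[i, k]) and float(a[i, k]) < 0:
                ext = (conditions.external_labels[i]
                       if conditions.external_labels
                       and i < len(conditions.external_labels) else f"a[{i}]")
                msgs.append(f"condition {label!r}: external concentration "
                            f"{ext!r} = {a[i, k]} is negative")
    return CheckResult("nonnegativity", "fail" if msgs else "pass", msgs)


def check_mass_conservation(model: GBAModel, *, tol: float = COLUMN_SUM_TOL
                            ) -> CheckResult:
    """Positive entries of each M column must sum to 1, negative to -1."""
    if not _numeric(model.M):
        return CheckResult("mass_conservation", "fail",
                           ["M contains non-numeric values; cannot check"])
    M = np.atleast_2d(np.asarray(model.M, dtype=float))
    msgs = []
    for j in range(M.shape[1]):
        col = M[:, j]
        pos = col[col > 0].sum()
        neg = col[col < 0].sum()
        label = (model.reaction_labels[j]
                 if j < len(model.reaction_labels) else j)
        if abs(pos - 1.0) > tol or abs(neg + 1.0) > tol:
            msgs.append(f"column {label!r}: positive sum {pos:.9g}, "
                        f"negative sum {neg:.9g} (expected +1 / -1)")
    return CheckResult("mass_conservation", "fail" if msgs else "pass", msgs)


def repair_km_defaults(model: GBAModel) -> tuple[GBAModel, list[tuple[str, str]]]:
    """Assign the default Km of 0.1 g/L to substrate entries (negative in M)
    whose Michaelis constant is zero.

    For reversible reactions (kcat_b > 0) zero product Kms are repaired too,
    since the reversible rate law needs them; products of irreversible
    reactions are left untouched.

    Returns the (possibly) repaired model and the list of repaired
    (reactant_label, reaction_label) cells.
    """
    repaired = model.copy()
    M = np.atleast_2d(np.asarray(repaired.M, dtype=float))
    K = np.atleast_2d(np.asarray(repaired.K, dtype=float))
    kcat_b = np.atleast_1d(np.asarray(repaired.kcat_b, dtype=float))
    cells = []
    for j in range(M.shape[1]):
        for i in range(M.shape[0]):
            needs_km = M[i, j] < 0 or (M[i, j] > 0 and kcat_b[j] > 0)
            if needs_km and K[i, j] == 0.0:
                K[i, j] = DEFAULT_KM
                cells.append((model.reactant_labels[i], model.reaction_labels[j]))
    repaired.K = K
    return (repaired if cells else model), cells


def check_model(model: GBAModel, conditions: ConditionSet, *,
                fix_km: bool = True,
                max_reactions: int | None = MAX_REACTIONS) -> ValidationReport:
    """Run the full validation pipeline in order: integrity, dimensions,
    non-negativity, mass conservation, Km repair, size limit.

    Later checks still run when earlier ones fail, where structurally
    possible.  Pass ``max_reactions=None`` to lift the size limit.
    """
    checks = [
        check_data_integrity(model, conditions),
        check_dimensions(model, conditions),
        check_nonnegativity(model, conditions),
        check_mass_conservation(model),
    ]

    repaired_model = None
    M, K = np.atleast_2d(np.asarray(model.M)), np.atleast_2d(np.asarray(model.K))
    if _numeric(M) and _numeric(K) and M.shape == K.shape:
        fixed, cells = repair_km_defaults(model)
        if cells:
            msgs = [f"K[{r!r}, {c!r}] = 0 repaired to {DEFAULT_KM} g/L"
                    for r, c in cells]
            if fix_km:
                repaired_model = fixed
                checks.append(CheckResult("km_defaults", "repaired", msgs))
            else:
                checks.append(CheckResult("km_defaults", "fail", msgs))
        else:
            checks.append(CheckResult("km_defaults", "pass"))
    else:
        checks.append(CheckResult(
            "km_defaults", "fail",
            ["cannot evaluate Km defaults: M/K non-numeric or shape mismatch"]))

    if max_reactions is None:
        checks.append(CheckResult("size_limit", "pass",
                                  ["size limit lifted (--allow-large)"]))
    elif model.n_reactions > max_reactions:
        checks.append(CheckResult(
            "size_limit", "fail",
            [f"model has {model.n_reactions} reactions, limit is "
             f"{max_reactions}"]))
    else:
        checks.append(CheckResult("size_limit", "pass"))

    kf = np.atleast_1d(np.asarray(model.kcat_f))
    if _numeric(kf) and np.any(kf <= 0):
        bad = [model.reaction_labels[j] for j in np.nonzero(kf <= 0)[0]
               if j < len(model.reaction_labels)]
        checks.append(CheckResult(
            "kcat_positive", "fail",
            [f"kcat_f must be positive; offending reactions: {bad}"]))
    else:
        checks.append(CheckResult("kcat_positive", "pass"))

    return ValidationReport(checks, repaired_model)
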