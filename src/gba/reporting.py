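"""Serialize solutions to tidy tables, render condition-sweep plots, and
export the flux map as a bipartite graph."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import networkx as nx  # noqa: E402
import numpy as np  # noqa: E402

from .model_core import ConditionSet, GBAModel  # noqa: E402
from .solver import GrowthSolution  # noqa: E402

__all__ = ["ResultsBundle", "write_results", "plot_sweep", "export_flux_map"]

_QUANTITIES = {"mu", "c", "p", "phi", "v"}


@dataclass
class ResultsBundle:
    """Everything a solve run produced, one record per condition."""

    model: GBAModel
    conditions: ConditionSet
    solutions: list[GrowthSolution]
    options: dict = field(default_factory=dict)
    model_hash: str = ""
    wall_clock: list[float] = field(default_factory=list)

    @property
    def condition_labels(self) -> list[str]:
        return self.conditions.condition_labels


def _fmt(x: float) -> str:
    """Full-precision float formatting (repr round-trips exactly)."""
    return repr(float(x))


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(header)
        for row in rows:
            writer.writerow([v if isinstance(v, str) else _fmt(v)
                             for v in row])


def write_results(bundle: ResultsBundle, out_dir) -> dict[str, Path]:
    """Write growth_rates / fluxes / proteins / protein_fractions /
    concentrations TSVs plus summary.json into ``out_dir``."""
    if not bundle.solutions:
        raise ValueError("bundle has no solutions")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, sols = bundle.model, bundle.solutions
    cond = bundle.condition_labels
    files: dict[str, Path] = {}

    files["growth_rates"] = out / "growth_rates.tsv"
    _write_tsv(files["growth_rates"], ["condition", "mu", "converged"],
               [[lbl, s.mu, str(s.converged).lower()]
                for lbl, s in zip(cond, sols)])

    def matrix_tsv(name, row_labels, extract):
        path = out / f"{name}.tsv"
        rows = [[lbl, *[extract(s)[i] for s in sols]]
                for i, lbl in enumerate(row_labels)]
        _write_tsv(path, [name.rstrip("s") if name != "protein_fractions"
                          else "reaction", *cond], rows)
        files[name] = path

    matrix_tsv("fluxes", model.reaction_labels, lambda s: s.v)
    matrix_tsv("proteins", model.reaction_labels, lambda s: s.p)
    matrix_tsv("protein_fractions", model.reaction_labels, lambda s: s.phi)
    matrix_tsv("concentrations", model.internal_labels, lambda s: s.c)

    summary = {
        "options": bundle.options,
        "model": {
            "reactants": model.reactant_labels,
            "reactions": model.reaction_labels,
            "hash": bundle.model_hash,
        },
        "conditions": cond,
        "results": [
            {
                "condition": lbl,
                "mu": s.mu,
                "converged": s.converged,
                "solver": s.solver_used,
                "n_iterations": s.n_iterations,
                "residuals": {k: v for k, v in s.constraint_residuals.items()
                              if isinstance(v, (int, float, str))},
            }
            for lbl, s in zip(cond, sols)
        ],
        "wall_clock_s": bundle.wall_clock,
    }
    files["summary"] = out / "summary.json"
    with open(files["summary"], "w") as fh:
        json.dump(summary, fh, indent=1)
    return files


def plot_sweep(bundle: ResultsBundle, quantity: str, path) -> Path:
    """Line plot of a solution quantity across conditions (one line per
    labeled series).  The file type follows the extension (.svg / .png)."""
    if quantity not in _QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}; "
                         f"choose from {sorted(_QUANTITIES)}")
    if len(bundle.solutions) < 2:
        raise ValueError(">=2 conditions required for a sweep plot")
    cond = bundle.condition_labels
    x = np.arange(len(cond))
    fig, ax = plt.subplots(figsize=(6, 4))
    if quantity == "mu":
        ax.plot(x, [s.mu for s in bundle.solutions], marker="o", label="mu")
        ax.set_ylabel("growth rate mu (1/h)")
    else:
        labels = (bundle.model.internal_labels if quantity == "c"
                  else bundle.model.reaction_labels)
        ylab = {"c": "concentration (g/L)", "p": "protein (g/L)",
                "phi": "protein fraction", "v": "flux (g/L/h)"}[quantity]
        for i, lbl in enumerate(labels):
            ax.plot(x, [getattr(s, quantity)[i] for s in bundle.solutions],
                    marker="o", label=lbl)
        ax.set_ylabel(ylab)
    ax.set_xticks(x, cond)
    ax.set_xlabel("condition")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def export_flux_map(model: GBAModel, solution: GrowthSolution, path,
                    conditions: ConditionSet | None = None,
                    condition_index: int = 0) -> Path:
    """Write the solution as a bipartite reactant/reaction GraphML graph.

    Edge weight = |v_a * M_ia| (mass flux through that arc, g/L/h); node
    weight = concentration (internal c_i; external a_i when conditions are
    given).  All nonzero-M arcs are kept, including zero-flux ones.
    """
    if not solution.converged:
        raise ValueError("flux map requires a converged solution")
    G = nx.DiGraph()
    n_ext = model.n_external
    a = (np.atleast_2d(conditions.a)[:, condition_index]
         if conditions is not None and np.asarray(conditions.a).size
         else np.zeros(n_ext))
    for i, lbl in enumerate(model.reactant_labels):
        if i < n_ext:
            G.add_node(lbl, kind="external", weight=float(a[i]))
        else:
            G.add_node(lbl, kind="internal",
                       weight=float(solution.c[i - n_ext]))
    M = np.asarray(model.M, dtype=float)
    for j, rxn in enumerate(model.reaction_labels):
        G.add_node(rxn, kind="reaction", weight=float(solution.p[j]),
                   flux=float(solution.v[j]))
        for i, rct in enumerate(model.reactant_labels):
            if M[i, j] == 0.0:
                continue
            w = abs(float(solution.v[j]) * M[i, j])
            if M[i, j] < 0:
                G.add_edge(rct, rxn, weight=w, mass_fraction=float(M[i, j]))
            else:
                G.add_edge(rxn, rct, weight=w, mass_fraction=float(M[i, j]))
    path = Path(path)
    nx.write_graphml(G, path)
    return path
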