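# gba — growth balance analysis for coarse-grained cell models

`gba` constructs, validates, and numerically solves coarse-grained
self-replicating cell models (growth balance analysis, GBA). Given a
mass-fraction stoichiometry, kinetic parameters (convenience kinetics:
irreversible or reversible, with activation/inhibition), and a total
cell-density constraint, it predicts the optimal balanced growth rate and
the full biomass composition — fluxes, metabolite concentrations, protein
concentrations, and proteome fractions — for each growth condition.

Concentrations and Michaelis constants are in g/L, turnover numbers in 1/h
(mass of product per mass of catalyst per hour).

## Model files

A model is a spreadsheet with six tabs (ODS) or a directory with six CSVs
(`M.csv`, `K.csv`, `KA.csv`, `KI.csv`, `kcat.csv`, `conditions.csv`):

| tab | contents |
|---|---|
| `M` | mass-fraction matrix: reactants × reactions; negative = consumed, positive = produced; each column's positive entries sum to +1 and negative entries to −1 |
| `K` | Michaelis constants (g/L), same layout as `M` |
| `KA`, `KI` | activation / inhibition constants (g/L), internal reactants only; 0 = no effect |
| `kcat` | two rows `kcat_f`, `kcat_b` (1/h); `kcat_b = 0` marks a reaction irreversible |
| `conditions` | one column per growth condition: row `rho` (cell density, g/L) then one row per external (`x_`-prefixed) reactant |

External reactants carry the `x_` prefix and come first; the last row is
total protein `P`, and the last column is the protein-producing ribosome
reaction `r`. Columns are ordered transport, enzymatic, ribosome.

## CLI

```sh
gba template --reactants 5 --reactions 5 --out model.ods   # skeleton to edit
gba example  --out example.ods                             # packaged 5-reaction model
gba random   --reactions 8 --seed 3 --out random.ods       # random valid model

gba validate model.ods [--fix-km] [--allow-large] [--json] # exit 0 iff valid
gba solve    model.ods [--solver slsqp|lbfgs|mma] [--starts N] [--seed S]
                       [--config opts.yaml] [--out DIR]
gba plot     model.ods --quantity mu --out mu.svg          # condition sweep
gba fluxmap  model.ods --out map.graphml                   # bipartite flux graph
```

`gba solve` writes `growth_rates.tsv`, `fluxes.tsv`, `proteins.tsv`,
`protein_fractions.tsv`, `concentrations.tsv`, and `summary.json` to the
output directory. Validation repairs zero substrate Michaelis constants to
the default 0.1 g/L and rejects models with more than 20 reactions unless
`--allow-large` is given.

## Library

```python
import gba

model, conditions = gba.build_example_model()
report = gba.check_model(model, conditions)
assert report.is_valid
solutions = gba.solve_all(model, conditions, gba.SolverOptions(seed=42))
for s in solutions:
    print(s.condition_label, s.mu, s.phi)
```

The solver maximizes the balanced growth rate over the growth-scaled fluxes
`xi = v / mu`, under which internal concentrations are linear
(`c = M_int @ xi`), the density constraint `sum(c) = rho` is linear, and
`mu(xi) = c_P / sum(xi * tau)` with `tau` the per-reaction turnover time.
SLSQP is the default backend; `lbfgs` and `mma` run an augmented-Lagrangian
outer loop around an L-BFGS-B inner solver. Multistart is deterministic
given the seed, and condition sweeps warm-start from the previous optimum.

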