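# qbretsim

Lattice Monte Carlo simulation and quantitative analysis of BRET-based
membrane-protein dimerization experiments.

## Why

Quantitative BRET (qBRET) titrations are the workhorse evidence for direct
physical interaction between membrane proteins such as GPCRs: a luciferase-
tagged donor receptor is co-expressed with increasing amounts of a
fluorophore-tagged acceptor, and the BRET ratio is plotted against the
acceptor/donor expression ratio. Specific dimerization gives a saturating
one-site curve y = BRET_max·x/(BRET_50 + x); random crowding ("bystander"
BRET) gives a linear rise. The catch: the classical analysis assumes donor
expression is constant across the titration, and in transient transfection
it rarely is. When donor expression falls as acceptor expression rises,
even purely non-specific adjacency produces a beautiful saturation curve —
a false positive for dimerization.

`qbretsim` provides:

* a stochastic hexagonal-lattice simulator of donor/acceptor diffusion,
  association and dissociation on a membrane patch, with the simulated
  BRET ratio counted as adjacent donor–acceptor pairs per donor;
* the quantitative analysis toolkit: BRET/intensity ratios, one-site
  saturation fits, donor-stratified "Type I" plots (BRET ratio vs acceptor
  expression by luminescence group), classical "Type II" plots (BRET ratio
  vs acceptor/donor ratio), an ANCOVA test of slope equality, and a
  specific/non-specific classifier that prefers the stratified evidence;
* synthetic plate-reader-style data generators (lattice-driven and a fast
  closed-form surrogate) with independent or anticorrelated expression and
  relative Gaussian noise.

## Worked example

```python
import qbretsim as qs
from qbretsim.simulator import run_grid, SPECIFIC, NON_SPECIFIC
from qbretsim.analysis import fit_one_site, classify_interaction
from qbretsim.io import adapt_simulation_grid

levels = range(100, 1001, 100)
grid = run_grid(levels, levels, NON_SPECIFIC, n_rep=5, seed=1)
agg = grid.groupby(["n_donor", "n_acceptor"])["bret"].mean().reset_index()
fit = fit_one_site(agg["n_acceptor"] / agg["n_donor"], agg["bret"])
print(f"non-specific pooled one-site R^2 = {fit.r_squared:.3f}")
print(classify_interaction(adapt_simulation_grid(grid)).verdict)
```

prints

```
non-specific pooled one-site R^2 = 0.486
non_specific
```

— with no binding at all (all association probabilities zero), the pooled
classical saturation fit is poor (R² ≈ 0.49), and the classifier reads the
donor-stratified slopes as non-specific. Running the same sweep with
`SPECIFIC` (donor–acceptor association probability 1) raises the pooled
R² to ≈ 0.85 and the classifier verdict to `specific`; running
`run_anticorrelated(1100, levels, NON_SPECIFIC, n_rep=5, seed=1)` — donor
falling one-for-one as acceptor rises — pushes the *non-specific* pooled
fit to R² ≈ 0.99, the false positive that motivates the stratified
analysis.

The same workflows are available from the shell:

```
qbret-sim simulate --preset specific --donors 100:1000:100 \
    --acceptors 100:1000:100 --steps 1000 --reps 5 --seed 1 -o grid.csv
qbret-sim synth --mode non_specific --n 100 --noise 0.1 --seed 1 -o wells.csv
qbret-sim analyze wells.csv --report report.json
qbret-sim classify wells.csv
```

Plate-reader CSVs (columns `well, condition, fluorescence,
total_luminescence, em485, em530`, donor-only wells labeled
`condition=donor_only` for baseline subtraction) are accepted by
`analyze`/`classify` directly.

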