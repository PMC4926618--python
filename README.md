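# barcodiv

Tree-based biodiversity assessment for DNA-barcode surveys.

Large-scale inventories of hyperdiverse groups — tropical leaf beetles and
their host plants are the motivating case — increasingly rest on one or a
few standardised DNA barcodes (mitochondrial *cox1* for the insects, plastid
spacers for diet) rather than on prior taxonomic expertise. `barcodiv`
implements the analytical side of that workflow for people running such
surveys: it delimits species on single-locus trees without prior hypotheses,
attaches taxonomy to unidentified sequences from their placement among
tagged references (conservative by design: phylogenetic bracketing trades
resolution for protection against false positives), extrapolates how much
of the fauna the sampling has captured, and scores molecular delimitations
against morphospecies sorting. A multispecies-coalescent survey simulator
with complete ground truth makes every claim testable at desk scale.

## The models in brief

**Species delimitation.** The general mixed Yule-coalescent (GMYC) model
locates a threshold age *T* on an ultrametric gene tree separating
between-species branching from within-species coalescence. With waiting
times *x_i* between successive branching events, lineage counts *n_d,i*
(species level) and *n_j,i* (within entity *j*), each interval contributes
ln *b_i* − *b_i x_i* with

&nbsp;&nbsp;&nbsp;&nbsp;*b_i* = λ₁ *n_d,i*^*p₁* + λ₂ Σ_j [*n_j,i*(*n_j,i* − 1)]^*p₂*

profiled over all candidate thresholds; a likelihood-ratio test against the
single-process null (χ², 3 df) asks whether a species boundary exists at
all, and the thresholds within 2 log-likelihood units of the optimum give a
confidence range of entity counts. The Poisson tree processes (PTP) model
is the non-ultrametric alternative: branch lengths fall into speciation and
coalescent exponential classes over an antichain of species roots, fitted
exactly (small trees) or by deterministic hill climbing.

**Assignment.** For each query, STRICT reports the unanimous taxonomic
prefix of the least inclusive supported clade in which references bracket
the query; LIBERAL reports the majority lineage of the nearest
reference-bearing clade. Strict is always a prefix of liberal.

**Richness.** Incidence-based Chao2 and jackknife estimators plus Chao1 on
abundances, analytic rarefaction E[*S_t*] = Σ_i [1 − C(*m*−*Y_i*, *t*)/C(*m*, *t*)],
and completeness *S*_obs/*Ŝ* reported across estimators as an interval.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## A worked example

```sh
python examples/02_species_delimitation.py
```

prints, for a simulated 10-species survey of 50 individuals:

```
GMYC entities       : 10 [10-11] (true: 10)
threshold age       : 0.0358 subs/site
LR vs single process: 18.36 (p = 0.00037)
PTP species         : 12 (from 41 unique haplotypes)
```

The mixed model places the species boundary at 0.036 substitutions/site and
recovers the 10 simulated species exactly, with a confidence range of 10–11
entities; the likelihood-ratio test firmly rejects a single branching
process, i.e. the tree really does contain a species boundary. PTP, fitted
on the non-ultrametric NJ tree of the dereplicated haplotypes, splits
slightly finer — its usual behaviour on shallow clusters.

Continuing with the same toolkit (`examples/04_richness_extrapolation.py`,
25-species pool sampled with patchy detection):

```
observed species    : 25 (true pool: 25)
chao2      : S_hat =   26.0   completeness =  96.1%
jackknife1 : S_hat =   29.5   completeness =  84.7%
```

so this survey would be reported as 85–96% complete depending on estimator
— the interval form in which inventory completeness is customarily given.

The other scripts in `examples/` cover simulation, taxonomic assignment,
morphospecies comparison and the end-to-end pipeline; the `barcodiv` command
exposes the same stages as subcommands (`barcodiv simulate`, `cluster`,
`tree`, `delimit`, `assign`, `richness`, `compare`, `pipeline`) for shell
use.

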