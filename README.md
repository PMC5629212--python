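# cytocausal

Causal discovery for perturbed single-cell signaling data.

Mass-cytometry perturbation studies measure a panel of phosphoprotein
markers in thousands of single cells per experimental condition: cells
from a gated subpopulation are stimulated (or not) with an extracellular
**activator**, and treated with one of many **inhibitors** at increasing
dosages. `cytocausal` implements two complementary routes from such
tables to directed causal claims between markers, plus the machinery to
test those claims:

1. **CLCD — conservative local causal discovery.** The activation
   indicator *A* is set by the experimenter, so it has no causes among
   the markers. For a marker pair (*S*, *T*), the pattern

   *S* ⫫̸ *A*, *T* ⫫̸ *A*, *S* ⫫̸ *T*, *S* ⫫̸ *T* | *A*, *S* ⫫̸ *A* | *T*, and *T* ⫫ *A* | *S*

   identifies the chain *A* → *S* → *T* and licenses the prediction
   "*S* causes *T*" — robustly even under latent confounding of *S* and
   *T* or an *S*–*T* feedback loop, either of which destroys the
   conditional independence *T* ⫫ *A* | *S*. All six tests use dual
   thresholds (reject independence at *p* < α = 0.001, accept at
   *p* > β = 0.15) and a prediction additionally requires the same
   pattern on at least 10 of the 27 replicate dose-zero plates.

2. **Shift-intervention estimation (backshift-style).** Across the
   dosage environments *e* of one inhibitor, the linear model
   x = **B** x + c<sup>e</sup> + ε implies

   (I − **B**) Σ<sub>x</sub><sup>e</sup> (I − **B**)ᵀ = Σ<sub>ε</sub> + Σ<sub>c</sub><sup>e</sup>,

   with Σ<sub>ε</sub> invariant over environments and each intervention
   covariance Σ<sub>c</sub><sup>e</sup> diagonal (targets unknown).
   Differencing the observed covariances against their pooled average
   cancels Σ<sub>ε</sub>; joint diagonalization of the differences
   recovers I − **B** up to row permutation and scale, which a linear
   sum assignment resolves. Three or more environments identify **B**
   even with cycles and confounders; a parametric bootstrap on the
   diagonalization residual flags model violations, and stability
   selection (E(V) = 5, 100 half-subsample refits, π = 0.75) bounds
   false edge discoveries.

Predictions are then (a) checked for **consistency in independent
datasets** by exactly scoring all 12 source-restricted trio networks
with the BGe (Bayesian Gaussian equivalent) marginal likelihood, and
(b) scored for **ranked precision** against a directed ancestry ground
truth (e.g. mined from KEGG pathways), with stratified random baselines.

A first-class synthetic-data generator reproduces the full study layout
(activator × inhibitor × dosage × replicate plate, per-condition cell
counts down to the tens) from known linear causal models, so every stage
is testable against ground truth without any data download.

## Worked example

```bash
cytocausal simulate --p 4 --edge-density 0.5 --n-inhibitors 27 \
    --n-dosages 8 --n-per-condition 300 --seed 7 --out-dir study
# wrote 432 condition tables to study

cytocausal clcd --study study --out predictions.csv
# 1 predictions -> predictions.csv
```

`predictions.csv`:

```
cause,effect,activator,subpopulation,support,total
pP02,pP04,act1,pop1,15,27
```

The trio pattern for (pP02, pP04) held on 15 of the 27 replicate
plates, so CLCD predicts pP02 → pP04 — a true edge of the generating
model (`study/truth_edges.tsv` lists its ancestral pairs).

```bash
cytocausal backshift --study study --seed 7 --out edges.csv
# 2 stable edges (100/100 successful refits) -> edges.csv
cat edges.csv
# from,to,coefficient,selection_frequency
# pP01,pP04,-0.8893617279305286,0.87
# pP04,pP02,0.7773043224359734,0.82
```

From the 8 dosage environments of one inhibitor, the estimator keeps
two edges that survived stability selection: pP01 → pP04 matches the
ground truth (true coefficient −0.89 magnitude recovered), while
pP04 → pP02 is the true pP02 → pP04 edge reversed — the kind of
orientation error that the reversed-precision diagnostic below makes
visible.

```bash
cytocausal evaluate --predictions predictions.csv \
    --truth study/truth_edges.tsv --seed 7 --out metrics.json
# precision 1.000 (reversed 0.000), chance 0.300, z = 1.45
```

The CLCD prediction has precision 1.0 against the ancestral ground
truth; a random prediction of the same size scores 0.30 on average.
`cytocausal run-all --config cfg.yaml` chains all stages (simulate →
clcd → backshift → score-consistency → evaluate) and writes a manifest
with content hashes for reproducibility.

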