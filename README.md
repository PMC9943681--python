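# colocseq

RNase protection kinetics for subcellular transcriptome topology.

Fractionation-based subcellular transcriptomics isolates an organelle,
digests surface-attached RNA with an RNase, and sequences what survives.
Its chronic weakness is false positives: abundant or slowly digested
contaminants survive the treatment and get called "resident". This package
implements the computational side of a kinetically controlled alternative:
instead of one digestion snapshot, the organelle prep is split across a
gradient of RNase A concentrations (plus an untreated reference), and each
transcript's depletion dynamics across the gradient is modelled explicitly.
A parallel experiment on detergent-lysed organelles (the "mock" condition)
separates membrane protection from intrinsic RNase resistance.

## Model

Digestion of the accessible pool of transcript *i* by a kinetically perfect
RNase is pseudo-first order, dR/dt = −k·R·A. At fixed digestion time *t*,
with a pool fraction P₀ shielded from the enzyme, the measured remaining
fraction as a function of RNase concentration *A* (μg/ml) is

    Model 1:  f(A) = (1 − P₀) · exp(−k′A) + P₀        0 ≤ P₀ ≤ 1,  k′ ≥ 0
    Model 2:  f(A) = exp(−k′A)                         (P₀ = 0, pure contaminant)
    Model 3:  f(A) = 1                                 (P₀ = 1, fully protected)

P₀ — the protected fraction — is the parameter of interest; k′ (per μg/ml)
folds the bimolecular rate constant and the fixed time, k′ = k·c·t.
Comparing P₀ fitted with intact membranes (coloc) and after lysis (mock)
classifies each transcript:

| coloc P₀ | mock P₀ | call |
|---|---|---|
| < 0.1 | < 0.1 | degradable contaminant |
| ≥ 0.2 (CI above 0.1) | < 0.1 | resident |
| ≥ 0.2 | ≥ 0.1 | RNase-resistant (potential false positive) |

## Worked example

Simulate a mixed experiment (77% contaminants, 18% residents, 5%
RNase-resistant transcripts, the composition typical of a crude
mitochondrial prep), fit, and classify:

```
colocseq simulate --scenario mixed --seed 5 --n-features 50 --outdir sim
colocseq fit --counts sim/counts.tsv --samples sim/samples.tsv --outdir fit
colocseq classify --fits fit/fits.tsv --outdir calls
```

The classify step prints the topology landscape:

```
 tau_low  tau_high               category  n  fraction features
     0.1       0.2               resident  9      0.18 gene_0039,...
     0.1       0.2 degradable_contaminant 39      0.78 gene_0000,...
     0.1       0.2        rnase_resistant  2      0.04 gene_0048,...
     0.1       0.2              ambiguous  0      0.00
```

`fit/fits.tsv` carries one row per (transcript, condition) with the fitted
P₀ and k′, 95% profile-likelihood confidence intervals, R², the
parameter-dependency diagnostic that triggers the Model-2 fallback, and k
converted to M⁻¹ s⁻¹ (at k′ = 1 per μg/ml, RNase A mass 13,700 g/mol and
t = 600 s this gives k ≈ 2.28 × 10⁴ M⁻¹ s⁻¹, the scale of a slow RNase A
substrate). Every output directory receives the effective configuration
and its hash for provenance.

The same operations are available as library functions
(`colocseq.select_model`, `colocseq.classify_transcript`,
`colocseq.simulate_counts`, ...); see the docstrings and
`docs/methods.md` for the modelling details.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the main computation from scratch: it simulates a 200-transcript
mixed gradient experiment with known ground truth at the generator
defaults, fits every profile in both conditions, classifies all
transcripts, and prints the recovered landscape together with the median
P₀ recovery error and the fraction of correct topology calls to stderr.
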