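# shapereadout

Tools for quantifying and interpreting **DNA shape readout** by
transcription factors.

Transcription factors recognize DNA both by contacting bases directly
("base readout") and by sensing the local three-dimensional structure of
the double helix ("shape readout") — minor groove width (MGW), propeller
twist (ProT), roll, and helix twist (HelT). Structural parameters are
available as exhaustive k-mer lookup tables (pentamers for base-pair
parameters, tetramers for step parameters after recentering), which makes
shape a *function of sequence* — and therefore makes shape and base
readout nearly collinear. This package implements a complete workflow for
disentangling them from binding data alone:

1. **Shape tables** (`shapereadout.tables`) — read/write k-mer tables,
   reverse-complement symmetrize, recenter step parameters onto
   tetramers, permute, and synthesize tables with controlled structure.
2. **Sequence-to-shape regression** (`shapereadout.seq2shape`) — linear
   models `φ̂(s) = X(s)·γ` with mononucleotide, adjacent-dinucleotide, or
   all-pairs indicator features; exact degrees-of-freedom accounting for
   the reverse-complement-symmetric designs (⌈(3k+1)/2⌉ mono,
   4⌊3k/2⌋−2 dinucleotide); leave-one-out cross-validation that holds
   out reverse-complement pairs together.
3. **Binding models** (`shapereadout.models`) — mechanism-agnostic
   free-energy models −ΔΔG/RT = β⁽⁰⁾ + Σᵢ β⁽¹⁾ᵢ,ₛᵢ + Σᵢ β⁽²⁾ᵢ,ₛᵢ:ᵢ₊₁ and
   shape-readout models β⁽⁰⁾ + Σᵢ β⁽¹⁾ᵢ,ₛᵢ + Σᵢ β⁽ᵠ⁾ᵢ φ(sᵢ₋₂:ᵢ₊₂), with
   the exact sequence-only representation of the latter (convolution of
   the sensitivity profile with the sequence-to-shape coefficients) and
   O(k) transfer-matrix partition sums σ(β) = Σₛ exp(X(s)·β) with
   analytic gradients.
4. **Desk-scale SELEX inference** (`shapereadout.selex`) — simulate
   two-round SELEX by exact enumeration (variable region ≤ 12 bp), fit
   the round-0 k-mer bias model and the round-1 multi-view binding model
   (mono, mono+di, or mono + table-derived shape predictors = direct
   shape regression) by multinomial maximum likelihood, and score models
   by the Pearson correlation of held-out 10-mer log counts.
5. **Shape projection** (`shapereadout.projection`) — the core method:
   decompose a mechanism-agnostic model into base readout plus
   per-position shape-sensitivity profiles by minimizing either the KL
   divergence between the models' Boltzmann sequence distributions or the
   summed squared affinity error, with p-norm penalties normalized by the
   unpenalized solution (defaults λ_shape = λ_mono = 1).
6. **Significance** (`shapereadout.significance`) — complexity-matched
   random tables (U(0,1) mono+di coefficient draws rescaled so the
   conditional-variance matrix C_ij = E_{c,d} Var[φ(s)|sᵢ=c, sⱼ=d]
   matches the reference table), null bands, empirical per-position
   p-values and Benjamini–Hochberg q-values.
7. **Profiles** (`shapereadout.profiles`) — Metropolis–Hastings sampling
   of sequences stratified by free-energy bin with mean shape profiles
   per bin; alignment of high-affinity SELEX probes.
8. **Fixtures** (`shapereadout.fixtures`) — deterministic synthetic study
   generators (structured tables, planted-readout models, SELEX reads).

## Worked example

Generate a synthetic study with a planted MGW sensitivity of −1 RT/Å at
position 5 of an 8-bp footprint, project the mechanism-agnostic model,
and test significance against 200 complexity-matched random tables:

```bash
cat > spec.yaml <<EOF
seed: 5
table: {k: 5, feature_name: synthetic-MGW}
binding: {footprint: 8, base_scale: 0.5, planted: [[synthetic-MGW, 4, -1.0]]}
selex: {L: 8, n0: 20000, n1: 20000}
EOF
shapereadout fixtures --spec spec.yaml --seed 5 --out-dir study
shapereadout project --model study/agnostic_model.json \
    --tables synthetic-MGW=study/synthetic-MGW.tsv --out proj.json
shapereadout nulls --model study/agnostic_model.json \
    --tables synthetic-MGW=study/synthetic-MGW.tsv --n 200 --seed 2 --out ens.json
shapereadout fdr --observed proj.json --ensemble ens.json --out fdr.tsv
```

The projection step prints

```
loss 3.73e-14 (reference 8.278e-13); wrote proj.json
```

(the achieved KL loss is numerically zero because the planted model is
exactly representable), and `fdr.tsv` contains, per interior position,
the sensitivity coefficient β (−ΔΔG/RT per unit shape), its empirical
two-sided p-value against the null ensemble, and the BH q-value:

```
feature	position	beta	p	q
synthetic-MGW	3	1.32903e-08	1	1
synthetic-MGW	4	9.55134e-08	1	1
synthetic-MGW	5	-1	0.0243902	0.097561
synthetic-MGW	6	-7.29971e-08	1	1
```

The planted position (5, 1-based) carries the full −1 RT/Å sensitivity —
a preference for a narrowed minor groove there — and is the only
position whose coefficient escapes the matched-table null (q ≤ 0.1;
shown here with a 40-table ensemble for brevity).

Parameter-count queries work directly:

```bash
$ shapereadout seq2shape dof --k 5 --order mono      # -> 8
$ shapereadout seq2shape dof --k 5 --order mono+di   # -> 26
```

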