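# gmma — global multi-mutant analysis of binary folding screens

`gmma` infers the stability effect of individual amino acid substitutions
from growth/no-growth selection of heavily mutated protein libraries, and
combines the best effects into multi-mutant stabilization designs.

## The problem

Deep mutational scans usually introduce one substitution per clone and read
out a continuous enrichment score. An alternative strategy dopes a gene
window at a high per-base rate (~10%), so that each library member carries
many substitutions at once (here, about nine on average), and couples folding
to cell survival through a genetic folding sensor: a variant either
complements growth (folds) or does not. Multiply substituted variants are
informative precisely because substitutions meet in many different genetic
backgrounds — a stabilizing substitution reveals itself by *rescuing*
combinations that would otherwise inactivate the protein. Global multi-mutant
analysis (GMMA) turns this combinatorial structure into per-substitution
stability estimates by fitting one additive model jointly to every
variant–phenotype pair.

## The model

Each variant `v` carries a set of substitutions; its folding free energy is
assumed additive,

```
dG(v) = dG_ref + sum_{s in v} ddG_s        [kJ/mol, negative = stable]
```

and the probability of the active (complementing) phenotype follows a
logistic link on the stability scale,

```
P(active | v) = 1 / (1 + exp(dG(v) / RT))
```

so with a binary readout the model is a logistic regression on the variant ×
substitution incidence matrix. All parameters (`dG_ref` and one `ddG_s` per
substitution, typically hundreds) are fitted jointly by Levenberg–Marquardt
damped least squares of the 0/1 labels against `P(active)`, seeded by a
mean-field initialization. Standard uncertainties come from the curvature of
the objective at the optimum; effects observed in at least 40 variants with
uncertainty at or below 6.3 kJ/mol are deemed reliable, ranked, and combined
(one substitution per position) into a multi-mutant whose expected stability
assumes perfect additivity. A binary readout only identifies `dG/RT`, so the
link scale `RT` (default 2.52 kJ/mol, thermal energy at the 30 °C screen)
pins the energy unit; see `docs/methods.md` for what that does and does not
buy you.

The package also implements the surrounding data path: amplicon read
validation and mutation calling against a reference template, per-pool
genotype counting with a sequencing-noise cutoff derived from the mutation
rate in the 2 × 10 bp flanks, aggregation of DNA genotypes to protein
variants, activity labelling, exclusion rules (nonsense variants,
irreversibly fatal substitutions, variants absent from the input pool), and
a substitution co-occurrence connectivity check. A synthetic doped-library
generator with known ground truth makes the whole chain testable without any
external data.

## Worked example

Simulate a screen of 15,000 transformants over a 140-base doped window with
known ground-truth effects, fit it, and design a multi-mutant:

```python
from gmma import simulate_dataset, run_gmma
from gmma.design import rank_reliable, select_combination
from gmma.simulate import recovery_report

variants, truth, template = simulate_dataset(seed=7, n_transformants=15_000)
analysis = run_gmma(variants)
print(f"variants: {len(variants)}  in fit: {analysis.n_variants_fit}")
print(f"unique substitutions: {len(analysis.stats)}  reliable: {len(analysis.reliable)}")
ranked = rank_reliable(analysis.fit, analysis.reliable, analysis.stats_fit)
for entry in ranked[:5]:
    print(f"  {entry.rank:2d}. {entry.substitution}  ddG = {entry.ddG:6.2f} "
          f"+/- {entry.su:.2f} kJ/mol  (n = {entry.n_variants})")
design = select_combination(ranked, top_k=15, params=analysis.fit.parameters)
print(f"predicted ddG if additive: {design.predicted_ddG:.1f} kJ/mol")
report = recovery_report(truth, analysis.fit, analysis.stats_fit)
print(f"truth recovery: r = {report['pearson_r']:.3f}, "
      f"top-5 in fitted top-15: {report['top_overlap']}/5")
```

prints

```
variants: 15000  in fit: 10294
unique substitutions: 812  reliable: 278
   1. T87R  ddG = -13.51 +/- 0.70 kJ/mol  (n = 279)
   2. V78D  ddG = -11.41 +/- 0.76 kJ/mol  (n = 277)
   3. I51V  ddG = -10.74 +/- 0.72 kJ/mol  (n = 322)
   4. V75I  ddG = -10.27 +/- 0.74 kJ/mol  (n = 281)
   5. P70L  ddG = -10.20 +/- 0.65 kJ/mol  (n = 362)
predicted ddG if additive: -123.5 kJ/mol
truth recovery: r = 0.963, top-5 in fitted top-15: 5/5
```

About a third of the library is excluded from the fit (nonsense-carrying
variants), several hundred substitutions pass the reliability filter, and
the fitted ranking recovers the truly most stabilizing substitutions; the
quoted `ddG` magnitudes are inflated relative to truth because a binary
readout constrains ranking far better than absolute scale (`docs/methods.md`).

A command-line layer covers the same path from files:
`gmma simulate`, `gmma count`, `gmma label`, `gmma fit`, `gmma design`
(see `--help` on each).

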