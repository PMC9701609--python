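# Methods

This note documents the model, the reconstructed procedures, the synthetic
data generator, and the numerical choices behind `gmma`, including the
places where the design was genuinely open.

## Model and assumptions

The analysis assumes that substitution effects on folding free energy are
additive: variant `v` has `dG(v) = dG_ref + Σ_{s∈v} ddG_s` (kJ/mol, negative
stable). The binary phenotype — a clone either complements growth or does
not — is linked to stability by a logistic function,
`P(active) = 1/(1 + exp(dG/RT))`. Two assumptions matter:

* **Additivity.** Epistasis beyond additive free energies is not modelled;
  compensation between substitutions is captured exactly insofar as it is
  energetic (a stabilizing substitution offsets destabilizing ones in the
  sum), which is the phenomenon the method exploits.
* **Scale identifiability.** A binary readout determines `dG` only up to a
  positive factor: multiplying `RT`, `dG_ref` and every `ddG` by the same
  constant leaves every predicted probability unchanged (this covariance is
  asserted numerically in the test suite). Fixing `RT = 2.52` kJ/mol (thermal
  energy at the 30 °C screening temperature) pins the unit, but the *data*
  still prefer sharper-than-true links: for a correctly classified variant,
  inflating all energies monotonically shrinks its squared residual. The
  global least-squares optimum therefore tends to inflate the energy scale,
  and `dG_ref` can run to its box bound while the *ranking* and relative
  spacing of effects remain excellent (truth-recovery Pearson r ≈ 0.96 at
  study scale). Conclusions should rest on ranking and on effects relative
  to `dG_ref`, not on absolute kJ/mol values — which is also how the method
  is used for engineering.

## Fitting procedure

**Mean-field initialization** (reconstructed; the published description is a
single sentence, and the original continuous-readout formulation differs).
Two steps: (a) fit a two-parameter burden model — `P(active at burden n) =
sigmoid(−(d0 + n·m)/RT)` — to the survival-vs-burden curve by least squares
weighted by √(class size); (b) for each substitution `s`, minimize over one
scalar `ddG_s` the squared residuals of the variants containing `s`, every
co-occurring substitution contributing the background mean `m`. Substitutions
seen only in active (only inactive) variants are clamped to the lower (upper)
`ddG` bound, since one-sided data only bound the effect. The per-substitution
step is verified against a dense 0.01 kJ/mol grid of its own objective.

**Global fit.** All parameters are refined jointly by Levenberg–Marquardt
damped least squares on the binary residuals `y_v − P(active|v)` (least
squares, not Bernoulli likelihood, is the default objective). The residual
Jacobian is analytic and sparse — `∂r_v/∂θ_j = p_v(1−p_v)/RT` for every
parameter θ_j touching variant v — so one iteration on ~15,000 variants ×
~800 parameters costs a sparse product plus one dense solve of the damped
normal equations. Damping multiplies the diagonal; it grows ×10 on rejected
steps and shrinks ×0.1 on accepted ones. Only improving steps are accepted,
so the final RSS never exceeds the initial one. Parameters are kept in their
boxes by projection; a parameter whose bounds coincide (e.g. pinning
`dG_ref` in oracle tests) is frozen out of the solve entirely, because
solving for it and then clipping distorts the step. Convergence: step norm
< 1e-8, relative RSS decrease < 1e-12, absolute RSS < 1e-12 (an already
exact fit), or no improving direction; hitting the iteration cap (500) flags
`converged=False` without raising. On toys with few free parameters the fit
matches dense/refined grid-search optima within the grid resolution.

**Standard uncertainties.** `su_i = sqrt(σ² [(JᵀJ)⁺]_ii)` with
`σ² = RSS/(n−p)` at the optimum. The pseudo-inverse handles singular
directions; hanging substitutions (observed in a single variant) are
unidentifiable and receive the sentinel cap of 100 kJ/mol. The analytic
Jacobian and the formula are tested against a central-finite-difference
Jacobian oracle, and the expected ≈1/√2 shrinkage under dataset duplication
is verified with its exact degrees-of-freedom correction.

**Reliability and categories.** A substitution is *reliable* when observed
in ≥ 40 variants with su ≤ 6.3 kJ/mol (both configurable). Reliable effects
are stabilizing if `ddG + su < 0`, destabilizing if `ddG − su > 0`, else
neutral; the ±1·su boundary is this package's choice and is exposed as
`su_factor`. A non-reliable effect estimated to destabilize more than the
reference (`ddG > −dG_ref`) is still called destabilizing — such variants
are unfolded regardless of the estimate's noise; the remaining non-reliable
effects are unknown, and irreversibly fatal substitutions form their own
class. Category counts always sum to the substitution universe.

## Data-path rules

* **Read processing.** A merged amplicon read is accepted iff its length
  matches the template and it contains only A/C/G/T. Mismatches inside the
  doped window become the genotype; mismatches in the two 10-base flanks are
  only counted, as the sequencing-error estimate. The per-pool count cutoff
  is reconstructed (the original work states only its input, the flank
  mutation rate): with per-read window-error probability
  `q = 1 − (1 − rate)^window`, the cutoff is the smallest `c` at which the
  expected number of error-derived genotypes reaching `c` reads — one
  Poisson class with mean `q·R` per parent genotype with `R` reads, a
  deliberately conservative aggregation — drops below 0.5. Both the 0.5
  threshold and a fixed per-pool override are configurable. The cutoff is
  non-decreasing in the error rate by construction.
* **Activity labels.** Active ⇔ selected-pool count ≥ its cutoff; inactive ⇔
  input-represented but not active; selected-only variants (absent from the
  input pool) are discarded as uninterpretable; variants below both cutoffs
  are dropped as unobserved. "Above the cutoff" is implemented inclusively
  (the cutoff is the smallest kept count), with a strict mode available. No
  pseudo-counts anywhere. Whether the original read filtering rejected reads
  with flank mismatches outright is unknown; this package keeps them (more
  data) and uses flank mismatches solely for error estimation.
* **Exclusions.** Nonsense mutations set a variant flag (stops are not
  parameters) and force the variant inactive; nonsense variants are excluded
  from fitting. A substitution is irreversibly fatal when never observed
  active despite ≥ 20 observations (`min_obs`, configurable; the published
  count of such substitutions implies a threshold but not its value). Fatal
  detection runs on stop-free variants only — nonsense variants are inactive
  for reasons unrelated to their substitutions and would fake fatality.
  Variants carrying fatal substitutions are excluded from both the
  mean-field and the global fit for model coherence.
* **Connectivity.** Substitutions are fit jointly only insofar as they
  co-occur: the co-occurrence graph is checked and a disconnected graph is
  reported (information cannot flow between components).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes — it
is the package's test bed, not a model of any particular wet-lab protocol.

* **Template.** A fixed synthetic 50-codon window (residues 48–97) with
  10-base flanks; a 10-base undoped cloning cassette splits the window into
  doped blocks of 71 and 69 bases (140 dopable positions). The sequence is
  random but frozen (stop-free reference); it is not a natural gene.
* **Doping.** Each doped base independently substituted with probability
  0.10, uniformly over the three alternatives. At this rate a molecule
  carries ~14 base changes ≈ 9 amino acid substitutions, and ~30% of
  molecules acquire a stop codon.
* **Truth.** Ground-truth `ddG` per reachable substitution (enumerated at
  codon level, covering multi-base codon changes) from a three-component
  normal mixture: 80% destabilizing N(+4, 2²), 15% neutral N(0, 0.5²), 5%
  stabilizing N(−2.5, 1²) kJ/mol; reference stability −25 kJ/mol. The
  mixture is invented (no published distribution exists to copy); it is
  chosen to put the mean burden near the inactivation midpoint so the
  transition is well probed, yielding roughly a quarter of variants active —
  the regime a well-designed screen operates in. The generated libraries
  satisfy the two published library-design requirements: many-fold more
  variants than unique substitutions, and mean burden within ±3 of the
  half-inactivation burden.
* **Screen.** Bernoulli mode draws survival from the logistic probability
  (optionally flipping labels at a noise rate ε); threshold mode activates
  iff `dG_true < 0`. Nonsense genotypes never survive.
* **Reads.** Input-pool reads sample genotypes proportional to multiplicity;
  selected-pool reads only from surviving clones; every base (window and
  flanks) flips independently at the read error rate (default 0.001),
  producing the spurious low-count genotypes the cutoff must remove.
* **Not modelled:** PCR chimeras, quality scores, colony-growth amplification
  noise, position-dependent error rates, and indels (doped oligos
  substitute only). Passing tests therefore demonstrate correctness of the
  inference given the model's own assumptions, not robustness to every
  artifact of real sequencing data.

The whole simulate → call → label → fit chain is deterministic under a fixed
seed.

## Problem sizes

Tests and the acceptance script run the full-scale chain at 15,000
transformants (≈ 15,000 unique protein variants, ≈ 800 unique substitutions,
≈ 10,300 variants in the fit), which completes in under a minute; the
sequencing-read path is exercised at 2,000 transformants × 20,000 reads per
pool, enough for the flank-rate estimate to resolve the simulated error rate
within binomial uncertainty. Oracle comparisons use toys with ≤ 4 free
parameters where dense grid search is exact.

## Known limitations

* Absolute energies are soft (see above); only ranking and large relative
  differences are trustworthy. The fitted `dG_ref` may sit at its box bound.
* Hanging substitutions and substitutions seen in few variants get clamped
  or high-uncertainty estimates; the reliability filter exists to keep them
  out of downstream conclusions, and truth-recovery metrics are accordingly
  computed over well-observed substitutions.
* The mean-field initialization is a reconstruction of a briefly described
  procedure; it only needs to be good enough to seed the global fit, and its
  burden-curve background systematically underestimates heterogeneous
  effects.
* Multi-mutant predictions assume perfect additivity; realized stabilities
  of combined substitutions are typically somewhat smaller in magnitude.
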