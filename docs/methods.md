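# Methods

## Model and assumptions

`nascentfold` treats a nascent protein domain as a two-state folder riding
on a stochastically elongating ribosome. The model rests on six
assumptions, stated here because every engine in the package implements
exactly these and nothing more:

1. **Steady-state translation** — initiation and termination fluxes
   balance, so the bound-ribosome position distribution is stationary.
2. **Two-state folding** — the domain interconverts between unfolded and
   folded with rates k_F,i and k_U,i at nascent length i (no
   intermediates).
3. **Exponential dwells** — the ribosome's residence time at codon i is
   exponential with rate k_A,i (amino acids per second). A
   two-exponential (hypoexponential) translocation-cycle dwell is
   available in the stochastic simulator to probe this assumption.
4. **Uniform rates by default** — preset schedules use one mean rate at
   every codon (3.9 AA/s, the measured average in CHO cells); any
   per-codon schedule may be substituted.
5. **Exit-tunnel steric block** — folding rates are identically zero
   below the onset length (domain end + tunnel linker; default linker 30
   residues, a mid-range literature value), because the tunnel is too
   narrow for tertiary structure.
6. **Bulk rates beyond the onset** — at and beyond the onset, and after
   release, the domain folds and unfolds at its bulk rates.

Position `M` (1-based) is the stop codon; its dwell is a real dwell during
which folding continues, and P_F,Co-T is read after it. Sense codons are
1..M−1.

## Steady-state profile

With P_eq,i = k_F,i/(k_F,i+k_U,i) and λ_i = k_A,i/(k_A,i+k_F,i+k_U,i),

    P(0) = 0,   P(i) = P_eq,i + (P(i−1) − P_eq,i)·λ_i,

and P(i) = P(i−1) where both folding rates vanish. λ_i is the Laplace
transform of the exponential dwell at the folding relaxation rate. The
reported value is the folded probability at the moment of elongation away
from codon i, averaged over the dwell. A `convention="residence"` flag
reports the time-average over the occupancy of codon i instead; for
exponential dwells the renewal–reward integral reduces to the same factor
λ_i, so the two conventions coincide identically (they differ for any
non-exponential dwell). Both code paths are kept and compared in the test
suite as an algebra check.

Domains with P_F,Co-T = P(M) ≥ 0.5 are classified co-translational
(inclusive at the boundary), otherwise post-translational.

## Pulse-chase engine

Only chains that incorporate at least one observable residue during the
incorporation window [d, p+d) are visible; a chain enters the assay pool
at its labelling time (phosphorimaging cannot see chains that do not yet
carry label). The incorporation instant of residue j is the end of the
dwell at codon j (peptide bond completed). Reported times are
chase-shifted (chase start = 0). The curve is the folded fraction of the
visible pool; report times with an empty pool are flagged undefined, not
returned as 0.

Two deterministic realizations are provided:

- **Master equation (default).** Densities over the joint state
  (codon position × unfolded/folded × unlabelled/labelled), plus a
  released labelled pool, are propagated on a time grid: initiation
  injects constant flux (its magnitude cancels in every reported ratio);
  a ribosome at codon i advances with probability k_A,i·δt per step,
  which makes the discrete dwell geometric with *exactly* the mean
  1/k_A,i and, for small k_A,i·δt, variance within a factor (1−k_A,i·δt)
  of the exponential's; folding relaxes in closed form within each step;
  the advancing flux out of an observable codon inside the window moves
  to the labelled classes. The integration step is automatically
  sub-divided below the protocol's δt (default 0.1 s) so that
  max(k_A,i)·δt ≤ 0.04. Injection starts early enough that every chain
  with a non-negligible labelling probability is represented (mean
  passage time to the last observable codon plus 8 standard deviations)
  and stops at p+d, after which no chain can be labelled. This engine
  retains the stochastic spread of elongation trajectories and agrees
  with the Gillespie simulator within Monte-Carlo error at every report
  time.

- **Cohort mean-field (`method="cohort"`).** One cohort per δt of
  initiation time follows the mean trajectory (codon j occupied during
  [t0+τ_cum(j−1), t0+τ_cum(j))) with closed-form folding. Transparent
  and grid-error-free, but it ignores the dwell-time jitter of the
  onset-crossing time (s.d. ≈ √onset / k_A, about 3.4 s for SFVP ΔC) and
  therefore leaves an unsmoothed kink of up to ~0.02 where the last
  labelled cohorts cross the onset. It was kept because its cohort
  ledger makes the bookkeeping inspectable; the master engine is the
  default precisely because the stochastic simulator arbitrates between
  the two.

The fraction of labelled full-length protein is f_L,R(t) =
N_L,R(t)/N_L,R(t_final) with t_final the last chase report time.

Auto-catalytic cleavage (the SFVP C-protein readout) is identified with
folding: with k_U ≈ 4×10⁻⁵ s⁻¹ refolding of the released domain is
negligible, so the folded fraction equals the cleaved fraction and no
separate cleaved state is modelled.

## Stochastic simulator

Independent ribosome–nascent-chain complexes (no collisions — complexes
do not interact) are simulated event-by-event. The steady-state initial
condition places one ribosome at every nascent length at t = 0 (the
remaining dwell is exponential by memorylessness; complexes already past
the onset start from an equilibrium-sampled folding state). New
initiations arrive with exponential inter-arrival times at rate k_in
(default M/τ_total, the rate implied by one ribosome per nascent length)
until the end of the incorporation window — chains initiated later can
never carry label, so truncating there is exact. For the
non-steady-state virtual experiment the initiation rate is modulated as
k_in(t) = k_in(0)·(1 + A·sin(2πt/τ_p)) and intervals are drawn
sequentially from the instantaneous mean (the simple sequential method);
an exact thinning sampler is available behind a flag for comparison.

Dwells are exponential or hypoexponential: in the two-exponential model
the fitted translocation rates k₁ = 4.7363 s⁻¹ and k₂ = 22.0649 s⁻¹
(mean 1/k₁+1/k₂ ≈ 0.2565 s ≈ 3.9 AA/s) are scaled per codon by a common
factor so each codon's mean dwell matches the schedule's 1/k_A,i,
preserving the k₂/k₁ ratio.

The curve estimator is P_F(t) = (1/N(t))·Σᵢ δ_t(i) over labelled
molecules, N(t) counting molecules whose labelling time has passed.
Replicates (default 20) are averaged; replicates with zero labelled
molecules are flagged and excluded with a warning. Identical seed and
configuration reproduce the event sequence bit-for-bit.

### Comparing engines statistically

The deterministic/stochastic agreement tests use
SEM_eff = max(empirical across-replicate SEM, √(p(1−p)/N_total)) with p
the deterministic prediction. The second term is the pooled binomial
standard error; it matters because at near-saturated time points the
expected number of unfolded molecules is of order one, so the empirical
SEM collapses to zero with sizable probability while the true sampling
scale is ~10⁻⁴. This is a variance floor for a degenerate estimator, not
a tolerance on the physics.

## Rate tables, scaling and recoding

Tables store per-codon times (s) or rates (AA/s); DNA and RNA codons are
accepted and normalized to RNA. Missing sense codons default to the
table's mean value (the occupancy-1.000 convention of relative
ribosome-profiling scores); missing stop codons take 256 ms, the measured
mean codon time in CHO cells. Global scaling multiplies every rate by
χ = target / (arithmetic mean of per-position rates over the reference
CDS's sense codons) — the arithmetic-mean convention is deliberate, for
compatibility with the published scaling procedure, even though the
harmonic mean governs synthesis time. Slowest-synonymous recoding
replaces each sense codon by the synonym with the largest table time
(lexicographically smallest codon on ties, for determinism); the encoded
protein is provably unchanged and no position gets faster.

## Synthetic fixtures

`generate_fixture` builds self-consistent (CDS, rate table, construct,
FactSeq-like signal) bundles: codon times are log-normal (median 0.25 s,
σ_log 0.4, the spread of ribosome-profiling-derived estimates), CDSs are
uniform over sense codons, and bulk rates are rejection-sampled into a
timescale regime. The *marginal* regime (k_F within 10× of the mean k_A,
0.05 < P_F,Co-T < 0.95) requires few codon positions beyond the folding
onset — with many post-onset positions a k_F ≈ k_A domain saturates —
so fixtures place the onset 3–15 positions before the stop, the geometry
of the marginally folding yeast domains in the preset table. FactSeq-like
signals are baseline noise clipped at zero (reproducing the heavy ties at
zero of real signals) with a level shift beyond the onset.

What the generator does **not** emulate: codon-usage bias, correlated
rate structure along real transcripts, ribosome collisions, folding
intermediates, or FactSeq probabilities above 1 from mismatched
numerator/denominator experiments. Passing tests therefore demonstrate
the engines' internal correctness and mutual consistency under the
model's assumptions, not the model's adequacy for any particular real
protein.

## FactSeq region statistics

Per-codon signals are split into Region I (codons 1–50, baseline: the
tunnel forbids folding), Region II (expected unfolded) and Region III
(expected folded); preset boundaries for FRB (51–150 / 151–379) and HA1
(51–309 / 310–565) are included. Pairwise comparison uses the
Mann–Whitney U test (exact enumeration when both samples are ≤ 20 with
no ties, normal approximation with tie correction otherwise; two
identical constant samples return p = 1), with 95% percentile-bootstrap
confidence intervals on region medians (default 100,000 resamples,
computed in memory-bounded chunks).

## Numerical choices and problem sizes

- Master-equation sub-step: max(k_A,i)·δt ≤ 0.04 (≈10 ms at 3.9 AA/s);
  halving it moves the SFVP ΔC curve by < 10⁻³ sup-norm.
- Report grid: 1 s spacing over the chase; report times are snapped to
  the integration grid, no interpolation.
- Gillespie folding jumps are simulated only for labelled molecules;
  cross-engine comparisons use 20 replicates (~6,000 labelled molecules
  for SFVP ΔC), and the length-resolved oracle uses 10⁴ trajectories,
  sizes at which binomial error is ~0.5% and every comparison completes
  in seconds.
- Ties in slowest-synonym selection, the ≥ in the 0.5 classification
  threshold, and the strict > in the 50-residue domain-segment rule are
  all inclusive/exclusive exactly as stated above; the segment rule has
  an `strict=False` escape hatch.
- Degenerate inputs: internal stop codons warn but do not fail
  (polyproteins are in scope); constructs whose onset reaches the stop
  codon are rejected (the domain could never fold on the ribosome);
  empty visible pools yield flagged-undefined curve values.

## Known limitations

- Two-state folding only; domains with long-lived intermediates or
  misfolded states are outside the model.
- Chaperone effects enter only implicitly, by rescaling k_F,i.
- No ribosome exclusion or collisions; initiation never stalls
  elongation.
- The uniform-rate default hides codon-to-codon rate variation; supply a
  per-codon schedule to drop it.
- The sinusoidal-initiation amplitude is a free knob (0 ≤ A < 1); the
  sequential-draw sampler is an approximation to a non-homogeneous
  Poisson process, which is why the exact thinning alternative exists.
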