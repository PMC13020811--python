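# Model and methods

## Entities and state

The simulation holds one *environment* (step counter, consecutive-
starvation counter *t*, predator count, drift map) and a population of
*individuals* (age in steps, life phase egg/living, infection status, and
a genome of two bit-string haplotypes). Genomes are fixed for life — all
mutation is germline. Space is not modelled; individuals interact only
indirectly, through the shared environment (crowding, prevalence, predator
abundance) and through the mating pool.

## Genotype → phenotype map

The heritable traits are survival, reproduction and, optionally, the
germline mutation rate. An age-dependent trait owns one block of
`bits_per_block` bits per age class on each haplotype; an age-independent
trait owns a single block. The trait value is a linear map of the fraction
of bits (over both haplotypes) matching the environmental drift map:

    value = lower + (upper − lower) · matching / (2 · bits_per_block)

so every bit is an additive variant of effect (upper − lower)/(2b),
age-targeted through its block. This is one deliberately simple
realization of "many variants with age-specific effects": it produces a
tunable spectrum of effect sizes, supports SFS annotation by trait, age
and beneficial direction, and makes heterozygous/homozygous dosage
explicit (a site matching on both haplotypes contributes twice the per-bit
effect). Dominance, epistasis and bidirectional alleles at one site are
out of scope. Reproduction values are clipped to zero below maturity and
from menopause on; the reproduction upper bound defaults to 0.5 per step.

Two haplotypes are kept in *all* modes; asexual inheritance copies both.
This keeps one genome representation for both reproduction modes and lets
recombination, assortment and mutation be defined uniformly.

## Mortality processes

Each step executes a configurable process order (default: intrinsic,
abiotic, infection, predation, starvation, reproduction, aging, drift).
Within a process all individuals are evaluated against the state at the
process start; deaths are committed between processes. Each death carries
exactly one cause tag. Eggs are structurally exempt: they live in a
separate pool that no hazard reads. Re-ordering two state-independent
hazards changes which cause claims the deaths but not the distribution of
their total — the `expected_sequential_mortality` helper computes the
expected attribution for any hazard sequence.

* **Intrinsic** — individual of age a dies with 1 − s(a), from its genome.
* **Abiotic** — hazard(step) = baseline + amplitude · waveform(·), with
  flat/sinusoid/square/triangle/sawtooth waveforms scaled to [0, 1];
  baseline + amplitude ≤ 1 is enforced at load time.
* **Infection** — an SIS process. Susceptibles are infected with
  background + transmissibility · (infected/living), clipped to [0, 1];
  infected die with the fatality rate, else recover with the recovery
  rate. The linear force of infection is the simplest form consistent
  with a transmissibility/fatality/recovery parameterization.
* **Predation** — per-prey kill probability vulnerability · (1 −
  exp(−P/N)), a saturating functional response that stays a probability
  for any predator load; predators then grow logistically,
  P′ = P + g·P·(1 − P/N), floored at zero and capped by prey abundance.
* **Starvation** — engages only while the living count exceeds the
  carrying capacity K; the streak counter t increments each such step and
  resets otherwise. *Instantaneous*: exactly N − K uniformly chosen
  individuals die. *Gradual*: per-step survival (1 − m)^t. An optional
  age weighting w(a), normalised to mean 1 over the living so the age-flat
  case reduces exactly to the stated law, skews gradual starvation by age
  (per-individual survival (1 − m·w/w̄)^t, clipped).

Whether eggs count toward K is unspecified in the source model's terms;
here egg invulnerability dominates and eggs are excluded from N.

## Reproduction and the egg stage

Reproduction runs after all mortality, so offspring never face hazards in
their birth step. Eligible individuals (alive, maturity ≤ age <
menopause) attempt with probability f(age); in sexual mode attempts are
shuffled and paired consecutively — random mating, each individual mates
at most once per step, an odd leftover skips the step. One offspring per
pair (or per asexual attempter): each parent's haplotypes are recombined
(Poisson(r) crossovers, cut positions uniform without replacement,
segments alternating), one haplotype is assorted from each parent, and
the genome is mutated bit-wise at the offspring-relevant rate — the
mother-of-record's (first pair member's) evolved rate when the mutation
rate is evolvable, a constant otherwise. Mutation is symmetric (0↔1).
Sexes are not modelled.

Viviparous offspring enter as living age-0 individuals. Oviparous
offspring enter an invulnerable egg pool and hatch either at a fixed
incubation (an egg laid at step s hatches at s + 1 + incubation) or, for
non-overlapping generations, all at once at the first step with zero
living individuals. Aging increments every living individual's age except
same-step recruits; reaching `n_age_classes` is fatal (cause
`age_limit`).

## Environment, randomness, snapshots

Environmental drift flips a Poisson(rate) number of uniformly chosen
drift-map bits per step (default rate 0: static fitness landscape). One
master seed spawns a named RNG stream per process, so disabling one
process never perturbs another's draws; identical configuration + seed
reproduces all outputs byte for byte. Snapshots are single-file zip
containers of named `.npy` blocks plus a JSON header carrying the
architecture (validated on load), environment counters and, optionally,
the per-stream RNG states — restoring them continues a run exactly where
it stopped. Extinction terminates a run gracefully with the step recorded.

## Recorders

Exposure at age a accumulates the living head-count at a each step; since
an individual spends exactly one step per age class this equals the count
entering the age class (a period life table). Observed mortality
q(a) = deaths(a)/exposure(a) (undefined, not zero, at unexposed ages),
survivorship l(a) = Π(1 − q), fertility f(a) = births to parents aged
a / exposure(a); births are credited to the mother of record, and egg
layings count as births at laying. Intrinsic curves are computed from the
genomes alone — population-mean intrinsic mortality and its survivorship,
plus per-individual curves. Life expectancy is Σₐ l(a) (each age class
contributes the probability of entering it as one age-class unit); median
lifespan is the lower weighted median of the age-at-death distribution,
while curve-based medians interpolate the 0.5 crossing linearly. The SFS
uses all haplotypes of a genotype dump; fixed loci are excluded from the
binned spectrum by default (toggle provided), and every locus is
annotated with trait, age class, per-bit effect and the currently
beneficial bit.

## Experiments

The harness runs a burn-in once, snapshots it (without RNG states, so
each arm restarts from its own seed), and starts every arm — baseline
plus named dotted-key deltas — from that hash-verified snapshot.
Replicates are paired across arms by derived seed.

**Rose-style preset.** Two arms with non-overlapping generations, K =
1000, maturity at age class 14. Each generation a same-aged cohort lives
under benign (intrinsic-only) laboratory mortality and lays eggs tagged
with the laying day; arm B propagates from eggs laid on days 14–21, arm O
lets adults lay to day 50 and carries the latest-laid eggs over, up to K
(strict latest-first ranking; a weighted variant with carry-over
probability ∝ laying day is available). A single collection day cannot
sustain K = 1000 at a fertility ceiling of 0.5 per step — at most ~K/4
eggs per day — hence the 8-day B window. Burn-in runs 200 generations
under B conditions; the arms then evolve 30 generations (a scaled-down
version of the ~50-generation original design). The wild-like extension
re-runs each evolved population with overlapping generations (viviparity)
and resource limitation in which starvation risk rises with age
(w(a) = 1 + 0.3a) — an environment in which extrinsic mortality, not
late-life genetics, dominates realized survival; the life table is taken
from a 200-step window after 400 settling steps so the demographic waves
of the imported single-age cohort have dissipated. The wild comparison is
reported as an equivalence band rather than a significance test: with
~200,000 person-steps of exposure, any systematic difference is
"significant", so the meaningful statement is that the replicate-averaged
curves coincide within 0.06 at every age ≤ 12 while the laboratory
intrinsic-lifespan gap is large.

## Study presets and what they (don't) show

* `preset_emergent_aging` — K = 500, maturity 10, 25 age classes, 4
  bits/block, per-bit germline mutation 0.002, gradual starvation
  m = 0.1, 10,000 steps, initialized age-flat with survival fraction 0.95
  and fertility at its ceiling. The mutation rate is chosen so the
  mutation-pressure relaxation time, 1/(2µ) = 250 generations, fits well
  inside the ~700 generations the run spans; the ceiling-flat fertility
  start makes the subsequent age-graded erosion directly attributable to
  mutation accumulation. Ten replicates typically all show positive
  mortality–age and negative fertility–age rank correlations.
* `preset_neutral_drift` — a Wright–Fisher-like control: 40 zero-effect
  loci (survival bounds collapsed to 1), no mutation, discrete
  generations via oviparity with hatch-on-extinction, and instantaneous
  trimming of a ~2,500-egg pool to K = 200. Uniform trimming of a large
  egg pool is a Cannings resampling with near-Poisson offspring variance
  (variance ≈ 1 − K/pool ≈ 0.92–0.98 of Poisson), so a plain binomial
  Wright–Fisher oracle at 2N = 400 over the realized generation count is
  the matched reference for the martingale and SFS checks.

These are desk-scale designs: hundreds of generations, not the hundreds
of thousands a full equilibrium study would use. Passing them shows the
mechanics produce the right directions and neutral behaviour at small
scale; they say nothing about long-run equilibria, mutation–selection
balance at realistic per-locus effects, or robustness across the full
parameter space. The genome is an abstract additive bit string — no
molecular realism, linkage maps, or dominance — so population-genetic
statistics on its output should be read qualitatively.

## Numerical choices and limitations

Per-step hazard draws are vectorised over individuals; recombination for
a whole offspring batch draws Poisson counts and takes the k
lowest-ranked of i.i.d. uniforms per haplotype pair as cut positions
(exactly uniform-without-replacement). Trait values are clipped to their
bounds; degenerate inputs (empty populations, zero-exposure ages, runs
with no deaths) yield flagged NaNs rather than zeros. The weighted-median
convention for age at death and the Σ l(a) life-expectancy convention are
fixed and documented above; tie-breaks in the Rose egg ranking (eggs of
the marginal day) are resolved uniformly at random. Known limitations:
no parental care, no spatial structure, no somatic mutation,
genotype-independent infection/predation susceptibility, and mutational
meltdown in small populations under high mutation rates (visible as arm
extinction in the high-mutation experiment).
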