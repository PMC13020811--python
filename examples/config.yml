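# Example configuration for `senesim run examples/config.yml --out out/`.
# Any omitted block falls back to the documented defaults; unknown keys
# are rejected with the offending key named.

steps: 2000
seed: 1
carrying_capacity: 400

genome:
  n_age_classes: 20
  survival:
    bits_per_block: 4          # per-bit effect = 1 / (2*4)
  reproduction:
    bits_per_block: 4
    upper_bound: 0.5           # at most a 50% chance to reproduce per step
  mutation_rate:
    evolvable: false
    age_dependent: false
    initial_value: 0.002       # constant germline rate per bit

reproduction:
  mode: sexual
  maturity_age: 5
  oviparous: false             # viviparity: overlapping generations
  recombination_rate: 1.0      # expected crossovers per haplotype pair
  mutation_rate: 0.002

hazards:
  abiotic:
    shape: sinusoid            # seasonal hazard
    amplitude: 0.05
    period: 50
  starvation:
    model: gradual
    susceptibility: 0.1        # survival (1 - m)^t while over capacity

init:
  n: 400
  ones_fraction:               # age-flat, non-aging starting phenotype
    survival: 0.95
    reproduction: 1.0

recording:
  window: 200
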