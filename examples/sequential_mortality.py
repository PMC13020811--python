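"""Order of mortality sources changes the death structure, not the total.

Applies two hazards (40% and 80%) to a cohort of 1000 in both orders and
prints the expected per-source deaths and observed population-level rates.
"""

from senesim import expected_sequential_mortality

for hazards in ([0.4, 0.8], [0.8, 0.4]):
    r = expected_sequential_mortality(1000, hazards)
    print(f"hazards {hazards}:")
    print(f"  deaths per source : {r['deaths'].astype(int).tolist()}")
    print(f"  observed rates    : {[f'{x:.0%}' for x in r['observed_rates']]}")
    print(f"  total deaths      : {r['total_deaths']:.0f}  "
          f"(total rate {r['total_rate']:.0%})")

print("\nThe second source only reaches the survivors of the first, so its")
print("observed rate is smaller than its per-capita rate; the total number")
print("of deaths is the same in both orders.")
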