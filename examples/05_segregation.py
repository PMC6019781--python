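"""Mendelian seed segregation for a recessive embryo-lethal allele.

A selfed heterozygote yields homozygous-mutant (white, aborted) seeds with
probability 1/4 — the classic 3:1 ratio used to diagnose single-locus
embryo lethality from a seed count.
"""

from chloroedit import simulate_seed_segregation

draw = simulate_seed_segregation(n_seeds=10_000, seed=1)
print(f"seeds: {draw.n_seeds}  green: {draw.n_green}  white: {draw.n_white}")
print(f"white fraction: {draw.white_fraction:.4f} (expected 0.2500)")
print(f"green:white ratio: {draw.n_green / draw.n_white:.2f} (expected 3.00)")
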