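"""Entropy-based inhomogeneity metrics on a known composition.

Takes the population and money fractions of a settled baseline run and
computes the normalized Shannon entropies and their deficits, plus the
per-capita money of the rarest and the poorest emotion.
"""

import numpy as np

from spatial_ultimatum.metrics import inhomogeneities, money_per_agent, normalized_entropy
from spatial_ultimatum.strategies import EMOTIONS

# fractions at t=100 of one baseline run (anger, fear, joy, sadness, surprise)
p = np.array([0.012, 0.318, 0.292, 0.254, 0.124])  # share of agents
q = np.array([0.025, 0.357, 0.298, 0.255, 0.065])  # share of money

Hp = normalized_entropy(p)
Hq = normalized_entropy(q)
Ip, Iq = inhomogeneities(Hp, Hq)
phi = money_per_agent(p, q, money_init=100.0)

print("population entropy Hp = %.3f  ->  inhomogeneity Ip = %.3f" % (Hp, Ip))
print("money entropy      Hq = %.3f  ->  inhomogeneity Iq = %.3f" % (Hq, Iq))
for k, e in enumerate(EMOTIONS):
    print(f"  phi_{e.value:<9s} = {phi[k]:6.1f} dollars/agent")
print()
print("Ip, Iq in [0,1]: 0 = five-way even split, 1 = one emotion holds all.")
print("Anger is ~26x rarer than fear yet holds ~208 dollars per agent;")
print("surprise holds ~52 — random bargaining halves its per-capita wealth.")
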