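"""2-mode affiliation network: which animals over-use which facilities.

Simulates a hen-pen-sized arena with fixed facilities and one individual
homed on the feeder, then builds the individual x nearest-facility
contingency table and flags cells with |SR| > 1.96 — the bipartite analogue
of the social network.
"""

import numpy as np

from proxnet import SyntheticConfig, affiliation_association, generate

homes = np.random.default_rng(1).uniform((0.0, 0.0), (3.0, 4.6), size=(8, 2))
homes[0] = (1.5, 2.3)  # Ind00 lives on the feeder

cfg = SyntheticConfig(
    n_individuals=8,
    days=5,
    scans_per_day=96,
    arena=(3.0, 4.6),
    facilities={"Feed": (1.5, 2.3), "Drink": (0.5, 1.0), "Nest": (2.5, 0.5), "Perch": (0.5, 4.0)},
    home_centers=homes,
    home_sd=0.6,
    seed=23,
)

ds, _ = generate(cfg)
aff = affiliation_association(ds)
print("observed individual x facility counts:")
print(aff.matrix("observed"))
print()
for i, ind in enumerate(aff.individuals):
    for j, fac in enumerate(aff.facilities):
        if aff.positive[i, j] > 0:
            print(f"  {ind} over-uses {fac} (SR = +{aff.positive[i, j]:.1f})")
        if aff.negative[i, j] > 0:
            print(f"  {ind} under-uses {fac} (SR = -{aff.negative[i, j]:.1f})")
# Positive cells mark individuals found near a facility far more often than
# the margins predict; Ind00, homed on the feeder, should top the list.
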