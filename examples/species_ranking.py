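"""Rank species by their contribution to service robustness.

Builds a 10-species, 5-trait network containing a generalist that
provides three uncommon traits and a specialist sharing one common
trait, then ranks all species by how much the (dispersion-corrected)
network fragility would rise if they were lost — both via the
first-order prediction and by exact removal.
"""

import numpy as np

from fragnet import SpeciesTraitNetwork, rank_species, ranking_table

species = ["generalist", "specialist", "a1", "a2", "a3", "a4", "a5",
           "b1", "b2", "b3"]
traits = ["common", "u1", "u2", "u3", "u4"]
inc = np.zeros((10, 5), dtype=int)
inc[1:7, 0] = 1        # common trait: specialist + a1..a5
inc[0, 1:4] = 1        # generalist: three uncommon traits
inc[7, [1, 4]] = 1
inc[8, [2, 4]] = 1
inc[9, [3, 4]] = 1
net = SpeciesTraitNetwork(tuple(species), tuple(traits), inc)

records = rank_species(net, c=0.5, lambda_c=1.42, mode="exact")
print(ranking_table(records).round(4).to_string(index=False))
print()
print("Reading: delta_fstar is the predicted rise in corrected network")
print("fragility were that species lost.  The generalist provider of")
print("several uncommon traits tops the ranking; the specialist on a")
print("well-shared trait is nearly redundant and sits at the bottom.")
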