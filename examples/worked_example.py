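"""Enumerate the robustness distribution of the 5-species worked example.

Five species share two functional traits (species 1-3 provide trait A,
species 3-5 provide trait B).  The service needs both traits, each
trait survives while one provider remains, and we ask: along every one
of the 120 possible extinction orders, what fraction of species must
be lost before the service fails?
"""

from fragnet import and_service, enumerate_robustness, five_species_example

net = five_species_example()
dist = enumerate_robustness(net, and_service(net.n_traits))

print("network: S =", net.n_species, "species, N =", net.n_traits, "traits")
print(dist.to_frame().to_string(index=False))
print("median robustness R_0.5 =", dist.median)
print()
print("Reading: in half of all extinction orders, losing 4 of the 5")
print("species (R = 0.8) or fewer is enough to lose the service; 24")
print("orders lose it at the 3rd removal and 24 only at the last.")
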