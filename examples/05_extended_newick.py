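"""Define a hybridization network in extended Newick and simulate from it.

The hybrid node is tagged #H1 and appears twice; ':length::gamma'
annotations give the inheritance probabilities of the two hybrid edges.
"""

from hils import SimulationConfig, jc69, parse_extended_newick, simulate_dataset

text = ("(((P1:0.5,(H:0.5)#H1:0::0.7):0.5,(P2:0.5,#H1:0::0.3):0.5):1.0,"
        "O:2.0);")
network = parse_extended_newick(text)
print(f"taxa: {network.taxa}")
print(f"hybrid: {network.hybrid}  outgroup: {network.outgroup}  "
      f"gamma (weight of the first #H1 edge): {network.gamma}")
print(f"S1: {network.s1.to_newick()}")
print(f"S2: {network.s2.to_newick()}")

alignment = simulate_dataset(network, jc69(),
                             SimulationConfig(mode="multilocus", n_loci=50,
                                              locus_length=100),
                             rng_or_seed=5)
print(f"simulated multilocus alignment: {alignment.n_taxa} taxa x "
      f"{alignment.length} sites")
# gamma = 0.7 means 70% of loci draw their gene tree from the parental
# tree that attaches H beside P1 (the first #H1 attachment).
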