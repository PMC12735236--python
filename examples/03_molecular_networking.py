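"""Feature-based molecular networking on a synthetic corpus.

Generates the default seeded corpus (44 features, 11 structural classes),
builds the network with the standard FBMN parameters (0.02 Da fragment /
0.01 Da parent tolerance, cosine > 0.7, >= 5 matched peaks, mutual
top-10, family cap 100) and reports component statistics.
"""

from isomet import CorpusConfig, build_network, generate_corpus, network_stats

corpus = generate_corpus(CorpusConfig(rng_seed=1))
net = build_network(corpus.spectra)
n_nodes, n_singletons, hist = network_stats(net)

print(f"nodes      : {n_nodes}")
print(f"singletons : {n_singletons}")
print(f"components : {dict(sorted(hist.items()))}  (size -> count)")

for comp in net.components():
    if len(comp) < 2:
        continue
    classes = sorted({corpus.ground_truth[f].class_id for f in comp})
    print(f"  {len(comp):2d} nodes: {', '.join(classes)}")

# Spectra sharing a fragmentation template cluster together; the one mixed
# component joins the 3-hydroxy-4-carboxy cores with the jaspiferal-type
# cores, which genuinely share their low-mass fragment series.
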