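"""Compressed likelihood against the plain-pruning oracle.

The compressed engine shares partials across duplicate subtree patterns;
the oracle recomputes every column independently.  Both must give the same
log likelihood to floating-point accuracy, here on a 14-taxon gene.
"""

import numpy as np

from chronosite import (
    HKYModel,
    HKYParams,
    SimConfig,
    encode_gene,
    gene_log_likelihood,
    plain_pruning_log_likelihood,
    simulate_dataset,
)

tree, alignments, rates = simulate_dataset(
    SimConfig(n_taxa=14, n_genes=1, n_sites=600, seed=5)
)
labels = [tree.nodes[n].label for n in tree.leaf_order]
enc = encode_gene(alignments[0], labels)
model = HKYModel(HKYParams(kappa=2.0, alpha=0.5, n_cats=4))

compressed = gene_log_likelihood(tree, enc, model, rates[0])
plain = plain_pruning_log_likelihood(tree, enc, model, rates[0])

print(f"compressed engine : {compressed:.10f}")
print(f"plain pruning     : {plain:.10f}")
print(f"relative difference: {abs(compressed - plain) / abs(plain):.2e}")
print("\nIdentical log likelihoods from two independent code paths confirm")
print("that pattern sharing changes the cost, not the result.")
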