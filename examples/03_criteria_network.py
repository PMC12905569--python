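"""Build the diagnostic-criteria overlap network.

Disorders are sets of diagnostic criteria; two disorders are linked if they
share at least one criterion, weighted by the overlap coefficient of the two
sets — the same similarity measure used for the coposting layer.
"""
from copanet import synth
from copanet.criteria import build_criteria_network

codes = ["F32", "F41.1", "F42", "F20", "F25", "F60.3"]
blocks = [["F32", "F41.1", "F42"], ["F20", "F25"]]
table = synth.generate_criteria(codes, blocks, n_criteria_per_disorder=10,
                                shared_within_block=5, seed=0)
net = build_criteria_network(table, restrict_to=set(codes))

print(f"criteria network: {net.n_nodes} nodes, {net.n_edges} edges, "
      f"density {net.density:.3f}")
print(net.edge_dataframe()[["disorder_a", "disorder_b", "weight"]]
      .to_string(index=False))
# weight 0.5 = the pair shares 5 of its 10 criteria; F60.3 has no shared
# criteria with anything, so it is isolated in this layer.
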