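"""Anatomy of a module seed: q-connectivity on a probabilistic network.

Edge confidences are interaction probabilities. A vertex set is
q-connected when every bipartition is bridged by at least one true
interaction with probability >= q; the seed of a vertex is the largest
q-connected subset of its (cleaned) neighbourhood, plus the vertex.
"""

import itertools

from hunter.graph_io import WeightedNetwork
from hunter.seeds import is_q_connected, maximal_q_connected, module_seed

# two strong 4-cliques (w = 0.95) joined by one weak bridge (w = 0.5)
edges = []
for blob in (["a", "b", "c", "d"], ["e", "f", "g", "h"]):
    for x, y in itertools.combinations(blob, 2):
        edges.append((x, y, 0.95))
edges.append(("d", "e", 0.5))
net = WeightedNetwork.from_edges(edges)

q = 0.95
print(f"q = {q}")
print("one clique q-connected?    ",
      is_q_connected({"a", "b", "c", "d"}, net, q))
print("both cliques + bridge?     ",
      is_q_connected(set("abcdefgh"), net, q))
# The bridge is a single 0.5-probability edge: the bipartition cutting
# it is bridged with probability 0.5 < q, so the union fails.

core = maximal_q_connected(set("abcdefgh"), net, q)
print("maximal q-connected subset:", sorted(core))

for v in ("a", "e", "h"):
    ms = module_seed(v, net, q=q)
    print(f"seed of {v}: {sorted(ms.members) if ms else '(empty)'}")
# Each vertex's seed is its own clique: the weak bridge never survives
# the minimum-cut split, so the two modules stay separate.
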