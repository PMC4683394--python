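"""Multi-resolution mode: anchor each node to its n-th most similar neighbor.

On a hierarchical toy network (4 cliques, paired into 2 super-groups),
increasing n makes nodes follow ever weaker ties, so the detected
partitions coarsen through the hierarchy: cliques -> merged groups ->
the whole network.
"""

import itertools

import networkx as nx

import ksimnet as ks

# 4 cliques of 6 nodes; cliques (0,1) and (2,3) paired by 4 edges each;
# the two pairs joined by 3 edges
g = nx.Graph()
cliques = [list(range(i * 6, (i + 1) * 6)) for i in range(4)]
for block in cliques:
    g.add_edges_from(itertools.combinations(block, 2))
for a, b in ((0, 1), (2, 3)):
    for j in range(4):
        g.add_edge(cliques[a][j], cliques[b][j])
for j in range(3):
    g.add_edge(cliques[1][5 - j], cliques[2][5 - j])

for n in (1, 2, 6, 7):
    p = ks.detect(g, ks.KsimConfig(nth_mode=n)).partition
    blocks = sorted(sorted(b) for b in p.blocks().values())
    print(f"n={n}: {len(blocks)} communities: {blocks}")
print("partitions nest: each level merges whole blocks of the previous one")
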