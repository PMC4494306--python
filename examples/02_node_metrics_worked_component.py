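"""Node metrics of a disconnected sociogram: the four-animal path component.

A 15-node network holding a path of four juveniles, two fully isolated
animals and a connected main group. Shows degree, Freeman betweenness,
farness (unreachable pairs counted at distance n = 15), cutpoints and
biconnected blocks — the per-individual table a welfare manager reads to
decide who holds the group together.
"""

import networkx as nx

from proxnet.network import blocks, node_table

g = nx.Graph()
g.add_nodes_from([f"Bear{k:02d}" for k in range(1, 16)])
g.add_edges_from([("Bear11", "Bear12"), ("Bear12", "Bear13"), ("Bear13", "Bear14")])
g.add_edges_from(
    [("Bear01", "Bear04"), ("Bear04", "Bear05"), ("Bear01", "Bear05"), ("Bear01", "Bear09"),
     ("Bear09", "Bear10"), ("Bear04", "Bear10"), ("Bear06", "Bear07"), ("Bear06", "Bear15"),
     ("Bear07", "Bear15"), ("Bear01", "Bear06"), ("Bear04", "Bear08"), ("Bear01", "Bear08")]
)

table = node_table(g)
print(table.loc[["Bear02", "Bear11", "Bear12", "Bear13", "Bear14"],
                ["degree", "betweenness", "farness", "cutpoint"]])
print()
print("blocks of the path component:", [b for b in blocks(g) if set(b) & {"Bear11", "Bear12", "Bear13", "Bear14"}])
# Bear02 (isolated) has farness 14 x 15 = 210; the path endpoints 171 and
# interiors 169; the interiors are the cutpoints whose removal strands a juvenile.
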