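# Bundled fixture data

- `football.edgelist`, `football_truth.tsv` — the American college
  football schedule network of Girvan & Newman (2002): 115 Division I-A
  teams, one edge per regular-season game of the Fall 2000 season, with
  the conference of each team (12 conferences, "Independents" included)
  as ground truth. Derived from the canonical public `football.gml`
  distribution; the original file lists 616 edge records of which 3 are
  duplicates, so the simple graph has 613 edges. Team names have spaces
  replaced by underscores.

The karate-club network (Zachary 1977) and the Les Misérables character
co-appearance network (Knuth 1993) are not stored here: they are built at
run time from networkx's canonical bundled copies (`karate_club_graph`,
`les_miserables_graph`). All three are tiny, ubiquitously redistributed
research datasets.
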