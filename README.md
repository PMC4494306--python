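# proxnet

Signed social networks from nearest-neighbour scan samples of animal groups
managed by humans — herds, flocks, pens and enclosures where welfare depends
on who seeks whom and who avoids whom.

## The problem and the method

Scan sampling records, every few minutes, either the x–y position of each
identified animal or its directly observed nearest neighbour (NN). Tallying
how often each ordered (focal, neighbour) pair occurs gives a directed NN
count matrix. A dyad is *significantly attracted* or *avoidant* according to
the standardized residual of that contingency table,

```
SR = (o − e) / √e,        e[i,j] = row_i · col_j / n
```

with |SR| > 1.96 (the two-sided 5% normal point) flagging a cell. The SR
matrix is split into a **positive** network (attraction, SR > 1.96) and a
**negative** network (avoidance, SR < −1.96, weights negated to stay
positive); a dyad gets an undirected edge when either direction passes, with
the larger residual as its weight and a one-way/two-way annotation.

On these sociograms proxnet computes the welfare-relevant metrics used for
small managed groups: density, degree, unnormalized Freeman betweenness,
farness/closeness (unreachable pairs counted at distance *n*, the node
count), cutpoints (articulation animals holding subgroups together) and
blocks (biconnected subgroups). Day-to-day persistence of the structure is
measured by seeded Mantel permutation tests between consecutive daily NN
matrices; their mean correlation is the group's stability index. The same
residual machinery applies to 2-mode animal × facility tables (who over- or
under-uses the feeder, nests, perches). A synthetic herd generator with
planted affinity/avoidance pairs, home ranges, facilities and missingness
makes every stage testable without animal data.

## Worked example

`examples/01_simulate_and_recover.py` plants four strongly bonded pairs in a
12-animal free-mixing herd, 5 days × 100 scans, and recovers them:

```
5737 NN observations over 5 days
positive network: 10 edges, density 0.15
  Ind00 -- Ind01  weight 51.2 (two-way)
  Ind02 -- Ind03  weight 52.0 (two-way)
  Ind04 -- Ind05  weight 51.9 (two-way)
  Ind06 -- Ind07  weight 50.9 (two-way)
  Ind08 -- Ind09  weight 9.6 (two-way)
  ...
recovery vs planted pairs: precision 0.40, recall 1.00
```

All four planted pairs appear with weights ~51 (they were mutually nearest
in ~90% of scans, vastly above expectation). Recall is perfect; the extra
lower-weight edges connect the four *unpaired* animals — strong pairs soak
up the column margins and deflate everyone else's expected counts, a known
bias of the margins-product null discussed in `docs/methods.md`.

`examples/03_day_to_day_stability.py` contrasts a stationary bonded herd
with a daily re-mixing one:

```
stationary bonded herd:
  consecutive r: 0.99, 0.99, 0.99, 0.99
  stability index (mean consecutive r): 0.99
free-mixing null herd:
  consecutive r: -0.24, -0.02, -0.10, 0.06
  stability index (mean consecutive r): -0.07
```

A stability index near 1 means the same animals are neighbours day after
day; near 0, the apparent network is noise. The other examples cover node
metrics of a disconnected sociogram (`02`) and 2-mode facility affiliation
(`04`).

The command-line pipeline wraps the same library:

```
proxnet simulate --config herd.yaml --seed 7 --out scans.csv
proxnet run --config pipeline.yaml        # full artifact bundle, see --help
```

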