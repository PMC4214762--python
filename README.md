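# roostnet

Co-roosting social network analysis for mark-recapture bat data.

Woodland *Myotis* bats (here, Natterer's bat *M. nattereri* and Daubenton's
bat *M. daubentonii*) roost in tree holes and bird boxes, switch roosts
every few days, and are individually ringed and re-found during periodic
box checks. Each check yields one capture record per bat — *who* was in
*which* roost on *which* date. From five summers of such records, roostnet
answers the questions a behavioural ecologist or disease modeller asks of
them: do individuals form stable social groups? are the groups assorted by
sex? how long do pairwise associations last? and do the groups partition
the woodland into exclusive roosting areas?

It is a library plus a thin CLI, aimed at researchers with ring-recapture
co-occurrence data (bats, box-nesting birds, communal roosters generally)
who want the full chain — network construction, community detection,
permutation tests, temporal association curves, and home-range geometry —
as tested, scriptable Python rather than a point-and-click toolchain.

## Methods at a glance

* **Association network.** Individuals *a* and *b* are associated iff they
  were recorded in the same roost on the same date; edges are binary and
  undirected. Individuals captured only once, or recaptured but never with
  a companion, are excluded before structural analysis.
* **Social groups.** Girvan–Newman edge-betweenness decomposition: the
  edge with the highest betweenness is removed, betweenness is recomputed,
  and every time the component count grows the modularity
  *Q* = Σᵢ (*eᵢᵢ* − *aᵢ*²) of the component partition is evaluated on the
  original network. The maximum-*Q* partition is the social-group
  assignment; *Q* > 0.3 is read as evidence of structure.
* **Sex assortment.** Join counts (MM / FF / MF edges) and mean degree by
  sex, tested by permuting sex labels over nodes with the network fixed
  (add-one permutation p-values, both tails).
* **Temporal structure.** Lagged association rate g(τ): the probability
  that a pair found together is together again when the focal individual
  is next captured τ days later, per directed sex-class pair (M–M, F–F,
  M–F, F–M); compared to a within-occasion permutation null and given
  leave-one-block-out jackknife standard errors over 30-day blocks.
* **Roost home ranges.** Per group, a 100% minimum convex polygon over its
  supporting roosts after removing roosts used by a single group member
  and roosts isolated by > 1 km; groups with ≤ 3 remaining roosts are
  excluded. Areas in km², optional habitat-mask cropping, intra- and
  inter-species overlap percentages, radio-fix range fidelity, and an OLS
  regression of range area on group size, species, and sampling effort.
* **Synthetic populations.** A generator plants social groups with known
  membership, sex composition (female-core vs > 90%-male bachelor groups),
  spatially clustered roosts, a box-check schedule (each roost at most
  once per 14 days, only a fraction of roosts checked per occasion),
  imperfect detection, and rare inter-group visits — so every stage can be
  validated against ground truth.

## Worked example

```python
from roostnet import (SimulationConfig, simulate_population, build_network,
                      filter_network, girvan_newman, intergroup_fraction,
                      join_count_test, lagged_association_rate,
                      null_association_rate)

cfg = SimulationConfig(seed=42, survey_prob=0.3)
caps, roosts, truth = simulate_population(cfg)

G = filter_network(build_network(caps, species="daubentonii"), caps)
part = girvan_newman(G)
print(f"social groups: {part.n_groups}, modularity Q = {part.q:.2f}")
print(f"inter-group associations: {intergroup_fraction(G, part.assignment):.1f}%")

jc = join_count_test(G, n_perm=10000, seed=1)
print(f"female-female associations: observed {jc.observed['FF']}, "
      f"chance {jc.perm_mean['FF']:.1f}, p = {jc.p_greater['FF']:.4f}")

daub = caps[caps.species == "daubentonii"]
bins = ((1, 30), (30, 120), (120, 400))
obs = lagged_association_rate(daub, "F", "F", bins)
null = null_association_rate(daub, "F", "F", bins, n_perm=20, seed=2)
for k in range(len(bins)):
    print(f"lag {bins[k][0]:>3}-{bins[k][1]:>3} d: "
          f"g = {obs['g'].iloc[k]:.2f}, null = {null['g'].iloc[k]:.2f}")
```

prints

```
social groups: 5, modularity Q = 0.61
inter-group associations: 16.8%
female-female associations: observed 173, chance 113.8, p = 0.0001
lag   1- 30 d: g = 0.67, null = 0.35
lag  30-120 d: g = 0.64, null = 0.42
lag 120-400 d: g = 0.69, null = 0.41
```

The five planted Daubenton's groups are recovered with strong modularity;
female–female edges are far above their permutation expectation (sex
assortment); and pairs found together are still together at a two-thirds
rate a year later, well above the random-association null — long-term
companionship, exactly what the generator planted.

The same analyses run from the shell:

```sh
roostnet simulate --seed 42 --out-dir sim/
roostnet summary sim/captures.csv
roostnet communities sim/captures.csv --species nattereri --out groups.csv
roostnet run --config pipeline.cfg --out-dir results/   # full chain + report.json
```

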