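# netclus

Network-constrained spatio-temporal clustering analysis of point events on
street networks — built for traffic-collision analysis, usable for any
point process that lives on a linear network (crime, 311 calls, urban
incidents).

Events in cities happen *on streets*, and planar spatial statistics
systematically over- or under-detect clustering when applied to them. This
package keeps every computation on the network: distances are shortest
paths, densities live on linear pixels ("lixels"), the null model is
uniform-by-length, and neighborhoods are defined by network distance
between road segments. It provides four complementary views of where and
when events cluster:

1. **Weighted network kernel density estimation.** For an on-network point
   q,

       λ(q) = (1/n) Σᵢ wᵢ Kᵢ(q)

   where Kᵢ is the *equal-split* kernel: the base kernel k(d(q,i), h) at
   shortest-path distance d, divided by Π (nⱼ − 1) over the intersection
   nodes crossed, so mass splits evenly among outgoing branches and
   intersections are not over-weighted. Event weights wᵢ come from
   quantile-rank normalization of a numeric attribute (e.g. direct
   financial loss) into an interval R = [r_min, r_max].

2. **Network cross K-function.** Against fixed typed points (POIs of one
   category) a₁…a_{n_a} and events b₁…b_{n_b},

       K_ba(d) = (1/ρ_b) Σᵢ Σⱼ I(|s(aᵢ, bⱼ)| < d) / n_a,   ρ_b = n_b / L,

   with Monte-Carlo envelopes from repeated CSR simulation of the events;
   the observed curve above/below the envelopes reads as
   clustered/dispersed around that POI type at that distance.

3. **Network differential local Moran's I.** Per-segment counts from two
   periods become standardized rate changes
   zᵢ = z(vᵢ(t₂)/L_{t₂} − vᵢ(t₁)/L_{t₁}), and

       Iᵢ = zᵢ Σⱼ wᵢⱼ zⱼ

   under a binary distance-band network weight matrix, with
   conditional-permutation pseudo p-values and HH/LL/HL/LH cluster labels
   — where did collisions significantly increase or decrease together?

4. **Network GIMA/LIMA rank concordance.** Kendall's τ over segment pairs
   decomposes exactly into neighbor and non-neighbor parts,
   τ = ψ·τ_w + (1−ψ)·τ_w̄; the neighbor part τ_w (a global indicator of
   mobility association) and its three local decompositions τᵢ, τ̃ᵢ, τ̃̃ᵢ
   measure whether segments keep or swap their risk ranks between periods,
   with conditional-permutation inference.

A synthetic-data module generates reproducible networks (grids, rings,
random planar), CSR and hotspot-boosted events with timestamps and
zero-inflated loss attributes, and two-period Poisson counts with planted
changes, so the whole pipeline is testable without any proprietary data.

## Worked example

Generate a synthetic district and run the full workflow from the shell:

```sh
netclus synth --rows 4 --cols 4 --n-events 300 --n-pois 12 --seed 3 --out-dir demo
netclus kde    --streets demo/streets.geojson --events demo/events.csv \
               --weight-col loss --out demo/kde.csv
netclus crossk --streets demo/streets.geojson --events demo/events.csv \
               --pois demo/pois.geojson --n-sim 199 --seed 9 --d-max 400 \
               --out demo/k.csv
netclus dmoran --streets demo/streets.geojson --events demo/events.csv \
               --n-perm 999 --seed 9 --out demo/moran.csv
```

The KDE table ranks lixels by loss-weighted collision density (events per
meter, weight-scaled); the densest lixels in this run:

```
 lixel_id  edge_id  start_m  end_m  length_m  density
       78       26      0.0   40.0      40.0 0.003776
       79       26     40.0   80.0      40.0 0.003672
       80       26     80.0  100.0      20.0 0.003455
```

The cross-K table compares the observed curve with its CSR envelopes per
distance; here CSR events stay inside the band at every lag, so the
verdict is "random" throughout:

```
d,K_obs,K_lo,K_hi,verdict
20.0,54.44,33.33,60.00,random
40.0,106.67,82.22,116.67,random
60.0,168.89,143.33,185.56,random
```

`dmoran` reports `labels {'NS': 40}` for this null data — no segment shows
a significant weekday→weekend change, as it should. In the library, a
planted hotspot is recovered explicitly:

```python
from netclus import build_network, differential_local_moran, subdivide, weight_matrix
from netclus.synth import make_two_period_counts

net  = build_network([[(i * 100.0, 0), ((i + 1) * 100.0, 0)] for i in range(100)])
segs = subdivide(net, 100.0, kind="segment")
W    = weight_matrix(segs, net, threshold_m=300.0)
pc   = make_two_period_counts(segs, seed=0, base_rate_per_day=2.0,
                              L=(5.0, 2.0), hotspot_ids=[47, 48, 49, 50, 51],
                              multiplier=3.0)
res  = differential_local_moran(pc, W, n_perm=999, seed=0)
print(res.to_frame().query("label != 'NS'"))
```

which prints the planted corridor stretch (and only it) as a high-high
cluster of rate increases.

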