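# macronull

Null-model macroecology of latitudinal richness gradients, built around
the complete analysis chain used for the Chilean freshwater-mollusk
fauna: ~84 taxa whose latitudinal ranges span the 38 one-degree bands
between 18°S and 56°S, asking whether the observed richness gradient is
shaped by ecology or could arise from geometry and chance alone.

Everything operates on a binary **incidence matrix** `M` (species ×
1°-latitudinal bands, `M[i,k] = 1` when species *i*'s range intersects
band *k*) and asks, stage by stage:

- **Inventory completeness** — Chao2,
  `S_est = S_obs + Q1²/(2·Q2)`, from the numbers of species found in
  exactly one (`Q1`) and exactly two (`Q2`) bands.
- **Biogeographic structure** — Jaccard similarity between bands,
  UPGMA clustering, and SIMPROF permutation tests that cut the
  dendrogram into statistically supported groups.
- **Rapoport's rule** — OLS of range extent on range midpoint, with a
  permutation null (extents shuffled across midpoints).
- **Mid-domain effect (MDE)** — Monte Carlo null holding the empirical
  range sizes fixed and placing each range uniformly between the hard
  domain limits, with and without replacement; 95% envelopes per band.
- **Nestedness** — NODF (0–100, higher = more nested), matrix
  temperature T (0–100, lower = more nested) and BR discrepancy,
  against a fixed-rows/equiprobable-columns null.
- **Co-occurrence** — the C-score, mean of
  `CU_ij = (r_i − S_ij)(r_j − S_ij)` over species pairs, against the
  SIM9 fixed-fixed null sampled by sequential checkerboard swaps.
- **Environmental models** — Poisson GLMs (log link) of per-band
  richness on 11 climatic/topographic/hydrographic predictors, ranked
  by AICc (`AIC + 2k(k+1)/(n−k−1)`) with McFadden and Nagelkerke
  pseudo-R², plus bidirectional stepwise selection.

A synthetic-data module generates range lists, nested and
co-occurrence-structured matrices, and Poisson richness counts with
known parameters, so every statistic is verified by parameter recovery
rather than trust.

## Worked example

Generate a study-scale synthetic fauna (84 species, right-skewed range
sizes over 18–56°S), build the matrix, and run the chain:

```python
import macronull as mn

dom = mn.BandDomain(18, 56)
ranges = mn.gen_ranges(mn.GeneratorConfig(n_species=84, domain=dom, seed=42))
matrix = mn.ranges_to_incidence(ranges, dom)

mn.chao2(matrix)
rap = mn.rapoport_test(ranges, n_perm=10_000, seed=1)
env = mn.simulate_mde(ranges, dom, mode="without", n_sim=10_000, seed=2)
nest = mn.nestedness_null_test(matrix, metric="T", n_iter=1000, seed=3)
co = mn.cooccurrence_test(matrix, n_iter=1000, seed=4)
```

which prints (via the pipeline's per-stage summaries):

```
matrix: (84, 38) fill 0.091
Chao2: S_obs=84 Q1=0 Q2=24 S_est=84.0
Rapoport: slope=0.0014 r=0.009 p=0.940
MDE: coverage=1.000 deviations=[]
NODF_total: obs=9.32 null=9.29 CI=(8.76, 9.89) p=0.4326
T: obs=32.35 null=33.65 CI=(30.59, 36.66) p=0.2068
C-score: obs=10.156 null=9.767 SES=24.75 p_upper=0.0010
SIMPROF: 16 groups
```

Reading it: every band's observed richness sits inside the MDE 95%
envelope (`coverage=1.000`) — the gradient is indistinguishable from
random range placement between hard limits; the Rapoport slope is flat
(`p=0.94`); and the strongly positive C-score SES says species pairs
share bands far less than a marginal-preserving shuffle would — the
contiguous-range geometry itself checkerboards the matrix, which is why
the SIM9 null must be read with care on interval-filled data.

The same chain runs from the shell:

```sh
macronull simulate --model ranges --n-species 84 --seed 42 --out ranges_matrix.csv
macronull build-matrix --ranges ranges.csv --domain 18:56 --out matrix.csv
macronull rapoport --ranges ranges.csv --nperm 50000 --seed 1
macronull mde --ranges ranges.csv --mode both --nsim 50000 --seed 2 --out mde.csv
macronull nested --matrix matrix.csv --metrics nodf,t,br --niter 50000 --seed 3
macronull cscore --matrix matrix.csv --niter 5000 --seed 4
macronull cluster --matrix matrix.csv --nperm 50000 --seed 5
macronull glm --matrix matrix.csv --covariates covariates.csv --mode rank
macronull run --config run.yaml          # the whole pipeline
```

`macronull run` consumes a YAML config (input paths, domain bounds,
per-stage iteration counts, master seed) and writes one CSV per stage,
a Newick dendrogram, a JSON summary and a log; `--paper-scale` raises
all stochastic stages to 50,000 iterations.

## Layout

- `macronull.core_io` — domain types, incidence matrix construction and
  packing, CSV I/O
- `macronull.synthetic_data` — generators with known structure
- `macronull.gradient_stats` — Chao2, Rapoport randomized regression
- `macronull.mde_null` — mid-domain-effect Monte Carlo envelopes
- `macronull.nestedness` — NODF, temperature, BR, null-model tests
- `macronull.cooccurrence` — C-score, SIM9 sequential swap
- `macronull.similarity_clustering` — Jaccard, UPGMA, SIMPROF
- `macronull.glm_selection` — Poisson GLMs, AICc ranking, stepwise
- `macronull.pipeline` / `macronull.cli` — orchestration and CLI

See `docs/methods.md` for the statistical details, null-model
definitions, numerical choices and known limitations.
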