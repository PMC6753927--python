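# biofilmnet

Co-occurrence networks and beta-diversity decomposition for stream-biofilm
microbial communities.

Glacier-fed streams run along steep environmental gradients: from the glacier
terminus downstream, the share of glacier melt in the flow (GS) and the
glaciated catchment area (GA) fall, while distance to the terminus (GD),
vegetation cover (NDVI) and conductivity rise. `biofilmnet` implements the
standard analysis chain used to ask how bacterial and fungal biofilm
communities respond to such gradients:

1. **Preprocessing** — relative abundance, removal of OTUs at or below 0.01%
   relative abundance (strict `>`), Hellinger transformation
   (√ of within-sample relative abundance), and unit-norm scaling of
   environmental variables.
2. **Co-occurrence network** — all pairwise Spearman correlations ρ between
   OTU abundance profiles; an edge is kept iff ρ > 0.7 or ρ < −0.7 **and**
   p < 0.01 (two-sided t approximation by default, permutation p optional).
   Whole-network descriptors follow the usual conventions: mean local
   clustering coefficient, characteristic path length (median over nodes of
   the mean within-component shortest-path length), density 2E/(N(N−1)),
   heterogeneity (coefficient of variation of the degree sequence), and
   Newman–Girvan modularity Q = Σ_c [L_c/m − (d_c/2m)²].
3. **Modules** — seeded Louvain modularity maximization; Q > 0.4 is read as a
   modular network; modules with more than 15 nodes are "major" and named
   BM1, BM2, … / FM1, … by decreasing size.
4. **Distances** — Bray–Curtis Σ|x−y|/Σ(x+y) for communities and module
   sub-tables; Euclidean distances over environmental blocks (overall /
   hydrological {GD, GA, GS} / nutrient {TN, NO₃, NH₄, TP, SRP} /
   vegetation {NDVI}); great-circle (haversine) geographic distance; an
   NDVI = (NIR − RED)/(NIR + RED) utility with sub-catchment masking.
5. **Inference** — seeded Mantel and partial Mantel tests (Spearman on
   distance triangles, one-sided greater, p = (1 + #{r\* ≥ r})/(1 + n_perm)),
   all-vs-all Mantel grids, and one-way PERMANOVA
   (pseudo-F from the squared-distance decomposition, label permutation),
   including pairwise PERMANOVA between major modules over OTU
   abundance-profile distances.

A first-class synthetic-data generator plants known module structure and
known environment responsiveness, so every stage can be validated against
ground truth (see `docs/methods.md`).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with known truth (each accepts `--seed`/`--outdir`):

```sh
python analysis/01_simulate_data.py
python analysis/02_build_networks.py
python analysis/03_detect_modules.py
python analysis/04_distances.py
python analysis/05_inference.py
```

`02_build_networks.py` prints the side-by-side topology summary
(seed 1):

```
bacteria: 392 OTUs kept (dropped samples: none); network 391 nodes / 20647 edges, Q = 0.328
fungi: 149 OTUs kept (dropped samples: ['S02']); network 149 nodes / 1963 edges, Q = 0.631
```

The bacteria-like community forms the denser, more connected network; the
fungi-like community the sparser but more clustered, more modular one
(higher clustering coefficient and Q). `05_inference.py` then reports which
dissimilarity matrices track the environment:

```
community/module x environment Mantel (p < 0.05):
  BC    ~ hydrological r = 0.48, p = 0.003
  BM1   ~ hydrological r = 0.47, p = 0.006
  ...
  FM4   ~ hydrological r = 0.59, p = 0.002
no environmental association: BM2, FC, FM1, FM2, FM3, FM5, FM6
```

i.e. the bacterial community and most bacterial modules covary with the
hydrological/vegetation gradient, while the fungal community does not —
only the single planted responsive fungal module (detected here as FM4)
does. Nutrient dissimilarity, decoupled from the gradient by construction,
is significant nowhere. Pairwise PERMANOVA finds every pair of major
modules compositionally distinct.

A `biofilmnet` console command exposes the same machinery
(`biofilmnet simulate | run | topology | mantel | permanova`); `run`
executes the full pipeline from a YAML config naming the OTU and
environment tables.

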