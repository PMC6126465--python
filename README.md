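# isomerge

Multi-crystal X-ray diffraction data management: decide which crystals are
isomorphous enough to merge, trim radiation-damaged image tails, scale and
merge the surviving observations, and report the quality statistics that
drive those decisions.

Membrane-protein crystals rarely survive a full data collection: radiation
damage limits each crystal to a small wedge of reciprocal space, so a
complete dataset has to be assembled from many partial ones. That only works
if the crystals are isomorphous, and it works best after the damaged tail of
each wedge is discarded. `isomerge` automates this workflow on plain-text
unmerged reflection tables (one observation per row: h, k, l, I, sigma(I),
image number), with optional readers for XDS INTEGRATE.HKL and unmerged MTZ.

## The model

**Isomorphism clustering.** Each crystal is described by its unit-cell
parameters (a, b, c, alpha, beta, gamma). Datasets are clustered
agglomeratively (Ward linkage, Euclidean metric) on mean-scaled cell
parameters. Every dendrogram node carries the Linear Cell Variation of its
members, computed from the three cell face diagonals d_f:

    aLCV = max over faces, pairs (i,j) of |d_f(i) - d_f(j)|        [Angstrom]
    LCV  = max over faces, pairs of 100 |d_f(i) - d_f(j)| / min    [percent]

LCV above ~2 % warns of non-isomorphism.

**Radiation damage.** Per resolution shell (equal counts in s = 1/d^2) the
intensity decay over images is modelled as I = exp(amplitude - B * image),
fitted by least squares on the log scale. A dataset is flagged as damaged
when the decay rate B increases significantly with s (one-sided weighted
trend test, alpha = 0.05); the suggested last accepted image is where the
highest-resolution shell has dropped to the RADFRAC fraction (default 0.75)
of its starting intensity: cutoff = first - 1 + floor(ln(1/RADFRAC)/B).

**Resolution estimate.** Shell averages of unscaled I and sigma give an
<I>/<sigma> curve in s; a polynomial of degree min(10, shells-1) is fitted
and the first grid point where it falls below ISIGI (default 1.5) sets the
suggested resolution.

**Scaling and merging.** Each dataset j gets a multiplicative scale and an
isotropic B factor, I_scaled = k_j exp(-2 B_j s) I_obs, fitted by least
squares on the log scale against the shared reflection means (reference
dataset: k = 1, B = 0). Symmetry-equivalent observations (rotations of the
header space group plus Friedel mates) are merged by inverse-variance
weighting, and the usual statistics are reported: R_merge, R_meas, R_pim,
completeness against a directly enumerated unique set, multiplicity, CC1/2
from seeded random half-dataset splits, and Mn(I/sd).

**Pruning.** Starting from any dataset selection, each cycle removes the
trailing 10 % of images from the dataset with the worst per-dataset R_merge
contribution and re-merges; cycling stops at a completeness floor (default
95 %) and the cycle with the lowest R_pim wins.

## Worked example

```python
from isomerge import synthgen, modes
from isomerge.reflio import KeywordSet

# 67 synthetic wedges: 63 isomorphous (two sub-groups) + 4 gross outliers
datasets, truth = synthgen.make_scenario("teha_like", "demo_data", seed=7)

dendro, entries = modes.mode_analysis("demo_data", "demo_work")
print(len(dendro.nodes), "clusters; root LCV %.2f %%" % dendro.root.lcv)

from isomerge.cellclust import flag_outliers
print("outliers:", flag_outliers(dendro))
```

prints

```
66 clusters; root LCV 29.27 %
outliers: [64, 65, 66, 67]
```

The root LCV of ~29 % says the full set of 67 crystals must not be merged
as-is; the flagged serials are exactly the four planted mis-indexed
outliers. Removing them from the input list (edit `mtz_names.dat`, re-run)
leaves 63 wedges with root LCV 0.71 %, 62 dendrogram nodes, and
`FINAL_list_of_files.dat` rows like

```
.../group0_crystal04.refl 5 11 1 30 3.001
```

i.e. dataset 5 is damage-cut at image 11 of 30 with a suggested resolution
of 3.001 Angstrom. `modes.mode_synthesis(work, "height", root+1, KeywordSet())`
then scales and merges all 62 nodes and writes `MERGING_STATISTICS.info`,
sorted by completeness, with one row per node (R_meas, R_pim, completeness,
multiplicity, resolution criteria).

The same flow from a shell:

```sh
isomerge -a demo_data          # analysis (keywords on stdin, Enter = defaults)
isomerge -s 42 < bkeys.dat     # merge every node below height 42
isomerge -saLCV 3 < bkeys.dat  # ... or every node with aLCV <= 3 Angstrom
isomerge -c "[49] [[41]]"      # merge cluster 49 without dataset 41
isomerge -cP "[13]"            # pruning variant of combination
isomerge -g D 60 5             # annotated subtree around cluster 60
```

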