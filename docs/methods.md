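# Methods

This note records the models, conventions and numerical choices behind
`isomerge`, and what the synthetic test bed does and does not establish.

## Cell clustering and the LCV/aLCV score

Datasets are clustered on the six cell parameters with Ward linkage and a
Euclidean metric. Before clustering, each component is centred and divided
by its across-dataset mean, so the coordinates are fractional deviations.
This scaling is unit-free (edges in Angstrom and angles in degrees become
comparable) while preserving the relative size of variation: a 2 Angstrom
shift on one edge dominates 0.05 Angstrom measurement jitter on the others.
We deliberately do not standardise to unit variance per component — that
would amplify components carrying nothing but jitter to the same scale as a
genuinely varying edge and can destroy an otherwise clean group structure.

LCV and aLCV are computed from the three face diagonals of each cell. For a
face spanned by edges (p, q) with included angle theta we take the *longer*
parallelogram diagonal, sqrt(p^2 + q^2 + 2pq|cos theta|); the two diagonals
coincide at 90 degrees, the dominant crystallographic case. aLCV is the
largest absolute pairwise diagonal difference over the cluster members
(attained by the extreme pair within a face), and LCV divides by the smaller
diagonal of the pair. Both are exactly the all-pairs maxima; the
implementation exploits that the extreme pair attains them.

Node ids follow the convention: leaves carry the dataset serials 1..n
(lexicographic path order), internal nodes are numbered n+1..2n-1 in merge
order. `merge_level` = member count - 1, so equal-sized clusters share a
level in the merging-level plot.

Outlier flagging is advisory. The greedy rule removes, from the extreme
pair of the worst face, the member whose diagonal lies farther from the
median of the remaining cells, until the root LCV falls under the threshold
(default 2 %). Nothing is deleted automatically; the user edits the input
list, which mirrors the intended interactive workflow.

## Radiation-damage detection

Per equal-count shell in s = 1/d^2 the decay of intensity with image number
is modelled as a linear exponential, I = exp(amplitude - B * image), and
fitted by ordinary least squares of ln(I) on image number over the
individual positive observations of the shell. In a balanced design this
slope equals the regression on per-image log-means, but the per-image means
are heteroscedastic (counts vary by image), which we measured to inflate the
downstream trend test's type-I rate to ~6 % at nominal 5 %; individual
observations give iid residuals and an honestly calibrated slope standard
error (measured type-I 4-5 % on both flat and Wilson-distributed null data).
Shells observed on fewer than three distinct images are dropped.

A dataset is flagged as damaged when the decay rate increases with
resolution: weighted least squares of B on the shell midpoint s, weights
1/se(B)^2, one-sided t test at alpha = 0.05, requiring at least three
fitted shells. Wedges shorter than 5 images are never assessed — too few
dose points for the trend to mean anything. Resolution-independent decay
(beam or bulk-crystal intensity loss) deliberately does not trip the test;
pruning (below) is the remedy for that regime.

The suggested cutoff uses the highest-resolution fitted shell's decay rate
B: the shell mean falls to RADFRAC (default 0.75) of its first-image value
after ln(1/RADFRAC)/B images, and the cutoff is the floor of that dose,
clamped to the image range. Floor rounding keeps the retained wedge
conservative. A cutoff equal to the last image means "keep everything".

## Resolution estimate

Shell averages (default 20 equal-count shells, at least 5 observations per
shell) of raw unscaled intensities and sigmas are formed over *all* images,
before any damage cutoff. The ratio curve <I>/<sigma> versus s is smoothed
with a polynomial of degree min(10, shells - 1) — with the default shell
count this is a least-squares fit rather than an exact interpolation, a
robustness choice — and evaluated on a 1000-point grid over the observed s
range. The first grid point below ISIGI (default 1.5) wins; this
lowest-resolution-crossing rule is conservative. If the curve never drops
below the threshold the dataset's own resolution limit is returned. File
output rounds to 3 decimals.

## Scaling and merging

Observations are mapped to canonical unique reflections: the
lexicographically greatest image of (h,k,l) under the space group's rotation
parts (from the header symbol, via gemmi) plus Friedel negation. Integrated
intensities are treated as P1 until this mapping is applied.

The scale model per dataset j is I_scaled = k_j * exp(-2 B_j s) * I_obs —
a deliberate minimal replacement for a full scaling program: no absorption,
detector or partiality corrections. On the log scale the model is linear,
ln I = mu_h - ln k_j + 2 B_j s, so all (k_j, B_j) are estimated in one exact
least-squares solve with the per-reflection effects mu_h profiled out
(reducing to a (2J-1)-dimensional normal system). Only positive intensities
on multiply-observed reflections inform the fit. The multiplicative gauge is
pinned during the solve; the B gauge is left to the data and afterwards
re-expressed relative to the lowest-serial reference dataset (k = 1, B = 0).
Fixing the reference's B *during* estimation instead would leave an
irreducible parameter bias of order B_ref * (cell mismatch) when member
cells differ; the free-gauge solve recovers planted scales on noiseless data
to better than 1e-6. Sigmas are scaled by the same factor as intensities.
A group in which no unique reflection is seen by two datasets is refused
("unconnected"), as is any group failing the pairwise cell tolerance check
(default 2 % on edges / 2 degrees on angles; tolerance >= 100 disables the
check entirely).

Merging is the inverse-variance weighted mean per unique reflection with
sigma = (sum 1/sigma^2)^(-1/2). R statistics use the plain per-reflection
means of the scaled unmerged intensities over reflections with >= 2
observations; the weights sqrt(n/(n-1)), 1 and sqrt(1/(n-1)) give R_meas >=
R_merge >= R_pim identically. Completeness divides the observed unique count
by a direct enumeration of the unique set to the resolution limit;
epsilon/centric corrections are ignored, a documented approximation that
shifts absolute completeness only marginally on the toy groups used here.
CC1/2 is the Pearson correlation of two merged half-datasets from a seeded
random split of every reflection's observations (the seed lives in the
keyword set, so results are reproducible); the sigma-tau closed form is not
used. Shell resolution criteria: finest shell with CC1/2 > 0.3 and with
Mn(I/sd) > 2; both thresholds configurable.

## Modes, state and pruning

Analysis writes mtz_names.dat (absolute paths, serial order), CLUSTERS.txt
(node id, height, LCV, aLCV, members), FINAL_list_of_files.dat (six columns:
path, serial, cutoff image, first, last, resolution) and a JSON state file.
Synthesis and combination reload the state and rebuild the dendrogram from
the same inputs, which is deterministic, instead of serialising the tree.
Merges honour the per-dataset accepted image ranges and the RESOLUTION
keywords; synthesis writes per-node scaled/merged reflection files and logs
under merged_files/ and a statistics table sorted by descending
completeness; combination runs are numbered sequentially under
combined_files/.

Pruning (the -cP variant) starts from the unpruned merge (cycle 0). Each
cycle identifies the member dataset with the highest own-observation R_merge
contribution (its sum of |I - <I>| over its sum of I, restricted to
multiply-observed reflections, on the current scaling), removes the trailing
10 % (at least one image) of that dataset's currently accepted range, and
re-merges. The victim is re-selected every cycle. Cycling halts when
completeness drops below the target (default 95 %), when a dataset would be
eliminated entirely, or at the cycle cap (default 20). The winner is the
cycle with the lowest R_pim among cycle 0 and all cycles meeting the
completeness floor — cycle 0 is always eligible, so pruning that never helps
returns the unpruned result unchanged.

## Synthetic data

The generator emulates multi-crystal collections without simulating
diffraction geometry. True unique intensities are acentric-Wilson
(exponential) draws whose means carry a Debye-Waller factor with B = 20
Angstrom^2. Each crystal gets a cell offset per group plus Gaussian edge
jitter, a random (k, B) scale pair, and a sweep in which every image samples
reflections from a shuffled cycle through the unique list — long sweeps
cover the unique set multiply, short wedges stay partial. Noise is Gaussian
with sigma = sqrt((f*I)^2 + background^2). Damage has two channels: a B
factor growing linearly with image number (decay rate 2*B_rate*s, faster at
high resolution — what the damage detector tests for) and a
resolution-independent per-image decay (invisible to the trend test by
design; the pruning workflow handles it). Rogue datasets receive per-image
log-normal scale errors that no smooth k*exp(-2Bs) model can absorb.
Outlier datasets get a grossly shifted cell edge.

Named scenarios fix the study conditions: `teha_like` (63 isomorphous
~30-image wedges in two sub-groups 0.35 Angstrom apart plus 4 outliers
shifted by 25 Angstrom, resolution-dependent damage), `h1r_like` (18
full-sweep datasets in 3 groups 5 Angstrom apart — far enough that only
within-group nodes stay under ~3 Angstrom aLCV — with uniform decay),
`two_group` (2 Angstrom shift, 0.05 Angstrom jitter, noiseless; the
clustering- and scale-recovery condition), `rogue` and `damaged`. The
default problem sizes (a few thousand observations per dataset, cells
around 40-60 Angstrom, 3 Angstrom resolution) keep a full 62-node synthesis
in seconds while leaving every statistic well populated.

What passing these tests shows: the algorithms recover planted structure
(groups, scales, decay rates, rogues) under counting-type noise and the
stated damage models. What they do not show: behaviour under real detector
artefacts, absorption, anisotropy, mis-indexing beyond gross cell shifts,
or intensity distributions with twinning/centric statistics — none of which
the generator emulates.

## Numerical conventions

- Images are 1-based inclusive; s = 1/d^2 is the internal resolution
  coordinate; resolutions print in Angstrom.
- Serial order is lexicographic over absolute input paths; repeated runs
  give identical serials.
- Equal-count shell edges come from quantiles of s; degenerate (duplicate)
  edges are collapsed.
- The canonical text format writes floats with shortest-roundtrip repr, so
  write-then-read is an exact identity.
- Merge ties and half-split randomness are governed by the SEED keyword
  (default 42); identical inputs and seeds give byte-identical outputs.
- Degenerate inputs: a single dataset scales to identity; reflections
  observed once carry no R statistic (reported as absent); an empty node
  selection in synthesis produces an empty table with a warning.
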