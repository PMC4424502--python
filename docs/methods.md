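# Methods

## Model and scope

`loopmotif` operationalizes a composite regulatory pattern — the *closed
loop-motif* — on two-group (sham vs injured) expression time courses. A
loop is a triple (miR, TF, gene) with the three directed relations
miR→TF, miR→gene and TF→gene, all present in interaction catalogs and all
supported by significantly dependent expression profiles. Only this
topology is enumerated; loops with two TFs, two miRs, or TF→miR edges are
out of scope, as is computing enrichment statistics (process annotations
are consumed as externally produced tables).

The unit correlated along an edge is the per-time-point **log2 fold
change** (mean injured − mean sham), one value per time point. This is the
quantity in which an injury response is comparable between a miRNA and an
mRNA measured on different platforms; correlating raw per-sample
intensities across platforms is not possible here because the two
platforms have different samples and different time grids.

## Stages and the choices behind them

### Normalization

Raw intensities are floored at 0.01, log2-transformed, per-chip shifted so
the 75th percentile of each column is 0, and (mRNA mode only) per-gene
median-centered. The column quantile is the linear-interpolation (type 7)
definition — the numpy/R default — stated here because quantile conventions
differ. The miRNA platform skips per-gene centering. The synthetic
generator emits log2-scale matrices directly, so its output feeds the DE
stage without renormalization.

### Differential expression

Per entity and time point: Welch's two-sided t-test (no equal-variance
assumption; with six replicates per group the cost over the pooled test is
negligible and the robustness is free), Benjamini–Hochberg adjustment
within platform × time point, and the inclusive filter |log2FC| ≥ 1 and
adjusted p ≤ 0.05. BH is applied within a platform rather than within the
finer TF/mRNA classes: class labels come from a user-supplied TF list, and
letting an annotation file change adjusted p-values would be surprising.
Zero-variance entities (possible in noise-free simulations) get p = 0 when
the group means differ and p = 1 otherwise.

### Interaction catalogs

Pair files merge with union semantics — the union of target databases is
more sensitive than their intersection, at the price of false positives
that the downstream correlation filter is designed to absorb. Provenance
(the set of contributing catalog names) is kept per pair. Restriction to a
time point keeps pairs whose two endpoints both pass DE there.

### PWM promoter scanning

De-novo TF→gene pairs come from a Match-style matrix similarity score.
With per-position base frequencies f(i,b) and information weights
I(i) = Σ_b f(i,b)·ln(4 f(i,b)), a window s scores
(Σ_i I(i)·f(i,s_i) − Min)/(Max − Min), where Max/Min use the per-position
max/min frequency; the score lies in [0,1] and is thresholded at 0.8 by
default. Numerical choices: frequencies are floored at 1e-4 inside the
logarithm (the information weight is undefined at 0); an `N` base
contributes the position minimum, so masked sequence can never create a
hit; a matrix longer than the sequence yields no hits with a warning; a
zero-information (flat) matrix scores 0 everywhere. Both strands are
scanned and the best window score, strand and forward-strand offset are
reported. Only the matrix-score cutoff is modeled — no separate
core-similarity cutoff, since a single reproducible threshold is
preferable to guessing vendor profiles. TRANSFAC-like count blocks are
parsed with Biopython.

### Temporal imputation

The mRNA platform measures 3 of the 5 time points. Each mRNA profile is
completed by one global ordinary-least-squares line v = a + b·t in raw
hours (7 d = 168 h) fitted to its measured points, predicting the missing
times. This is the simplest defensible reading of "least squares" for a
3-point profile: any per-interval method would be interpolation, and
regression on co-expressed neighbor profiles would leak information
between the very entities whose dependence is subsequently tested.
Measured values are never altered, imputed points are flagged, and
collinear inputs reproduce exactly.

**Known limitation (important).** A line can only represent monotone
trends. When the true response peaks at an interior time point (e.g. 24 h
in a 0–168 h design), the imputed 2 h and 48 h mRNA values fall far from
the peaked curve the miRNAs follow, and with only n = 5 points the
miR–mRNA edges of even noise-free planted loops fail both tests
(Pearson p ≈ 0.08–0.13, exact dCor p ≈ 0.14–0.2 in the package's own
simulations). The pipeline therefore recovers loops reliably when the
injury response is monotone over the sampled window and systematically
loses peaked responses; the test suite asserts both behaviours. This is a
property of line-imputation at five time points, not of the
implementation.

### Edge testing

Pearson r uses the sample covariance over the product of sample SDs, with
the two-sided p from t = r·√((n−2)/(1−r²)) on n−2 df; constant profiles
degenerate to r = 0, p = 1 and are never significant. Distance correlation
double-centers the pairwise |x_j − x_k| and |y_j − y_k| matrices, takes
dCov² as the mean elementwise product, and normalizes by the distance
variances; a vanishing variance gives dCor = 0. Its p-value is a
permutation test on the pairing of y with x: exact enumeration of all n!
permutations while n! ≤ 5040 (so exact at the default five time points,
where the p-value granularity is 1/120), otherwise seeded Monte-Carlo with
the (1 + hits)/(1 + n_perm) estimator. Ties at the observed statistic are
counted as hits (within 1e-12), so the exact p for perfectly dependent
distinct 5-point profiles is 2/120 — the identity *and* the full reversal
of y both attain dCor = 1, because negating a variable leaves its distance
matrix unchanged.

Edge significance defaults to the **OR** of the two tests at α = 0.05:
distance correlation exists precisely to catch dependence Pearson misses,
and requiring both would reduce it to a veto. The AND rule and a
positive-correlation-only filter are configuration options, not defaults;
no sign constraint is imposed and no multiple-testing correction is
applied across edges.

### Loop filtering and networks

Candidates are enumerated deterministically (lexicographic by ids) from
the typed pair sets; a loop is kept iff all three edges are significant,
and the kept/total fraction is reported. Networks are undirected for
degree purposes — direction survives only as the `edge_class` attribute —
and node degree counts distinct neighbors; hub ties break
lexicographically by id since no other rule is defensible. Loop identity
for cross-time-point and cross-process comparisons is the (miR, TF, gene)
id triple. GraphML exports carry node class and edge class and round-trip
exactly (contributing loop keys are serialized into a string attribute,
as GraphML has no list type).

## The synthetic study

The generator mirrors the study design: 6 replicates per group, mRNA at
{0, 24, 168} h, miRNA at {0, 2, 24, 48, 168} h. Planted loops share a
unit-peak piecewise-linear response r(t), scaled by a log2 effect (default
2.0 — four-fold at the peak) and added to injured samples only; the miR
side is multiplied by the coupling sign (default +1, co-directional, since
repression-dominated loops would carry negative correlations that the
default pipeline still accepts; −1 is available to probe that regime).
The curve rises from 0 at t = 0 to 1 at `peak_time_h` (default 24 h, where
the real response is largest) and decays to `late_level` (default 0.75,
reflecting a late response roughly three quarters of the early one).
Setting the peak at the final time point gives a monotone ramp for which
line imputation is exact; recovery guarantees are stated, and tested, in
that regime (see the imputation limitation above). Gaussian noise
(default SD 0.3 log2 units, a typical between-replicate spread for
microarray log-intensities) is added everywhere; baselines are
N(8, 1.5²) per entity.

Decoy entities receive baseline plus noise only, and decoy catalog pairs
connect exclusively non-planted entities, so null edges are independent by
construction and a decoy loop can only be reported through a genuine
false positive chain (DE by chance *and* three correlated edges).
Sample sizes are desk-scale by design — 30 miRs, 6 TFs, 80 genes, 10
planted loops, 40 decoy pairs per class by default — large enough for the
null-calibration checks, small enough that the complete suite runs in
seconds. What the generator does **not** emulate: probe-level artifacts
(background, dye bias), correlated noise between entities, biologically
structured target networks, or realistic database error modes; passing
tests therefore demonstrate correctness of the machinery and its behaviour
under the stated noise model, not performance on real arrays.

`evaluate_recovery` reports sensitivity (recovered planted / planted) and
the false-discovery fraction (reported non-planted / reported; 0 with a
warning when nothing is reported).

## Degenerate inputs and numerics

Empty matrices, missing groups at a time point, duplicate times, profiles
shorter than two points, unscored loop edges, empty annotations and
unknown export formats raise informative errors. Constant profiles are
systematically non-significant rather than erroneous. The vectorized
distance correlation agrees with a literal O(n²) double-loop
implementation to 1e-12; the exact permutation enumeration uses a 1e-12
tie tolerance; Pearson r is clipped to [−1, 1] before the t transform.

## Problem sizes in the checks

The acceptance script runs two full synthetic studies (zero and default
noise, 10 planted loops each), 10,000 vectorized null simulations for the
Pearson type-I rate, the 120-permutation exact dCor enumeration, and a
round-trip on the integrated network; the test suite adds a 500-node
GraphML round trip, 100 random dCor oracle comparisons, a 20×3-simulation
noise-monotonicity study and a 2,000-entity null-uniformity check. These
sizes were chosen so each property is measured with comfortable
statistical margin while the whole suite stays fast enough to run on
every change.
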