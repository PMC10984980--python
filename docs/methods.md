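# Methods

This note records the models, parameter choices and numerical decisions
behind `tempo3d`, and what the synthetic-data experiments do and do not
demonstrate.

## Contact-matrix processing

Input matrices are symmetric per-chromosome cis grids of raw counts at a
fixed resolution (100 kb for compartments, 50 kb for TAD borders).

**Bin filtering.** A bin is kept when the fraction of its contacts at pair
distance below `max_dist` (default 5 Mb) is at least `min_ratio` (default
1, i.e. *all* of its signal must be mid-range); bins with excess long-range
signal are treated as artefacts and masked, as are bins with no signal.
Self-interactions (the main diagonal) are excluded from both numerator and
denominator by default (`include_diagonal` flips this; the convention is a
package choice — either reading of "mid-range over total" is defensible).
Filtering zeroes masked rows/columns and is idempotent.

**ICE balancing.** Iterative correction divides each entry by the product
of its row/column marginal (relative to the valid-bin mean) until the
coefficient of variation of valid-bin marginals drops below `tol` (1e-5,
`max_iter` 100). Masked bins keep bias 1 and stay zero. Total mass is
rescaled to the input total, so balancing conserves signal to floating
precision. Non-convergence returns the last iterate with a warning and
`converged=False` rather than failing.

**Distance correction.** Observed/expected per genomic-distance stratum:
each entry is divided by the mean of its diagonal over valid-bin pairs.
Strata with zero mean map to zero (no division error); on supported strata
the output has valid-bin mean exactly 1.

**Correlation matrix.** Pearson correlation between valid-bin O/E rows.
Strata carrying no signal at all (e.g. beyond the contact support of the
map) are treated as *unsupported* rather than as observed zeros: each row
pair is correlated over columns lying in supported strata of both rows.
For a fully populated chromosome this is exactly the plain row-wise
correlation; on band-limited maps it prevents shared structural zeros from
manufacturing a positional gradient that would contaminate the leading
eigenvectors. Rows with zero variance are folded into the mask. A square
3-bin median filter then damps isolated noise; it is mask-aware (masked
bins are NaN and excluded from windows) and truncates at matrix borders,
and the result is re-symmetrised (median windows are asymmetric at mask
edges) with the diagonal restored to 1.

## Compartment calling

Per chromosome and time point, the top three eigenvectors of the valid-bin
correlation submatrix are computed (unit norm, descending eigenvalue,
masked bins re-embedded as missing). Selection is automated: the
eigenvector with maximal |Pearson r| against a transcriptional-activity
track wins, with GC content as fallback when the activity track is
degenerate, and a per-chromosome `override` index for manual choices —
on some chromosomes the leading eigenvector tracks features other than
chromatin state and the second one is the right call. All candidate correlations and eigenvalues are returned as
diagnostics rather than being folded into a hard rule. The sign is set so
activity correlation is positive: A compartments are positive.

**Sigmoid.** To damp eigenvector outliers the score applies a bounded
sigmoid; this package uses `tanh(e/2σ)` with σ the
per-chromosome standard deviation over valid bins. The form is bounded,
odd, strictly monotone, and invariant to positive rescaling of the
eigenvector; the 2σ scale puts typical bins on the quasi-linear part of the
curve while compressing outliers. Both form and scale are deliberate,
configurable package choices.

**Dynamics.** Bins valid at every time point are stable A (all scores
positive), stable B (all negative) or dynamic (any sign change). A score of
exactly 0 carries no label and is treated as a change-point neighbour only
through its sign comparisons. Pairwise A→B / B→A tallies are reported for
every ordered time-point pair. Dynamic-bin trajectories are clustered by
Ward linkage on Euclidean distance, cut at 7 clusters by default (Ward
matches the linkage used for border-trajectory clustering, keeping the two
dynamics views comparable). Cluster ids are renumbered by first
occurrence so a fixed input yields fixed ids.

## TAD borders

**Insulation.** For each bin boundary, the raw insulation is the mean
contact over the window of pairs spanning it within 50–400 kb (valid bins
only; boundaries whose window leaves the chromosome are missing, not
errors). The log2 track is centred to zero mean over valid bins —
equivalently a ratio to the chromosome *geometric* mean. (A ratio to the
arithmetic mean would not give the zero-mean log track the rest of the
module assumes; the two differ by an additive constant that cancels in
border calling.) Boundaries with zero raw signal are floored at half the
smallest positive raw value before the log, so fully insulated planted
junctions stay finite and maximally deep. Smoothing is a NaN-aware centred
running mean of half-span `delta` = 2 bins.

**Calling.** Candidates are strict local minima over ±delta bins (plateaus
resolve to the leftmost bin, for determinism; candidates need a fully
finite window). Boundary strength is `min(left flank max − min, right
flank max − min)` within 400 kb of the minimum. The 1–10 robustness score
emulates TADbit's border score as the decile of strength *on the
chromosome's strength scale*: `ceil(10·strength/max strength)`, so the
strongest border scores 10 and equal strengths share the same (higher)
decile. A rank-based decile among candidates was considered and rejected:
it necessarily promotes ~60 % of candidates above the "score > 4" cutoff
regardless of how weak they are, which is incompatible with the caller's
own recovery requirements on maps with few true junctions. Because the
score emulates an opaque original, absolute border counts are not
comparable between this caller and TADbit's. Only borders with score strictly
above `min_score` = 4 are returned.

**Alignment and dynamics.** Borders from different samples are homologous
when ≤ 100 kb (2 bins) apart. Grouping is greedy nearest-first
single-linkage under two constraints — all pairwise gaps within a group ≤
tolerance, at most one border per sample per group — with ties broken by
leftmost coordinate, making the result deterministic and symmetric in
sample order. A group present at every time point is invariant; otherwise
each absent→present step at an adjacent transition is a gain and each
present→absent step a loss, tallied per transition.

## Reproducibility metrics

**SCC.** Both maps are smoothed with a box mean of span 3 bins
(3 bins at 100 kb is the package default, configurable). Windows truncate at matrix
borders and are normalised by actual coverage — zero-padding would imprint
the same edge-shrinkage pattern on both maps and bias the null upward.
Per-diagonal Pearson correlations up to 5 Mb are averaged with weights
`N_d · sqrt(var(rank x_d) · var(rank y_d))`; zero-variance strata are
skipped. Self-comparison returns exactly 1; the statistic is invariant to
positive scaling up to floating-point tie reordering in the ranks.

**PCA / WED.** Centered PCA via SVD; variables with missing values are
dropped; up to N = 10 components are retained with weights = variance
explained. Signs follow a deterministic convention (largest-|loading|
positive). The weighted Euclidean distance is a true metric on the
retained components (symmetry, identity, triangle inequality), and
homogeneous of degree 1 in the coordinates.

## Regulome integration

Promoters span 1000 bp upstream to 200 bp downstream of the TSS,
strand-aware, clipped at chromosome edges; for genes with several
annotated TSSs the first annotation wins (configurable by pre-filtering
the gene list). Enhancers are intersections of H3K4me1 and H3K27ac peaks
per time point, merged across time points, minus anything overlapping a
promoter window by ≥ 1 bp; states per time point come from mark presence
on the consensus interval (both = active, H3K4me1 only = primed, else
absent — H3K27ac alone does not make an enhancer). Functional TF sites
overlap H3K27ac by ≥ 1 bp at an activation time point (full peaks, not
summits). Classification precedence is promoter-bound > enhancer-bound
(element active at either activation time point) > other-distal.

Distal assignment: for an enhancer-bound site, candidate genes are baits
of interactions significant at the queried time point (score ≥ 5) whose
other end overlaps the site by ≥ 1 bp (the same overlap rule as
functionality); the candidate(s) with maximal promoter log2 fold change
are retained, exact ties all kept. Distance is site midpoint to TSS; the
nearest-gene flag compares TSS distances over all annotated genes,
strand-ignorant. Priming tests whether a supporting loop is significant at
the 0 h baseline. Interaction dynamics per time-point pair are gained /
lost / maintained at the ≥ 5 threshold; records significant somewhere get
a cluster id C1–C7, the lexicographic enumeration of significance patterns
over (0 h, 1 h, 10 h): C1 = (0,0,1), C2 = (0,1,0), C3 = (0,1,1),
C4 = (1,0,0), C5 = (1,0,1), C6 = (1,1,0), C7 = (1,1,1). Within each
pattern, records are ordered by complete-linkage clustering of
asinh-transformed scores.

Differential signal replaces an off-the-shelf differential package with
the same normalisation logic it would apply: per-sample size factors are
the median across background 10-kb bins (bins overlapping any enriched
region are excluded) of the bin count over its across-sample geometric
mean, normalised to geometric mean 1; the per-region statistic is
`log2((mean_B + 1)/(mean_A + 1))` on normalised counts, finite by
construction. When a precomputed log2FC column is supplied it is used
verbatim.

## Synthetic data

Generators emulate every input class with planted truth; all randomness
flows through `numpy.random.default_rng` (PCG64), so a fixed seed is
bit-reproducible across platforms.

**Contact maps.** `λ_ij = depth·(1+|i−j|)^(−α)·c^(s_i s_j)·t^[same TAD]`,
Poisson counts, with defaults depth = 500, α = 1, one 10 Mb chromosome
(100 bins at 100 kb for compartments; 200 bins at 50 kb with 4 junctions
and t = 3 for TADs; c = 2 for the checkerboard of 1 Mb blocks). Expected
counts are truncated beyond 5 Mb: the analysis is mid-range by
construction — its bin filter masks any bin with long-range signal — so
the generator models maps whose support matches that assumption, and bins
with planted long-range contacts are exactly the artefacts the filter
removes. Time courses (6 points) flip the labels of 12.5 % of bins in
contiguous 3-bin runs (300 kb) at a random time point, and add/remove
junctions on request; switches come in runs because compartment switches
span regions and the correlation median filter deliberately suppresses
single-bin flips as noise.

**Peaks and counts.** p53/H3K4me1/H3K27ac peaks are placed with controlled
overlap structure (functional vs non-functional sites, primed vs active
elements, promoter-bound and decoy sites). Promoter H3K27ac counts are
negative-binomial (dispersion 0.05, 3 replicates per condition, base mean
≈ 150 fragments) around size-factor-scaled means with planted log2 fold
changes (targets +2, others ~N(0, 0.3)); background 10-kb bins use
dispersion 0.02 around mean 50. One sample carries a planted 2× scale
factor. **Interactions** draw planted-loop scores as 5 + Gamma(2, 2) at
active time points and Uniform(0.5, 4.5) otherwise; primed loops are
significant at 0 h; decoys never cross the threshold. Candidate gene
triples of different sites are disjoint so each planted target is
identifiable.

**What recovery does and does not show.** Passing recovery tests shows the
pipeline correctly inverts its own generative assumptions at realistic
signal strengths and desk-scale problem sizes (seconds per run; sizes
chosen so the full suite stays fast). It does not demonstrate robustness
to features real data have and the generator lacks: restriction-fragment
granularity, copy-number and mappability artefacts, translocations,
distance-decay curvature, antibody efficiency differences between ChIP
samples, or CHiCAGO's distance-dependent background. Absolute counts from
real datasets (numbers of borders, loops, target genes) depend on
sequencing depth and caller internals and are not recovery targets.

## Known limitations

- Compartment calling is per-chromosome cis only; no trans inference, no
  sub-compartments.
- The border caller is an insulation-score caller; it emulates, not
  reimplements, the original 1–10 robustness score.
- The correlation step's pairwise-complete mode is O(n²) pairs with an
  O(n) inner reduction; fine at 100-kb desk and chromosome scale, but the
  fast path (fully supported maps) is the one that matters genome-wide.
- The differential-signal estimator is a pseudocount log2FC, not a
  shrinkage estimator; with few replicates and low counts its variance is
  larger than a full GLM's.
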