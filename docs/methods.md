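# Methods

`ecoplace` quantifies microbial ecotypes in shotgun metagenomes by
phylogenetic placement of translated marker-gene reads, and analyzes the
resulting depth profiles. This note documents the models, the numerical
choices, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Placement model

### Reference packages

A reference package per marker gene consists of (i) a phylogeny with
branch lengths in expected amino-acid substitutions per site, (ii) the
gapped amino-acid alignment its leaves were inferred from, and (iii) a
taxonomy path per leaf (e.g. `Bacteria;SAR11;IIb;IIb.x`). The tree is
rooted on the edge above the MRCA of a designated outgroup clade; without
a rooting, "distal side of an edge" is ill-defined and edge labels would
be ambiguous. Edges are numbered in post-order of the rooted tree, which
makes edge ids stable under serialize/parse round trips (newick preserves
child order). Multifurcations are handled natively; no arbitrary
binarization is performed.

Every edge is labeled with the longest common taxonomic prefix of the
leaves distal to it. A terminal edge therefore carries the leaf's full
path, an edge inside a monophyletic ecotype carries the ecotype's path,
and a backbone edge carries a truncated path. How root-adjacent edges
should be labeled is a convention; we apply the same prefix rule there.

### Substitution model

Both the sequence simulator and the placement likelihood use a
Poisson-type equal-rates amino-acid model: all exchangeabilities equal,
uniform stationary frequencies. With time in substitutions/site,

    P(same, t)  = 1/20 + (19/20) exp(-(20/19) t)
    P(other, t) = 1/20 - (1/20)  exp(-(20/19) t)

The closed form keeps per-edge likelihoods cheap (no matrix
exponentials), makes an exact brute-force oracle easy to write, and is
orthogonal to the pipeline logic; an empirical matrix (LG, WAG) is a
natural extension point but would change none of the surrounding
machinery.

### Recruitment (translated search)

Each 150 bp mate is translated in all six frames and scored by an
ungapped local alignment (maximum-sum diagonal segment, BLOSUM62)
against one representative reference sequence per distinct taxonomy
path, found via exact 5-mer amino-acid word seeding — the same
seed-and-extend logic as a translated BLAST search, restricted to
ungapped extensions. The best hit anchors the mate's residues to the
reference alignment columns of the matched segment; columns outside the
hit are dropped, as are stop codons and ambiguous residues. Queries with
fewer than 10 mapped columns are rejected.

The default score cutoff (45) was calibrated by simulation so that
i.i.d.-random 150-mers are accepted well under 1% of the time (measured
0.25% at n = 2000), while intact marker reads score an order of
magnitude higher. Frame ties resolve to the lower frame index
(+1,+2,+3,−1,−2,−3); a pair whose two mates recruit to different marker
genes is rejected entirely.

Mates of a pair are merged into one column→residue map. Non-overlapping
mates simply union; where both mates cover a column with different
residues, the residue from the mate with the higher recruitment score
wins (ties to mate 1).

### Per-edge placement

A query is attached by a pendant branch at the **midpoint** of each
candidate edge (EPA's default heuristic; along-edge optimization is a
documented non-feature). For every edge, the partial likelihoods of the
two tree halves seen from the midpoint are precomputed per alignment
column by standard inner/outer Felsenstein passes with per-column
rescaling. The per-column likelihood of the augmented tree then reduces
to

    L_col(v) = a_col + b_col · exp(-(20/19) v)

in the pendant length v, so the summed log-likelihood is concave in
u = exp(-λv) and has a unique maximum. The pendant is optimized on
[1e-8, 10] substitutions/site by safeguarded Newton/bisection on the
derivative, vectorized over all edges at once (28 iterations bound the
bracket below 1e-8). The edge with the highest optimized log-likelihood
wins; ties within 1e-9 log units resolve to the lowest edge id. Only one
placement per query is kept.

Correctness is checked against an independent brute-force implementation
(`ecoplace.bruteforce`) that physically builds the augmented tree per
edge and evaluates the likelihood by naive recursion with full 20×20
transition matrices, optimizing the pendant with
`scipy.optimize.minimize_scalar`; on random small instances the two
agree to < 1e-9 log units.

### Filtering and counting

Placements with pendant length strictly greater than 2 substitutions/site
are removed (the pendant measures how poorly the query fits anywhere on
the tree; the threshold is in the same units as the jplace field).
Mutation-free synthetic reads are essentially never removed. Each kept
placement is counted once under its edge's clade path **at every rank**:
a read on an `Ia` backbone edge counts toward `Ia` and its ancestors but
toward no sub-ecotype, so sub-ecotype counts are never inflated by
ambiguous placements.

## Quantification

Cross-sample comparability uses a per-sample normalization factor
anchored on one reference sample: f_s = G_ref / G_s with G the
good-quality read total, and

    normalized = raw × f_s / L_g × 100

with L_g the marker's reference-alignment column count. Because all
reads are the same length, length normalization only matters when
comparing *between* genes — which the prd/rpoB ratio does — so both
behaviors are provided (`length_normalize=False` sets L_g = 1). The
reference sample is an explicit config key (defaulting, loudly, to the
lexicographically first sample); ecotype proportions and prd/rpoB ratios
are invariant to the choice.

The prd/rpoB ratio of a focal clade estimates the fraction of that clade
carrying proteorhodopsin, because both genes are single-copy and
gene-length normalization cancels the length bias of shotgun sampling. A
zero rpoB denominator yields a missing value, never 0.

## Depth profiles and landmarks

Simpson's index of diversity (1 − D = 1 − Σ p_i²) is computed over
clades passing a presence cutoff of 1 normalized read (applied to the
final normalized value, after the ×100 scaling), with proportions
renormalized over the passing clades.

Profile derivatives are plain first differences Δv/Δz reported at
depth-interval midpoints — symmetric, and faithful to "change between
adjacent sampled depths" without any smoothing.

Three landmark depths are extracted per station:

* **z_negmax** — midpoint depth of the most negative derivative of the
  prd/rpoB series (steepest loss of proteorhodopsin carriage);
* **z_lli** — depth of the maximum normalized low-light (LLI)
  picocyanobacterial psbD abundance (a light-horizon proxy);
* **z_onset** — the shallowest depth where the deep clade "begins to
  increase", operationalized as: abundance ≥ θ of the profile maximum
  (θ = 0.1) and non-decreasing over the next m = 2 samples. The
  threshold-plus-sustained-rise rule is our choice of definition for an
  informally stated concept; both parameters are exposed in the config.
  Note the rule fires on a sampled logistic roughly ln(9)/k metres above
  the midpoint (≈ 44 m at k = 0.05 /m), i.e. systematically slightly
  shallow — within two grid steps on the 50 m grids used here.

Ties in extrema resolve to the shallowest depth. Stations missing a
landmark are excluded pairwise from cross-station regressions, with a
logged count.

## Statistics

Pearson correlations use the product-moment formula with
pairwise-complete deletion and a two-sided t test (n − 2 df); zero
variance or fewer than 3 complete pairs gives a missing value. No
multiple-testing correction is applied to the reported r/p (a
Benjamini–Hochberg q column is emitted alongside for convenience). OLS
is solved from the normal equations.

Redundancy analysis is implemented from first principles: center the
community matrix Y, z-score the predictors X, project Y onto the column
space of X by least squares, and take the SVD of the fitted values. The
constrained proportion is SS(fitted)/SS(total); eigenvalues are s²/(n−1);
site scores are U·S, response scores V, and predictor loadings are
correlation-style (correlations of each predictor with each constrained
axis) — one of several scaling conventions, stated rather than assumed.
Collinear or constant predictors are dropped greedily with a warning. No
community transform (Hellinger etc.) is applied by default; the analysis
operates on plain proportions. The permutation significance test is
available with a seeded RNG but is not part of the default path.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* **References**: random clade-structured topologies (long clade stems,
  short within-clade branches, a two-leaf outgroup) with sequences
  evolved column-wise under the same equal-rates model the likelihood
  uses. Within-clade amino-acid distance is strictly below between-clade
  distance at the default depth scale (0.3 subst/site).
* **Community truth**: the summed deep-ecotype share of the focal
  compartment follows a logistic in depth, 1/(1 + e^{−k(z−z*)}) with
  steepness k = 0.05 /m by default; surface, deep and background clades
  split their compartments with fixed Dirichlet(4) weights held constant
  over depth. Background (non-focal) prokaryote clades occupy 55% of the
  community by default so percent-of-community is non-trivial.
* **Proteorhodopsin carriage**: all surface clades carry prd; a
  configurable fraction of deep clades do (default none) — so the
  carriage fraction drops across z*.
* **LLI profile**: expected psbD abundance of the low-light clade is a
  Gaussian bump centred at z* (offset configurable, width 80 m); other
  phototrophs decay from the surface.
* **Reads**: templates are reverse-translated leaves (uniform codon
  choice — the pipeline works on amino acids, so codon bias is
  irrelevant); mates are forward/reverse 150 bp windows with an
  inter-mate gap uniform on [0, 150] nt (overlapping with probability
  0.2, exercising the merge-conflict path); per-site substitutions at a
  configurable rate (0.02 in the validation runs, a typical
  environmental divergence from a reference). Read counts scale with
  each sample's good-read total (lognormal, σ = 0.2) — exactly the
  nuisance the normalization corrects — and with marker gene length, as
  in shotgun sampling. prd read depth is scaled by gene length relative
  to rpoB so the normalized ratio is unbiased.

Not emulated: quality-score error profiles, indels within reads,
chimeras, strain-level variation within leaves, compositional coupling
between markers, and real reference uncertainty (misannotated leaves,
alignment error). Passing recovery tests therefore demonstrates the
pipeline's internal correctness and statistical behavior under the
stated model, not robustness to every artifact of real sequencing.

## Validation harness problem sizes

The recovery checks run at sizes chosen to exercise the statistics
meaningfully on a single CPU:

* placement oracle: 100 random instances, ≤ 6 leaves, ≤ 30 columns;
* clade recovery: one 8-depth station, 2000 read pairs at 2% mutation,
  accuracy scored on queries with ≥ 50 mapped columns (expected
  multinomial + placement error well below the 5% allowance);
* proportion recovery: one 10-depth station, 2000 rpoB read pairs per
  nominal sample, generated without background clades so the whole rpoB
  budget samples the focal compartment whose proportions are being
  recovered (binomial standard error ≈ 0.011, comfortably inside the
  ±0.05 check);
* landmark coincidence: 8 stations × 13 depths (25–625 m, 50 m grid),
  z* varied 100–600 m, 700 rpoB pairs per nominal sample.

## Known limitations

* The equal-rates model understates placement certainty for real
  proteins; with an empirical matrix, pendant lengths and likelihood
  gaps would change (the pipeline logic would not).
* Midpoint attachment skips along-edge optimization, so placements on
  long edges are coarser than EPA-ng's.
* Recruitment scores are raw alignment scores, not e-values; the cutoff
  is calibrated for 150 bp reads and should be re-calibrated for other
  read lengths.
* The onset rule is sensitive to count noise at low coverage; at < 100
  focal reads per sample the onset landmark can wander by a grid step
  or two.
* Normalized "abundances" are relative to the reference sample's
  sequencing effort; they are not absolute cell densities.
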