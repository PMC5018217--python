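# Methods

This note documents the models and procedures the package implements, the
defaults it ships, and what its synthetic data can and cannot show.

## Fragment-based average nucleotide identity (`anitax.ani`)

ANI is estimated in the BLAST-fragment ("ANIb") style. The query genome is
cut per contig into consecutive, non-overlapping windows of
`fragment_len = 1020` bp; the terminal remainder is kept and judged against
its own length. Each fragment is aligned to its best location in the
subject — every contig, both strands — and retained when its identity
reaches `min_identity = 0.30` over at least `min_aln_cov = 0.70` of its
length (the conventional ANIb filter). One-way ANI is the mean percent
identity of retained fragments; the symmetric ANI of a pair is the
arithmetic mean of the two one-way values, which is also what the
pairwise matrix stores. Percent identity counts gap columns as
non-matches throughout, so values from different alignment backends are
comparable. A pair with no retained fragments is reported *missing*,
never 0.

Two alignment backends satisfy the same contract (identity plus aligned
length per fragment):

* **edlib** (default): semi-global bit-parallel edit-distance alignment of
  the whole fragment to its best subject infix. Unit costs, no affine
  gaps; fast enough for hundreds of fragments against megabase subjects.
* **dp**: affine-gap local alignment (match +1, mismatch −1, gap open −5,
  gap extend −2) via Biopython, quadratic time. Used on small inputs and
  as an independent cross-check of the edlib path in the tests.

Because the estimator takes the *best* alignment per fragment, a
fragment's identity can exceed the truth implied by the mutation process
by a few edits (the optimizer occasionally finds a slightly cheaper
alignment than the real homology). At substitution rates up to 0.10 this
bias is below ~0.3 percentage points per fragment and well below 0.1
points after averaging, which is why the estimator holds the
±0.5-point recovery band comfortably.

## Multilocus similarity (`anitax.mlsa`)

Taxa are compared over an ordered panel of loci (eight housekeeping genes,
6087 bp concatenated, in the canonical configuration). Sequences must
arrive aligned or equal-length; columns where either member of a pair
carries a gap or IUPAC ambiguity are excluded *pairwise*, so each pair
reports its own `compared_sites` with an integer difference count.
Similarity is `100·(compared − differences)/compared`, displayed at one
decimal, or two decimals at ≥ 99.9 % so that a single difference on
6087 sites (99.98 %) is not rounded into a spurious 100.0 %. Loci can be
harvested from assemblies by semi-global homology search against
reference locus sequences with a 90 % identity floor.

## Similarity→ANI calibration (`anitax.calibrate`)

For a taxon that cannot be genome-sequenced, ANI against sequenced
relatives is predicted from multilocus similarity through the
three-parameter logarithmic curve

    ANI = a + b · ln(sim − c),      sim > c.

This family is the standard three-parameter logarithmic regression; it is
monotone for b > 0 and saturates toward high similarity, matching the
empirically tight, curved relationship between the two quantities. The
model form is a documented assumption; alternative families can be fitted
externally and passed through the same prediction interface.

**Fitting.** For fixed c the model is linear in (a, b), so the fit
profiles the nonlinear parameter: a 20-node grid on
c ∈ [min(sim) − 40, min(sim) − 0.5] with closed-form (a, b) per node,
bounded 1-D refinement of c, then a full three-parameter
Levenberg–Marquardt polish with c held inside the same window. The bound
matters: the likelihood is flat as c → −∞ (the curve degenerates to a
straight line), and an unbounded optimizer drifts down that ridge without
a meaningful gain in fit. A corollary is that *exactly* linear data can
only be approximated (R² ≈ 0.997 within the window), which is the
expected behaviour, not a failure. Noiseless data generated from the
family itself is recovered to ~1e-13.

**Uncertainty.** Predictions carry a residual-based t interval,
`prediction ± t(1−α/2, n−3) · residual SD` — appropriate for the ~10-point
calibrations this workflow sees; a case-resampling percentile bootstrap
over (a, b, c) is available as an alternative and achieves near-nominal
coverage in simulation (≥ 90 % joint coverage of all three true
parameters at σ = 0.5 noise on 20 points). The correlation report also
runs an F-test of the fitted curve against an intercept-only model.

A prediction is flagged `below_species_threshold` only when the *upper*
interval bound is below 95 % ANI — the conservative direction for
proposing new species.

## Species demarcation (`anitax.demarcate`)

Prokaryotic genomes below the conventional 95–96 % ANI band are treated
as different species. The partitioner thresholds at 95.0 % by default
(the conservative end of the band) and clusters by single-linkage
connectivity, the conventional reading of ANI-based assignment. Two
safeguards are always on: pairs inside [95, 96) are flagged ambiguous
regardless of the chosen threshold, and clusters containing a
below-threshold pair (chaining) raise a warning instead of merging
silently. Raising the threshold provably refines the partition.

## Neighbour joining (`anitax.phylo`)

Distances are uncorrected p-distances with pairwise deletion of
gap/ambiguity columns (a Jukes–Cantor correction is available by flag,
with the 0.75 saturation limit enforced). Joining is the classic
Q-criterion agglomeration; ties resolve deterministically to the lowest
index pair in current matrix order and are counted, and negative
branch-length estimates are clamped to zero with a per-tree counter. The
final three lineages attach by the three-point formulas, giving an
unrooted tree with a trifurcating root, returned as a scikit-bio
`TreeNode`. On additive matrices NJ is consistent: the generating
topology and branch lengths are recovered exactly (verified to 1e-9 on
random trees).

Bootstrap support resamples alignment columns with replacement, rebuilds
the NJ tree per replicate, and reports, per internal edge of the original
tree, the percentage of replicates containing the same bipartition.
Supports are written as internal node labels in Newick output; a ≥ 60 %
display cutoff is a reporting option, never baked into the tree.

## Diagnostics (`anitax.diagnostics`)

Probe scanning matches IUPAC-ambiguous probes against IUPAC-ambiguous
sequences (a column matches when the two base sets intersect), on both
strands, with an optional mismatch budget; positions are 0-based
half-open internally and 1-based in command-line output. The packaged
probes are the 16S signature defining the PnecC species complex and the
finer 16S–23S ITS diagnostic. Note the "E. coli positions 445–463"
annotation spans 19 positions while the probe is 18 nt; the coordinate
note is informational and never used for matching.

Genome statistics report assembly size (Mbp, 2 d.p.) and G+C content
(mol%, 1 d.p.) over unambiguous bases only.

Trait tables are normalized onto {positive, weak, negative}, with numeric
abundances (e.g. fatty-acid percentages) binarized at detected (> 0) for
key induction while the raw values are preserved. The diagnostic key
lists, per taxon, traits whose value occurs in no other row, plus the
differing traits for every taxon pair (any one is a minimal
discriminating set); identical rows are reported indistinguishable.
Packaged fixtures carry the published gene-content, fatty-acid and
assimilation tables for the four free-living *Polynucleobacter* type
strains, and the published five-taxon ANI matrix.

## Synthetic data (`anitax.synthetic`)

The generator produces what the estimators assume and nothing more:
i.i.d. bases at a target G+C (default 0.45, mid-range of the
44.8–46.1 mol% the compared genomes span), Jukes–Cantor-like
substitutions (each site independently, uniform over the three
alternatives — no transition bias, matching the package's use of raw
identity rather than model-corrected distances), and geometric-length
indels at a per-site rate. Every mutation is recorded in a
coordinate-mapped log, so tests recompute true per-window identities
independently of any aligner. The joint generator drives a genome and a
locus panel with the same per-taxon rate from one shared ancestor,
reproducing the monotone multilocus-similarity↔ANI coupling the
calibration fits (Spearman ρ > 0.9 across pairs in the test
configuration).

Deliberate simplifications: no gene structure, codon bias,
rearrangements, repeats or horizontal transfer. Passing tests therefore
demonstrate estimator correctness under the stated divergence model, not
robustness to repeat-rich or mosaic real genomes; the accession
verification script (`scripts/verify_accessions.py`, requires network)
exists to close that gap against real assemblies.

**Problem sizes.** Tests and the acceptance script run genomes of
30–200 kbp rather than the ~2 Mbp of real *Polynucleobacter* genomes;
fragment ANI is length-stable, so the estimator's behaviour does not
depend on genome scale beyond sampling noise (a 200 kbp pair already
averages ~197 fragments). Panels are always full-size (6087 bp), since
multilocus arithmetic is printed-precision-exact. Bootstrap coverage of
the calibration uses 100 replicates × 199 resamples; NJ consistency uses
50 random 5–8-taxon trees and 200 bootstrap replicates.

## Determinism

Every stochastic operation takes an explicit integer seed
(`numpy.random.default_rng`); identical seeds and inputs reproduce
identical outputs, including pipeline files byte-for-byte. Derived seeds
stay below 2^31.
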