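# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a long-form methods appendix.

## The processing chain and its conventions

The 37f amplicon chain runs in a fixed order: quality filter → pair merging
→ demultiplexing → chimera removal → dereplication → taxonomic assignment →
preclustering → OTU clustering → habitat classification → occupancy filter
→ optional variant merging. Chimera removal is placed after demultiplexing
so that ISU abundances — which the detector's parent-abundance criterion
relies on — are computed over the whole dataset rather than per library.
Every stage logs its input and output record counts; end to end,
`assigned + unassigned + dropped(by cause) = raw`, which the tests assert.

Threshold semantics, where prose leaves room, are fixed as follows and are
all configurable through `PipelineConfig`:

* *mean Phred above 30*: strict, and evaluated per mate — both mates' means
  must exceed 30;
* *80% identity floor* for ISU assignment: strict (best identity must be
  > 0.80);
* *95% identity* for planktonic classification: inclusive (≥ 0.95);
* *more than three samples* for OTU retention: strict (> 3).

**Alignment identity.** Identity is matches divided by alignment columns,
with gap columns counted in the denominator. Because co-optimal global
alignments can disagree on the number of matches, the aligner optimizes the
triple (score, matches, −columns) lexicographically in a single dynamic
program — the three additive terms are folded into one integer key — so the
reported identity is deterministic. The default scoring is the classical
+1/−1/−2 scheme with end gaps charged. Assignment returns the deepest
taxonomy prefix shared by all exactly-tied best hits; assignment is by
pairwise alignment against each reference (not against a multiple sequence
alignment).

**Demultiplexing.** The observed 5′ block is compared by Hamming distance
to each sample's `fwd_tag + fwd_primer` construct and the 3′ block to the
reverse complement of `rev_tag + rev_primer`; the two distances are summed
and the unique sample at minimal distance ≤ 2 wins. An exact tie is never
guessed. The tag-scheme generator places tags at pairwise Hamming distance
≥ 6 within each 8-nt tag set, which makes ≤ 2 mismatches uniquely decodable
and guarantees that a read with 3 mismatches is closer to no sample than to
a wrong one.

**Preclustering and clustering.** The precluster signature is an exact
match on the first 30 bases of the primer-stripped insert (length
configurable; the published signature method is not reproduced here).
Within a precluster, OTUs come from average-linkage agglomeration on
1 − identity, cut at 0.03 by default with per-taxonomy overrides supplied
as a config map (no published values exist for these); members are ordered
lexicographically before clustering so distance ties resolve
deterministically. The OTU representative is the most abundant member
sequence (ties lexicographic).

**Chimera detection** is an intentionally simplified two-parent
single-breakpoint detector, not a UCHIME reimplementation. Scanning ISUs in
descending abundance, a query is flagged when two unflagged parents, each
at least twice as abundant, admit a breakpoint splice whose identity to the
query is ≥ 0.99 and exceeds the query's best single-parent identity. Splice
identity is computed in query coordinates from each parent's alignment
match profile with a prefix-sum over breakpoints, which makes the search
linear in query length per parent pair; at most the 20 most abundant
eligible parents are examined per query. The tests cross-check against an
oracle that splices literal sequences and re-aligns them.

## The burial-decay model

Planktonic eDNA delivered to the seafloor decays exponentially,
N(z) = N₀·exp(−λₚ·τ·z); the living benthic stock declines linearly from
B_surface = 99 to B_bottom = 1 (arbitrary units) across the inhabited zone
(0–10 cm); below it, benthic DNA decays by the same law with λ_b = 0.9 <
λₚ = 1, continuous at the boundary. The printed decay law has no explicit
depth variable, and with all constants at unity and depth in centimetres no
natural unit reproduces the observed field magnitudes; the package
therefore introduces an explicit depth-to-decay-coordinate scale τ
(default 0.02 per cm, chosen so the default fraction profile increases
through the inhabited zone) and asserts only the *shape* of the profile —
surface fraction exactly N₀/(N₀+B_surface) = 0.01, maximum at the base of
the inhabited zone, strictly decreasing below it, and the low/peak/
intermediate ordering of 10-cm depth-bin means — never field magnitudes.
Whether the published benthic constant 0.9 is absolute or relative to the
planktonic constant is ambiguous; it is implemented as absolute, which
preserves the stated ordering either way.

`fit_params` estimates any subset of the parameters by bounded least
squares on logit fractions (respecting the (0,1) range); λₚ is bounded
below by λ_b so fitted parameters always satisfy the model's ordering. With
the default free pair (λₚ, τ), noiseless profiles are identified to
machine precision (the two parameters decouple through the above-zone and
below-zone slopes), and under Gaussian logit noise of σ = 0.05 on 30
points the median relative error on λₚ is about 5%.

## The synthetic-data generator

The generator's defaults are the study conditions the analyses assume:
two PCR replicates per sample, cores extruded in 2-cm layers to 30 cm,
four sites spanning the polar (LC) / transition / temperate (NAC)
hydrographic gradient, 2,000 reads per sample and a multinomial read model
over the layer community. A layer's planktonic:benthic read mass follows
the decay model at the layer midpoint; within the planktonic pool, zone
base abundances are multiplied by per-taxon copy-number factors (the
temperate *G. inflata* carries an illustrative 5× rDNA multiplier, not an
estimate) and, above 4 cm, a 10× surface-enrichment factor for
*G. uvula* (the field pattern is qualitative; the factor is a free knob).
Taxa flagged with forward-primer mismatches (the spinose *G. bulloides*
and *T. quinqueloba*) receive zero read mass. Census counts are drawn from
the same zone assemblages *without* any of the molecular biases — spinose
taxa present, no multipliers — plus benthic tests at the ~100:1
planktonic:benthic shell ratio, so fossil/molecular congruence and its
known distortions can be studied with known truth.

Reference sequences are a common 110-nt ancestor independently mutated at
a `divergence` fraction of positions (default 0.2) per taxon, regenerated
until all pairwise differences exceed 10% of positions — comfortably above
both the 0.03 clustering threshold and the 1 − 0.95 classification margin,
so distinct taxa are separable by construction. Reads carry constant Q37
qualities; substitution errors are placed uniformly, irrespective of
quality (quality-filter behaviour is tested with separately constructed
low-quality reads). Chimeras are single-breakpoint two-parent splices with
abundance-weighted parents, matching the detector's model. The replicate
naming convention is `<site>_<top>-<bottom>.repK`.

What the generator does **not** emulate: polymerase-specific error spectra,
PCR-cycle-resolved amplification, fragment-length taphonomy, real rDNA
copy-number distributions, or reference databases with missing/partial
coverage. Passing tests therefore demonstrate correctness of the machinery
under the stated statistical structure, not performance on field data.

## Community statistics

CSS normalization implements the scaling step only: the per-sample factor
is the sum of counts ≤ the chosen quantile (default the median) of the
sample's nonzero counts, and values are rescaled to a common scale of
1,000. The zero-inflated Gaussian mixture sometimes used downstream of CSS
affects differential-abundance testing, which this package does not
perform. An optional adaptive mode picks the smallest quantile at which
the across-sample instability of median-ratio factors falls below a bound.

PCoA is classical scaling (double-centering + eigendecomposition).
Negative eigenvalues are kept and reported; an additive (Lingoes)
correction is available and recorded when applied. The dispersion test
embeds samples by PCoA and measures each sample's distance to its group
*centroid* (not spatial median; the convention is recorded), with
negative-eigenvalue axes contributing negatively to squared distances —
the betadisper convention, and the F statistic matches
`vegan::betadisper` to 1e-6 in the cross-check test. Significance comes
from label permutations with centroids and distances recomputed under each
permuted labelling, which respects exchangeability exactly; p-values use
the +1 correction and a mandatory seed (999 permutations by default). The
same machinery provides PERMANOVA (pseudo-F partition of squared
distances; statistic cross-checked against scikit-bio) and Mantel
correlation. Both permutation tests hold their nominal 5% size within two
binomial standard errors over 500 null simulations.

Depth-binned planktonic fractions use the reporting bins [0,10), [10,20),
[20,30) cm with layer midpoints deciding membership, and PCR replicates
are summed before fractions (how replicates were combined in the field
studies is unstated; summing is the recorded default). Census relative
abundances are computed on planktonic tests only, with benthic tests
tracked separately.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: the end-to-end
study uses 40–60 samples × 2 replicates at 1,000 reads per replicate
(1.2×10⁵ reads), alignment oracles use 200 pairs at ≤ 12 nt plus full
enumeration at ≤ 6 nt (enumerating all alignments at length 12 is ~10⁸
paths and is left to the memoized oracle), and calibration uses 500
simulations at 199 permutations. The aligner is a pure-Python dynamic
program; its cost is quadratic in sequence length and linear in the number
of ISU×reference pairs, which is the dominant cost on noisy data where
dereplication yields many singleton ISUs — the main known performance
limitation. Degenerate inputs are defined: empty sequences raise, an ISU
shorter than the precluster signature uses its full length, all-zero
samples are excluded from CSS and fraction profiles with a warning, and
fit non-convergence is flagged in the result rather than raised.
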