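# Methods

## The analysis and its statistics

The package reimplements, over synthetic data with known truth, the
comparative stages of a plastome phylogenomics study: quadripartite
structure and junction behavior, gene census and length dispersions,
sliding-window divergence with hotspot calling, site classification,
construction and filtering of phylogenetic matrices, ORF-integrity
scanning with dN/dS, and distance-based topology recovery.

**Mutation-event proportion.** For a window of aligned length L, the
statistic is `100·(NS + ID)/L`. NS is the number of columns with at least
two distinct unambiguous non-gap states (each variable column counts once,
regardless of how many states it shows; columns informative in fewer than
two sequences cannot be variable and so never enter NS). ID counts indel
*events*: a maximal run of consecutive columns sharing one identical
gap presence/absence pattern across taxa is one event however long,
so a shared multi-column deletion is one mutation. L includes gap
columns. An event straddling a window boundary counts in every window it
touches. Windows are 600 columns at a 200-column step, with one truncated
tail window; hotspot calls require proportion strictly greater than 20%
and merge overlapping or adjacent qualifying windows. The generalization
of this originally pairwise statistic to a multiple alignment (variable
columns rather than summed pairwise differences) is a package choice; the
alternative (mean pairwise) was considered and rejected because the
threshold semantics would then depend on taxon sampling depth.

**Site classes.** Per column, using unambiguous non-gap states only:
constant (one state), variable (≥ 2 states), parsimony-informative (≥ 2
states each present in ≥ 2 taxa), singleton (variable but not PI). Columns
with no such state are unclassifiable and count only toward the total.

**Dispersion convention.** Cross-genome length summaries use the sample
standard deviation (denominator n − 1) rounded half away from zero to
integer bp. This is the only convention that reproduces all five published
dispersions of the reference table simultaneously (the IR value is 146.54,
printing as 147). Only the fifteen Cornales individuals enter summaries;
the Ericales outgroup is excluded.

**NG86 dN/dS.** Synonymous/nonsynonymous potential sites per codon are
counted as fractions of the three possible changes per position, with
changes to stop codons counted as nonsynonymous (the original counting
scheme); observed differences in multi-hit codons average over all minimal
substitution paths with equal weights, excluding paths through stop codons
whenever a stop-free path exists. Proportions pN = Nd/N and pS = Sd/S
receive the Jukes–Cantor correction `d = −(3/4)·ln(1 − 4p/3)`; saturation
(p ≥ 3/4) maps to +∞ so ω = dN/dS degrades gracefully (ω = 0 when dN is
finite), and ω is undefined (None), never infinite, when dS = 0. The
genetic code is translation table 11 (plastid/bacterial). Likelihood
branch models are deliberately out of scope; the scientific claim they
served — no rate-ratio difference between stop-containing and intact
lineages — is tested instead by a label permutation: per-taxon ω against a
designated outgroup, group means, range statistic, p-value from ≥ 999
seeded shuffles with add-one correction.

**Filtering.** Strict filtering keeps exactly the columns with zero gap
characters. Light filtering is a deterministic, parameterized
simplification of Gblocks-style trimming: columns with gap fraction
> 0.5 are removed; gap-containing columns whose majority-state frequency
(over non-gap characters) is below 0.5 are removed; retained islands
shorter than 10 columns in which every column has a gap are removed.
Because only gap-containing columns are ever dropped, the light output
always contains the strict output — which mirrors how the study's strict
alignment was derived from its light one, and makes the containment a
machine-checked invariant rather than an accident of parameters. Exact
Gblocks output is not reproduced by design: the claim under test is that
the *level* of filtering does not change the topology, not byte equality
with one trimming tool.

**Neighbor joining.** Canonical Saitou–Nei with the Q criterion; ties in Q
are broken by the lexicographically smallest pair of cluster-representative
names, making the tree deterministic. Negative branch-length estimates are
clamped to zero (topology is unaffected). JC distances are computed over
columns where both sequences have unambiguous non-gap characters; p ≥ 3/4
is flagged missing and NJ refuses incomplete matrices rather than
guessing. Bootstrap support resamples columns with replacement, seeded.

## The synthetic-data generator

The generator is the stand-in for the study's raw data and defines the
test conditions; it is not tuned per experiment.

**Genome plan.** The default plan is full study scale: LSC 86,500 bp, SSC
18,500 bp, IR 26,000 bp (157 kb total), 114 unique genes — 79 CDS, 31
tRNA, 4 rRNA — with 16 duplicated in the IR (130 total), 17 one-intron and
2 two-intron (ycf3, clpP) genes, placed in a realistic order with typical
lengths. Spacer lengths are derived deterministically from the region
budgets. The plan emulates the published gene complement rather than
copying any deposited record: two of the seventeen one-intron genes
(rps12, treated as cis-spliced, and trnE-UUC) are designated intron
bearers to reach the published census, and matK sits between trnK and
rps16 rather than inside the trnK intron (so the trnK–rps16 hotspot maps
to the matK–rps16 spacer). Base composition targets GC 40.3% in coding
and 34.5% in noncoding sequence (≈ 37.9% overall); realized CDS GC runs
≈ 0.5 points high because stop-codon rejection discards AT-rich codons.

**Evolution.** Each branch applies a Jukes–Cantor kernel per site:
substitution probability `(3/4)(1 − exp(−4d/3))` with d = branch length ×
site rate multiplier, the multiplier being the product of region (IR
0.3×), coding status (0.5×) and hotspot (default 10× on nine designated
regions) factors. The two IR copies evolve as one locus: mutations are
drawn on IRb and mirrored, keeping the pair an exact reverse complement
(and the four junction-flanking bases are kept non-extending so the
planted IR is always the maximal pair). Substitutions that would create an
in-frame stop, destroy the start codon, or destroy the terminal stop of a
CDS are vetoed; background indels (Poisson events, geometric lengths, mean
4 bp) fall only in single-copy noncoding sites. Reading-frame disruptions
therefore arise exclusively from the explicit disruption spec
(nonsense: an internal codon set to TAA; frameshift: an indel of length
≢ 0 mod 3 inside the CDS), which the analysis drivers use to plant the
published rpl22 pattern (19/19/5 bp insertions in Cornus, 1 bp deletions
in Alangium, 1 bp insertion in Curtisia, TGG→TGA-style nonsense in
Mastixia — seven affected individuals).

**Truth bookkeeping.** Every ancestral site carries a sortable key;
insertions mint fresh keys ordered after their anchor site. The union of
leaf keys defines the true alignment columns, so degapping any alignment
row reproduces that leaf's genome exactly, and per-column provenance
(feature/spacer label, quadripartite region) survives evolution. Truth
bundles also record per-leaf IR coordinates, hotspot column intervals,
injected disruptions and per-branch realized substitution counts.

**What the generator does not emulate.** Gene order change (the study
found identical gene order, so order is fixed), IR expansion/contraction,
selection heterogeneity among sites or lineages (background evolution is
neutral within the frame constraints, so NG86 ω on simulated whole genes
is ≈ 1, and the ω ≈ 0.35 recovery experiments use the separate codon-pair
simulator with an explicit nonsynonymous acceptance ratio), alignment
error (the true alignment is known, whereas real pipelines inherit
aligner artifacts), ambiguity codes, and RNA editing. Passing tests
therefore demonstrate correctness of the statistics and the recovery
behavior of the methods under the stated generative model — not robustness
to misalignment or annotation error in real data.

**Default tree.** Fifteen taxa arranged as in the study's recovered
topology (Cornaceae–Alangiaceae sister to Curtisiaceae; Nyssaceae–
Davidiaceae–Mastixiaceae; Hydrangeaceae), branch lengths 0.0006–0.010
substitutions/site on the noncoding scale — divergence of the same order
as the study's plastomes (windowed identities bottoming out near 80% in
hotspot regions, > 90% elsewhere).

## Problem sizes

Replicate-heavy experiments (topology invariance, hotspot
recall/specificity) run on a proportionally scaled plan — LSC 12 kb, SSC
4 kb, IR 3.2 kb (~22.4 kb genome, 16 genes including IR-duplicated copies
of all three kinds and a two-intron gene) — at the same per-site
divergence, 50 replicates each; the scaled plan keeps the full plan's
structural ingredients while allowing many independent replicates. IR
recovery uses 100 planted genomes with IR lengths drawn from 20–30 kb
(single-copy flanks 20 kb + 6 kb); brute-force oracle comparisons use 100
random alignments of ≤ 50 (window events) or ≤ 300 (strict filter)
columns; NJ consistency uses 50 random additive trees of 4–10 leaves; ω
recovery uses 50 pairs of 300 codons at ω = 0.35; permutation calibration
uses 200 null replicates of two 4-taxon groups with 999 shuffles each.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; GenBank's 1-based
  inclusive convention exists only at the I/O boundary.
- Ambiguity codes are preserved in sequence and treated as missing in all
  statistics (GC, site classes, distances, identity).
- Equal-length single-copy gaps between the IRs raise an error instead of
  silently picking LSC/SSC labels.
- An alignment shorter than one window yields a single full-length window
  with a warning; an empty hotspot list is a valid result.
- Proportions are reported to two decimals in tables; the hotspot
  threshold comparison is strict (> 20).
- gc_content follows its definition, 100·(G+C)/(A+C+G+T).
- The IR detector's mismatch tolerance (off by default; plastome IRs are
  treated as exact) admits mismatches during extension while their running
  fraction stays within budget, with exact-match flanks.
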