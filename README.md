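# plastcomp

Comparative analysis of quadripartite plastid (chloroplast) genomes, built
around the questions a plastome phylogenomics study asks of a clade like
Cornales: how is each genome organized (LSC–IRb–SSC–IRa structure, gene
complement, junction behavior), where does it vary (sliding-window
mutational hotspots, site classes), are any genes pseudogenized (premature
stop codons, frameshifts, dN/dS), and is the recovered phylogeny robust to
how the alignment is subdivided and filtered?

The package is organized as an analysis project: every computation lives in
the library under `src/plastcomp/`, and the numbered scripts under
`analysis/` run the stages in order on a synthetic 15-taxon data set with
known ground truth.

## What it computes

- **Quadripartite structure** (`quadripartite`): the inverted-repeat pair is
  the maximal pair of disjoint intervals with `seq(IRb) = revcomp(seq(IRa))`
  (seed-and-extend on k-mer anchors, k = 21, searched on the doubled
  circular sequence); the two single-copy gaps are labeled LSC (longer) and
  SSC (shorter). Gene–junction reports classify each of the four region
  boundaries as spanned by a gene (with the overlap in bp), abutted, or
  inside a spacer.
- **Inventory** (`inventory`): gene censuses (unique/total/IR-duplicated,
  intron counts), coding/noncoding split by exon-interval union, and
  cross-genome dispersions using the sample (n−1) standard deviation
  rounded half away from zero.
- **Divergence** (`divergence`): per-column site classes (constant,
  variable, parsimony-informative, singleton); the sliding-window
  mutation-event proportion `100·(NS + ID)/L`, where NS counts substitution
  columns, ID counts indel events (one maximal run of columns sharing a gap
  pattern = one event) and L is the aligned window length (defaults 600 bp
  windows, 200 bp step); hotspots are merged runs of windows with
  proportion strictly > 20%.
- **ORF integrity** (`orf`): internal-stop scanning under the
  plastid/bacterial genetic code (table 11), frameshift/point-nonsense
  characterization against an intact reference, and Nei–Gojobori (1986)
  dN/dS — equal-weight minimal-path counting with Jukes–Cantor correction,
  ω = dN/dS — plus a label-permutation contrast of group ω values.
- **Matrix building** (`matrices`): complete/coding/noncoding data sets with
  one IR copy removed; unfiltered, light (deterministic Gblocks-style) and
  strict (no column with any gap) filtering; per-gene/intron/spacer
  partition subsets with small or invariant subsets pooled by functional
  category (minimum 200 columns).
- **Tree recovery** (`trees`): Jukes–Cantor distances
  `d = −(3/4)·ln(1 − 4p/3)`, canonical Saitou–Nei neighbor joining with
  deterministic tie-breaking, column bootstrap, Robinson–Foulds topology
  comparison.
- **Synthetic data** (`sim`, `plan`): circular ~157 kb quadripartite
  plastomes (114 unique genes: 79 CDS, 31 tRNA, 4 rRNA; 16 duplicated in
  the ~26 kb IRs) evolved along a known tree under a JC kernel with
  region-specific rates (IR 0.3×, coding 0.5×, noncoding 1×), localized
  hotspots, noncoding indels, mirrored IR evolution and optional
  nonsense/frameshift gene disruptions — emitting an exact true alignment
  and truth bundle for every downstream stage.

`plastcomp.published` carries the published per-plastome feature table of
the fifteen Cornales individuals (+ outgroup) as reference input for the
summary recomputations.

## Worked example

```bash
cd analysis
python 01_simulate.py
python 02_structure_junctions.py
python 03_inventory.py
python 04_divergence_hotspots.py
python 07_trees.py
```

prints (abridged):

```
simulated 15 genomes (seed 2024); alignment 15 x 158100
IR pair recovered exactly in 15/15 genomes
published region-length s.d. (bp): {'LSC': 586, 'SSC': 188, 'IR': 147, 'coding': 115, 'noncoding': 789}
7 hotspot regions above the 20% threshold (planted elevated-rate regions: 8)
  [3200, 5800) peak 48.8%  trna:trnK-UUU, spacer:trnK-UUU-matK, cds:matK, ...
dataset  filter      columns  rf_to_truth
complete unfiltered  132100   0
coding   strict      75343    0
noncoding light      55682    0
bootstrap (100 reps) minimum support on the complete matrix: 1.00
```

Reading: the detector recovers every planted IR exactly; the five printed
region-length dispersions of the published table are reproduced from its
rows; sliding windows above the 20% mutation-event threshold coincide with
the planted elevated-rate regions (adjacent ones merge); and the NJ
topology equals the generating tree (RF = 0) for all nine dataset ×
filtering combinations — the invariance the analysis is designed to test.
Tables land in `results/`, bulky sequence artifacts in `scratch/`.

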