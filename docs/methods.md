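# Methods

`mosaicpath` reimplements, on synthetic data, the computational core of a
BAC-based "monoploid" reference build for a mosaic interspecific polyploid
such as a modern sugarcane cultivar: a genome carrying ~100–130
chromosomes drawn mostly from *Saccharum officinarum* (x = 10), partly
from *S. spontaneum* (x = 8), with some interspecific recombinants.  The
strategy sidesteps whole-genome assembly of such a genome by selecting a
minimum tiling path (MTP) of BAC clones over a diploid guide genome
(sorghum-like), trimming it to a single tiling path (STP) that holds each
gene once, and annotating the result with ancestral-species origin and a
single-dose SNP genetic map.

## Synthetic study conditions (`synthio`)

The generator produces every input the pipeline consumes, with the
statistical structure the analysis assumes.  All coordinates are 0-based
half-open in memory; GFF3 and AGP on disk are 1-based inclusive.

* **Guide genome** — `n_chromosomes` (default 10) random chromosomes of
  `chrom_length` bp with non-overlapping, strand-labelled genes placed one
  per equal-width slot.
* **Ancestral genomes** — species A and B each accumulate
  `divergence_subs_per_site / 2` substitutions per site away from the
  guide (independent sites, uniform over the three alternatives —
  Jukes–Cantor-like; no indels, since transposon evolution is out of
  scope).  Species B then undergoes the `rearrangement_spec` fusions: each
  entry splits one donor chromosome and appends its arms to two
  recipients, so two fusions turn x = 10 into x = 8, mirroring the
  structural difference between the two ancestral species.  A segment map
  records the guide coordinates of every base of both genomes; it is the
  ground truth for anchoring and gene placement.
* **BAC library** — `n_bacs` clones with Normal(`bac_insert_mean`,
  `bac_insert_sd`) inserts, drawn from species A with probability
  `frac_species_a` (default 0.78, the officinarum share of assigned
  contigs in the kind of cultivar modelled) and stored in random
  orientation.  Whole-genome-profiling tags are the `tag_length` = 50 bp
  substrings starting at each occurrence of the restriction motif
  (default `CTGCAG`, PstI — the enzyme family used for the genotyping
  chemistry; the profiling enzymes themselves are a free parameter).
* **WGS depth tracks** — a toy exact-match read placer: reads of
  `read_length` bp are sampled uniformly from the homologous interval of
  each ancestral genome at `wgs_depth` (default 20×), sequencing errors
  added at `seq_error`/base, and a read is placed iff it matches the
  contig with ≤ `max_mismatch` (default 0) mismatches.  Same-species reads
  differ only by errors; the other species' reads carry the full
  interspecies divergence, so their acceptance rate decays exponentially
  with divergence × read length.  This reproduces the *signal* a real
  aligner produces (differential coverage) without modelling mapping
  quality, paralogy or repeats.
* **Selfing progeny** — each single-dose marker sits on one homolog of a
  simplex parent; a selfed offspring carries 0/1/2 doses with probability
  1/4, 1/2, 1/4 (carriers 3:1).  Read counts are Poisson(`depth_mean`,
  default 60×) with alt-read fraction dose/`ploidy` (default ploidy 12,
  the hom(oe)olog count of the cultivars modelled) perturbed by the error
  rate.  An optional linkage map turns the markers into Markov chains
  along chromosomes with stated adjacent recombination fractions, for
  grouping experiments; without it markers segregate independently.
* **Species panel** — 12 + 9 + 13 officinarum/robustum/spontaneum
  accessions by default; `n_diag` markers (default 40% of markers, split
  evenly) are fixed-present in one side of the panel and absent from the
  other, the rest shared at random.

What the generator does **not** emulate: repeat families and TE turnover,
read mapping artefacts, segregation distortion, aneuploid dosage
variation, and assembly errors.  Green tests therefore demonstrate that
the decision rules and estimators are implemented correctly and recover
truth under their own assumptions — not that those assumptions hold for
any particular real dataset.

## Anchoring (`wgp_anchor`)

Tags whose sequence occurs in more than one BAC are discarded.  Remaining
tags are placed on the guide with a seed-and-verify index (packed 25-mer
seeds, string verification, both strands; exact by default, ≤ 1 mismatch
by pigeonhole on the two tag halves), or consumed from an external
BED-like table.  A BAC is anchored when some `window` = 300 kb window on
one chromosome contains at least `max(min_count, ceil(min_frac ×
total_tags))` uniquely placed tags — "at least 20% of the tags and a
minimum of three" with both comparisons inclusive, the fraction applied
with a ceiling.  The window slides over tag positions only (an
event-driven scan; counting is what matters, not window phase), ties
between equal-count windows resolve leftmost with chromosomes in sorted
order, and the anchor interval is `[min, max)` of the supporting tag
starts; the midpoint is reported as the anchor position.  Multi-position
tags with a hit inside an anchored BAC's winning window are credited as
rescued support and may widen the interval, never beyond the window and
never changing the anchoring decision.

MTP selection replaces the manual curation step with the optimal interval
point-cover greedy: scan genes (fully contained in ≥ 1 anchored BAC) left
to right; for the leftmost uncovered gene pick the containing BAC that
extends furthest right (ties: more contained genes, then lexicographic
id).  This covers every coverable gene with a provably minimum number of
BACs, which the tests confirm against exhaustive search on ≤ 12-BAC
instances.

## Single tiling path (`stp_build`)

BAC pairs sharing ≥ 2 guide genes are redundant overlaps.  Walking each
chromosome's MTP in order, both trim choices for each overlapping pair
are costed — genes lost from the union first, then bp removed — and the
cheaper side is trimmed, with the cut at the midpoint between the last
kept and first removed gene (the text behind this procedure does not fix
a cut site; the midpoint loses no annotated sequence on either side).  A
gene shared by a pair below the two-gene threshold is kept only in the
leftmost segment's retained list (no sequence trimmed), and genes spanning
non-adjacent segments stay with the leftmost with a warning, so no guide
gene ever appears in two segments.  Segments are then ordered per
chromosome by the median guide position of their retained genes, a
segment is reverse-complemented when a strict majority of its genes align
in reverse (tie → forward), and segments are joined with `gap_size` =
10,000 N into one super-scaffold per guide chromosome, described by AGP
v2.1 (gap type `scaffold`, evidence `map`).  Segments without gene
evidence follow the genic ones ordered by anchor midpoint; with no anchor
either they go to an `unplaced` bin, never silently dropped.

## Ancestry (`ancestry`)

Per contig, the covered fraction is the share of bases at depth ≥
`min_depth` = 5 under each species' reads (alignment-quality filtering
belongs to the upstream aligner).  The "10% difference in total
coverage" rule is read as an absolute difference of covered-base
fractions (≥ `delta` = 0.10), not a ratio, since the quantities compared
are cumulative coverages; the rule is symmetric under label swap by
construction.  Contigs left unassigned and longer than `min_length` =
50 kb fall back to species-specific canonical 24-mers harvested from the
assigned contigs' repetitive (depth > mean + 2 SD; "2 × SD of mean" is
read as mean + 2·SD) and well-covered (within 1 SD of the mean) regions,
with mean and SD computed per contig; each species' set excludes every
k-mer observed in the other species' assigned contigs, making the two
sets disjoint by construction.  The contig goes to the species masking
strictly more bases; equal masking (including 0 = 0) stays unassigned.

## Genetic map (`singledose`)

Genotypes from allele counts: depth outside [30, 1000] → missing; minor
allele frequency ≥ 4% with ≥ 2 reads → heterozygous; < 1% → homozygous
for the major allele; the [1%, 4%) band → missing ("1 to 4%" read as
half-open), as is a frequent but under-supported minor allele.  Carriers
(het or hom-alt) versus non-carriers are tested against 3:1 by Pearson
chi-square, df = 1, no continuity correction, retaining markers with
p ≥ 0.05 and < 20% missing data.  Because the statistic is discrete, the
exact size of this nominal-5% test at n = 186 is 4.17% (and its power
against 1:1 segregation exceeds 0.9999); the calibration checks allow for
this.

Two-point linkage assumes both markers coupling-phase on one homolog of a
selfed simplex parent: with q = (1−r)/2 the 2×2 carrier-table class
probabilities are q², ¼−q² (each discordant class) and ½+q², the
likelihood is maximised over r ∈ [0, 0.5] by bounded search (endpoints
checked explicitly), and LOD = log₁₀ L(r̂) − log₁₀ L(0.5).  Repulsion
and multi-dose configurations are outside the single-dose framework and
out of scope.  Cosegregation groups are single-linkage components over
edges with LOD ≥ 10 and rf ≤ 0.35; components under 5 markers are
discarded and counted.

A SNP's species origin requires carriers in ≥ 2 accessions of one panel
side (officinarum ∪ robustum vs spontaneum) and none on the other;
missing panel calls count as absence of evidence by default, with a
strict mode that refuses to certify "absent from all" through missing
data.  A group is labelled for a species when ≥ 90% of its
origin-labelled markers agree, recombinant when both species reach 10% —
the labelling rule itself is this package's choice (the underlying
procedure is not published as an algorithm), and both thresholds are
configurable.  Orthology reports the top one or two guide chromosomes
holding ≥ 5 markers and ≥ 10% of a group's aligned markers.

## Comparative layer (`comparer`)

Reciprocal best hits over BLAST-outfmt-6-like tables (score ties broken
by identity, then subject id) with identity ≥ 70% and coverage ≥ 40% on
both directions.  A pair is colinear when the subject gene overlaps the
query's host-segment guide region; unanchored hosts are undetermined and
excluded from rate denominators.

Ks/Ka follow Nei–Gojobori (1986) with the standard genetic code only:
per-codon synonymous site fractions (changes to stops count as
non-synonymous), observed differences averaged over all shortest
mutational paths with equal weight, paths through stop codons excluded
(all paths used if every one is blocked), sites averaged over the two
sequences, and the Jukes–Cantor correction −(3/4)·ln(1 − (4/3)p).
Gapped or ambiguous codons are dropped pairwise; a terminal stop pair is
ignored; internal stops and saturation (p ≥ 3/4) raise errors.  Every
site count and difference count is checked exactly against a brute-force
enumeration oracle over all 61 × 61 sense-codon pairs.

Dating is linear: T = Ks/(2k) with k = 6.5 × 10⁻⁹ substitutions/site/year
for the synonymous clock, and T = d/(2r) with r = 1.3 × 10⁻⁸ for LTR
pairs, where d is the Kimura two-parameter distance
−½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q).  The two published median-Ks readings
for the cultivar/guide split (0.111, dating it at 8.5 My, and 0.1268,
which would give 9.75 My) are mutually inconsistent under the same clock;
the package implements the formula and exposes both inputs without
resolving the discrepancy.  Ages are reported at 2 significant figures in
summaries and full precision in tables.

## Problem sizes

The test suite and `scripts/acceptance.py` run the pipeline at desk
scale, chosen to keep every recovery statistic well separated from its
failure mode: a 10 × 1 Mb guide with 200 clones of ~100 kb for anchoring
recovery (zero divergence), a 10 × 300 kb guide with 120 clones for
ancestry recovery (divergence 0.02, 20× depth), 2,000 replicates of the
n = 186 segregation test, 60 simulated 300-codon ortholog pairs for the
Ks ladder, and exhaustive-search cross-checks on instances of ≤ 12 BACs.
The headline resource numbers of a real build (hundreds of Mb, tens of
thousands of clones) depend on real libraries and are not reproducible at
this scale; the worked-value and ratio checks cover the arithmetic they
rest on.

## Known limitations

* The tag placer is exact-match (≤ 1 mismatch optional); at divergences
  well beyond a few percent, tag attrition rather than window logic
  limits anchoring.
* The two-point model ignores repulsion-phase pairs, which in a real
  polyploid selfing design contribute weak negative association.
* k-mer fallback masking is quadratic-ish in contig count at Python
  speed; it is intended for the residual minority of contigs, as in the
  procedure it models.
* `collapse_to_stp` resolves overlaps pairwise along the MTP order;
  pathological mutual three-way overlaps are resolved leftmost-first with
  a warning rather than globally optimised.
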