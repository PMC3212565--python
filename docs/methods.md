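# Methods

`replowpass` implements a low-pass sequencing strategy for characterising
the repetitive fraction of a genome without assembly, together with a
ground-truth simulator that reproduces the statistical structure the
strategy relies on.  This note documents the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## The measurement principle

At sequencing coverage far below 1x (here ~0.06-0.2x of the haploid
genome), two reads sample the same single-copy locus with negligible
probability, so any pair of similar reads almost surely derives from a
repeat.  A repeat family with *c* copies of an *L*-bp unit is sampled at an
effective unit coverage of roughly `genome_coverage x c`, deep enough to
reconstruct and quantify the family even when the genome as a whole is
barely touched.  Everything in the package follows from this asymmetry:

1. **Clustering** groups long reads (~250 nt) whose best local alignment
   reaches 90% identity over 55% of the shorter read, on either strand, and
   reads communities of the resulting graph as repeat families.
2. **Quantification** maps 30-nt short-read tags from separate male and
   female samples onto the clustered reads (at most 2 edits, best hit, one
   cluster per tag) and converts per-cluster tag counts into genome
   proportions, which are compared between the sexes through the statistic
   `M/(M+F)`.
3. **Satellite reconstruction** rebuilds tandem-repeat monomers as circular
   consensus sequences from the k-mer spectrum of a cluster's tags.
4. **Annotation profiling** converts local-alignment hit depth of family
   read databases along a query clone into copy-number estimates via the
   long-read genome coverage.

## Synthetic genomes

`GenomeSimSpec` declares a male/female genome pair: repeat families
(dispersed, tandem, rDNA-like with a tandem subrepeat block embedded in the
intergenic spacer, or spike-in controls), an i.i.d. background at
configurable GC, and per-sex copy numbers.  Family master sequences, copy
pools and background are shared between the sexes, so the genomes differ
only in copy number and block order — the situation the male/female
comparison assumes.

**Divergence model.**  A family's `divergence` parameter is the mean
per-copy substitution distance from the family consensus; individual copies
mutate at rates drawn uniformly from `[0, 2 x divergence]`, so the mean
pairwise divergence between copies is `2 x divergence`.  The uniform rate
spectrum mimics a family amplified over time: recent copies are
near-identical and link older, more diverged copies into one cluster by
transitivity.  A fixed per-copy rate would place every copy pair at the
same distance and make family connectivity collapse abruptly at the
clustering threshold, a behaviour real repeat families do not show.

**Read models.**  Long reads: Gaussian length (default mean 250 nt, sd 30,
truncated to [50, 500]), uniform or GC-biased start positions, both strands
with probability 0.5, per-base substitution/insertion/deletion rates
(defaults 0.2%/0.15%/0.15%, the indel-dominated ~0.5% error profile of
pyrosequencing), and a configurable fraction of exact duplicate reads
emulating emulsion-PCR artefacts (default 5%).  Short reads: fixed 36 nt
with per-position Phred qualities drawn around a profile whose first two
and last four cycles are markedly worse — the motivation for trimming tags
to positions 3-32.  `gc_bias_slope` is the change in log sampling odds per
unit GC fraction of the sampled window (0 = uniform).

**Spike-ins.**  Control reads are appended so that each control's expected
base fraction of the final pool equals its requested mass fraction.  The
expectation for a 3% total split 3:1 is therefore 2.25%/0.75%; the package
derives expectations from the requested fractions throughout.

**What the simulator does not model:**  homopolymer-specific flowgram
errors, paired ends, chromosome-scale karyotype structure, nested or
truncated repeat insertions, and sequence heterogeneity of the background.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated sampling model, not robustness to every artefact
of real libraries.

## Clustering details

Overlap detection is exact with respect to its definition: for every read
pair and strand, the optimal Smith-Waterman alignment (match +1, mismatch
-1, gap -2; identity = matches / alignment columns) is computed, and an
edge is recorded if identity >= 0.90 and the aligned span covers >= 0.55 of
the shorter read.  Two provable accelerations keep this practical: a pair
is aligned only if it shares an exact k-mer whose length is chosen so that
any alignment meeting the thresholds must contain one (k <= 9 here), and
traceback is skipped when the alignment score is below
`(3t - 2) * c0 * Lmin`, a lower bound implied by the thresholds.  All ties
(best cell, traceback direction) are fixed deterministically so independent
implementations can be compared edge-for-edge.

Communities: connected components first; a component is subdivided by
greedy modularity maximisation only when the partition improves modularity
by > 0.05 *and* at most `max(2(k-1), 1%)` of the component's edges run
between communities.  Modularity alone is uninformative here — the overlap
graph of a single tandem or dispersed family is an elongated ring or line
whose arc partitions always score high modularity — whereas genuinely
distinct families accidentally merged by chimeric or shared-segment reads
hang on a handful of bridging edges.  The bridge condition separates the
two situations.

Graph shapes: density >= 0.2 marks near-clique *globular* layouts
(short-monomer satellites, where every read overlaps every other).  Among
sparse graphs, a cycle-like layout (tandem unit much longer than the read)
has nearly constant node eccentricity while a path-like layout (dispersed
element) has a ~2x eccentricity spread between ends and middle; the
min/max-eccentricity ratio with threshold 0.75 classifies *circular*
versus *linear*, with small or ambiguous graphs labelled *other*.  (A
diameter-to-size ratio does not work for this purpose: at realistic
coverage the graphs are thick, and hop diameters stay far below any fixed
fraction of the node count.)

Tandem periodicity is the smallest self-alignment lag with >= 80% matching
positions, ties within 2% resolved towards the smallest lag so the
fundamental period beats its multiples.

## Quantification details

"Up to two mismatches, including gaps" is operationalised as unit-cost edit
distance of the tag against the best window of a read (edlib infix mode).
A pigeonhole index guarantees exactness of the acceleration: a 30-nt tag
within 2 edits of a read must contain one of its three 10-nt thirds as an
exact substring.  Ties across clusters at equal distance go to the larger
cluster, then the smaller cluster id — deterministic, and biased towards
abundant repeats as a proxy for best similarity.

Proportions are fractions of the sampled tag total, so spike-in tags count
against the denominator.  The default reporting floor is 0.005% of tags;
when running at reduced tag depth the floor should be interpreted as the
equivalent absolute tag count (the floor exists to exclude clusters whose
`M/(M+F)` is dominated by counting noise, which is a property of absolute
counts, not fractions).

Sex-differential candidates are flagged by the spike-in envelope rule: a
cluster is reported only if its `|M/(M+F) - 0.5|` exceeds the most extreme
deviation observed among the controls, whose true asymmetry is known
(3:1 and 1:3).  No additional multiple-testing machinery is applied.

The GC-bias diagnostic reports the Spearman correlation between cluster GC
and `M/(M+F) - 0.5` with a two-sided permutation p-value (999 permutations,
seeded).  Sign convention: negative rho means GC-rich clusters shift toward
the female sample, the direction produced when the male library sequences
GC-rich templates less efficiently.

Copy numbers: `copies = proportion x 1C / unit_length`, with 1C defaulting
to half the published 2C DNA amounts (2.925/2.865 Gb male/female).

## Satellite reconstruction details

The k-mer census counts every k-length window of every tag, plus reverse
complements under the default both-strands policy.  Reconstruction walks
greedily from the globally most frequent k-mer, extending by the
highest-count (k-1)-overlapping k-mer; revisiting the start closes a
circular consensus whose length equals the number of steps.  The count
floor for extension is 1% of the maximum k-mer count — low enough to keep
5% variant branches visible, high enough to suppress error k-mers.  All
ties break lexicographically, so the consensus is a pure function of the
spectrum; the reported rotation is the lexicographically minimal one and
the orientation is the strand carrying the walk's start k-mer.

Per-position support is the branch frequency of the consensus k-mer at that
position among all k-mers sharing its (k-1)-prefix; variants are branch
paths that diverge from and rejoin the consensus with relative frequency
above 5%.  Probe selection maximises the minimum support inside a window of
26-50 nt (ties: longest, then leftmost); variant-targeting mode substitutes
the variant bases and requires the window to cover them.

## Annotation profiling details

Database reads are locally aligned to the query (both strands,
seed-and-extend around shared 12-mers, iterative masking so one read can
contribute several distinct alignments).  Alignments scoring >= 50 add +1
to the per-base hit depth over their query span; window means divided by
the long-read genome coverage give copy numbers.  Per-base depth (rather
than counting each alignment once per window it touches) is what makes a
single-copy region read out at ~1 regardless of window size.  The score
threshold of 50 under +1/-1/-2 scoring plays the role of a stringent
similarity cutoff for ~250-nt reads.

## Scale of the bundled simulations

Test and demo runs use 1C sizes of 100 kb (demo) to 4 Mb (statistical
acceptance runs), long-read pools of 250-1,300 reads at 0.06-0.2x combined
coverage, and 100k tags per sample, with family copy numbers (40-2,000)
chosen so every family reaches >= 8x effective unit coverage.  These sizes
preserve the low-pass regime (background reads essentially never overlap)
while keeping binomial tolerances meaningful; they are scaled-down study
conditions, not tuning knobs.  At 100k tags the 0.005% reporting floor is
applied as its absolute-count equivalent (>= 250 tags, i.e. 0.25%).

## Known limitations

* Families whose copies diverge pairwise beyond ~8-10% fragment into
  subfamily clusters — inherent to a 90%-identity membership rule, and
  consistent with how such families behave in the source methodology.
* Cluster "bleeding" into flanking unique sequence grows with genome
  coverage as junction-spanning reads chain outward; at the intended
  low-pass coverage the effect is negligible, but quantification biases
  appear if the tool is run on deep data.
* The greedy consensus walk assumes one dominant monomer per cluster;
  clusters mixing two unrelated satellites yield the more frequent one.
* Duplicated-region satellite variants are reported as branch variants,
  not expanded into alternative full-length consensus monomers.
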