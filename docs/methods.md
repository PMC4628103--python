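# Methods

## The analysis in brief

`cenrepeat` reimplements, at desk scale, the similarity-clustering route to
centromeric repeat discovery: unassembled input and ChIP reads are pooled
and clustered by pairwise overlap; each cluster is scored by its ChIP
enrichment ratio (ER = ChIP reads / input reads, selection at ER > 2.0,
strictly); selected clusters are classified by cluster-graph topology and
characterized on a greedy consensus; and cluster-level enrichment is
cross-validated with simulated qPCR relative enrichment (RE) and the
Pearson correlation between ER and RE. A synthetic-genome generator with
planted repeat families supplies ground truth for every stage.

## The similarity criterion and its two evaluation routes

Two reads are joined when their best dovetail overlap — on either strand —
covers at least `min_overlap_fraction` (default 0.55) of the shorter read
at `min_identity` (default 0.90) or better. These thresholds are this
package's own defaults in the conventional range for read-level repeat
clustering; both are configuration keys. Candidate relative offsets come
from shared 17-mers; each candidate window is scored by per-base identity,
and windows within 0.04 of the identity threshold are re-scored with a
banded edit-distance alignment (edlib) so that occasional indels in
external data do not cost true edges (the simulator itself introduces
substitutions only).

Two routes compute the partition. `build_similarity_graph` materializes
every qualifying edge (optionally by exhaustive all-offset scanning) and is
quadratic; it serves moderate read counts, topology subgraphs, and oracle
comparisons in the tests. `cluster_reads` computes the same connected
components incrementally: reads are processed in sorted-id order (making
the result invariant to input order), candidates are drawn from an inverted
index over a hash-selected ~1/6 subset of each read's k-mers (hash
selection is position-independent, so overlapping reads sample identical
k-mers regardless of offset), and each read is aligned against at most a
few best-supported candidates per currently distinct component, merging
through a union-find. Below 400 reads the caps are disabled, so small-input
results equal the full-graph components exactly; at scale the caps bound
work the way greedy clusterers (CD-HIT, MMseqs) do and can only miss edges
between borderline-identity pairs that are already well connected through
their neighborhoods.

Before clustering, reads dominated by low-complexity sequence are removed
(DUST-like: trinucleotide Shannon entropy below 3.5 bits in 50-nt windows;
read dropped when more than half its length is masked). The 3.5-bit
threshold sits between measured window entropies of noisy simple repeats
(≤ 2.9 bits) and of genuine random or AT-rich satellite sequence
(≥ 4.6 bits). The 0.5 mask cap has a second, structural role: kept reads
can carry at most 150 nt of simple-sequence tail, which is below the
minimum qualifying overlap (0.55 × 300 = 165 nt), so simple tails alone can
never create an edge.

## Enrichment model and the ER statistic

ChIP is modeled as preferential sampling: each fragment's weight is the
enrichment factor of the repeat family at its midpoint (1.0 on background),
and the ChIP library size scales with the genome-average weight — i.e. the
two libraries are coverage-matched, not read-count-matched, exactly as in
real experiments where the two libraries are sequenced to similar depth but
never to identical counts. Under this model the expected per-family
chip/input read ratio equals the planted enrichment factor at equal nominal
coverage, so the raw ER of a family's cluster is an unbiased estimate of
its planted ChIP weight. A fixed-equal-read-count model cannot satisfy this
at desk scale: with planted families occupying a non-negligible genome
fraction, multinomial normalization would compress every ER by the mean
enrichment weight.

ER defaults to the raw count ratio; a normalized mode (each count divided
by its library size) is available for badly unbalanced libraries, and the
two agree exactly when library sizes are equal. A pseudocount of 0.5 is
applied to both counts only when one of them is zero, so typical records
are untouched; clusters with both counts zero are flagged undetermined and
excluded from ranking. Selection is strict (ER > threshold).

## Topology classification

Metrics per cluster subgraph: node count, density, normalized diameter
(diameter / n), maximum degree fraction, a closure flag, and an elongation
index `diameter × mean_degree / (2n)`. Elongation is ~1.0 for a
path-of-overlaps graph at any coverage and ~0.5 for rings and complete
graphs; it makes line detection coverage-independent, because normalized
diameter alone shrinks as read depth grows while the locus length stays
fixed. Rules, in order: **star** if one node is adjacent to ≥ 50% of the
others and normalized diameter ≤ 0.1; **ring** if the consensus closes on
itself (terminal 40-mer recurs near the contig start) and the graph
survives single-node removal at 10 sampled nodes; **line** if elongated
(normalized diameter ≥ 0.3, or elongation ≥ 0.7) and not closed; otherwise
**other**, as are clusters under 20 nodes. When no consensus is available a
graph-only closure fallback (2-connected and not elongated) supports
classifying bare graphs. All thresholds are configuration keys; their
validation surface is the planted-class agreement test (tandem → star/ring,
dispersed elements → line, ≥ 90% over ten fixtures). For large clusters the
subgraph is computed on a seeded subsample (default 200 nodes in the
pipeline; 120 in the test harness) — the class signal (complete vs
elongated vs cyclic) is preserved under uniform node subsampling at these
densities.

## Consensus, monomer, ORFs, junctions

The consensus assembler is a deliberately simple greedy
overlap-layout-consensus: longest exact suffix/prefix overlaps (≥ 40 nt,
after a k-mer-based orientation pass) merge first into read chains; each
chain is majority-voted per column; the top contigs are then polished by
mapping every read back and re-voting, which restores full depth to columns
that the chain left thin. Reads without any qualifying overlap remain
single-read contigs.

Monomer length is the smallest lag L (from 2 to length/3) at which the mean
per-base self-match of the sequence against itself shifted by L reaches 0.8
and is a local maximum — exact, alphabet-native, and trivially checkable by
a direct loop; it is phase- and strand-invariant. (Lags start at 2 rather
than 10: a dinucleotide microsatellite's true period is real and the score
floor already rejects random sequence.) AT content is (A+T)/(length−N) on
the longest contig. ORFs are ATG-initiated spans immediately followed by a
stop codon on any of the six frames, reported with the stop excluded, so a
429-nt ORF encodes 143 aa. Junctions are contig positions where ≥ 30% of
spanning reads terminate with an unaligned, heterologous tail of ≥ 20 nt
from ≥ 2 distinct sequences; clip coordinates jitter a few bases with end
trimming, so support is pooled within ±5 nt before thresholding.

## Split-satellite detection

A satellite whose monomer exceeds the read length cannot form a single
cluster; its conserved segments become separate clusters. The connection
analysis counts, for every retained cluster pair, (a) mate links — read
pairs whose mates sit in different clusters — and (b) end-similarity hits —
terminal 100-nt segments of assembled contigs (≥ 3 reads) from different
clusters aligning at ≥ 80% identity over ≥ 50 nt, with a k-mer prefilter
restricting the quadratic comparison to plausibly similar ends. Clusters
join a split group when either count reaches the link threshold (default
5). An `end_hits`-only joining mode is provided for data where coverage
gaps fragment single loci into mate-linked cluster pairs; at the default
fixture's coverage such fragmentation is rare (see below) and the
either-count rule is the default.

## The synthetic fixture: what it emulates, and what it does not

Default study conditions (all configurable):

| family  | class      | unit ×copies | divergence | ChIP weight | notes |
|---------|-----------|--------------|------------|-------------|-------|
| sat187  | tandem     | 187 bp × 200 | 2% per copy | 52.0 | 58.3% AT, exact by construction |
| line1   | line_like  | 2,100 bp × 20 | 40% pairwise | 15.0 | intact 429-nt ORF in the master |
| ltr1    | ltr        | 1,200 bp × 8 | 3% pairwise | 2.5 | 150-bp identical terminal repeats per copy |
| rdna    | rdna_like  | 5,000 bp × 8 | 0.2% blocks | 1.0 | two conserved blocks + 400-bp (AT)n spacers |

Background is uniform 25% per base (AT-richness exists only inside the
satellite, isolating that signal); chromosome 300 kb; reads 2×300 bp,
insert 700 ± 120, substitution error 0.1% (no indels, keeping overlap
detection exact); coverage 1.6× per fraction. Dispersed copies are mutated
from a master at the per-copy rate that yields the requested *pairwise*
divergence; at 40% pairwise divergence LINE copies fall below the 90%
clustering identity, so each insertion seeds its own cluster — which is the
realistic outcome (dispersed families appear as many clusters, each
line-shaped, each inheriting the family's ER). Each LTR copy carries two
identical terminal repeats (young insertions) flanked by unique sequence,
producing clip junctions at both element boundaries.

The rdna-like monomer has real rDNA architecture: two near-identical
conserved blocks (0.2% divergence — concerted evolution keeps units
near-identical) separated by 400-bp low-complexity spacers. The
low-complexity read filter removes spacer-centered reads, which severs the
positional read chain inside every spacer; the conserved blocks then
cluster (across copies) into two daughter clusters that reconnect through
mate pairs spanning the spacers and through the simple-sequence tails at
their contig ends — reproducing the long-monomer-satellite split that the
analysis must recognize and flag.

Three scale choices are load-bearing and deliberate:

* **Coverage 1.6×.** An overlap chain along a locus breaks wherever
  consecutive read starts are > 135 bp apart ((1−0.55)×300). The expected
  number of such gaps per locus is n·e^(−135·n/L); at 1.6× per fraction a
  LINE copy collects ~180 reads and the expectation is ~0.002 per copy, so
  single copies essentially never fragment into mate-linked cluster pairs.
* **≥ 3 kb between planted loci.** At desk-scale background coverage,
  flank reads chain a few hundred bp outward from each locus; loci closer
  than flank reach + insert length would acquire spurious mate links.
  Dispersed elements in a multi-Gb genome are rarely within an insert
  length of each other, so wide spacing is the realistic regime.
* **Coverage-matched libraries** (see the enrichment model above).

What the fixture does **not** emulate: real sunflower sequence content,
genome size or chromosome number; indels and structural variation;
GC/duplication library biases; quality-score error profiles; nested or
truncated element insertions; mixed clusters. Passing tests therefore show
that the statistics and classifiers recover planted truth under a clean
substitution-only model — not that they are robust to assembly-hostile real
data.

## qPCR model and validation statistics

Wells follow `Ct = log_(1+E)(K / amount) + N(0, σ)` with one threshold
constant K for all wells; the default efficiency is 1.0 (perfect doubling)
and σ = 0.15 cycles. RE pairs replicates index-wise (replicate i antibody
over replicate i mock — each independent ChIP reaction yields one matched
pair), so the proportionality constant and any global Ct shift cancel; an
unpaired mean-ratio mode exists. The t-test is the two-sample, two-tailed,
equal-variance Student's t on raw replicate REs against the negative
control (log-scale testing would be statistically tidier for ratios, but
raw REs are the face-value convention here and a log option is a one-line
transform by the caller); zero pooled variance with equal means returns
t = 0, p = 1, with unequal means it is flagged degenerate. ER–RE
concordance is the Pearson product-moment r over targets matched by id,
flagged undefined below 3 pairs or at zero variance. In the pipeline's
validation arm the true antibody/mock ratio of each target is the planted
enrichment factor of its cluster's majority family, so both assays estimate
the same quantity and r is expected near 1 — the fixture validates the
machinery, not the field-observed degree of concordance.

## Numerical and reproducibility notes

All randomness flows through numpy Generators seeded from a single master
seed (per-stage seeds derived arithmetically and recorded in the run
manifest, alongside SHA-256 digests of every output file; a rerun with the
same seed is byte-identical). Cluster ranking breaks size ties by the
lexicographically smallest member read id. Degenerate inputs are either
rejected with a message (empty read sets, invalid thresholds, overflowing
placements) or flagged in the result (undetermined ER, degenerate t,
undefined r) rather than silently propagated.

Problem sizes in the test-suite and reproducibility script (300-kb fixture,
1.6× coverage, 10 fixture seeds for stochastic recoveries, 20 for the null
ER calibration, 30× for the monomer recovery, read subsampling caps of
24,000 pooled / 400 per assembly / 120–200 per topology subgraph) are the
package's default desk-scale conditions: small enough to run in minutes,
large enough that every recovered quantity is estimated within the stated
tolerance bands.

## Known limitations

* The bounded-work clusterer can, in principle, miss borderline edges
  (identity within a few points of the threshold) between otherwise
  unconnected components; the exact graph route exists for audits.
* Greedy exact-overlap assembly fragments across diverged copies (by
  design, it has no error-corrective overlap alignment); consensus quality
  relies on the polish pass, and contigs rarely extend deep into
  low-complexity regions.
* Junction detection reports clip sites on the consensus, not genomic
  breakpoints; with a single flank sequence per cluster (e.g. one copy) the
  two-distinct-tails rule suppresses the call by construction.
* The topology rules assume clusters are single families; mixed clusters
  (e.g. a satellite sharing a cluster with element fragments) are not
  modeled and would land in `other` or mislabel.
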