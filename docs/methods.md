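# Methods

`thawvir` re-implements, as a tested library plus numbered analysis
drivers, the inference chain used in viromics studies of thawing
permafrost peatlands: viral-population (vOTU) dereplication, detection
and quantification by read recruitment, gene-sharing network taxonomy,
CRISPR- and similarity-based host prediction, and community ecology.
Because the original deposited sequencing data are not required, the
package ships a synthetic-community generator with complete ground truth
that emulates the study system; every downstream stage is exercised and
scored against that truth.

## Synthetic communities

The generator realises three thaw-gradient habitats — palsa (intact
permafrost), bog (partial thaw), fen (full thaw) — each holding a pool of
viral populations with configurable pairwise sharing. Defaults, chosen
once to mirror the study system:

| parameter | default | rationale |
|---|---|---|
| habitats | palsa, bog, fen | the thaw gradient |
| vOTUs per habitat | 8 | desk-scale analogue of the 53-vOTU community |
| pairwise sharing | palsa–bog 2, bog–fen 2, palsa–fen 0 | minority of populations shared; none between gradient ends |
| genome length | uniform 12–18 kb | vOTU contigs are ≥10 kb, ~20 kb on average |
| within-habitat abundance | log-normal, σ = 0.5 | moderate rank-separable spread |
| habitat fold gradient | 1 / 3 / 12 | bog viruses 3-fold, fen 12-fold more abundant than palsa |
| viral library fraction | 0.08 × fold | palsa-depleted, fen-enriched virome libraries |
| reads per library | 100k / 60k / 25k × 2 replicates | library size decreases along the gradient, as in the real viromes |
| read length / error | 100 bp, 1% substitutions | short-read point-error model |
| hosts | 6 × 40 kb: 4 CRISPR (5 spacers each), 1 shared-segment, 1 untouched | both host-evidence channels plus a negative control |
| contaminant | 1 contig at 98% identity to a bundled "lab phage" reference | exercises the screening stage |

Genome sequences are i.i.d. uniform nucleotides except planted
protospacers and shared segments, giving maximal contrast for ANI-based
operations: unrelated genomes share essentially no 13-mers, while
within-vOTU variants (2% divergence, 85–100% length) sit far above every
threshold. Each operation draws from its own pseudo-random stream
derived from (master seed, operation name), so changing, say, the host
layout never perturbs the community. A fixed seed reproduces every
output byte-for-byte (checked in the test suite via output checksums).

Reads are drawn with probability proportional to abundance × genome
length with uniform starts, reverse-complemented with probability 0.5.
Each library mixes viral reads (bp share = 0.08 × habitat fold) with
background reads from the host genomes; because read probability is
abundance × length, the per-genome abundance passed to the simulator is
the target bp share divided by genome length.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: indels and quality-score structure, GC and
coverage bias, strain microdiversity within a population, repeat-rich
host genomes, degenerate CRISPR repeats, and assembly artefacts.
Real-data performance of the thresholds is the original study's
evidence, not ours; the synthetic suite shows the *implementation* of
those rules is correct, not that the rules are optimal.

## Dereplication (vOTUs)

Contigs cluster greedily, longest first, into populations at ≥95% ANI
over ≥80% coverage. The coverage denominator is the **shorter** contig
of the pair — permissive toward fragmented members, the common
dereplication convention (configurable). Ties in length break
lexicographically by id, so output is deterministic. The literature does
not fix the clustering scheme; one-pass greedy longest-first is adopted
and documented.

ANI itself comes from a k-mer-anchored aligner: exact 13-mers shared by
the pair are clustered on near-constant diagonals, each cluster window is
aligned with edlib (semi-global on the query window, so end gaps are
free), and ANI is matches / aligned columns over query-disjoint merged
alignments. `N` never counts as a match. Pairs are canonically ordered
(shorter, then lexicographic) before alignment, making the result exactly
symmetric. The test suite pins this engine to a full
dynamic-programming oracle (Biopython `PairwiseAligner`) on ≤2 kb pairs
at 1–12% divergence; unrelated random pairs share no anchors and report
"no qualifying alignment", which is what makes the 80%-coverage rule
meaningful.

## Read recruitment and abundance

A minimal k-mer-seeded mapper (17-mer seeds, diagonal voting, edlib
verification consuming the whole read) exists only so the synthetic path
needs no external aligner; SAM (via pysam, CIGAR + NM) and
BLAST-tabular alignments are accepted as drop-in inputs. Reads are kept
at ≥90% identity over **aligned columns** (matching alignment-tool
identity fields; a read-length denominator is available), best hit per
read, ties to input order. Detection requires reads to cover ≥75% of
the contig (union of intervals, no double counting). Abundance is

    (mapped bp / contig length) / library bp × 10⁹

i.e. per Gbp of library — the constant keeps values O(1–100); undetected
cells are reported as zero. Total-sum scaling divides each sample row by
its sum (all-zero rows warn and stay zero).

The breadth gate matters in the synthetic scenario exactly as intended:
background host reads recruit at ~100% identity into the planted
prophage-like shared segment of one vOTU, but cover only ~20% of it, so
they never create presence artefacts. They do inflate that vOTU's
abundance where it is legitimately detected (~3% of the bog habitat
total at the defaults) — a realistic cellular-contamination signature
visible in the fold-gradient estimates.

Habitat fold factors are estimated from the **length-weighted** detected
abundance sum, which equals the mapped viral bp share of the library.
The unweighted per-Gbp sum weights populations by 1/length, so habitat
comparisons would inherit the genome-length draw of each pool (several
percent noise, occasionally >10%); the weighted sum is exact in
expectation and recovers the configured 1/3/12 gradient to within ~5% at
the defaults.

## Gene-sharing network and viral clusters

Protein similarity edges at ≥50 bits and E ≤ 1e-4 are clustered into
protein clusters (PCs) with MCL; PCs spanning fewer than two genomes are
demoted to singleton proteins and never used for scoring. The protein
graph is clustered **unweighted**: the thresholds decide family
membership, and residual bitscore variation (largely alignment-length
noise) is not evidence of substructure — fed as affinities it fragments
small families.

A genome pair with `a` and `b` PCs sharing `c` of them, in a universe of
`n` PCs, is scored by the hypergeometric upper tail

    P = Σ_{i=c}^{min(a,b)} C(a,i)·C(n−a,b−i) / C(n,b)

computed in log space (scipy `hypergeom.logpmf` + logsumexp): tails
underflow double precision long before the scores they feed stop being
meaningful. The similarity score is `S = −log10(P × T)` with
`T = N(N−1)` ordered genome comparisons — a Bonferroni-style correction
under which the canonical `S ≥ 1` edge threshold means "expected number
of equally-shared pairs under chance < 0.1". The alternative grammatical
reading `(−log10 P) × T` would make that threshold vacuous, so it is not
the default; `N` is an explicit parameter (defaulting to the number of
profiles) so scores are stable when passive genomes are added.

MCL is implemented directly (no maintained Python MCL exists in the
stack): column-stochastic normalisation, expansion by squaring, inflation
by elementwise power, pruning at 1e-5, convergence at max|Δ| < 1e-8,
clusters read from attractor rows, all deterministic. Two numerical
choices matter:

* **Self-loops carry the column-maximum weight (floored at 1), not 1.0.**
  For any clique with loop weight below the edge weight, the diagonal of
  the expanded matrix exceeds the off-diagonals by (p_loop − p_edge)², so
  a high enough inflation shatters even a perfect clique into singletons
  — the upper end of an inflation scan would measure nothing but this
  artefact. Column-max loops (the convention of the reference MCL
  implementation) put loops and edges on equal footing; perfect cliques
  then survive the whole grid.
* **Clustering runs per connected component, and 1–2-node components are
  their own clusters.** MCL on an isolated pair is degenerate: the
  column-stochastic matrix is nearly a permutation whose powers collapse
  to the identity, splitting the pair.

The inflation grid is 1.0–5.0 in steps of 0.2 (21 values). The reported
optimum maximises weighted modularity of the partition on the
thresholded network (ties to the smaller inflation); the source studies
do not state their criterion, so all 21 partitions are retained and any
inflation (e.g. 1.6) can be pinned. Genomes classify as *clustered*
(cluster ≥3, assigned a VC id), *doubleton* (two-node component), or
*singleton* (isolated), mirroring how such networks are reported.

## Host prediction

**CRISPR.** The array finder scans a genome for words of the minimum
repeat length recurring at spacings compatible with repeat+spacer
(repeats 23–47 bp, spacers 26–50 bp, ≥3 identical copies). The repeat
length is the minimum longest-common-extension over *all* consecutive
occurrence pairs — using only the first pair absorbs shared spacer
prefixes (probability 1/4 per base) into the repeat and breaks the run.
Overlapping candidate runs are resolved by most-repeats-then-leftmost,
because a flanking-base coincidence can otherwise shadow the true array.
Exact repeat copies are required: a genome-based finder can afford to
favour precision over the read-based detectors it stands in for
(a mismatch allowance is configurable). Spacers are matched exhaustively
on both strands with zero mismatches by default (a mismatch budget is a
flag); sub-20 bp spacers warn about specificity but are processed.

**Similarity.** Viral-host local alignments (11-mer anchoring so ~70%
identity segments still seed) yield a link only when all four thresholds
pass: ≥50 bits, E ≤ 1e-3, ≥70% ANI, ≥2,500 aligned bp. Bit scores and
E-values use ungapped Karlin–Altschul parameters for the +1/−2
nucleotide scoring (λ = 1.28, K = 0.46), with gaps penalised like
mismatches; all statistics are recorded on each link so the thresholds
stay auditable. A test cross-checks the accept decision against blastn
on a planted segment.

## Ecology

Richness, Shannon H′ (natural log by default; base configurable, Pielou
J = H′/ln richness and defined 0 for richness ≤1) are computed on
total-sum-scaled, detection-masked abundances — the sources do not state
which scale they used, so this is the adopted, configurable convention.
Bray–Curtis goes through scipy; pairs of all-zero samples are defined as
distance 0 with a warning. PCoA is classical scaling (double-centre
−D²/2, eigendecompose); negative eigenvalues — expected for
Bray–Curtis input — are excluded from the coordinates and reported, with
variance fractions computed against Σλ⁺ + Σ|λ⁻| so they sum to ≤1 (no
Cailliez correction; skbio's pcoa serves as a cross-check oracle in the
tests, with which eigenvalues agree to 1e-8). Axis signs follow
first-nonzero-loading-positive. Collector curves accumulate distinct
detected taxa over randomized sample orders (50 randomizations by
default) and report per-randomization and mean curves. Habitat sharing
reduces detection to per-habitat presence sets, pairwise shared counts,
and Euler region sizes that partition the detected taxa. Codon-usage
profiles are 64-component frequency vectors (codons containing N are
skipped) feeding the same Bray–Curtis + PCoA path. The contaminant
screen flags contigs whose best qualifying alignment (≥500 columns, so
incidental word hits cannot flag) to any reference exceeds 95% ANI;
removal is the caller's decision.

## Problem sizes and limits

The default end-to-end scenario — 20 genomes, 52 contigs, six libraries
totalling 370k reads, 6 hosts — runs in under half a minute on one core
and is the size at which the whole chain (including two replicate runs
for the byte-identity check) stays comfortable for routine testing;
counts scale linearly in reads and quadratically in genomes (pairwise
ANI and scoring). The mapper is not a production aligner: no indel-rich
or repeat-heavy references, no paired-end logic. Host prediction assumes
assembled host genomes (no read-level CRISPR detection or binning).
Published headline counts that depend on the deposited reads and a
reference virus catalogue (53 vOTUs; a 1,772-node, 58,201-edge network;
17 host links; 30 AMGs) are context, not desk-scale targets; what is
reproduced exactly is the printed per-virome read accounting and its
derived statistics, plus full ground-truth recovery on the synthetic
scenario.
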