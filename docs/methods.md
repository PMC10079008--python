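# Methods

This note documents the models and procedures behind each pipeline stage, the
parameters that matter, the design choices made where the design was genuinely
open, and what the synthetic benchmarks do and do not demonstrate.

## The problem

A gene can be present in a genome yet absent from its assembly and annotation
when its coding sequence is GC-extreme: long uninterrupted G/C runs stall
polymerases and break assembly graphs. The avian LAT gene — a T-cell receptor
signaling adaptor conserved across vertebrates — is the motivating example:
the protein is conserved while the coding sequence exceeds 70% GC. Recovery
therefore has to work from raw reads, not from the assembly, and verification
has to rest on protein-level evidence: conserved signaling motifs, phylogenetic
placement, and a lymphoid-biased expression profile.

## Synthetic data generator

The generator produces every input the pipeline consumes, with known truth.

**Protein scaffold** (`make_lat_like_protein`). A random protein with the
adaptor motif panel planted at fixed 1-based positions: start methionine; a
C-x-x-C palmitoylation pair (first cysteine at 26); a PLCγ-recruiting
tyrosine in Y-L-V-V context at 132 with a configurable residue at 131
(G, the tetrapod state, or D/E, the state seen in some fish where the site
becomes an optimal kinase substrate); further docking tyrosines in Y-x-N
(Grb2-type) context at 171/191/226; a proline-enriched region spanning
residues 30–100 (proline probability 0.4); optionally the exact LCK-binding
hexapeptide PIPRSP at position 50. Unplanted sites avoid C and Y so the
planted motifs are unique with high probability. Half of the unplanted sites
draw from {A, G, P, R} — the amino acids with an all-G/C codon — because
GC-extreme adaptor genes are alanine/glycine/proline-rich and because a
uniform composition caps the achievable CDS GC near 0.67, below the regime of
interest (`gc_friendly_fill`, settable to 0 for a uniform fill).

**GC-biased reverse translation** (`reverse_translate_gc_biased`). Codon
choice per site samples synonymous codons with weights exp(β·GC(codon)); β is
tuned by bisection so the expected GC matches the target, then single
synonymous swaps nudge the realized GC to within 0.02 of the target (or of
the closest achievable bound; targets unreachable by more than 0.05 are an
error reporting the achievable range). Because only synonymous codons are
used, the protein — and hence the motif panel — is exactly preserved,
mirroring the real situation where the protein is conserved while the CDS is
GC-extreme.

**Ortholog families** (`evolve_orthologs`). Along each branch of a Newick
tree (branch length b = expected substitutions per site) every non-invariant
site substitutes with probability 1 − exp(−b), uniformly over the 19 other
residues. Motif sites are passed as invariant. A uniform replacement model
(not LG or another empirical matrix) is deliberate: the tree stage is
distance-based and only topology recovery is asserted, so an empirical model
would add machinery without changing what is testable — and keeping the
generator's model different from any inference model keeps the two
independent.

**Reads** (`simulate_reads`). Single-end, uniform coverage: template chosen
proportionally to weight × length, uniform start, uniform strand, each base
substituted with probability `error_rate` (default 0.01, the Illumina-like
regime where errors are substitution-dominated). Qualities are constant Q30.
An indel mode exists (per-base deletion/insertion at `indel_rate/2` each) but
is off by default; it exists to stress the assembler. True origin is encoded
in the read id for truth tracking. Because starts are uniform over the
template, template *ends* receive vanishing coverage; coding sequences are
therefore embedded in 100-nt UTR-like flanks (`embed_in_transcript`) so the
CDS itself is covered at full depth — as it would be inside a real transcript.

**Tissue panels** (`make_tissue_panel`). Per tissue, each truth-listed gene
contributes Poisson(RPKM × gene-kb × library-millions) reads; the rest of the
library comes from background genes with weight proportional to length. The
default panel is six chicken-like tissues at 10⁵ reads each: spleen/thymus/
bursa (immune; true RPKM 300/250/200) and liver/brain/muscle (non-immune;
30/10/5) — a lymphoid-biased profile with realistic library sizes for a
desk-scale benchmark.

What the generator does **not** emulate: empirical codon-usage tables,
machine-specific error and quality profiles, paired ends, intron-containing
genomic reads, coverage biases (including the GC-coverage dips that motivate
the whole exercise). Passing benchmarks therefore demonstrates correctness of
the procedure under its stated model, not performance on any particular
sequencing chemistry.

## G/C-stretch statistics

A stretch is a maximal run of ≥ `min_len` (default 3) consecutive G/C
nucleotides; runs shorter than the cutoff are excluded both from being called
stretches and from the mean-stretch-length average. N terminates a run and is
excluded from the GC fraction numerator and denominator — a conservative
choice that can never inflate either statistic (assembled CDSs should be
N-free, so this only affects robustness). Background profiling keeps CDSs of
≥ 300 nt and histograms per-gene mean stretch length at bin width 0.1; the
reported per-gene table and the query percentile rank are binning-independent.

## Recruitment

Seeding: exact 11-mer lookup against the bait and its reverse complement.
Extension: banded local Smith–Waterman around each seed diagonal, band
half-width 15, match +1, mismatch −2, affine gaps (a gap of length L costs
open + L·extend with open −5, extend −2). The band half-width is safe because
recruitment operates at ≤ ~5% divergence where the optimum alignment stays
near the seed diagonal; a test checks equality against an unbanded oracle at
2% divergence. Raw scores convert to bit scores via
bits = (λS − ln K)/ln 2 with ungapped Karlin–Altschul constants λ = 1.28,
K = 0.46; reads are kept at ≥ 100 bits. The 100-bit threshold together with
this scheme puts the effective recruitment floor at a 54-nt exact match. The
scheme is a self-contained, documented stand-in for a BLASTN-style search: it
reproduces the *procedure* (bit-score-thresholded recruitment) without
claiming score-identical output to any particular BLAST build, and every
constant is configurable.

## Assembly and iterative rescue

Greedy overlap–layout–consensus: repeatedly merge the contig/read pair with
the longest suffix–prefix overlap ≥ 30 nt whose mismatch rate is ≤ 2%,
considering both orientations; ties prefer the longer resulting contig, then
lexicographic contig ids (a contig is named by its smallest read id).
Consensus per column is a weighted majority (weights = base qualities when
present, else 1), ties broken by the fixed base order A < C < G < T. Depth is
the number of reads covering each column. Candidate overlaps are generated
from shared exact 12-mers, so an overlap is considered whenever it contains
one clean 12-mer — essentially always at ≤ 2% substitution divergence; this
makes the merge loop near-linear in practice instead of quadratic in overlap
length. A greedy single-gene assembler is adequate at targeted-rescue scale
and, unlike the commercial assemblers typically used interactively for this
task, is fully specified including tie-breaking, hence reproducible.

`iterative_rescue` alternates recruit → assemble, promotes the longest contig
to next-round bait (oriented to the strand that scores higher against the
original bait, which keeps rounds and reports stable), and stops when the
recruited read set is unchanged or after `max_rounds` (default 5). Zero
recruits in round 1 is an error (bait too diverged or threshold too strict).
ORF extraction scans ATG…stop in all six frames (≥ 50 codons by default) and
flags the longest as the candidate CDS. Spliced alignment is out of scope:
the pipeline targets contiguous (transcript) templates; genomic,
intron-containing read sets are future work.

## Ortholog verification

Pairwise alignment is global Needleman–Wunsch/Gotoh with BLOSUM62 and affine
gaps (open −10, extend −1; a gap of length L costs open + L·extend);
traceback ties prefer diagonal, then up, then left, making output
deterministic. The progressive MSA builds an NJ guide tree from pairwise
(1 − identity) distances and merges profiles bottom-up by profile–profile
alignment with column-average scoring (residue-vs-gap scored at the extend
penalty). One progressive alignment over all inputs replaces the common
practice of aligning clades separately and merging: the merge step exists
only as an interactive workflow artifact. Reference-position mapping
transfers 1-based positions in a designated reference row through alignment
columns, which is how human-numbered motif positions (G131, Y132, …) are
checked in every other sequence.

The tree stage is Saitou–Nei neighbor joining on p- or Poisson-corrected
distances (d = −ln(1 − p)) with deterministic lexicographic tie-breaking on
the Q-criterion and negative branch lengths clamped to zero (logged).
Bootstrap supports resample alignment columns with replacement and report the
percentage of replicates containing each internal bipartition. Distance-based
NJ deliberately replaces maximum-likelihood inference: the tree's role here
is orthology verification — does the rescued gene cluster with its clade —
which is a topology-level question that NJ with bootstrap answers at a tiny
fraction of the implementation and compute budget; ML/Bayesian inference and
divergence-time estimation are out of scope.

## Expression

RPKM = count / ((gene length/1000) × (library size/10⁶)). The denominator is
the **total** read count of the dataset, not "mapped" reads: recruitment
operates on whole read sets where no genome-wide mapping is ever performed,
so total reads is the only computable normalization, and outputs say so.
Enrichment is an artifact-defined score, since the underlying observation is
qualitative: the immune/non-immune median-RPKM ratio (reported as undefined
when a median is zero) plus a flag that is true exactly when every immune
tissue's RPKM exceeds the non-immune median. The tissue→immune map is user
configuration; no taxonomy is assumed.

## Benchmark problem sizes

The shipped benchmarks run at desk scale, chosen so the full suite and the
acceptance script each finish in a few minutes on one CPU: a 600-nt planted
CDS at 40× coverage for rescue; 1,000 reads each for recruitment sensitivity
and false-positive measurement; 50 additive matrices (5–8 taxa) and 100
simulated 6-taxon families (400 sites) for topology recovery, with 100
bootstrap replicates; 100 scaffolds for the motif panel; six tissues at 10⁵
reads for expression. At the default expression levels the low-expression
tissues receive single-digit read counts, so per-tissue RPKM estimates are
dominated by Poisson discreteness there; the benchmark checks recovery within
3 standard errors rather than a relative tolerance for that reason.

## Known limitations

- Recruitment sensitivity degrades for baits shorter than ~54 nt of
  conserved exact match and for divergence beyond the seed word size's reach.
- The assembler assumes substitution-only disagreement between reads;
  overlaps requiring gaps are not merged (the indel read-error mode will
  fragment assemblies, which is its purpose as a stress mode).
- The progressive MSA has no iterative refinement; deep families with heavy
  indel content will align worse than dedicated aligners.
- p/Poisson distances ignore rate heterogeneity across sites; for strongly
  saturated families the NJ topology will be less reliable than model-based
  inference.
- Multi-gene expression quantification and differential-expression testing
  are out of scope; one bait gene is quantified per run.
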