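# Methods

## The recruitment model

The pipeline's central object is the read-overlap graph: nodes are
reads, and an edge joins two reads whose best semi-global alignment
(terminal gaps free on both sequences, scored +1 match / −1 mismatch /
−2 gap) spans ≥ `min_overlap` aligned columns at ≥ `min_identity`
matches per column, on either strand. Terminal overhangs are excluded
from both counts — this is the only identity definition under which two
staggered reads that genuinely overlap by half their length can score
95%, which is what lets recruitment walk outward along a locus. `N`
never counts as a match.

Expansion is breadth-first search on this graph, organised so no pair
is aligned twice: the seed set is cycle 0; each cycle aligns the
current frontier only against still-unrecruited reads, and recruited
reads leave the searchable pool. After `cycles` rounds the recruited
set is exactly the radius-`cycles` BFS ball around the seeds — the test
suite and the acceptance script verify exact set equality against a
brute-force all-pairs oracle on randomized pools.

Defaults: `cycles = 5`, `min_identity = 0.95`, `min_overlap = 50 nt`.
The identity and cycle count are the tool's conventional operating
point; the 50 nt overlap floor is ours — without a floor, a chance
16 nt exact match would join unrelated reads. Mates of recruited reads
are added to the assembly input (`--mate-rescue`, default on): a mate
is physical evidence its fragment came from the locus even when the
mate itself never aligned.

**Candidate prefilter.** Before any alignment, candidate partners are
restricted to reads sharing a canonical 15-mer with a frontier read.
k = 15 is provably lossless at the default gates: an alignment with
C ≥ 50 columns at ≥ 95% identity has at most m = ⌊C/20⌋ non-match
events, so by pigeonhole its longest exact stretch is at least
⌈(C − m)/(m + 1)⌉ residues; minimising over feasible (C, m) gives 15.
(k = 16 would not be safe: C = 60 with 3 mismatches can split the 57
matches into stretches of at most 15.)

## Profile scoring

Profiles are read from HMMER3 ASCII files; stored negative-log
probabilities become bit log-odds against the standard amino-acid
background. Reads are translated by a six-frame scan that keeps the
frame with the longest stop-free stretch (ties break +1, +2, +3, −1,
−2, −3); a full gene-model HMM is out of proportion for 90–250 nt
reads, and for recruitment only a reasonable frame choice is needed.

Scoring is uni-local Viterbi in bits: one alignment of any peptide
substring to any stretch of match states. Entry into match state `k`
costs the Plan7 uniform local-entry score `log2(2 / (M(M+1)))`; exit
after any match is free. The entry term is not optional: with free
entry, every (position, state) cell is an alignment start, and a
handful of chance consensus matches in a random 50-aa peptide crosses
any workable threshold — measured on the reference metagenome, roughly
a quarter of pure background reads would seed, and recruitment then
floods the entire dataset. With the entry term, a 20-codon fragment of
a true gene scores tens of bits above the threshold while random reads
sit far below it. Non-canonical residues emit at background (0 bits).
The acceptance threshold is the model's GA gathering cutoff when the
file provides one, else 15 bits (`--hmm-bits`). The kernel is verified
against exhaustive path enumeration on small random models.

The bundled profile set is synthetic: eight Cas-family stand-ins
(cas1, cas3_cas2, csy1–3, cas6, cse1, cse2) generated deterministically
from a fixed internal seed, with consensus emission probability 0.9 and
shared node transitions (M→M 0.97). They are shaped like real profiles
but carry no real sequence information; production runs should pass a
real collection via `-hmm`. They are generated at import time rather
than shipped as a file only to keep the repository small; `casbait.resources.write_demo_hmm` materialises them as a valid
HMMER3 file.

## Targeted assembly

A canonical de Bruijn graph at a single fixed k, built from the
recruited subset. k-mers seen fewer than `min_count = 2` times are
dropped (`--meta` keeps singletons, for low-abundance community
members). Simplification alternates until stable:

- **tip clipping** — a dead-end unitig shorter than 2k is removed only
  when its junction offers a better continuation (a non-dead-end
  branch, or a longer / better-covered competing dead end). Clipping
  *every* short dead end would eat the assembly inward from any
  coverage boundary that carries a sequencing error near it.
- **bubble popping** — parallel unitigs sharing both flanking junction
  k-mers and differing by ≤ 3 edits collapse to the higher-coverage
  branch (3 edits absorbs the duplicated-error bubbles a 1% error rate
  produces at 2k scale).
- **relative coverage cleanup** — after tips and bubbles converge,
  unitigs below 25% of the graph's length-weighted mean coverage are
  removed and simplification reruns once. This clears interleaved
  error paths (two reads sharing a substitution) that pairwise bubble
  popping cannot pattern-match.

Contigs are maximal unambiguous paths, reported on the
lexicographically smaller strand, longest first; output is independent
of read order. Default k = 41: k must comfortably exceed natural
direct-repeat lengths, because two repeat copies whose (k−1)-mer
contexts coincide collapse into one node and break the contig
mid-array. At k = 31 a natural 28 nt repeat leaves only two
discriminating bases per side (collision odds ~1/16 per copy pair);
k = 41 leaves twelve (~5·10⁻⁶) while 100 nt+ reads still cover every
position with dozens of k-mers. No scaffolding and no repeat
resolution: the pipeline's gains come from read subsetting, not
assembler novelty.

## Annotation

ORFs are maximal ATG/GTG/TTG-to-stop spans of ≥ 60 codons on both
strands; each ORF is scored against every profile and called for the
best model at or above threshold (no overlap resolution — overlapping
calls are both reported).

The array detector is seed-and-verify: an exact 8-mer recurring at a
period of 48–115 nt anchors a candidate; anchors are slid across the
triggering window and chains extended in both directions, keeping the
longest chain, so the column vote sees every unit. Repeat boundaries
grow outward while ≥ 80% of units agree per column, capped so spacers
keep their 25 nt minimum; accepted arrays need ≥ 3 repeats, repeat
length 23–55 nt and spacer lengths 25–60 nt. The consensus is the
per-column majority. An array whose spacers are all pairwise identical
is flagged `suspicious_duplicate` — real spacers record distinct
acquisition events, and perfect copies of one repeat–spacer unit are
the signature of a collapsed assembly artifact.

Genes on one contig within 500 nt of a neighbour form an operon, typed
by transparent signature subsets of the called family names: csy1+2+3 →
I-F; cse1+cse2 → I-E; two of {cas8c, cas5c, cas7c} → I-C; two of
{csf1..csf4} → U; else unclassified (precedence in that order). This is
a deliberately minimal mapping — the full 20+-subtype taxonomy is out
of scope. An array is *isolated* iff its contig carries no cas call:
targeted contigs are short, so contig co-occurrence is the decidable
criterion, rather than a base-pair distance.

GFF3 output uses 1-based inclusive coordinates; contigs under 500 bp
are skipped entirely (`--min-contig 0` disables the cutoff).

## Synthetic data and what it shows

`simdata.make_genome` plants reverse-translated consensus peptides of
the bundled profiles as genes (20–200 nt intergenic gaps) and a
repeat–spacer array downstream (or on a second replicon in
isolated-array mode) inside an i.i.d. uniform background;
`make_reads` samples fragments uniformly (insert ~N(300, 30)),
applies substitution-only errors (Q38 for correct bases, Q∈[2,20] for
substituted ones) and encodes each read's true origin interval in its
id, so recruitment completeness is evaluated exactly from coordinates
with no mapping step. The default study conditions are three 20 kb
genomes at ~30× combined depth with 1% errors; the planted array is
4 × 28 nt repeats with 32 nt spacers — the type I-F norms.

Two generator details matter for exactness. Spacers are resampled
until they are pairwise distinct with non-unanimous first and last
bases: if every unit boundary column agreed, the repeat/spacer
decomposition of the planted array would be mathematically
ambiguous — a column that is identical across all units belongs
equally well to the repeat — and no detector could recover the
recorded truth. And the substitution-only error model is intentional:
indels would conflate assembler behaviour (bubbles, tips) with
recruitment behaviour in tests.

What passing does **not** show about real data: no quality ladders, GC
bias, coverage waviness, optical duplicates or chimeras; uniform
community abundances; synthetic profiles much sharper than real Cas
family HMMs; a single locus per genome. The end-to-end results
demonstrate the machinery is correct under its stated model, not that
the default thresholds are optimal for any particular instrument or
biome.

## Numerical and design notes

- Quality trimming keeps the maximal-sum window of (Q − cutoff)
  (Mott's algorithm; cutoff Q10, minimum surviving length 50 nt).
  Adapter removal requires an exact 12-mer seed of the adapter prefix
  and extends allowing ≤ 1 mismatch per 8 aligned bases; contaminant
  removal is canonical 21-mer membership against the reference, not
  alignment. Unmerged mates are both retained — retaining maximises
  recruitable evidence.
- Pair merging scans ungapped 3′ overlaps ≥ 20 nt at ≤ 5% mismatches;
  agreeing bases take the max quality, disagreements take the
  higher-quality base with quality |Q1 − Q2|; score ties prefer the
  longer overlap.
- Alignment and Viterbi kernels are numba-compiled; all tie-breaks are
  fixed (forward strand first, then smaller coordinates; alphabetical
  model names), so every stage is deterministic given its input, and
  identical run manifests reproduce byte-identical outputs.
- DNA-mode matching is an ungapped containment scan: the repeat must
  lie within the read (terminal read overhangs free) with ≥ 90% of the
  reference aligned; identity is counted over aligned reference
  columns. Repeats are much shorter than reads, so containment, not
  whole-read identity, is the meaningful criterion.
- The CLI accepts `-cpu`/`-mem` for interface parity; execution is
  single-process (the desk-scale kernels don't need a memory cap), and
  `-mem` is only logged.
- Problem sizes in the test suite and acceptance script (3 × 20 kb
  genomes, 12 000 reads, pools of ≤ 80 reads for the BFS oracle,
  2–5 kb genomes for reconstruction) are chosen so the full validation
  runs on a laptop in a couple of minutes while every claim is still
  checked exactly.

## Known limitations

- Single fixed k: loci containing exact repeats longer than k − 2
  (e.g. unusually long direct repeats, or two near-identical cas
  paralogs) will fragment; there is no multi-k ladder or read
  threading.
- The symmetric overlap rule may over-recruit relative to asymmetric
  query-vs-database coverage rules; on large datasets this costs time,
  not correctness.
- Operon typing covers only the four signatures above.
- The array detector assumes a fixed period within an array; arrays
  with large spacer-length variance (> the seed window tolerance) can
  be missed or truncated.
- No E-values: seed decisions are bit-score thresholds, so the
  false-positive rate depends on the profile set's sharpness.
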