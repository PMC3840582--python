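# Methods

This note documents the models, the numeric choices behind them, what the
synthetic data does and does not emulate, and the design decisions taken
where the workflow left room.

## Read cleaning

A read survives iff it has no N base, at most 4 bases below Q10, at most
6 below Q13 (both evaluated on the untrimmed read), a detectable 3′
adapter, a trimmed insert of ≥ 18 nt, and the insert is neither a
5′-adapter contaminant nor poly-A. Rules fire in that fixed order and
each rejected read increments exactly one counter, so the QC report is an
exact partition of the input. Choices the rule names leave open:

* **3′ adapter detection** — longest prefix of the adapter aligned at the
  insert 3′ end, ≥ 6 nt overlap, ≤ 1 mismatch; no detectable adapter is
  its own rejection class. Adapter-dimer reads (insert length 0) fall
  under the short-insert counter.
* **5′ contamination** — first 8 nt of the insert match the 5′ adapter
  with ≤ 1 mismatch.
* **Poly-A** — ≥ 80 % A overall or a terminal run of ≥ 8 A.
* Quality thresholds are strict inequalities (Q < 10, Q < 13), read
  literally from their phrasing.

Only Phred+33 FASTQ is accepted; other encodings are rejected rather
than auto-detected.

## Tags and normalization

Unique tags identify T with U, because mature miRNA references circulate
in the RNA alphabet while genomic/EST references are DNA. Normalization
is library scaling to reads per million of clean reads; the scaling base
is configurable (`norm_scale`) since the classic description names the
method but not the constant. `mean_norm` averages over *all* configured
libraries, zeros included, matching the "mean over the three libraries"
convention of replicate designs.

## Homology matching

BlastN with small edit allowances over 18–26-nt queries is replaced by
exhaustive edit-bounded infix alignment (edlib, Myers bit-vector). At
these query lengths the bounded alignment is strictly more sensitive than
a heuristic seeded search and fully deterministic, so E-values are not
modeled — the edit budget is the rule. Interpretation choices:

* The seed window (positions 2–8, 1-based) is measured on the **tag's**
  5′ end. A gap column is charged to the following tag position.
* "Sequence coverage differing by ≤ 2 nt" is read as the absolute
  tag-vs-reference length difference.
* "Less than three mismatches or gaps" (relative ncRNA tier) is ≤ 2
  edits.
* Ties among equal-edit references break by fewest seed-adjacent edits,
  then lexicographically smallest reference id, for determinism.
* Star references name their matches miRNA\* (a `*` suffix); star tags
  are excluded from the family-abundance sum, since the 15-RPM filter
  describes mature expression.

## Novel hairpin evaluation

Excision windows of (−250, +50) and (−50, +250) nt around a mapped tag
follow common plant precursor-excision practice; both are configurable.
The duplex statistics come from the MFE fold's pair table: `duplex_pairs`
is the number of paired bases inside the mature span; bulges are runs of
unpaired bases interior to the mature or star side of the duplex;
asymmetry is the difference of total unpaired counts between the two
sides; the star span is the mature's pairing partner extended to the
canonical 2-nt 3′ overhang. A mature whose pairing partners interleave
with itself sits in the terminal loop and is rejected before evaluation.

The classic two-pass energy check (initial fold and an independent
re-check with a second folding engine, both at −18 kcal/mol) collapses
into one check here because a
single folding engine (ViennaRNA, default Turner parameters) does both
jobs; the parameter set is fixed, so folds are deterministic. The
machine-learned precursor classifiers sometimes layered on top are
external trained artifacts; they are replaced by the explicit structural
rule set above plus the dominance filter, which is the printed substance
of those criteria. Dominance uses a 50 % cutoff and ≤ 2 nt 5′
heterogeneity — the community annotation criteria are qualitative, so the
values are exposed in config. Overlapping accepted precursors collapse to
the highest-dominance one regardless of strand, because a perfect
inverted repeat is one physical locus seen from both strands.

Mapping is exact ("contig mode", 0 mismatches) in the pipeline, with a
1-mismatch "genome mode" available; both use exhaustive 8-nt
seed-and-extend (pigeonhole-complete for ≤ 1 mismatch) and are verified
against a brute-force all-offsets scan in the tests.

## Phasing statistic

The phasing p-value is the hypergeometric upper tail
P(X ≥ k | N = 21·cycles, K = cycles, n occupied) with an 11-cycle
(231-nt) window sliding in 21-nt steps and the best of the 21 registers
kept per window. The same kernel (scipy's log-space survival function)
backs the GO term-for-term test, so one enumeration oracle validates
both. Scanning is single-strand by default; the workflow description
does not state strand handling, and the planted loci are sense-strand.
One wording convention is worth surfacing: phased-locus predictors are
sometimes described as discarding loci "below" the threshold, which read
literally would discard the phased ones; here the convention is explicit —
loci at p ≤ 10⁻³ are retained — and the CLI prints it on every run.

## Target scoring

Only +5 (canonical) and +2 (G:U) are fixed by the scheme. Mismatch −3, gap open
−9, gap extend −4 and the ×4 seed scaling follow the reference
implementation's documented defaults; the scaling is also forced by
internal consistency — without it a perfect 21-mer tops out at 105,
below the 130 acceptance threshold. G:U counts as non-canonical for the
seed rule (disallowed at positions 2–8) while still scoring +2 outside;
a flag restores the permissive reading. The site scan evaluates an
ungapped antiparallel alignment at every offset (vectorized) and refines
anchors above half the score threshold with a banded DP (±3), which
admits the short bulges the gap penalties leave affordable; overlapping
sites keep the best scorer. Per miRNA the top 10 hits are reported, or
20 when more than 50 raw hits exist. Duplex energies come from the
ViennaRNA nearest-neighbor duplex fold.

## GO enrichment

Term-for-term: per term with ≥ 1 study gene, the hypergeometric upper
tail of the study count against the annotation universe, Bonferroni-
multiplied by the number of terms actually tested (terms with no study
gene neither get a p-value nor inflate the factor, the behavior of the
standard implementations). Annotations propagate up the is-a DAG first;
propagation is idempotent and cycle-checked. The population is the full
gene universe of the provided annotation map by default and is an
explicit input, since enrichment backgrounds are a study-design choice.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structure* of a three-replicate leaf
small-RNA experiment: adapter-flanked 18–30-nt inserts with Phred
qualities; conserved families split into native and other-plant
reference tiers with 1–3 members differing by 1–2 non-seed
substitutions; novel hairpins as perfect 21-bp stems with 12-nt loops
planted mid-contig (each verified in genomic context at construction —
excised, folded and evaluated — and redrawn otherwise, so planted loci
are genuine hairpins); TAS loci as 8 consecutive in-register 21-mers;
ncRNA/repeat fragments; mRNA degradation fragments; and perfect
complementary target sites in a subset of transcripts whose genes share
a GO term.

Abundance is log-normal over species (σ = 1.5), giving the heavy skew of
real libraries (a few dominant species, long tail). Planted miRNA and
TAS species carry a small guaranteed per-library floor (5 reads),
emitted verbatim — the pipeline discovers *expressed* molecules, so
simulated expression is never zero and the floor copies are what
"expressed" means here; substitution errors (0.001/base) apply to the
multinomially sampled remainder. Five percent of reads are labeled
QC-negative classes (N, low-Q10, low-Q13, short insert, 5′ adapter,
poly-A, missing 3′ adapter) constructed to violate exactly one rule.

Not emulated: instrument-specific error and quality profiles, genome-
scale sequence composition, isomiR end-heterogeneity beyond the error
process, antisense/dual-strand TAS signal, and degradome evidence.
Passing recovery tests therefore demonstrates that the pipeline's rules
and statistics behave as specified under realistic abundance skew and
noise — not that the thresholds themselves are optimal for any
particular real library.

## Problem sizes and numerics

The study-scale experiment used in the recovery tests and the acceptance
script is 3 libraries × 50 000 reads with 20 conserved families, 10
hairpins, 3 TAS loci, 12 contaminant references and 30 transcripts —
large enough that every stage sees hundreds of distinct tags and the
log-normal tail is populated, and it completes in well under a minute.
The null false-positive rate of the phasing scan is estimated from 1 000
simulated 231-nt windows with 8 uniformly placed occupied positions.
Hypergeometric tails are computed in log space (no normal
approximation); fold and duplex energies are deterministic for a fixed
parameter set; all simulation randomness flows from one integer seed
through a single PCG64 stream, and re-running a pipeline config
byte-identically reproduces every TSV output.

## Known limitations

* The annotation cascade assigns one category per tag; multi-locus tags
  (e.g. a miRNA inside a repeat) resolve by cascade priority alone.
* Star-span inference assumes the canonical 2-nt overhang; stems shorter
  than the 16-pair rule are never rescued by end effects.
* `match_known_tas` is an edit-bounded surrogate for a BlastN search at
  E ≤ 10⁻³ on 21-mers; for longer reference tasiRNAs the equivalence
  loosens.
* The miRNA-trigger relationship of TAS loci (22-nt trigger model) is
  not modeled; loci are reported with their phasing evidence only.
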