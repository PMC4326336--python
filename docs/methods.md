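# Methods

## Search contract

The engine answers the exhaustive off-target question for equal-length
matches: given a 20-nt guide *Q*, a PAM pattern, a mismatch budget
*M* ∈ 0..5 and a seed mask *S* ⊆ {0..19}, report **every** site on either
strand of the genome whose 20-mer *q* has Hamming(*q*, *Q*) ≤ *M*, agrees
with *Q* at all positions in *S*, and is immediately followed — 3′ on the
protospacer's own strand — by a window matching the PAM. Matching is purely
Hamming: bulges/indels and off-target activity scoring (CFD/MIT-style) are
out of scope by design; the output is the raw candidate set that such
post-processing would consume.

Position 0 of the guide is its 5′-most base. Seed masks may also be given as
`3prime:k`, the wet-lab convention of counting PAM-proximal bases:
positions {20−k .. 19}. Seed positions must be identical between guide and
site; since an identical position contributes zero mismatches, "seed
consumes budget" and "seed outside budget" coincide — the engine simply
never substitutes there.

## Coordinates and strand geometry

All positions are 0-based and always refer to the forward-strand leftmost
base of the 20-mer, regardless of strand; the strand flag disambiguates. A
reverse-strand protospacer occupying forward window [i, i+20) is read as the
reverse complement of that window, and its PAM occupies forward coordinates
[i−L, i), read reverse-complemented (3′ on the reverse strand is the lower
forward coordinate). The CLI's `--one-based` flag shifts reported positions
for genome-browser pasting; internal storage stays 0-based.

## Index layout

16+4 split: a 20-mer's first 16 bases form the Table A key
(base-4 positional code, A=0 C=1 G=2 T=3, leftmost most significant; range
0..4^16−1), and its last 4 bases are stored per record. One 64-bit word per
(site, PAM pattern) pair:

| bits  | field |
|-------|-------------------------------|
| 0–27  | position (≤ 268 Mb chromosomes) |
| 28    | strand (0 fwd / 1 rev) |
| 29–33 | chromosome ordinal (≤ 32 sequences) |
| 34–36 | PAM id (≤ 8 patterns per index) |
| 37–44 | captured bases at the PAM's unspecified positions, 2 bits each, pattern order, low bits first |
| 45–52 | 4-nt tail code |

The capacity limits fail loudly (`CapacityError`) rather than silently
widening a field: a serialized index must mean the same thing everywhere.
Within a prefix group, records sort by (chromosome, position, strand,
PAM id), making builds bit-deterministic. A site matching several indexed
patterns yields one record per pattern; queries filter on the requested
pattern's id.

Table A's canonical realization is dense — one offset per possible 16-mer,
4^16+1 cells, tens of GB, appropriate for an all-in-RAM server. The default
here is a sparse ordered map over occupied prefixes with identical lookup
semantics (`dense=True` / `--dense-table-a` materializes the dense array).
Construction is two-pass — count per prefix, then fill — so that
consecutive Table A pointer differences equal group sizes exactly; this
identity is asserted against an independent string-scan counter in the
tests.

PAM patterns support N (any base) and R (purine) — all motifs shipped
(NGG, NAG, NNNNACA, NNGRRT) need nothing else — and other IUPAC symbols are
rejected rather than silently accepted. R captures are stored in 2 bits
like N for a uniform record layout. Built-in patterns hold fixed ids 0–3;
user patterns take ids 4–7. Windows containing N never match a PAM and
never enter the index: an undetermined reference base cannot be asserted to
satisfy a motif, and exhaustiveness is defined over determined sequence.
Soft-masked (lowercase) genome regions are uppercased and indexed; IUPAC
ambiguity codes and gaps in the FASTA fold to N at ingestion.

## Query strategies

`find_offtargets` enumerates candidate 16-mer prefixes two ways, chosen by
whichever is smaller:

* **enumerate** — walk the Hamming ball of the guide's prefix (skipping
  seed positions), Σ<sub>i≤M</sub> C(f,i)·3<sup>i</sup> candidates for f
  free prefix positions;
* **scan** — vectorized Hamming test of the index's occupied prefixes
  (cheaper whenever the genome occupies fewer prefixes than the ball holds,
  which is every genome up to hundreds of Mb at M = 5).

Tail mismatches are resolved through a precomputed 256-entry table
(mismatch count, positions, seed compatibility per possible tail). Both
strategies provably return the same set — enumeration covers every prefix
within budget, scanning tests every occupied prefix against the same
predicate — and both are checked against the brute-force oracle. Hits sort
by (chromosome ordinal, position, strand). The guide's own intended site
satisfies the contract and is reported; `drop_self_hit` removes it when
unwanted.

## Oracle and fixtures

The oracle is a deliberately naive sliding-window scan of both strands
sharing only the nucleotide codecs and PAM matcher with the indexed path,
so agreement is evidence rather than tautology. Test genomes are capped at
50 kb to keep it honest and fast.

The synthetic generator draws i.i.d. bases with a configurable GC bias —
the only genome property the engine's correctness depends on — and plants
protospacer+PAM windows with exact, non-overlapping mismatch sets. It does
**not** model repeat structure, segmental duplications or compositional
heterogeneity of real genomes; passing tests therefore demonstrate
correctness of the search contract, not performance characteristics on
repeat-rich genomes (where group sizes grow but semantics are unchanged).
Random background can contain chance look-alikes, so planted ground truth
is a subset of the full hit set; `make_exact_fixture` retries background
seeds until the oracle confirms the planted set is the whole truth, giving
exact-set fixtures for recovery tests.

## Numerical and size choices

* Randomized equivalence testing uses 200 trials over genomes of 1–50 kb
  (40 genomes × 5 queries: random and genome-sampled guides, all four
  built-in PAMs, budgets 0–5, empty/3′/random seed masks), completing in
  well under a minute on one core; the trial mix weights small genomes
  where per-trial cost is low and disagreement would be just as visible.
* All comparisons are exact set equality on (chromosome, strand, position,
  sequence, mismatch set, dereferenced PAM) — no tolerances anywhere; the
  algorithm is discrete.
* Hypothesis property tests run derandomized (fixed example corpus) so CI
  results are reproducible.
* Index serialization is little-endian with a magic string and version
  byte; truncation, foreign files and version mismatches all fail loudly
  before any array is interpreted.

## Annotation

GTF (1-based inclusive, converted on read) and BED (0-based half-open)
files load into per-chromosome interval trees. A hit is tagged with every
feature overlapping its 20-mer window by ≥ 1 bp, ignoring feature strand —
an off-target lesion disrupts a feature regardless of which strand the
feature is annotated on. Region classes exposed: 5UTR, CDS, 3UTR, exon,
lincRNA (via transcript biotype), other; spliced/unspliced transcript
distinctions are not derived — raw feature classes are reported and left
to the caller. Unknown chromosomes annotate as intergenic rather than
erroring, since annotation files legitimately cover genome subsets.

## Known limitations

* Guide length is fixed at 20 nt (16+4 split is baked into the record
  layout); other protospacer lengths would need a different layout.
* 5′-side PAMs (e.g. Cas12a TTTV) are not supported; the PAM is always 3′
  of the protospacer.
* ≤ 32 sequences and ≤ 2^28 bases per sequence per index; larger genomes
  must be split.
* The brute-force oracle and the pure-Python planting utilities are test
  instruments, not production tools.
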