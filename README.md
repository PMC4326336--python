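# offtarget

Exhaustive enumeration of CRISPR/Cas guide-RNA off-target sites with a
prefix-hash genome index.

## The problem

A CRISPR guide RNA (gRNA) is a ~20-nt sequence designed to direct a Cas
nuclease to one genomic target. Cleavage also requires a short protospacer
adjacent motif (PAM, e.g. NGG for SpCas9) immediately 3′ of the 20-mer.
Because Cas tolerates imperfect pairing, any genomic 20-mer that is close
enough to the guide *and* PAM-adjacent is a potential off-target, and a
designer wants all of them — exhaustively, not heuristically.

Formally: given a genome *G*, a query 20-mer *Q*, a PAM pattern over
`{A,C,G,T,N,R}` (N = any base, R = purine), a mismatch budget *M* ≤ 5, and an
optional *seed* (a user-chosen subset of the 20 positions that must match
exactly), report every location on either strand of *G* whose 20-mer *q*
satisfies Hamming(*q*, *Q*) ≤ *M*, agrees with *Q* on the seed, and is
immediately followed on its own strand by the PAM.

## The algorithm

**Off-line stage** (once per genome). Every PAM-adjacent 20-mer is keyed by
the base-4 code of its 16-nt prefix, *i* = Σ<sub>j</sub> digit(N<sub>j</sub>)·4<sup>16−j</sup>
with A→0, C→1, G→2, T→3 (e.g. `AACTCCTGACCTCAGA` → 123,606,856). **Table A**
maps each prefix code to a contiguous group in **Table B**, a flat array of
64-bit records packing the 4-nt tail (8 bits), PAM id (3), captured bases at
the PAM's unspecified positions (2 bits each), chromosome (5), strand (1) and
0-based position (28). The prefix itself is never stored — it is recovered by
inverting the hash. Construction scans the genome twice: pass 1 counts sites
per prefix and lays out the offsets (so consecutive pointer differences equal
group sizes exactly), pass 2 fills the records.

**On-line stage** (per query). Enumerate the 16-mer prefixes within *M*
substitutions of the guide's prefix — never substituting at seed positions —
follow each prefix's Table A pointer, reconstitute prefix + stored tail, and
report the site if total mismatches (prefix + tail) stay within budget and
tail mismatches avoid the seed. At most Σ<sub>i≤M</sub> C(20,i)·3<sup>i</sup>
pointers are ever followed (4,192,468 at *M* = 5). When the genome occupies
fewer prefixes than that ball holds, the engine equivalently Hamming-tests
the occupied prefixes instead; both strategies return the identical,
provably complete hit set (a brute-force oracle enforces this in the tests).

**Annotation stage** (optional). Hits are tagged with overlapping gene /
transcript features from any GTF or BED file via per-chromosome interval
trees.

## Worked example

```python
import offtarget as ot

genome = ot.synth_genome(20_000, num_chroms=1, gc_bias=0.45, rng_seed=11)
spec = ot.PlantSpec(
    guide="GATTACAGATTACAGATTAC",
    sites=(
        ot.PlantSite(0, 2_000, "+", (), "AGG"),        # perfect site
        ot.PlantSite(0, 9_500, "-", (3, 18), "TGG"),   # 2-mismatch site
    ),
)
ngg = ot.builtin_pams()[0]
planted, truth = ot.plant_offtargets(genome, spec, ngg, rng_seed=11)

index = ot.build_index(planted, ot.builtin_pams())
hits = ot.find_offtargets(index, "GATTACAGATTACAGATTAC", ngg, max_mm=3)
for h in hits:
    print(h.chrom_name, h.strand, h.position, h.sequence,
          h.mismatch_count, h.pam_instance, f"{h.gc_content:.2f}")
print("histogram:", ot.mismatch_histogram(hits, 3))
```

prints

```
chr1 + 2000 GATTACAGATTACAGATTAC 0 AGG 0.30
chr1 - 9500 GATAACAGATTACAGATTCC 2 TGG 0.35
histogram: [1, 0, 1, 0]
```

— the planted perfect site (0 mismatches, PAM dereferenced to `AGG`), the
planted reverse-strand 2-mismatch site, and the per-budget histogram
`[1, 0, 1, 0]` (one hit at 0 mismatches, one at 2). Requiring a 6-nt
PAM-proximal seed (`seed=ot.SeedMask.parse("3prime:6")`) drops the second
site, whose mismatch at position 18 falls inside the seed, leaving 1 hit.

The same flow from the shell:

```bash
offtarget build --fasta genome.fa --out genome.idx
offtarget query --index genome.idx --pam NGG --max-mm 3 \
    --seed 3prime:6 --guides guides.txt --annotate genes.gtf --out report/
```

which writes one TSV of hits per guide (mismatched bases lowercased, GC
content, dereferenced PAM, gene/transcript/region columns) plus
`summary.tsv` with each guide's total and mismatch histogram.

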