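# smsmap

An end-to-end long-read mapper for noisy single-molecule sequencing
reads, with a bundled truth-emitting read simulator and a
mapping-evaluation toolkit.

Unlike local seed-and-extend mappers that soft-clip read ends outside
the seeded candidate region, this mapper aligns the **whole read**:

1. **Index** — every N-free k-mer (default k = 14) of the forward
   reference strand is stored in an exact-match word table
   (`smsmap.reference_index`). Words above an occurrence cap are masked.
2. **Anchor** — each read word's genome matches vote on "modified
   positions" `o = p − i` (match position minus read offset, constant
   along a gap-free diagonal). A candidate's credibility is the number
   of modified positions within the error-tolerant window
   `L(r) = 0.2 × read length`; the maximizer fixes the alignment start
   on read and genome. Both strands are scored against the forward
   index and the more credible one wins (`smsmap.anchor_locator`).
3. **Align** — the anchor splits read and genome into upstream and
   downstream segment pairs; the genome side takes 1.2× the read-side
   length (clipped at genome bounds). Each pair is aligned by a banded
   global-in-read dynamic program stored in a low-column matrix of
   `(segment length + 1) × (2b + 1)` cells with `b = ceil(0.1 × read
   length)` — memory never depends on the genome segment length
   (`smsmap.banded_aligner`). Scores: match +2, mismatch −2, linear gap
   −2; genome beyond the best final-row cell is free. The two segment
   alignments are combined into one SAM record; soft clips appear only
   where a genome boundary truncates the alignment.

The **simulator** (`smsmap.read_simulator`) generates random genomes,
injects insertions / deletions / inversions with variant-genome
breakpoint coordinates, and draws strand-random reads under a flat
per-base error rate with an indel-dominated substitution/insertion/
deletion mix (default 0.2/0.5/0.3), emitting an exact edit script per
read.

The **evaluation** module (`smsmap.evaluation`) implements:

- truth-based metrics cFAR / cFAB / cACR (correct read: right
  reference + strand and interval overlap ≥ 0.9 × read length; correct
  matched base: reference coordinate within 5 bp of the truth
  coordinate), plus base sensitivity and precision;
- truth-free metrics FAR / FAB / ACR and the population standard
  deviation of per-read coverage ratios;
- pairwise alignment agreement between mappers (x covers y when their
  reference-interval overlap is ≥ 90% of y's interval — asymmetric);
- counting of reads whose alignments span SV breakpoints.

## CLI

```sh
# simulate a genome (optionally with SVs) and reads with truth
smsmap simulate --length 100000 --depth 10 --error-rate 0.15 \
    --read-mean 2000 --read-sd 200 --seed 1 --out-prefix sim
# --sv-spec svs.tsv   (columns: sv_type, position, length)

# map reads to a reference
smsmap map --ref sim.fa --reads sim.reads.fq --out out.sam
# tunables: --k 14 --step 1 --alpha 0.1 --match 2 --mismatch -2
#           --gap 2 --tol-coeff 0.2 --max-occ 512

# evaluate against truth (or truth-free with --mode real)
smsmap eval --sam out.sam --truth sim.truth.tsv --mode simulated

# standalone word index; agreement between mappers; SV spanning counts
smsmap index --ref sim.fa --k 14 --out sim.idx
smsmap agree --sams a.sam --sams b.sam
smsmap svspan --sam out.sam --breakpoints sim.breakpoints.tsv --truth sim.truth.tsv
```

SAM output is v1.6: POS is 1-based, minus-strand records carry flag
0x10 with the sequence reverse-complemented, unmapped reads carry flag
0x4, the alignment score is in `AS:i` and the anchor credibility in
`XC:i`; MAPQ is 255 (unavailable). The truth sidecar is a TSV with
columns `read_id, ref_id, strand, ref_start, ref_end, edit_script`
(script ops `=`/`X`/`I`/`D`, always in forward-genome orientation).
All internal coordinates are 0-based half-open.

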