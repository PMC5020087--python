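# ssrforge

Genome-scale microsatellite analysis: mine simple sequence repeats (SSRs)
from FASTA sequences of any length, summarise and plot their distribution,
design deduplicated PCR markers from the repeat flanks, screen marker
polymorphism and transferability by in-silico PCR, and export everything as
genome-browser tracks.

It is aimed at people building molecular-marker panels from genome or
transcript assemblies: an SSR is a tandem repeat of a short unit (typically
1–6 bp) whose copy number mutates quickly, so a primer pair bracketing a
tract yields a cheap length-polymorphic genetic assay.

## What it computes

**Mining.** An SSR locus is a *maximal whole-copy tandem run* of a
*primitive* motif — a unit that is not itself a repetition of a shorter
word, so an (AT)×6 tract is never double-reported as (ATAT)×3. For each
period *k*, positions with `seq[i] == seq[i+k]` form a match array whose
maximal stretches delimit repeat regions; a region of length *m + k* holds
⌊(m+k)/k⌋ copies. Runs meeting the per-unit copy threshold (default ≥5
copies for units 2–6 bp; homopolymers opt-in, e.g. ≥12) are reported with
1-based inclusive coordinates, the motif written as it appears at the locus
start. Loci contained inside longer loci are filtered. Long sequences are
sliced into overlapping chunks (default 2 Mb, 20 bp overlap) and results are
lifted back and re-joined, so chunking never changes the output.

**Statistics.** Five classifications of the locus table: counts by motif
unit length (MT = Σᵢ L(i)), by motif composition, by complementary motif
group (a motif and its reverse complement are the same repeat when strand
is unknown: GA/TC, AT/AT, GCG/CGC …), per-sequence frequency
(scale · Σ(SSR) / Length, default per Mb), and the SSR length distribution
(SL = Σᵢ l). Each table carries counts and percentages in descending rank.

**Markers.** A 400 bp window around each locus is extracted and a primer
pair is designed wholly within the flanks (amplicon 100–400 bp, Tm target
60 °C, nearest-neighbour thermodynamics); 100 %-identical pairs collapse to
one marker, `MK1, MK2, …`. **e-PCR** then maps markers onto any FASTA set:
convergent primer-site pairs within size bounds become predicted amplicons,
amplicon sizes are a marker's alleles, and a marker is polymorphic when
targets disagree (Table cells like `200+204` or `NA`).

## Worked example

```bash
ssrforge fixture --length 50000 --n-loci 10 --seed 8 --out toy
printf 'fasta = toy.fa\nout_prefix = toy\n' > settings.cfg
ssrforge run --config settings.cfg
```

This plants 10 known tracts in a 50 kb synthetic sequence, then runs
mine → stats → plot → design → emap → export. The console reports

```
ssrforge INFO mine: 10 loci over 1 sequences
ssrforge INFO design: 10 markers from 10 loci (0 failures)
ssrforge INFO emap: 10 amplicons
```

`toy.ssr` begins

```
Name    Seq_Len StartPos  EndPos  Repetitions  Motif
>chr1   50000   1545      1576    8            AATA
>chr1   50000   5748      5771    8            CTA
```

i.e. an AATA tetramer repeated 8 times spans bases 1545–1576. `toy.sts`
lists the deduplicated markers ready for ordering
(`>MK1 TGGATTCCCCTTTCCAATCC TCGTAAAACGGGACCTAAGC 361` — forward primer,
reverse primer, expected 361 bp product), `toy.frg` holds the allele matrix
(here one target, every marker monomorphic), `toy.sat4` the mapping summary
(10 markers mapped, 10 amplicons, mean 1 per marker), and `toy.gff3` /
`toy.markers.gff3` load directly into a genome browser. Every subcommand
(`mine`, `stats`, `plot`, `design`, `emap`, `export`, `fixture`) is also
runnable on its own; see `ssrforge --help`.

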