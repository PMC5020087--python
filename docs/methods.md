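# Methods

## Repeat model and mining algorithm

A microsatellite locus is defined as a maximal whole-copy tandem run of a
primitive motif. *Primitive* means the unit is not an integer repetition of
a shorter word (ATAT fails, AT does not): attributing each run to its
minimal period exactly once is what prevents the redundant overlapping
calls that naive per-motif matching produces. *Maximal whole-copy* means
the run cannot be extended by a further unit on either side, and a trailing
partial unit is excluded from the reported interval, so the invariant
`end − start + 1 = repetitions × |motif|` always holds. By Fine and Wilf's
periodicity theorem, a run of ≥2 copies of a primitive unit cannot secretly
have a smaller period, so the per-period scans cannot double-report one
tract.

Detection is per period *k*: the boolean array `seq[i] == seq[i+k]`
(uppercased; positions with N or ambiguity codes never match) is computed
with numpy, and each maximal stretch of `m` matches delimits a repeat
region of length `m + k` holding `⌊(m+k)/k⌋` copies, anchored at the
leftmost phase. This is O(n) per period and allows genome-scale input.
The motif is reported exactly as read at the locus start — no canonical
rotation — matching the convention of the established locus-table layout.

**Containment filter** (default on): a locus whose interval lies inside
another reported locus is dropped, keeping the longer locus; on an exact
interval tie the shorter period wins as the more parsimonious description.
Partial overlaps between different periods are deliberately kept — both
runs are real, and neither subsumes the other.

**Copy-number thresholds.** The defaults are ≥5 copies for units of 2–6 bp
with monomer mining off (opt-in as `1=12`). These are inferred from the
worked examples and figure conventions of the tool family this package
re-implements (5-copy dimers and trimers appear in published locus tables;
monomer analyses use an explicit 12-copy minimum), since no canonical
default list is printed anywhere; they are exposed as `--min-repeats`.

## Chunking

Sequences longer than `chunk_size` (default 2 Mb) are sliced with a 20 bp
overlap; chunk *j* covers `[j·(chunk_size−overlap), …+chunk_size)`. Chunks
are scanned with the copy threshold lowered to 2 so that a run longer than
the overlap — which can straddle a boundary leaving fewer than the
threshold number of copies in *both* chunks — is still seen in at least one
chunk (any visible piece of ≥2 copies suffices, because dimer–hexamer
double units are at most 12 bp < 20 bp overlap). Every lifted candidate is
then *re-extended against the parent sequence* at its period, duplicates
collapse, the real thresholds apply, and only then is the containment
filter run. This construction makes chunked and unchunked mining provably
identical, which the tests check byte-for-byte on a >5 Mb genome with
tracts planted across the 2 Mb and 4 Mb boundaries.

## Statistics

Five classifications, each reporting count and percentage (2 dp) in
descending rank: unit-length (motif type), motif composition, complementary
groups, per-sequence frequency, and tract-length distribution.
Complementary grouping pairs a motif with its reverse complement only
(label = lexicographically sorted pair, e.g. `GA/TC`; self-complementary
motifs pair with themselves, `AT/AT`); rotations are *not* merged, since
the source convention reports rotated motifs separately. The per-sequence
frequency is `scale · count / length`. The historical formula printed the
scale 100 000 while describing the quantity as "per million bases"; the
package defaults to 1 000 000 (the interpretable per-Mb convention) and
`--freq-scale 100000` restores the printed constant.

## Marker design

Runtime scales with locus count, not genome length: only a ±400 bp window
per locus is examined. The designer enumerates candidate oligos by 3′-end
position and length (18–27 bp), applies hard constraints — GC 20–80 %,
melting temperature within ±3 °C of the 60 °C target, no single-base run
longer than 4, primer wholly inside one flank (never in the repeat tract) —
and ranks pairs by `|Tm_L−60| + |Tm_R−60| + |Tm_L−Tm_R|` subject to the
100–400 bp product window, with deterministic tie-breaks (smaller product,
leftmost primer). Only the top 40 candidates per side are paired, which
bounds cost at ~1600 pair evaluations per locus. Melting temperatures use
the nearest-neighbour model at 50 mM monovalent salt, 1.5 mM Mg²⁺, 50 nM
oligo with the Owczarzy (2008) salt correction; under these conditions
typical published 20-mer marker primers evaluate to 56–62 °C, consistent
with the 60 °C design convention. Design failures (short flank,
low-complexity window, no pair in the size window) are recorded with a
reason and never abort a batch. Identical `(left, right)` pairs are
clustered into one marker; ids `MK1, MK2, …` follow first occurrence, and
all distinct product sizes of a duplicated marker are retained while the
first-occurrence size is the one printed in `.sts`.

## In-silico PCR

A primer site is a match of the primer (or its reverse complement) with at
most `max_mismatches` substitutions (default 0) whose 3′-terminal 3 bases
match exactly; gapped matches are not modelled. An amplicon is any
convergent, non-overlapping pairing of an upstream site with the mate's
complement downstream, evaluated in both template orientations, within
absolute product bounds of 50–5000 bp. An optional `--margin` additionally
restricts products to the declared size ± margin when screening non-source
genomes; it is off by default because genuinely duplicated loci can yield
alleles far from the declared size. Multi-amplicon cells in the allele
matrix are sorted ascending and joined with `+` (the source material is
inconsistent on cell ordering; ascending is this package's convention), and
a marker is polymorphic when at least two distinct non-NA cell values occur
across targets — absence (`NA`) alone is not evidence of length
polymorphism.

## Synthetic genomes

The fixture generator emulates exactly the property the toolkit needs:
known tracts in repeat-free background. Background bases are i.i.d. at a
configurable GC content (default 0.42, a typical plant-genome value);
accidental tandem runs above strict cleaning thresholds (homopolymer ≥6,
dimer ≥4, units 3–6 ≥3 copies) are broken by targeted substitutions. After
a tract is written, the bases immediately bordering it are forced off-phase
(the base before may not equal the motif's last base, the base after may
not equal its first), which blocks both whole-unit and partial-unit
extension, so the planted (motif, copies) is exactly the maximal run at
exact coordinates. An optional verification pass mines the finished genome
and repairs any residual stray run. Variant genomes change tract copy
numbers by whole units, leaving flanks byte-identical and shifting
downstream coordinates, which models allele-length polymorphism between
genotypes. Everything is deterministic for a fixed seed.

What the generator does **not** model: interrupted/imperfect repeats,
compound SSRs, indel/substitution noise in flanks, real base-composition
structure (isochores, CpG), or genome duplication. Passing tests therefore
demonstrate algorithmic correctness on the defined repeat model, not
recall on real genomes, where imperfect repeats are simply outside the
perfect-run definition used here.

## Numerical and format choices

- Coordinates are 1-based inclusive in every user-facing table and file;
  chunk offsets are internal 0-based.
- Mining is case-insensitive (soft-masked lowercase is searched); reported
  motifs are uppercase.
- `.sat2` percentages are rounded to 2 dp; frequencies are written in
  shortest round-trip float representation.
- Plots render deterministically (Agg backend, fixed DPI, pinned SVG hash
  salt, no embedded dates) so outputs can be compared byte-for-byte.
- GFF3 export uses Sequence Ontology feature types `microsatellite` and
  `STS` with percent-encoded attributes; only GFF3 is emitted (no legacy
  browser dialects).
- Problem sizes in the test suite (5.2 Mb for chunking invariance, 120 kb /
  20 tracts for the design→mapping loop, 100 × 5–10 kb for oracle
  equivalence) were chosen as the smallest scales at which each property is
  non-trivially exercised.

## Known limitations

- Only perfect tandem runs are mined; mismatch-tolerant (interrupted) SSRs
  are out of scope.
- e-PCR supports substitution mismatches but not gapped primer alignment.
- The primer designer checks hairpin-free-ness only via the homopolymer
  rule; it does not model secondary structure or primer-dimer
  thermodynamics.
- Marker transferability across distant species is bounded by the strict
  default of 0 mismatches; raise `--mismatch` deliberately.
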