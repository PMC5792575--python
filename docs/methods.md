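# Methods

This note records the statistical definitions, modelling assumptions and
numerical conventions the package implements, and what its synthetic data
can and cannot show about real plastomes.

## Variation statistics

**Coordinates.** All arithmetic is 0-based half-open; reports print 1-based
inclusive coordinates (window ranges are printed 0-based half-open, matching
the round-hundred genome-anchored style of sliding-window tables). Regions
and windows are anchored on one designated *reference individual*: its
ungapped row defines the genome coordinate system, and a region's reference
interval is projected onto alignment columns monotonically, including gap
columns interior to the region (insertions relative to the reference) but
not insertions immediately after its last base. Region lengths — the P_V
denominators — are reference lengths, so a locus that is 286 bp in some
other individual still scores over its 285 bp reference length.

**SNP sites.** A column is a SNP site when ≥ 2 distinct states occur among
non-gap, non-N characters. `N` is missing data throughout: it never creates
a site, never breaks an indel run, and is deleted pairwise from π and from
pairwise difference counts. Multi-allelic columns count as one site.

**Indel events.** Gap columns are partitioned into maximal runs of adjacent
columns sharing a constant gapped-individual set; each run is one event.
This makes a two-base indel one mutation, a deletion shared by several
individuals one mutation, and overlapping gaps of different extent separate
mutations. A run crossing a window edge is counted in every window it
intersects (it is one mutation, but each window is scored independently);
with non-overlapping windows this can double-count at most boundary-
straddling runs, which the simulator avoids planting.

**P_V.** `100 · (SNP sites + indel events) / length`, rounded half-up to
two decimals (`Decimal` arithmetic, so `.125 → 0.13`). The same formula with
the window size as denominator scores sliding windows.

**π.** Nei's per-site pairwise diversity: the mean over all unordered
individual pairs of (substitution differences / comparable sites), where
comparable means both characters in {A,C,G,T}. A pair with no comparable
sites contributes 0. π is reported to six decimals. No substitution-model
correction is applied (divergences here are ≪ 1%, where the correction is
negligible).

**Pairwise differences.** substitution positions (both non-gap, non-N,
unequal) plus indel events restricted to the pair (maximal gap runs present
in exactly one of the two). Counting indels as events rather than positions
is a convention; the matrix is symmetric with zero diagonal but is not a
metric, so no triangle inequality is asserted anywhere.

**Effect calls.** Coding SNPs are classified synonymous/nonsynonymous by
assembling the codon from the spliced, strand-oriented CDS and translating
with the plastid/bacterial genetic code (table 11). Start-codon exceptions
are ignored; a stop-gaining change is flagged. Pseudogenization is reported
per individual as (a) frameshift — net indel length within the CDS not a
multiple of 3 — and (b) internal stop codons strictly before the final
codon, translating the gap-stripped CDS in the annotated frame.

## Discrimination criterion

A taxon is identified by a locus when no haplotype carried by any of its
individuals equals a haplotype of a different taxon. Haplotypes keep gap
characters, so indel-only differences discriminate. Conspecific individuals
need not match each other — a species whose two specimens differ at dozens
of sites is still identified as long as neither specimen matches another
taxon.

Two headline counts are reported, because the field mixes two conventions
when taxa share identical sequences. `n_identified` applies the criterion
taxon by taxon: a pair of taxa with identical plastomes is two failures
(19 taxa with one identical pair → 17 identified). `n_resolved_units`
collapses each class of mutually indistinguishable taxa to a single
unresolved case (the same situation → 18 of 19, the convention behind
"18 of 19 taxa discriminated" summaries). Both are computed from the same
haplotype classes; tables print the strict count.

Multi-locus barcodes concatenate the per-locus haplotypes; SNP/indel counts
add over loci, while P_V, π and discrimination are computed on the
concatenation. Concatenation can only split shared haplotypes, so the
identified set grows monotonically with added loci — a property the test
suite asserts on random fixtures. Greedy locus selection maximises newly
identified taxa per step over the per-locus identified sets (a set-cover
greedy; ties broken by higher P_V, then name). By monotonicity the
concatenation of the greedy picks identifies at least the best single
locus's set, but global optimality is not claimed.

## Region model

Regions tile the annotated genome exactly once: one coding region per gene
(exon parts), one intron region per inter-exon gap, one spacer per
inter-gene gap, named `geneA-geneB` in genome order regardless of strand.
Same-named duplicates (inverted-repeat copies) are ordered by genomic start
and disambiguated `name·k`. tRNA/rRNA gene bodies delimit spacers and are
extracted as coding regions with a non-protein flag, but hotspot tables
score protein genes only. A spacer spanning the circular origin is split at
position 0 and flagged; introns are numbered in genome order irrespective
of strand. Overlapping genes produce no spacer and a logged warning. Gene
counts are reported in both conventions — every annotated gene feature
(IR duplicates counted twice) and distinct names — since published gene
totals mix the two.

Inverted repeats are located by seed-and-extend: k-mers of the reverse
complement are matched against the forward strand, maximal exact matches
are extended, and the longest repeat ≥ `min_len` (default 10 kb) with
disjoint footprints defines IRa/IRb; the longer remaining arc is the LSC.
Only exact repeats are considered, which suits plastomes, whose IRs are
identical or nearly so; a genome with slightly diverged IRs would need a
smaller `min_len` or external alignment.

## Synthetic data

The generator emulates a low-divergence congeneric plastome set:

- **Reference** (defaults): LSC 81,700 bp, SSC 12,836 bp, IRs 21,616 bp
  (exact reverse complements, mirrored annotations), 127 genes = 81
  protein-coding + 38 tRNA + 8 rRNA counting IR duplicates twice, with 20
  genes duplicated in the IRs; four intron-containing genes (one with two
  introns); and a three-copy *rpl23* analogue — a 285 bp single-copy copy
  placed between *rbcL* and *psaI* analogues (fixed 274 bp and 350 bp
  spacers) plus two 282 bp IR copies — mirroring the grass mutational
  hotspot between *rbcL* and *psaI*. Coding tracts are random non-stop
  codons; base composition is drawn so the quadripartite GC profile echoes
  real plastomes (IR ≈ 48% > LSC ≈ 36% > SSC ≈ 35%, ≈ 39.7% overall).
- **Population** (defaults): 21 individuals in 19 taxa on a star phylogeny —
  every mutation is private to one lineage. Substitution rates per bp per
  lineage are 2.0·10⁻³ (spacer), 1.0·10⁻³ (intron), 2.5·10⁻⁴ (coding);
  indel rates 6·10⁻⁴ (spacer), 4·10⁻⁴ (intron), 0 (coding, barring the
  planned frameshift); indels 90% 1 bp / 10% 2 bp. These place the most
  divergent pair at a few hundred base differences on a ~137.7 kb genome
  (pairwise identity ≥ 99.7%) with variation concentrated in spacers.
- **Special plans**: one identical pair of taxa (two single-individual taxa
  sharing every mutation); one taxon with two divergent conspecific
  individuals (independent lineages); one taxon whose two individuals
  differ by exactly two single-base indels; one individual with a
  frameshifting 1 bp insertion in the single-copy rpl23 analogue; and one
  planted hotspot — 50 substitutions + 10 non-coding indels inside a single
  600 bp window grid cell around that gene, strong enough to dominate the
  Poisson background of every other window, so hotspot ranking has a known
  answer.
- **Truth manifest**: every event with type, position, length, carriers,
  region and (for coding substitutions) effect class. Events are kept
  mutually non-adjacent and within single regions by rejection sampling, so
  planted counts and pipeline-recovered counts agree exactly; the alignment
  is built analytically from the manifest (insertion columns gap all
  non-carriers) and gap-stripping any row reproduces that individual's
  sequence. One lineage (the first individual) receives substitutions but
  no indels and serves as the coordinate anchor.

A separate deterministic worked-example fixture (`worked_example_fixture`) lays a
~18 kb mini-plastome with fixed gene/spacer geometry (285 bp *rpl23*,
160 bp *rps19–psbA*, 274 bp *rbcL–rpl23*, …) and plants exact per-region
counts (8+1, 4+2, 31 SNPs + 15 indels across the six-locus barcode, …), so
published worked-example statistics reproduce through the full pipeline
rather than through the bare formula. Its geometry also pins the *rbcL* end
to make one 600 bp window decompose as 216/274/110 bp across gene, spacer
and downstream gene.

**What passing tests do not show.** The star phylogeny has no shared
internal branches, so site-frequency structure, homoplasy and
phylogenetically clustered variation are absent; real data concentrate
hundreds of pairwise differences into far fewer segregating sites than the
simulator does. There is no rate heterogeneity beyond the three region
classes, no concerted IR evolution (IR copies mutate independently after
duplication), no rearrangements or gene loss, no sequencing or alignment
error, and indel placement avoids the collisions that real aligners must
resolve. Recovery results therefore validate the counting machinery, not
the behaviour of any aligner on real reads.

## Numerical and engineering choices

- Rounding: half-up via `Decimal` (P_V and percent-identified to 2
  decimals, 1 decimal in prose-style output, π to 6).
- Ranking: windows sort by P_V desc, identified taxa desc, π desc, start
  asc; region tables by P_V desc, π desc, name asc, coding before
  non-coding. Report filters default to ≥ 100 bp and ≥ 3 PICs.
- Degenerate inputs: empty sequences, a window longer than the genome, a
  region outside the reference, duplicate loci in a concatenation and a
  zero-length P_V denominator are errors; an alignment with no variation
  yields all-zero summaries and an empty (warned) report, not an error.
- Column statistics (SNP flags, gap-run starts) are computed once per
  alignment and reused by regions and windows via prefix sums, which keeps
  the 20-seed full-scale recovery suite in the test budget; π over all
  windows is accumulated pair-by-pair from cumulative sums.
- Test problem sizes: the unit suite runs on hand-built toys and the ~18 kb
  fixture; recovery properties run on 20 full-scale (~137.7 kb, 21-
  individual) simulations, brute-force oracles on 100 random 10×50 gap
  matrices, all 576 single-base codon changes, and 50 random two-locus
  discrimination fixtures.

## Known limitations

- The unique-haplotype criterion is binary; no barcode-gap, distance-
  threshold or tree-based (PTP/GMYC-style) delimitation is provided.
- dN/dS and model-corrected distances are out of scope; effect calls are
  per-site, not codon-model based.
- Windows and spacers wrapping the circular origin are split at position 0
  rather than analysed as contiguous arcs.
- The GFF3 reader expects gene features with CDS/tRNA/rRNA children named
  consistently with the GenBank route; exotic annotation dialects may need
  normalisation first.
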