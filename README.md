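# plastoscreen

Barcode-locus screening for plastid genomes: given a whole-plastome multiple
alignment of congeneric individuals, find the mutation hotspots and measure
how well each candidate locus — or a multi-locus combination, or the whole
plastome used as a *super-barcode* — discriminates the sampled taxa.

The package is aimed at plant molecular systematists working on groups with
very low plastome divergence (congeneric grasses being the motivating case),
where standard barcoding loci fail and candidate regions have to be screened
genome-wide before primer design.

## What it computes

For every annotated region (protein-coding gene, intron, intergenic spacer)
and for every fixed-size sliding window (600 bp moved by 100 bp by default):

- **SNP sites** — alignment columns with ≥ 2 distinct non-gap, non-N states;
- **indel events** — maximal runs of adjacent gap columns with a constant
  gapped-individual set (a 2 bp deletion is one event, a deletion shared by
  three individuals is one event);
- **PIC** = SNP sites + indel events, and the percent of variation
  **P_V = 100 · PIC / L**, with *L* the region length in the reference
  individual's ungapped coordinates;
- **nucleotide diversity π** (Nei), the mean over all individual pairs of
  per-site differences with pairwise deletion of gap/N columns;
- **taxon discrimination** — a taxon is *identified* by a locus when none of
  its individuals' haplotypes (gaps retained) is shared with another taxon.

On top of that: synonymous/nonsynonymous classification of coding SNPs
(translation table 11), pseudogenization detection (frameshifting indels and
internal stop codons), pairwise base-difference matrices, inverted-repeat
detection, multi-locus concatenation, greedy locus selection, and
Circos-style plain-text variation tracks.

Because the statistics only need an alignment plus an annotated reference,
the package ships a synthetic plastome-population generator
(`plastoscreen.simulate`) that builds an annotated ~137.7 kb quadripartite
reference (LSC/IRa/SSC/IRb, 127 genes, a three-copy *rpl23* analogue) and a
population of 21 individuals from 19 taxa with every planted mutation
recorded in a truth manifest — so the entire pipeline is testable without
downloading genomes.

## Worked example

Generate the compact worked-example population (a mini-plastome with
published per-region mutation geometry planted on it) and run the full
analysis:

```bash
plastoscreen simulate --seed 3 --mini --out-dir sim
plastoscreen full --genome sim/reference.gb --alignment sim/alignment.fasta \
    --samples sim/samples.tsv --out-dir out
head -8 out/regions.tsv
```

```text
section     region      length_bp  snp  indel  p_v   pi        identified_taxa
coding      rpl23       285        8    1      3.16  0.002673  8 (42.11%)
coding      atpE        414        3    0      0.72  0.000690  3 (15.79%)
coding      rbcL        1434       8    0      0.56  0.000531  6 (31.58%)
coding      ccsA        975        4    1      0.51  0.000391  4 (21.05%)
coding      ndhH        1182       5    0      0.42  0.000403  3 (15.79%)
non-coding  rps19-psbA  160        4    2      3.75  0.002390  4 (21.05%)
non-coding  psbK-psbI   408        1    6      1.72  0.000233  3 (15.79%)
```

The 285 bp *rpl23* copy carries 8 SNP sites and 1 indel event, hence
P_V = 100 · 9 / 285 = 3.16%; the 160 bp *rps19–psbA* spacer carries 4 + 2,
hence 3.75%. A six-locus barcode and the whole-plastome super-barcode:

```bash
plastoscreen multilocus --genome sim/reference.gb --alignment sim/alignment.fasta \
    --samples sim/samples.tsv \
    --loci ndhH,rpl23,ndhF-rpl32,rpl32-ccsA,psbK-psbI,petA-psbJ
plastoscreen superbarcode --genome sim/reference.gb \
    --alignment sim/alignment.fasta --samples sim/samples.tsv
```

```text
ndhH+rpl23+ndhF-rpl32+rpl32-ccsA+psbK-psbI+petA-psbJ: 4508 bp, 46 PICs
(31 SNPs, 15 indels), P_V 1.02%, pi 0.000655, 16/19 taxa identified
super-barcode: 17/19 taxa identified (89.47%); 18 resolved units
```

The concatenated barcode is 4508 bp long with 46 polymorphic characters.
`taxa identified` applies the unique-haplotype criterion taxon by taxon;
`resolved units` counts each class of mutually indistinguishable taxa once
(see `docs/methods.md` for why both conventions are reported).

`plastoscreen windows` ranks the 600 bp sliding windows and decomposes each
into the regions it overlaps (e.g. `rbcL (216), rbcL-rpl23 (274),
rpl23 (110)`); `plastoscreen simulate` without `--mini` emits the full-scale
synthetic population with its truth manifest.

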