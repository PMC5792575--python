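"""Annotated plastome model: parsing, candidate barcode regions, summary statistics.

A plastid genome is a circular molecule, typically with a quadripartite
structure: a large and a small single-copy region (LSC, SSC) separated by two
inverted repeats (IRa, IRb) that are exact reverse complements of each other.
This module parses annotated plastomes (GenBank flat files or FASTA + GFF3),
derives the full set of candidate barcode regions -- protein-coding genes,
introns and intergenic spacers, with inverted-repeat gene copies
disambiguated -- and computes genome-level summary statistics.

Coordinates are 0-based half-open throughout; report writers convert to
1-based inclusive for display.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

from Bio import SeqIO

from .errors import InputParseError

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

#: feature kinds retained by the readers
KNOWN_KINDS = {"gene", "CDS", "tRNA", "rRNA", "exon", "intron"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """A typed annotation on the reference genome.

    ``parts`` holds one or more 0-based half-open intervals (multi-part for
    spliced genes), ordered by genomic start and non-overlapping.
    """

    name: str
    kind: str  # one of KNOWN_KINDS
    parts: tuple[Interval, ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        starts = [p[0] for p in self.parts]
        if starts != sorted(starts):
            object.__setattr__(self, "parts", tuple(sorted(self.parts)))

    @property
    def span(self) -> Interval:
        return (self.parts[0][0], self.parts[-1][1])

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.parts)


class PlastomeStructure(NamedTuple):
    """LSC/IRa/SSC/IRb intervals; single-copy regions may be split at the origin."""

    lsc: tuple[Interval, ...]
    ira: Interval
    ssc: tuple[Interval, ...]
    irb: Interval

    @property
    def ir_length(self) -> int:
        return self.ira[1] - self.ira[0]


@dataclass
class AnnotatedPlastome:
    """A circular genome sequence plus its typed features."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    structure: Optional[PlastomeStructure] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputParseError("plastome sequence is empty")
        self.sequence = self.sequence.upper()
        L = len(self.sequence)
        for f in self.features:
            for s, e in f.parts:
                if not (0 <= s < e <= L):
                    raise ValueError(
                        f"feature {f.name} interval [{s},{e}) outside [0,{L})"
                    )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gene_features(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "gene"]

    def subfeature_of(self, gene: Feature) -> Optional[Feature]:
        """The CDS/tRNA/rRNA feature carrying the exon structure of ``gene``.

        Matched by name and containment in the gene span; when a gene name is
        duplicated (IR copies), the copy at the same locus is returned.
        """
        gs, ge = gene.span
        for f in self.features:
            if f.kind in ("CDS", "tRNA", "rRNA") and f.name == gene.name:
                fs, fe = f.span
                if fs >= gs and fe <= ge:
                    return f
        return None


# ---------------------------------------------------------------------------
# Readers


def _name_of(qualifiers: dict) -> str:
    for key in ("gene", "locus_tag", "Name", "label"):
        if key in qualifiers:
            v = qualifiers[key]
            return v[0] if isinstance(v, (list, tuple)) else str(v)
    return "unnamed"


def _read_genbank(path: Path) -> AnnotatedPlastome:
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # malformed file, >1 record, ...
        raise InputParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    if len(record.seq) == 0:
        raise InputParseError(f"GenBank record {path} has no sequence")
    features: list[Feature] = []
    for f in record.features:
        if f.type == "source":
            continue
        if f.type not in KNOWN_KINDS:
            logger.warning("ignoring feature of unknown kind %r in %s", f.type, path)
            continue
        parts = tuple(sorted((int(p.start), int(p.end)) for p in f.location.parts))
        strand = "-" if (f.location.strand or 1) < 0 else "+"
        features.append(Feature(_name_of(f.qualifiers), f.type, parts, strand))
    return AnnotatedPlastome(record.id, str(record.seq), features)


def _read_fasta_single(path: Path):
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if len(records) != 1:
        raise InputParseError(
            f"expected exactly one sequence record in {path}, found {len(records)}"
        )
    return records[0]


def _read_fasta_gff(fasta: Path, gff: Path) -> AnnotatedPlastome:
    import gffutils

    record = _read_fasta_single(fasta)
    if len(record.seq) == 0:
        raise InputParseError(f"FASTA record {fasta} has no sequence")
    try:
        db = gffutils.create_db(
            str(gff), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:
        raise InputParseError(f"cannot parse GFF3 file {gff}: {exc}") from exc

    features: list[Feature] = []
    seen_types = set()
    for g in db.features_of_type("gene"):
        name = g.attributes.get("Name", g.attributes.get("gene", [g.id]))[0]
        strand = "-" if g.strand == "-" else "+"
        features.append(Feature(name, "gene", ((g.start - 1, g.end),), strand))
        for sub in ("CDS", "tRNA", "rRNA"):
            kids = list(db.children(g, featuretype=sub))
            if kids:
                parts = tuple(sorted((k.start - 1, k.end) for k in kids))
                features.append(Feature(name, sub, parts, strand))
    for t in db.featuretypes():
        seen_types.add(t)
        if t not in KNOWN_KINDS:
            logger.warning("ignoring GFF3 features of unknown kind %r in %s", t, gff)
    return AnnotatedPlastome(record.id, str(record.seq), features)


def read_annotated_genome(
    path: str | Path, gff: str | Path | None = None
) -> AnnotatedPlastome:
    """Read an annotated plastome from GenBank, or from a FASTA + GFF3 pair.

    The format is chosen by extension: ``.gb``/``.gbk``/``.genbank`` selects
    the GenBank reader; otherwise the file is treated as FASTA and ``gff``
    must name the annotation. Both routes yield the same feature model.
    """
    path = Path(path)
    if path.suffix.lower() in (".gb", ".gbk", ".genbank"):
        return _read_genbank(path)
    if gff is None:
        raise InputParseError(f"FASTA input {path} requires a GFF3 annotation file")
    return _read_fasta_gff(path, Path(gff))


# ---------------------------------------------------------------------------
# Regions


@dataclass(frozen=True)
class Region:
    """A named candidate barcode region: a gene, intron or intergenic spacer.

    Spacers are named ``"geneA-geneB"`` in genome order regardless of strand;
    introns ``"gene_intronK"``. Same-named duplicates (inverted-repeat copies)
    are ordered by genomic start and disambiguated with a ``·k`` suffix in
    :attr:`label`. ``is_protein`` is False for tRNA/rRNA gene regions, which
    delimit spacers but are left out of protein-coding hotspot tables.
    """

    name: str
    kind: str  # 'coding' | 'intron' | 'spacer'
    parts: tuple[Interval, ...]
    strand: str = "+"
    copy_index: int = 1
    n_copies: int = 1
    is_protein: bool = True
    wraps_origin: bool = False

    @property
    def start(self) -> int:
        return self.parts[0][0]

    @property
    def end(self) -> int:
        return self.parts[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.parts)

    @property
    def label(self) -> str:
        if self.n_copies > 1:
            return f"{self.name}·{self.copy_index}"
        return self.name


def extract_regions(genome: AnnotatedPlastome) -> list[Region]:
    """Derive the tiling set of coding / intron / spacer regions.

    One coding region per gene (exon parts only, concatenated logically),
    one intron region per inter-exon gap of a spliced gene, and one spacer
    per inter-gene gap, so that regions cover the genome exactly once.
    A gap spanning the circular origin is split at position 0 and flagged.
    """
    genes = sorted(genome.gene_features(), key=lambda f: f.span[0])
    if not genes:
        raise ValueError("genome has no gene features")
    raw: list[Region] = []

    for g in genes:
        sub = genome.subfeature_of(g)
        exon_parts = sub.parts if sub is not None else g.parts
        is_protein = sub is None or sub.kind == "CDS"
        raw.append(Region(g.name, "coding", tuple(exon_parts), g.strand,
                          is_protein=is_protein))
        # introns: gaps between ordered exon parts, numbered in genome order
        for k in range(len(exon_parts) - 1):
            gap = (exon_parts[k][1], exon_parts[k + 1][0])
            if gap[1] > gap[0]:
                raw.append(Region(f"{g.name}_intron{k + 1}", "intron",
                                  (gap,), g.strand, is_protein=is_protein))

    # spacers between consecutive gene spans
    for a, b in zip(genes, genes[1:]):
        if b.span[0] < a.span[1]:
            logger.warning("overlapping genes %s and %s; no spacer emitted",
                           a.name, b.name)
            continue
        if b.span[0] > a.span[1]:
            raw.append(Region(f"{a.name}-{b.name}", "spacer",
                              ((a.span[1], b.span[0]),)))
    # circular junction: gap after the last gene wrapping to the first
    last, first = genes[-1], genes[0]
    tail = (last.span[1], genome.length)
    head = (0, first.span[0])
    junction_name = f"{last.name}-{first.name}"
    wraps = tail[1] > tail[0] and head[1] > head[0]
    if tail[1] > tail[0]:
        raw.append(Region(junction_name, "spacer", (tail,), wraps_origin=wraps))
    if head[1] > head[0]:
        raw.append(Region(junction_name, "spacer", (head,), wraps_origin=wraps))

    # copy disambiguation by genomic start
    raw.sort(key=lambda r: (r.start, r.kind))
    counts: dict[str, int] = {}
    for r in raw:
        counts[r.name] = counts.get(r.name, 0) + 1
    seen: dict[str, int] = {}
    out: list[Region] = []
    for r in raw:
        seen[r.name] = seen.get(r.name, 0) + 1
        out.append(Region(r.name, r.kind, r.parts, r.strand,
                          copy_index=seen[r.name], n_copies=counts[r.name],
                          is_protein=r.is_protein, wraps_origin=r.wraps_origin))
    return out


def region_by_label(regions: Iterable[Region], label: str) -> Region:
    for r in regions:
        if r.label == label or r.name == label:
            return r
    raise KeyError(f"no region labelled {label!r}")


# ---------------------------------------------------------------------------
# Summary statistics


def _gc_percent(seq: str) -> float:
    if not seq:
        return 0.0
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    return 100.0 * gc / acgt if acgt else 0.0


@dataclass
class GenomeSummary:
    length: int
    gc_percent: float
    gc_by_region: dict[str, float]
    n_protein_coding: int
    n_trna: int
    n_rrna: int
    n_genes_total: int
    n_genes_distinct: int
    n_duplicated: int
    intron_genes: list[str]


def genome_summary(genome: AnnotatedPlastome) -> GenomeSummary:
    """Gene-class counts, GC content and intron-containing genes.

    Gene counts are reported in both conventions: ``n_genes_total`` counts
    every annotated gene feature (inverted-repeat duplicates counted twice,
    as they appear on the genome), ``n_genes_distinct`` counts unique names.
    """
    genes = genome.gene_features()
    by_class = {"CDS": 0, "tRNA": 0, "rRNA": 0}
    intron_genes: set[str] = set()
    for g in genes:
        sub = genome.subfeature_of(g)
        kind = sub.kind if sub is not None else "CDS"
        by_class[kind] = by_class.get(kind, 0) + 1
        if sub is not None and len(sub.parts) > 1:
            intron_genes.add(g.name)
    names = [g.name for g in genes]
    distinct = set(names)
    duplicated = {n for n in distinct if names.count(n) > 1}

    gc_by_region: dict[str, float] = {}
    if genome.structure is not None:
        st = genome.structure
        for label, parts in (
            ("LSC", st.lsc), ("IRa", (st.ira,)), ("SSC", st.ssc), ("IRb", (st.irb,)),
        ):
            seq = "".join(genome.sequence[s:e] for s, e in parts)
            gc_by_region[label] = _gc_percent(seq)
        ir_seq = genome.sequence[st.ira[0]:st.ira[1]] + genome.sequence[st.irb[0]:st.irb[1]]
        gc_by_region["IR"] = _gc_percent(ir_seq)

    return GenomeSummary(
        length=genome.length,
        gc_percent=_gc_percent(genome.sequence),
        gc_by_region=gc_by_region,
        n_protein_coding=by_class.get("CDS", 0),
        n_trna=by_class.get("tRNA", 0),
        n_rrna=by_class.get("rRNA", 0),
        n_genes_total=len(genes),
        n_genes_distinct=len(distinct),
        n_duplicated=len(duplicated),
        intron_genes=sorted(intron_genes),
    )


# ---------------------------------------------------------------------------
# Inverted-repeat detection


def detect_ir(
    genome: AnnotatedPlastome, min_len: int = 10_000, seed_k: int = 25
) -> Optional[PlastomeStructure]:
    """Locate the longest exact reverse-complement repeat pair >= ``min_len``.

    Seed-and-extend: k-mers of the reverse complement are matched against the
    forward strand and maximal exact matches are extended; the longest match
    whose two forward-strand footprints are disjoint defines IRa/IRb, and the
    two gaps between them become LSC (longer) and SSC (shorter). Returns
    ``None`` when no such repeat exists.
    """
    if min_len < 1000:
        raise ValueError("min_len must be >= 1000")
    seq = genome.sequence
    N = len(seq)
    if N < 2 * min_len:
        return None
    rc = revcomp(seq)

    index: dict[str, list[int]] = {}
    for i in range(0, N - seed_k + 1):
        index.setdefault(seq[i:i + seed_k], []).append(i)

    best: Optional[tuple[int, int, int]] = None  # (length, fwd_start, rc_start)
    found: list[tuple[int, int, int]] = []  # (li, ri, lj) of extended matches
    step = max(1, seed_k // 2)
    for j in range(0, N - seed_k + 1, step):
        hits = index.get(rc[j:j + seed_k])
        if not hits:
            continue
        for i in hits:
            # skip anchors inside an already-extended match on the same diagonal
            if any(li <= i and i + seed_k <= ri and i - li == j - lj
                   for li, ri, lj in found):
                continue
            # extend the exact match seq[i:] == rc[j:] in both directions
            li, lj = i, j
            while li > 0 and lj > 0 and seq[li - 1] == rc[lj - 1]:
                li -= 1
                lj -= 1
            ri, rj = i + seed_k, j + seed_k
            while ri < N and rj < N and seq[ri] == rc[rj]:
                ri += 1
                rj += 1
            found.append((li, ri, lj))
            length = ri - li
            if length < min_len:
                continue
            # footprint of the rc match on the forward strand
            b1, b2 = N - (lj + length), N - lj
            a1, a2 = li, ri
            if (a1, a2) == (b1, b2) or min(a2, b2) > max(a1, b1):
                continue  # self-match or overlapping footprints
            if best is None or length > best[0]:
                best = (length, min(a1, b1), max(a1, b1))
    if best is None:
        return None
    length, a1, b1 = best
    ira = (a1, a1 + length)
    irb = (b1, b1 + length)
    gap_mid = (ira[1], irb[0])
    gap_wrap_parts = tuple(
        p for p in ((irb[1], N), (0, ira[0])) if p[1] > p[0]
    )
    mid_len = gap_mid[1] - gap_mid[0]
    wrap_len = sum(e - s for s, e in gap_wrap_parts)
    if mid_len >= wrap_len:
        lsc, ssc = (gap_mid,), gap_wrap_parts
    else:
        lsc, ssc = gap_wrap_parts, (gap_mid,)
    return PlastomeStructure(lsc=lsc, ira=ira, ssc=ssc, irb=irb)


# ---------------------------------------------------------------------------
# Writers


def write_regions_bed(regions: Sequence[Region], path: str | Path) -> None:
    """BED (0-based half-open) of region parts; multi-part regions emit one line per part."""
    with open(path, "w") as fh:
        for r in regions:
            for s, e in r.parts:
                fh.write(f"region\t{s}\t{e}\t{r.label}\t0\t{r.strand}\n")


def write_regions_tsv(regions: Sequence[Region], path: str | Path) -> None:
    """TSV region table; coordinates printed 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("region\tkind\tstart\tend\tlength\tstrand\tcopies\tprotein\n")
        for r in regions:
            fh.write(
                f"{r.label}\t{r.kind}\t{r.start + 1}\t{r.end}\t{r.length}\t"
                f"{r.strand}\t{r.n_copies}\t{int(r.is_protein)}\n"
            )
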