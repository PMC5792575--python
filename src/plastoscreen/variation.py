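"""SNP/indel calling and variation statistics on region-mapped alignments.

Definitions used throughout:

* SNP site -- an alignment column with at least two distinct non-gap, non-N
  states among the individuals. Gaps and Ns never create or suppress a site
  on their own; a multi-allelic column counts as one site.
* indel event -- a maximal run of adjacent gap columns sharing a constant
  gapped-individual set. A two-base deletion in one individual is one event;
  a deletion shared by three individuals is one event; overlapping gaps of
  different extent split into separate runs.
* P_V (percent of variation) -- 100 * (SNP sites + indel events) / region
  length in bp, rounded half-up to two decimals. The denominator is the
  region's length in the reference individual's ungapped coordinates.
* pi (nucleotide diversity) -- Nei's per-site pairwise diversity: the mean
  over all unordered individual pairs of (pairwise substitution differences /
  pairwise comparable sites), with pairwise deletion of gap/N columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .alignment import GAP, NCHAR, MultipleAlignment
from .genome import Feature, Interval, Region, revcomp

#: plastid / bacterial genetic code
TRANSLATION_TABLE = 11


# ---------------------------------------------------------------------------
# Coordinate projection


def map_region(aln: MultipleAlignment, region: Region) -> list[tuple[int, int]]:
    """Project a region's reference intervals onto alignment columns.

    Returns one half-open column interval per region part. The projection is
    monotone and includes gap columns interior to each part.
    """
    return [aln.columns_for(s, e) for s, e in region.parts]


def region_column_indices(aln: MultipleAlignment, region: Region) -> np.ndarray:
    """Concatenated alignment-column indices of all parts of ``region``."""
    parts = map_region(aln, region)
    return np.concatenate([np.arange(a, b) for a, b in parts])


# ---------------------------------------------------------------------------
# Site and event calling


@dataclass(frozen=True)
class SnpSite:
    """A polymorphic alignment column."""

    column: int
    ref_position: Optional[int]  # None when the reference is gapped here
    alleles: dict[str, tuple[str, ...]]  # base -> carrier individual ids

    def __post_init__(self):
        if len(self.alleles) < 2:
            raise ValueError("SnpSite needs >= 2 distinct states")


@dataclass(frozen=True)
class IndelEvent:
    """A maximal gap-column run with a constant gapped-individual set."""

    start_col: int
    end_col: int  # half-open
    gapped: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.end_col - self.start_col


def _ref_position_lookup(aln: MultipleAlignment) -> np.ndarray:
    """Column -> reference position (or -1 for insertion columns)."""
    lookup = np.full(aln.n_columns, -1, dtype=np.int64)
    lookup[aln.col_of] = np.arange(aln.reference_length)
    return lookup


def call_snp_sites(
    aln: MultipleAlignment, columns: tuple[int, int]
) -> list[SnpSite]:
    """All SNP sites within a half-open alignment-column interval."""
    a, b = columns
    st = aln.stats
    lookup = _ref_position_lookup(aln)
    sites: list[SnpSite] = []
    for col in np.flatnonzero(st.is_snp[a:b]) + a:
        column = aln.matrix[:, col]
        alleles: dict[str, list[str]] = {}
        for i, ch in enumerate(column):
            if ch not in (GAP, NCHAR):
                alleles.setdefault(chr(ch), []).append(aln.ids[i])
        rp = int(lookup[col])
        sites.append(
            SnpSite(int(col), rp if rp >= 0 else None,
                    {k: tuple(v) for k, v in alleles.items()})
        )
    return sites


def count_snp_sites(aln: MultipleAlignment, columns: tuple[int, int]) -> int:
    a, b = columns
    st = aln.stats
    return int(st.csum_snp[b] - st.csum_snp[a])


def call_indel_events(
    aln: MultipleAlignment, columns: tuple[int, int]
) -> list[IndelEvent]:
    """Indel events intersecting a column interval.

    A run touching the interval boundary counts if at least one of its gap
    columns lies inside; such a run is truncated at the boundary (and hence
    counted once per window it intersects when windows are scanned).
    """
    a, b = columns
    st = aln.stats
    events: list[IndelEvent] = []
    col = a
    while col < b:
        if not st.eligible[col]:
            col += 1
            continue
        start = col
        pattern = st.is_gap[:, col]
        col += 1
        while col < b and st.eligible[col] and not st.run_start[col]:
            col += 1
        gapped = tuple(aln.ids[i] for i in np.flatnonzero(pattern))
        events.append(IndelEvent(start, col, gapped))
    return events


def count_indel_events(aln: MultipleAlignment, columns: tuple[int, int]) -> int:
    a, b = columns
    if a >= b:
        return 0
    st = aln.stats
    n = int(st.csum_run_start[b] - st.csum_run_start[a])
    if st.eligible[a] and not st.run_start[a]:
        n += 1  # run continuing in from before the interval
    return n


# ---------------------------------------------------------------------------
# Scalar statistics


def _round_half_up(num: int, den: int, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(num) / Decimal(den)).quantize(q, rounding=ROUND_HALF_UP))


def percent_variation(n_snp: int, n_indel: int, length_bp: int) -> float:
    """P_V = 100 * (SNP sites + indel events) / length, half-up to 2 decimals."""
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    return _round_half_up(100 * (n_snp + n_indel), length_bp, 2)


def nucleotide_diversity(
    aln: MultipleAlignment,
    columns: tuple[int, int] | Sequence[tuple[int, int]],
) -> float:
    """Nei's pi over a column interval (or a list of intervals, concatenated).

    Mean over unordered pairs of (substitution differences / comparable
    sites); a pair with no comparable sites contributes 0.
    """
    if aln.n_individuals < 2:
        raise ValueError("nucleotide diversity needs >= 2 individuals")
    intervals = [columns] if isinstance(columns[0], (int, np.integer)) else list(columns)
    idx = np.concatenate([np.arange(a, b) for a, b in intervals])
    m = aln.matrix[:, idx]
    valid = aln.stats.valid[:, idx]
    n = aln.n_individuals
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comp = int(both.sum())
            if comp:
                diff = int(((m[i] != m[j]) & both).sum())
                total += diff / comp
    return total / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# Effect classification and pseudogenization


@dataclass(frozen=True)
class EffectCall:
    gene: str
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    classification: str  # 'synonymous' | 'nonsynonymous'
    stop_gained: bool = False


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate(table=TRANSLATION_TABLE))


def classify_snp_effect(
    gene: Feature, ref_seq: str, alt_allele: str, position: int
) -> EffectCall:
    """Classify a substitution inside a CDS as synonymous or nonsynonymous.

    ``gene`` must be the CDS feature (exon parts, strand); ``position`` is a
    reference genome coordinate falling inside an exon. The codon is
    assembled from the spliced, strand-oriented coding sequence and
    translated with the plastid/bacterial code (table 11); start-codon
    exceptions are ignored.
    """
    cds = "".join(ref_seq[s:e] for s, e in gene.parts)
    offset = 0
    idx = None
    for s, e in gene.parts:
        if s <= position < e:
            idx = offset + (position - s)
            break
        offset += e - s
    if idx is None:
        raise ValueError(f"position {position} outside CDS exons of {gene.name}")
    alt = alt_allele.upper()
    if gene.strand == "-":
        cds = revcomp(cds)
        idx = len(cds) - 1 - idx
        alt = revcomp(alt)
    codon_index = idx // 3
    within = idx % 3
    ref_codon = cds[3 * codon_index: 3 * codon_index + 3]
    if len(ref_codon) < 3:
        raise ValueError(f"truncated terminal codon in {gene.name}")
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1:]
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    return EffectCall(
        gene=gene.name,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        classification="synonymous" if ref_aa == alt_aa else "nonsynonymous",
        stop_gained=alt_aa == "*" and ref_aa != "*",
    )


@dataclass(frozen=True)
class PseudogeneReport:
    gene: str
    individual: str
    length: int
    ref_length: int
    frameshift: bool
    internal_stops: int
    degenerate: bool = False


def assess_reading_frame(cds_seq: str, ref_length: int) -> tuple[bool, int, bool]:
    """Frameshift flag and internal-stop count for a gap-stripped CDS.

    Frameshift iff the net indel length (observed minus annotated length) is
    not a multiple of 3. Internal stops are stop codons strictly before the
    final codon, translating in the annotated frame. A CDS shorter than one
    codon is flagged degenerate.
    """
    seq = cds_seq.upper().replace("-", "")
    if len(seq) < 3:
        return (len(seq) != ref_length and (len(seq) - ref_length) % 3 != 0, 0, True)
    frameshift = (len(seq) - ref_length) % 3 != 0
    n_codons = len(seq) // 3
    stops = 0
    for k in range(n_codons - 1):  # strictly before the final codon
        if _translate_codon(seq[3 * k: 3 * k + 3]) == "*":
            stops += 1
    return frameshift, stops, False


def detect_pseudogenization(
    aln: MultipleAlignment, gene_region: Region, individual: str
) -> PseudogeneReport:
    """Frameshift / internal-stop report for one individual at a coding region."""
    if gene_region.kind != "coding":
        raise ValueError("pseudogenization detection needs a coding region")
    idx = region_column_indices(aln, gene_region)
    row = aln.matrix[aln.index_of(individual), idx]
    seq = row[row != GAP].tobytes().decode("ascii")
    if gene_region.strand == "-":
        seq = revcomp(seq)
    frameshift, stops, degenerate = assess_reading_frame(seq, gene_region.length)
    return PseudogeneReport(
        gene=gene_region.label,
        individual=individual,
        length=len(seq.replace("-", "")),
        ref_length=gene_region.length,
        frameshift=frameshift,
        internal_stops=stops,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Pairwise differences


def _pair_indel_events(
    gi: np.ndarray, gj: np.ndarray, intervals: Sequence[tuple[int, int]]
) -> int:
    """Maximal gap runs present in exactly one of the two individuals."""
    events = 0
    for a, b in intervals:
        x = gi[a:b] ^ gj[a:b]
        if not x.any():
            continue
        who = gi[a:b]
        prev_x = np.concatenate([[False], x[:-1]])
        prev_who = np.concatenate([[False], who[:-1]])
        starts = x & (~prev_x | (who != prev_who))
        events += int(starts.sum())
    return events


def pairwise_difference_matrix(
    aln: MultipleAlignment,
    intervals: Optional[Sequence[tuple[int, int]]] = None,
):
    """Symmetric matrix of base differences between individuals.

    differences(i, j) = substitution positions (both non-gap, non-N, unequal)
    + indel events restricted to the pair (maximal gap runs present in
    exactly one of the two). Returned as a pandas DataFrame indexed by
    individual id.
    """
    import pandas as pd

    if intervals is None:
        intervals = [(0, aln.n_columns)]
    n = aln.n_individuals
    st = aln.stats
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            subs = 0
            for a, b in intervals:
                both = st.valid[i, a:b] & st.valid[j, a:b]
                subs += int(((aln.matrix[i, a:b] != aln.matrix[j, a:b]) & both).sum())
            ev = _pair_indel_events(st.is_gap[i], st.is_gap[j], intervals)
            out[i, j] = out[j, i] = subs + ev
    return pd.DataFrame(out, index=aln.ids, columns=aln.ids)


# ---------------------------------------------------------------------------
# Region summary


@dataclass
class VariationSummary:
    """Per-region (or per-window) variation record."""

    name: str
    kind: str
    length_bp: int
    n_snp: int
    n_indel: int
    p_v: float
    pi: float
    n_identified: Optional[int] = None
    pct_identified: Optional[float] = None
    n_taxa: Optional[int] = None
    identified: Optional[frozenset] = None
    is_protein: bool = True

    @property
    def pic(self) -> int:
        return self.n_snp + self.n_indel


def summarize_region(
    aln: MultipleAlignment,
    region: Region,
    discriminate: bool = True,
    compute_pi: bool = True,
) -> VariationSummary:
    """Compose mapping, site/event calling, P_V, pi and discrimination."""
    parts = map_region(aln, region)
    n_snp = sum(count_snp_sites(aln, p) for p in parts)
    n_indel = sum(count_indel_events(aln, p) for p in parts)
    pi = nucleotide_diversity(aln, parts) if compute_pi else 0.0
    summary = VariationSummary(
        name=region.label,
        kind=region.kind,
        length_bp=region.length,
        n_snp=n_snp,
        n_indel=n_indel,
        p_v=percent_variation(n_snp, n_indel, region.length),
        pi=pi,
        is_protein=region.is_protein,
    )
    if discriminate and aln.n_taxa >= 2:
        from .barcode import identified_taxa  # deferred: barcode imports variation

        result = identified_taxa(aln, parts, locus=region.label)
        summary.n_identified = result.n_identified
        summary.pct_identified = result.pct_identified
        summary.n_taxa = result.n_taxa
        summary.identified = result.identified
    return summary
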