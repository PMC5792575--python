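"""Species discrimination by unique haplotypes; single- and multi-locus barcodes.

A taxon is *identified* by a locus when no haplotype carried by any of its
individuals equals a haplotype carried by an individual of a different
taxon. Haplotypes are the individuals' rows over the locus's alignment
columns with gaps retained, so indel-only differences discriminate.
Conspecific individuals need not match each other; they must only avoid
matching other taxa.

Two headline counts are reported: ``n_identified`` applies the criterion
taxon by taxon (a pair of taxa with identical sequences are two failures),
while ``n_resolved_units`` counts distinguishable units (each class of
mutually indistinguishable taxa collapses to a single unresolved case, the
convention behind summary statements like "18 of 19 taxa discriminated"
when exactly one pair of taxa shares a plastome).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .alignment import MultipleAlignment
from .errors import ConfigError
from .genome import Region
from . import variation


@dataclass(frozen=True)
class DiscriminationResult:
    loci: tuple[str, ...]
    n_taxa: int
    identified: frozenset
    failures: frozenset
    unresolved_classes: tuple[frozenset, ...]

    @property
    def n_identified(self) -> int:
        return len(self.identified)

    @property
    def pct_identified(self) -> float:
        return pct_identified(self.n_identified, self.n_taxa)

    @property
    def n_resolved_units(self) -> int:
        """Taxa minus the collapse caused by indistinguishable classes.

        Each class of k mutually identical taxa counts as one unresolved
        unit, i.e. removes k - 1 from the taxon count.
        """
        collapsed = sum(len(c) - 1 for c in self.unresolved_classes)
        return self.n_taxa - collapsed


def pct_identified(m: int, n_taxa: int, prose: bool = False) -> float:
    """100*m/n_taxa, half-up to 2 decimals (1 decimal in prose mode)."""
    if n_taxa < 1 or not 0 <= m <= n_taxa:
        raise ValueError("need 0 <= m <= n_taxa, n_taxa >= 1")
    digits = 1 if prose else 2
    q = Decimal(1).scaleb(-digits)
    return float((Decimal(100 * m) / Decimal(n_taxa)).quantize(q, ROUND_HALF_UP))


def _haplotypes(
    aln: MultipleAlignment, intervals: Sequence[tuple[int, int]]
) -> dict[str, bytes]:
    idx = np.concatenate([np.arange(a, b) for a, b in intervals])
    return {ind: aln.matrix[i, idx].tobytes() for i, ind in enumerate(aln.ids)}


def identified_taxa(
    aln: MultipleAlignment,
    intervals: Sequence[tuple[int, int]] | tuple[int, int],
    locus: str = "locus",
) -> DiscriminationResult:
    """Apply the unique-haplotype criterion over the given column intervals."""
    if aln.n_taxa < 2:
        raise ValueError("discrimination needs >= 2 taxa")
    if isinstance(intervals[0], (int, np.integer)):
        intervals = [intervals]  # a single (start, end) pair
    haplos = _haplotypes(aln, intervals)
    taxa_of_haplo: dict[bytes, set] = {}
    for ind, h in haplos.items():
        taxa_of_haplo.setdefault(h, set()).add(aln.taxon_of[ind])
    failures = set()
    shared_classes: list[frozenset] = []
    for taxa in taxa_of_haplo.values():
        if len(taxa) > 1:
            failures |= taxa
            shared_classes.append(frozenset(taxa))
    # merge overlapping classes into connected components
    merged: list[set] = []
    for cls in shared_classes:
        hit = [m for m in merged if m & cls]
        for m in hit:
            merged.remove(m)
        merged.append(set(cls).union(*hit) if hit else set(cls))
    identified = frozenset(set(aln.taxa) - failures)
    return DiscriminationResult(
        loci=(locus,),
        n_taxa=aln.n_taxa,
        identified=identified,
        failures=frozenset(failures),
        unresolved_classes=tuple(frozenset(m) for m in merged),
    )


# ---------------------------------------------------------------------------
# Multi-locus and whole-plastome evaluation


@dataclass
class MultilocusResult:
    summary: "variation.VariationSummary"
    discrimination: DiscriminationResult


def evaluate_multilocus(
    aln: MultipleAlignment, loci: Sequence[Region]
) -> MultilocusResult:
    """Concatenate loci into one barcode and evaluate it as a single region.

    Length is the sum of locus lengths; SNP/indel counts are sums over loci
    (sites do not interact across loci); discrimination, P_V and pi are
    computed on the concatenated haplotypes.
    """
    if not loci:
        raise ConfigError("need at least one locus")
    labels = [r.label for r in loci]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"duplicate locus in list: {labels}")
    intervals: list[tuple[int, int]] = []
    n_snp = n_indel = length = 0
    for r in loci:
        parts = variation.map_region(aln, r)
        intervals.extend(parts)
        n_snp += sum(variation.count_snp_sites(aln, p) for p in parts)
        n_indel += sum(variation.count_indel_events(aln, p) for p in parts)
        length += r.length
    disc = identified_taxa(aln, intervals, locus="+".join(labels))
    summary = variation.VariationSummary(
        name="+".join(labels),
        kind="multilocus",
        length_bp=length,
        n_snp=n_snp,
        n_indel=n_indel,
        p_v=variation.percent_variation(n_snp, n_indel, length),
        pi=variation.nucleotide_diversity(aln, intervals),
        n_identified=disc.n_identified,
        pct_identified=disc.pct_identified,
        n_taxa=disc.n_taxa,
        identified=disc.identified,
    )
    return MultilocusResult(summary=summary, discrimination=disc)


def superbarcode(
    aln: MultipleAlignment,
    mask_ir2: Optional[tuple[int, int]] = None,
):
    """Evaluate the whole plastome as a single discrimination marker.

    ``mask_ir2`` optionally excludes a reference interval (the second
    inverted repeat) from the haplotypes, mirroring the common practice of
    analysing plastomes with one IR removed. Returns the discrimination
    result together with the pairwise difference matrix over the same
    columns.
    """
    if mask_ir2 is None:
        intervals = [(0, aln.n_columns)]
    else:
        a, b = aln.columns_for(*mask_ir2)
        intervals = [iv for iv in [(0, a), (b, aln.n_columns)] if iv[0] < iv[1]]
    disc = identified_taxa(aln, intervals, locus="plastome")
    matrix = variation.pairwise_difference_matrix(aln, intervals)
    return disc, matrix


def greedy_locus_selection(
    summaries: Sequence["variation.VariationSummary"], k: int
) -> list[str]:
    """Greedy forward selection of loci by newly identified taxa.

    At each step the locus adding the most not-yet-covered identified taxa
    is taken (ties: higher P_V, then name); stops at ``k`` loci or when the
    union stops growing. Summaries must carry their identified-taxon sets.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    pool = [s for s in summaries if s.identified is not None]
    covered: set = set()
    chosen: list[str] = []
    while len(chosen) < k and pool:
        best = max(
            pool,
            key=lambda s: (len(s.identified - covered), s.p_v,
                           [-ord(c) for c in s.name]),
        )
        gain = len(best.identified - covered)
        if chosen and gain == 0:
            break
        covered |= set(best.identified)
        chosen.append(best.name)
        pool = [s for s in pool if s.name != best.name]
    return chosen
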