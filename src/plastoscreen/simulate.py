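"""Synthetic plastome populations with planted, manifest-recorded mutations.

The generator emulates a low-divergence congeneric plastome set: a circular
~137.7 kb reference with quadripartite LSC/IRa/SSC/IRb structure (exact
reverse-complement IRs), 127 annotated genes (81 protein-coding, 38 tRNA,
8 rRNA, counting inverted-repeat duplicates twice), spliced genes with
introns, and a three-copy gene (one single-copy pseudogene-prone copy next
to a large-subunit rubisco analogue, two IR copies) mirroring the rpl23
arrangement of grass plastomes.

Individuals are derived from the reference on a star phylogeny: every
mutation (substitution, or a mostly single-base indel) is planted
independently per lineage and recorded in a truth manifest that fully
determines the true alignment. Special plans produce one identical pair of
taxa, one taxon with two divergent conspecific individuals, one taxon pair
of near-identical individuals differing by two indels only, one individual
with a frameshifting insertion in the single-copy rpl23 analogue, and one
concentrated mutation hotspot around it. Planted events are kept mutually
non-adjacent and within single regions (by rejection) so that region-level
SNP/indel counts recovered by the pipeline equal the manifest exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alignment import GAP, MultipleAlignment
from .errors import ConfigError, StageError
from .genome import (
    AnnotatedPlastome,
    Feature,
    PlastomeStructure,
    Region,
    extract_regions,
    revcomp,
)
from .variation import classify_snp_effect

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _codon_weights(gc: float) -> np.ndarray:
    """Codon sampling weights for a target coding GC content."""
    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}
    w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in _CODONS])
    return w / w.sum()


_CODON_P = _codon_weights(gc=0.37)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimulationConfig:
    """Study-condition defaults: 21 individuals, 19 taxa, ~137.7 kb genomes.

    Substitution and indel rates are per base pair per lineage; spacers are
    the most mutable, coding regions the least, so that pairwise plastome
    identity stays >= 99.7% while the most divergent pair accumulates a few
    hundred base differences. Indels are 90% single-base, 10% two-base.
    """

    seed: int = 1
    # architecture (bp)
    lsc_len: int = 81_700
    ssc_len: int = 12_836
    ir_len: int = 21_616
    # gene plan (protein-coding / tRNA / rRNA; IR genes are duplicated)
    n_lsc_protein: int = 54
    n_ssc_protein: int = 11
    n_ir_protein: int = 8
    n_lsc_trna: int = 22
    n_ir_trna: int = 8
    n_ir_rrna: int = 4
    # population
    n_individuals: int = 21
    n_taxa: int = 19
    # mutation model (per bp per lineage)
    sub_rate: dict = field(
        default_factory=lambda: {"coding": 2.5e-4, "intron": 1.0e-3, "spacer": 2.0e-3}
    )
    indel_rate: dict = field(
        default_factory=lambda: {"coding": 0.0, "intron": 4.0e-4, "spacer": 6.0e-4}
    )
    indel_len_probs: dict = field(default_factory=lambda: {1: 0.9, 2: 0.1})
    # special plans
    identical_pair: bool = True
    near_pair: bool = True
    frameshift: bool = True
    hotspot: bool = True
    hotspot_n_sub: int = 50
    hotspot_n_indel: int = 10
    max_tries: int = 2000

    def validate(self) -> None:
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ConfigError("architecture lengths must be positive")
        if any(v < 0 for v in {**self.sub_rate, **self.indel_rate}.values()):
            raise ConfigError("rates must be >= 0")
        if self.n_individuals < self.n_taxa:
            raise ConfigError("need n_individuals >= n_taxa")


@dataclass(frozen=True)
class MutationRecord:
    """One planted mutation; ``position`` is a reference coordinate
    (insertions go immediately before it)."""

    type: str  # 'substitution' | 'insertion' | 'deletion'
    position: int
    length: int
    carriers: tuple[str, ...]
    region: str
    alt: str = ""
    effect: Optional[str] = None


@dataclass
class SimulatedPopulation:
    reference: AnnotatedPlastome
    config: SimulationConfig
    alignment: MultipleAlignment
    sequences: dict[str, str]
    taxon_of: dict[str, str]
    manifest: list[MutationRecord]
    regions: list[Region]
    roles: dict


def manifest_region_counts(manifest: Sequence[MutationRecord]) -> dict[str, list[int]]:
    """Region label -> [n substitution events, n indel events]."""
    counts: dict[str, list[int]] = {}
    for ev in manifest:
        c = counts.setdefault(ev.region, [0, 0])
        c[0 if ev.type == "substitution" else 1] += 1
    return counts


# ---------------------------------------------------------------------------
# Reference construction


@dataclass(frozen=True)
class GeneSpec:
    name: str
    subkind: str  # CDS | tRNA | rRNA
    exons: tuple[int, ...]
    introns: tuple[int, ...] = ()
    strand: str = "+"

    @property
    def span(self) -> int:
        return sum(self.exons) + sum(self.introns)


def _features_for(spec: GeneSpec, pos: int) -> list[Feature]:
    parts = []
    cursor = pos
    for k, ex in enumerate(spec.exons):
        parts.append((cursor, cursor + ex))
        cursor += ex
        if k < len(spec.introns):
            cursor += spec.introns[k]
    gene = Feature(spec.name, "gene", ((pos, pos + spec.span),), spec.strand)
    sub = Feature(spec.name, spec.subkind, tuple(parts), spec.strand)
    return [gene, sub]


def _place_segment(
    rng: np.random.Generator,
    specs: Sequence[GeneSpec],
    seg_start: int,
    seg_len: int,
    first_gap: Optional[int] = None,
    fixed_gaps: Optional[dict[int, int]] = None,
    min_gap: int = 10,
) -> tuple[list[tuple[GeneSpec, int]], list[Feature]]:
    """Place genes in order within a segment, distributing spacer slack randomly.

    ``fixed_gaps`` pins specific gap slots (slot g is the gap before gene g;
    slot 0 precedes the first gene) to exact widths.
    """
    total_span = sum(s.span for s in specs)
    n_gaps = len(specs) + 1
    fixed = dict(fixed_gaps or {})
    if first_gap is not None:
        fixed[0] = first_gap
    free = seg_len - total_span - sum(fixed.values())
    n_free_gaps = n_gaps - len(fixed)
    free -= min_gap * n_free_gaps
    if free < 0:
        raise ConfigError(
            f"segment of {seg_len} bp too small for gene plan ({total_span} bp of genes)"
        )
    extra = rng.multinomial(free, np.full(n_free_gaps, 1.0 / n_free_gaps))
    gaps = []
    k = 0
    for g in range(n_gaps):
        if g in fixed:
            gaps.append(fixed[g])
        else:
            gaps.append(min_gap + int(extra[k]))
            k += 1
    placed: list[tuple[GeneSpec, int]] = []
    features: list[Feature] = []
    pos = seg_start + gaps[0]
    for i, spec in enumerate(specs):
        placed.append((spec, pos))
        features.extend(_features_for(spec, pos))
        pos += spec.span + gaps[i + 1]
    assert pos == seg_start + seg_len
    return placed, features


def _random_cds(rng: np.random.Generator, length: int) -> str:
    assert length % 3 == 0 and length >= 9
    n_mid = length // 3 - 2
    mid = "".join(rng.choice(_CODONS, size=n_mid, p=_CODON_P))
    return "ATG" + mid + "TAA"


def _fill_bases(rng: np.random.Generator, out: np.ndarray, start: int, end: int,
                gc: float) -> None:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    out[start:end] = rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8), size=end - start, p=p
    )


def _write_seq(out: np.ndarray, start: int, seq: str) -> None:
    out[start:start + len(seq)] = np.frombuffer(seq.encode(), dtype=np.uint8)


def _pc_lengths(rng: np.random.Generator, n: int, lo: int = 100,
                hi: int = 434) -> list[int]:
    """Random CDS lengths in codons * 3 (default 300-1299 bp)."""
    return [int(rng.integers(lo, hi)) * 3 for _ in range(n)]


def generate_reference(config: SimulationConfig) -> AnnotatedPlastome:
    """Deterministically build the annotated reference plastome for ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    lsc = (0, config.lsc_len)
    ira = (lsc[1], lsc[1] + config.ir_len)
    ssc = (ira[1], ira[1] + config.ssc_len)
    irb = (ssc[1], ssc[1] + config.ir_len)
    L = irb[1]

    def strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    # --- LSC plan: a fixed rbcL / rpl23 / psaI neighbourhood plus generics.
    trio = [
        GeneSpec("rbcL", "CDS", (1434,), strand="+"),
        GeneSpec("rpl23", "CDS", (285,), strand="+"),
        GeneSpec("psaI", "CDS", (102,), strand="+"),
    ]
    spliced = [
        GeneSpec("atpF", "CDS", (144, 411), (700,), strand()),
        GeneSpec("rps16", "CDS", (39, 186), (860,), strand()),
        GeneSpec("ycf3", "CDS", (126, 228, 153), (720, 730), strand()),
    ]
    n_generic = config.n_lsc_protein - len(trio) - len(spliced)
    if n_generic < 0:
        raise ConfigError("n_lsc_protein too small for the fixed gene plan")
    generics = [
        GeneSpec(f"pcg{k + 1:02d}", "CDS", (l,), strand=strand())
        for k, l in enumerate(_pc_lengths(rng, n_generic))
    ]
    trnas = [
        GeneSpec(f"trn{chr(65 + k // 2)}{k % 2 + 1}", "tRNA",
                 (int(rng.integers(70, 91)),), strand=strand())
        for k in range(config.n_lsc_trna)
    ]
    lsc_specs = spliced + generics + trnas
    order = list(rng.permutation(len(lsc_specs)))
    lsc_specs = [lsc_specs[i] for i in order]
    # keep the trio adjacent mid-segment with grass-like fixed spacers
    at = len(lsc_specs) // 2
    lsc_specs = lsc_specs[:at] + trio + lsc_specs[at:]
    # gap slots: before rpl23 (rbcL-rpl23 spacer) and before psaI
    trio_gaps = {at + 1: 274, at + 2: 350}

    # --- SSC plan
    ssc_specs = [GeneSpec("ndhA", "CDS", (553, 536), (1080,), strand()),
                 GeneSpec("ndhF", "CDS", (2220,), strand=strand())]
    ssc_specs += [
        GeneSpec(f"sscg{k + 1:02d}", "CDS", (l,), strand=strand())
        for k, l in enumerate(_pc_lengths(rng, config.n_ssc_protein - 2, hi=300))
    ]

    # --- IR plan (placed in IRa, mirrored into IRb)
    ir_specs = [GeneSpec("rpl23", "CDS", (282,), strand="+"),
                GeneSpec("ycf2", "CDS", (6000,), strand=strand())]
    ir_specs += [
        GeneSpec(f"irg{k + 1:02d}", "CDS", (l,), strand=strand())
        for k, l in enumerate(_pc_lengths(rng, config.n_ir_protein - 2, hi=300))
    ]
    ir_specs += [
        GeneSpec(f"trnR{k + 1}", "tRNA", (int(rng.integers(70, 91)),),
                 strand=strand())
        for k in range(config.n_ir_trna)
    ]
    rrna_lens = [1491, 2880, 120, 102]
    ir_specs += [
        GeneSpec(f"rrn{k + 1}", "rRNA", (rrna_lens[k % 4],), strand=strand())
        for k in range(config.n_ir_rrna)
    ]
    ir_specs = [ir_specs[i] for i in rng.permutation(len(ir_specs))]

    features: list[Feature] = []
    placed_lsc, f = _place_segment(rng, lsc_specs, lsc[0], config.lsc_len,
                                   first_gap=0, fixed_gaps=trio_gaps)
    features += f
    placed_ira, f = _place_segment(rng, ir_specs, ira[0], config.ir_len)
    features += f
    placed_ssc, f = _place_segment(rng, ssc_specs, ssc[0], config.ssc_len)
    features += f

    # --- sequence
    # non-coding fill; coding tracts are overwritten below. IR intergenic DNA
    # and rRNA bodies are GC-rich, single-copy intergenic DNA is AT-rich, so
    # the quadripartite GC profile echoes real plastomes (IR > LSC > SSC).
    seq = np.empty(L, dtype=np.uint8)
    _fill_bases(rng, seq, lsc[0], lsc[1], gc=0.34)
    _fill_bases(rng, seq, ira[0], ira[1], gc=0.55)
    _fill_bases(rng, seq, ssc[0], ssc[1], gc=0.30)
    for placed in (placed_lsc, placed_ira, placed_ssc):
        for spec, pos in placed:
            if spec.subkind != "CDS":
                continue
            cds = _random_cds(rng, sum(spec.exons))
            genomic = revcomp(cds) if spec.strand == "-" else cds
            cursor = pos
            offset = 0
            for k, ex in enumerate(spec.exons):
                _write_seq(seq, cursor, genomic[offset:offset + ex])
                offset += ex
                cursor += ex
                if k < len(spec.introns):
                    cursor += spec.introns[k]

    # --- IRb: exact reverse complement of IRa, with mirrored annotations
    ira_seq = seq[ira[0]:ira[1]].tobytes().decode()
    _write_seq(seq, irb[0], revcomp(ira_seq))
    for feat in [f for f in features if ira[0] <= f.parts[0][0] < ira[1]]:
        mirrored_parts = tuple(
            sorted(
                (irb[0] + (config.ir_len - (e - ira[0])),
                 irb[0] + (config.ir_len - (s - ira[0])))
                for s, e in feat.parts
            )
        )
        flipped = "-" if feat.strand == "+" else "+"
        features.append(Feature(feat.name, feat.kind, mirrored_parts, flipped))

    structure = PlastomeStructure(lsc=(lsc,), ira=ira, ssc=(ssc,), irb=irb)
    return AnnotatedPlastome(
        id=f"simref_seed{config.seed}",
        sequence=seq.tobytes().decode("ascii"),
        features=features,
        structure=structure,
    )


# ---------------------------------------------------------------------------
# Mutation planting


class _Planter:
    """Plants non-colliding mutations on a reference and records the manifest.

    Collisions avoided by rejection: substitutions occupy globally distinct
    positions; indels never overlap, touch each other, sit next to a planted
    substitution, or cross a region boundary.
    """

    def __init__(self, reference: AnnotatedPlastome, regions: Sequence[Region],
                 rng: np.random.Generator, config: SimulationConfig):
        self.ref = reference
        self.rng = rng
        self.config = config
        self.regions = list(regions)
        L = reference.length
        self.region_id = np.full(L, -1, dtype=np.int32)
        kind_code = {"coding": 0, "intron": 1, "spacer": 2}
        self.kind_id = np.full(L, -1, dtype=np.int8)
        for ri, r in enumerate(self.regions):
            for s, e in r.parts:
                self.region_id[s:e] = ri
                self.kind_id[s:e] = kind_code[r.kind]
        self.kind_positions = {
            k: np.flatnonzero(self.kind_id == c) for k, c in kind_code.items()
        }
        self.sub_taken = np.zeros(L, dtype=bool)
        self.indel_blocked = np.zeros(L, dtype=bool)
        self.events: list[MutationRecord] = []
        self.seq = reference.sequence

    # -- helpers

    def _region_at(self, pos: int) -> Region:
        return self.regions[self.region_id[pos]]

    def _effect(self, pos: int, alt: str) -> Optional[str]:
        r = self._region_at(pos)
        if r.kind != "coding" or not r.is_protein:
            return None
        cds = Feature(r.name, "CDS", r.parts, r.strand)
        try:
            return classify_snp_effect(cds, self.seq, alt, pos).classification
        except ValueError:
            return None

    def plant_substitution(
        self, carriers: tuple[str, ...], kind: Optional[str] = None,
        pool: Optional[np.ndarray] = None,
    ) -> MutationRecord:
        rng = self.rng
        candidates = pool if pool is not None else self.kind_positions[kind]
        for _ in range(self.config.max_tries):
            pos = int(candidates[rng.integers(len(candidates))])
            if self.sub_taken[pos] or self.indel_blocked[pos]:
                continue
            ref_base = self.seq[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            self.sub_taken[pos] = True
            ev = MutationRecord(
                "substitution", pos, 1, carriers,
                self._region_at(pos).label, alt=str(alt),
                effect=self._effect(pos, str(alt)),
            )
            self.events.append(ev)
            return ev
        raise StageError(
            "could not place a substitution without collision; lower the rates"
        )

    def plant_indel(
        self, carriers: tuple[str, ...], kind: Optional[str] = None,
        pool: Optional[np.ndarray] = None, itype: Optional[str] = None,
        length: Optional[int] = None,
    ) -> MutationRecord:
        rng = self.rng
        candidates = pool if pool is not None else self.kind_positions[kind]
        lens = sorted(self.config.indel_len_probs)
        probs = [self.config.indel_len_probs[l] for l in lens]
        for _ in range(self.config.max_tries):
            ln = length if length is not None else int(rng.choice(lens, p=probs))
            t = itype if itype is not None else ("insertion" if rng.random() < 0.5
                                                 else "deletion")
            pos = int(candidates[rng.integers(len(candidates))])
            span = ln if t == "deletion" else 0
            lo, hi = pos - 1, pos + span + 1
            if lo < 0 or hi > len(self.seq):
                continue
            if t == "deletion" and self.region_id[pos] != self.region_id[pos + ln - 1]:
                continue
            if t == "insertion" and self.region_id[pos - 1] != self.region_id[pos]:
                continue
            if self.indel_blocked[lo:hi].any() or self.sub_taken[lo:hi].any():
                continue
            self.indel_blocked[lo:hi] = True
            alt = ""
            if t == "insertion":
                alt = "".join(rng.choice(list("ACGT"), size=ln))
            ev = MutationRecord(t, pos, ln, carriers, self._region_at(pos).label,
                                alt=alt)
            self.events.append(ev)
            return ev
        raise StageError(
            "could not place an indel without collision; lower the indel rates"
        )


# ---------------------------------------------------------------------------
# Population simulation


def default_taxon_plan(n_individuals: int = 21, n_taxa: int = 19):
    """Individual ids, taxon mapping and special-role assignments.

    Two taxa carry two individuals each (a divergent conspecific pair and a
    near-identical pair); two further single-individual taxa are planned to
    be identical to each other; one individual carries the frameshift plan.
    """
    if n_individuals - n_taxa not in (0, 1, 2):
        raise ConfigError("plan supports n_individuals - n_taxa in {0, 1, 2}")
    ids = [f"ind{k + 1:02d}" for k in range(n_individuals)]
    taxa = [f"T{k + 1:02d}" for k in range(n_taxa)]
    multi = []
    if n_individuals - n_taxa >= 1:
        multi.append("T03")  # divergent conspecifics
    if n_individuals - n_taxa >= 2:
        multi.append("T06")  # near-identical conspecifics
    taxon_of: dict[str, str] = {}
    it = iter(ids)
    roles: dict = {}
    for t in taxa:
        ind = next(it)
        taxon_of[ind] = t
        if t in multi:
            second = next(it)
            taxon_of[second] = t
            roles["divergent_pair" if t == "T03" else "near_pair"] = (ind, second)
    singles = [i for i in ids if list(taxon_of.values()).count(taxon_of[i]) == 1]
    roles["reference"] = ids[0]
    pool = [i for i in singles if i != ids[0]]
    if len(pool) >= 3:
        roles["identical_pair"] = (pool[-2], pool[-1])
        roles["frameshift"] = pool[len(pool) // 2]
    return ids, taxon_of, roles


def simulate_population(
    reference: AnnotatedPlastome, config: SimulationConfig
) -> SimulatedPopulation:
    """Plant mutations on the reference and build the true alignment."""
    config.validate()
    rng = np.random.default_rng(config.seed + 104729)  # distinct stream from the reference
    regions = extract_regions(reference)
    planter = _Planter(reference, regions, rng, config)
    ids, taxon_of, roles = default_taxon_plan(config.n_individuals, config.n_taxa)

    # individuals whose planted events are shared with a partner
    group_of: dict[str, tuple[str, ...]] = {i: (i,) for i in ids}
    if config.identical_pair and "identical_pair" in roles:
        a, b = roles["identical_pair"]
        group_of[a] = group_of[b] = (a, b)
    if config.near_pair and "near_pair" in roles:
        a, b = roles["near_pair"]
        group_of[a] = group_of[b] = (a, b)
    shadowed = {grp[1] for grp in group_of.values() if len(grp) > 1}
    lineages = [i for i in ids if i not in shadowed]

    kind_len = {k: len(v) for k, v in planter.kind_positions.items()}

    # background mutations, star phylogeny
    for ind in lineages:
        carriers = group_of[ind]
        for kind in ("coding", "intron", "spacer"):
            for _ in range(rng.poisson(config.sub_rate[kind] * kind_len[kind])):
                planter.plant_substitution(carriers, kind=kind)
            if ind == roles.get("reference"):
                continue  # the coordinate anchor stays indel-free
            for _ in range(rng.poisson(config.indel_rate[kind] * kind_len[kind])):
                planter.plant_indel(carriers, kind=kind)

    # near pair: the second individual differs by exactly two extra indels
    if config.near_pair and "near_pair" in roles:
        _, second = roles["near_pair"]
        planter.plant_indel((second,), kind="spacer", length=1)
        planter.plant_indel((second,), kind="intron", length=1)

    rpl23_lsc = next(
        (r for r in regions if r.name == "rpl23" and r.copy_index == 1), None
    )

    # frameshifting single-base insertion in the single-copy rpl23 analogue
    if config.frameshift and rpl23_lsc is not None and "frameshift" in roles:
        s, e = rpl23_lsc.parts[0]
        pool = np.arange(s + 10, e - 10)
        planter.plant_indel((roles["frameshift"],), pool=pool,
                            itype="insertion", length=1)

    # concentrated hotspot around the single-copy rpl23 analogue
    if config.hotspot and rpl23_lsc is not None:
        h = max(0, ((rpl23_lsc.start - 150) // 100) * 100)
        lo, hi = h + 2, min(h + 598, reference.length - 2)
        window_pool = np.arange(lo, hi)
        noncoding_pool = window_pool[planter.kind_id[window_pool] != 0]
        donors = [i for i in ids if i != roles.get("reference")]
        for _ in range(config.hotspot_n_sub):
            ind = donors[rng.integers(len(donors))]
            planter.plant_substitution(group_of[ind], pool=window_pool)
        for _ in range(config.hotspot_n_indel):
            ind = donors[rng.integers(len(donors))]
            planter.plant_indel(group_of[ind], pool=noncoding_pool)
        roles["hotspot"] = (h, h + 600)

    alignment, sequences = build_alignment(
        reference, planter.events, ids, taxon_of, reference_id=roles["reference"]
    )
    return SimulatedPopulation(
        reference=reference,
        config=config,
        alignment=alignment,
        sequences=sequences,
        taxon_of=taxon_of,
        manifest=planter.events,
        regions=regions,
        roles=roles,
    )


def build_alignment(
    reference: AnnotatedPlastome,
    events: Sequence[MutationRecord],
    ids: Sequence[str],
    taxon_of: dict[str, str],
    reference_id: str,
) -> tuple[MultipleAlignment, dict[str, str]]:
    """Build the true alignment analytically from the manifest.

    Every insertion contributes its own block of columns, gapped in all
    non-carriers; deletions gap the carriers at the deleted reference
    columns. Stripping gaps from a row reproduces that individual's
    unaligned sequence exactly.
    """
    L = reference.length
    ref_arr = np.frombuffer(reference.sequence.encode(), dtype=np.uint8)
    ins = sorted(
        (e for e in events if e.type == "insertion"), key=lambda e: e.position
    )
    ins_pos = np.array([e.position for e in ins], dtype=np.int64)
    ins_len = np.array([e.length for e in ins], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(ins_len)])
    total = L + int(cum[-1])
    ref_cols = np.arange(L) + cum[np.searchsorted(ins_pos, np.arange(L), side="right")]

    per_ind_sub: dict[str, list[tuple[int, str]]] = {i: [] for i in ids}
    per_ind_del: dict[str, list[tuple[int, int]]] = {i: [] for i in ids}
    for e in events:
        if e.type == "substitution":
            for c in e.carriers:
                per_ind_sub[c].append((e.position, e.alt))
        elif e.type == "deletion":
            for c in e.carriers:
                per_ind_del[c].append((e.position, e.length))

    rows: list[str] = []
    sequences: dict[str, str] = {}
    for ind in ids:
        base = ref_arr.copy()
        for pos, alt in per_ind_sub[ind]:
            base[pos] = ord(alt)
        for pos, ln in per_ind_del[ind]:
            base[pos:pos + ln] = GAP
        arr = np.full(total, GAP, dtype=np.uint8)
        arr[ref_cols] = base
        for k, e in enumerate(ins):
            if ind in e.carriers:
                start = e.position + int(cum[k])
                arr[start:start + e.length] = np.frombuffer(
                    e.alt.encode(), dtype=np.uint8
                )
        row = arr.tobytes().decode("ascii")
        rows.append(row)
        sequences[ind] = row.replace("-", "")
    aln = MultipleAlignment(list(ids), rows, taxon_of=taxon_of,
                            reference_id=reference_id)
    return aln, sequences


# ---------------------------------------------------------------------------
# Compact worked-example fixture


#: (name, subkind, exon lengths, intron lengths, strand) | explicit gap to next gene
_FIXTURE_LAYOUT = [
    ("trnH", "tRNA", (74,), (), "+", 5),
    ("rps19", "CDS", (279,), (), "-", 160),
    ("psbA", "CDS", (1062,), (), "-", 300),
    ("atpE", "CDS", (414,), (), "+", 288),
    ("rbcL", "CDS", (1434,), (), "+", 274),
    ("rpl23", "CDS", (285,), (), "+", 350),
    ("psaI", "CDS", (102,), (), "+", 400),
    ("psbK", "CDS", (186,), (), "+", 408),
    ("psbI", "CDS", (111,), (), "+", 300),
    ("ndhH", "CDS", (1182,), (), "+", 95),
    ("ndhF", "CDS", (2220,), (), "-", 916),
    ("rpl32", "CDS", (165,), (), "+", 895),
    ("ccsA", "CDS", (975,), (), "+", 280),
    ("petA", "CDS", (963,), (), "+", 822),
    ("psbJ", "CDS", (123,), (), "-", 200),
    ("matK", "CDS", (1530,), (), "+", 240),
    ("rps16", "CDS", (39, 186), (860,), "+", 150),
]

#: region label -> (planted substitution events, planted indel events)
FIXTURE_PLAN = {
    "rps19-psbA": (4, 2),
    "atpE": (3, 0),
    "rbcL": (8, 0),
    "rbcL-rpl23": (1, 2),
    "rpl23": (8, 1),
    "psbK-psbI": (1, 6),
    "ndhH": (5, 0),
    "ndhF-rpl32": (7, 3),
    "rpl32-ccsA": (4, 3),
    "ccsA": (4, 1),
    "petA-psbJ": (6, 2),
}

#: the six best-performing loci evaluated as one multi-locus barcode
FIXTURE_MULTILOCUS = ["ndhH", "rpl23", "ndhF-rpl32", "rpl32-ccsA",
                      "psbK-psbI", "petA-psbJ"]


def fixture_reference(seed: int = 0) -> AnnotatedPlastome:
    """A ~13 kb single-copy mini-plastome with fixed gene/spacer geometry."""
    rng = np.random.default_rng(seed)
    features: list[Feature] = []
    pos = 0
    spans = []
    for name, subkind, exons, introns, strand, gap in _FIXTURE_LAYOUT:
        spec = GeneSpec(name, subkind, exons, introns, strand)
        spans.append((spec, pos))
        features.extend(_features_for(spec, pos))
        pos += spec.span + gap
    L = pos
    seq = np.empty(L, dtype=np.uint8)
    _fill_bases(rng, seq, 0, L, gc=0.38)
    for spec, p in spans:
        if spec.subkind != "CDS":
            continue
        cds = _random_cds(rng, sum(spec.exons))
        genomic = revcomp(cds) if spec.strand == "-" else cds
        cursor, offset = p, 0
        for k, ex in enumerate(spec.exons):
            _write_seq(seq, cursor, genomic[offset:offset + ex])
            offset += ex
            cursor += ex
            if k < len(spec.introns):
                cursor += spec.introns[k]
    return AnnotatedPlastome(
        id="fixture_ref", sequence=seq.tobytes().decode("ascii"), features=features
    )


def worked_example_fixture(seed: int = 0) -> SimulatedPopulation:
    """Deterministic mini-population with exact per-region SNP/indel counts.

    Plants the counts in :data:`FIXTURE_PLAN` (chosen to reproduce the
    worked-example P_V values, e.g. 8 SNPs + 1 indel in the 285 bp rpl23
    analogue, 4 + 2 in the 160 bp rps19-psbA spacer) on a population of 21
    individuals from 19 taxa. The rpl23 indel is a frameshifting single-base
    insertion. Counts are independent of the seed; only base composition,
    positions and carriers vary with it.
    """
    config = SimulationConfig(
        seed=seed, identical_pair=False, near_pair=False, frameshift=False,
        hotspot=False,
    )
    reference = fixture_reference(seed)
    rng = np.random.default_rng(seed + 7919)
    regions = extract_regions(reference)
    planter = _Planter(reference, regions, rng, config)
    ids, taxon_of, roles = default_taxon_plan(config.n_individuals, config.n_taxa)
    donors = ids[1:]  # keep ind01 as the untouched coordinate anchor
    by_label = {r.label: r for r in regions}
    for label, (n_sub, n_indel) in FIXTURE_PLAN.items():
        r = by_label[label]
        pool = np.concatenate([np.arange(s + 2, e - 2) for s, e in r.parts])
        for _ in range(n_sub):
            ind = donors[rng.integers(len(donors))]
            planter.plant_substitution((ind,), pool=pool)
        for k in range(n_indel):
            ind = donors[rng.integers(len(donors))]
            if label == "rpl23":  # the pseudogenizing frameshift insertion
                planter.plant_indel((ind,), pool=pool, itype="insertion", length=1)
            else:
                planter.plant_indel((ind,), pool=pool, length=1)
    alignment, sequences = build_alignment(
        reference, planter.events, ids, taxon_of, reference_id=ids[0]
    )
    return SimulatedPopulation(
        reference=reference, config=config, alignment=alignment,
        sequences=sequences, taxon_of=taxon_of, manifest=planter.events,
        regions=regions, roles=roles,
    )


# ---------------------------------------------------------------------------
# Writers


def write_reference_fasta(genome: AnnotatedPlastome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for k in range(0, genome.length, 70):
            fh.write(genome.sequence[k:k + 70] + "\n")


def write_reference_genbank(genome: AnnotatedPlastome, path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(Seq(genome.sequence), id=genome.id[:16], name=genome.id[:16],
                       description="synthetic plastome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular"
    for f in genome.features:
        strand = 1 if f.strand == "+" else -1
        locs = [FeatureLocation(s, e, strand) for s, e in f.parts]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        record.features.append(SeqFeature(loc, type=f.kind,
                                          qualifiers={"gene": [f.name]}))
    from Bio import SeqIO

    SeqIO.write(record, str(path), "genbank")


def write_reference_gff3(genome: AnnotatedPlastome, path: str | Path) -> None:
    """GFF3 with one gene line per gene feature and Parent-linked subfeatures."""
    lines = ["##gff-version 3",
             f"##sequence-region {genome.id} 1 {genome.length}"]
    gene_count: dict[str, int] = {}
    genes = [f for f in genome.features if f.kind == "gene"]
    subs = [f for f in genome.features if f.kind != "gene"]
    for g in sorted(genes, key=lambda f: f.span[0]):
        gene_count[g.name] = gene_count.get(g.name, 0) + 1
        gid = f"gene-{g.name}-{gene_count[g.name]}"
        s, e = g.span
        lines.append(
            f"{genome.id}\tplastoscreen\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
            f"ID={gid};Name={g.name}"
        )
        for sub in subs:
            fs, fe = sub.span
            if sub.name == g.name and fs >= s and fe <= e:
                for k, (ps, pe) in enumerate(sub.parts):
                    phase = "0" if sub.kind == "CDS" else "."
                    lines.append(
                        f"{genome.id}\tplastoscreen\t{sub.kind}\t{ps + 1}\t{pe}\t.\t"
                        f"{sub.strand}\t{phase}\tID={gid}.{sub.kind}.{k + 1};"
                        f"Parent={gid};Name={g.name}"
                    )
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest_tsv(manifest: Sequence[MutationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("type\tposition\tlength\tcarriers\tregion\talt\teffect\n")
        for e in manifest:
            fh.write(
                f"{e.type}\t{e.position}\t{e.length}\t{','.join(e.carriers)}\t"
                f"{e.region}\t{e.alt}\t{e.effect or ''}\n"
            )


def write_population_fasta(pop: SimulatedPopulation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind, seq in pop.sequences.items():
            fh.write(f">{ind}\n")
            for k in range(0, len(seq), 70):
                fh.write(seq[k:k + 70] + "\n")
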