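"""Whole-plastome multiple alignment container.

Rows are individuals, columns are alignment positions over {A,C,G,T,N,-}.
One designated individual (the reference) anchors region coordinates: its
ungapped positions define the genome coordinate system that regions and
sliding windows are expressed in. Any character outside A/C/G/T/- is
normalized to N and treated as missing data.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .errors import InputParseError

GAP = ord("-")
NCHAR = ord("N")
_BASES = tuple(ord(b) for b in "ACGT")


@dataclass(frozen=True)
class ColumnStats:
    """Per-column summaries precomputed once per alignment (lazy).

    ``run_start`` marks the first column of each maximal run of adjacent gap
    columns sharing a constant gapped-individual set -- the unit counted as
    one indel event. All-gap columns (impossible in practice) are excluded.
    """

    is_gap: np.ndarray          # (n, L) bool
    valid: np.ndarray           # (n, L) bool: not gap, not N
    is_snp: np.ndarray          # (L,) bool: >=2 distinct non-gap non-N states
    eligible: np.ndarray        # (L,) bool: gap column, not all-gap
    run_start: np.ndarray       # (L,) bool
    csum_snp: np.ndarray        # (L+1,) int
    csum_run_start: np.ndarray  # (L+1,) int


class MultipleAlignment:
    """Equal-length gapped sequences keyed by individual, with taxon mapping."""

    def __init__(
        self,
        ids: Sequence[str],
        rows: Sequence[str],
        taxon_of: Optional[Mapping[str, str]] = None,
        reference_id: Optional[str] = None,
    ):
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in length")
        if len(set(ids)) != len(ids):
            raise InputParseError("duplicate individual ids in alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise InputParseError(f"rows have unequal lengths: {sorted(lengths)}")
        self.ids = list(ids)
        mat = np.frombuffer(
            "".join(r.upper() for r in rows).encode("ascii"), dtype=np.uint8
        ).reshape(len(rows), -1).copy()
        # normalize everything outside {A,C,G,T,-} to N (missing data)
        known = np.zeros(256, dtype=bool)
        for b in _BASES + (GAP,):
            known[b] = True
        mat[~known[mat]] = NCHAR
        self.matrix = mat
        self.taxon_of = dict(taxon_of) if taxon_of else {i: i for i in self.ids}
        missing = [i for i in self.ids if i not in self.taxon_of]
        if missing:
            raise InputParseError(f"individuals missing from sample sheet: {missing}")
        self.reference_id = reference_id or self.ids[0]
        if self.reference_id not in self.ids:
            raise ValueError(f"reference id {self.reference_id!r} not in alignment")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def taxa(self) -> list[str]:
        return sorted(set(self.taxon_of[i] for i in self.ids))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def index_of(self, individual: str) -> int:
        return self.ids.index(individual)

    def row(self, individual: str) -> np.ndarray:
        return self.matrix[self.index_of(individual)]

    @cached_property
    def col_of(self) -> np.ndarray:
        """Alignment column of each reference (ungapped) position."""
        ref = self.matrix[self.index_of(self.reference_id)]
        return np.flatnonzero(ref != GAP)

    @property
    def reference_length(self) -> int:
        return int(self.col_of.size)

    def columns_for(self, start: int, end: int) -> tuple[int, int]:
        """Alignment-column interval spanning reference positions [start, end).

        Includes gap columns interior to the region (insertions relative to
        the reference) but not those immediately following its last base.
        """
        if not (0 <= start < end <= self.reference_length):
            raise ValueError(
                f"reference interval [{start},{end}) outside "
                f"[0,{self.reference_length})"
            )
        return int(self.col_of[start]), int(self.col_of[end - 1]) + 1

    # -- cached column statistics -----------------------------------------

    @cached_property
    def stats(self) -> ColumnStats:
        m = self.matrix
        is_gap = m == GAP
        valid = (m != GAP) & (m != NCHAR)
        n_states = np.zeros(m.shape[1], dtype=np.int8)
        for b in _BASES:
            n_states += (m == b).any(axis=0)
        is_snp = n_states >= 2
        gap_any = is_gap.any(axis=0)
        gap_all = is_gap.all(axis=0)
        eligible = gap_any & ~gap_all
        pat = np.packbits(is_gap, axis=0)
        same_prev = np.concatenate(
            [[False], (pat[:, 1:] == pat[:, :-1]).all(axis=0)]
        )
        prev_eligible = np.concatenate([[False], eligible[:-1]])
        run_start = eligible & ~(prev_eligible & same_prev)
        czeros = lambda a: np.concatenate([[0], np.cumsum(a)])
        return ColumnStats(
            is_gap=is_gap,
            valid=valid,
            is_snp=is_snp,
            eligible=eligible,
            run_start=run_start,
            csum_snp=czeros(is_snp),
            csum_run_start=czeros(run_start),
        )


# ---------------------------------------------------------------------------
# I/O


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping individual_id -> taxon (header optional)."""
    mapping: dict[str, str] = {}
    path = Path(path)
    if not path.exists():
        raise InputParseError(f"sample sheet not found: {path}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InputParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            if lineno == 1 and fields[0].lower() in ("individual", "individual_id", "id"):
                continue
            mapping[fields[0]] = fields[1]
    if not mapping:
        raise InputParseError(f"sample sheet {path} is empty")
    return mapping


def read_alignment_fasta(
    path: str | Path,
    sample_sheet: str | Path | Mapping[str, str] | None = None,
    reference_id: Optional[str] = None,
) -> MultipleAlignment:
    """Read an aligned FASTA (gap '-', case-insensitive), plain or gzip."""
    path = Path(path)
    if not path.exists():
        raise InputParseError(f"alignment not found: {path}")
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise InputParseError(f"no sequences in alignment {path}")
    taxon_of = None
    if sample_sheet is not None:
        taxon_of = (
            dict(sample_sheet)
            if isinstance(sample_sheet, Mapping)
            else read_sample_sheet(sample_sheet)
        )
    return MultipleAlignment(
        [r.id for r in records],
        [str(r.seq) for r in records],
        taxon_of=taxon_of,
        reference_id=reference_id,
    )


def write_alignment_fasta(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, ind in enumerate(aln.ids):
            fh.write(f">{ind}\n")
            row = aln.matrix[i].tobytes().decode("ascii")
            for k in range(0, len(row), 70):
                fh.write(row[k:k + 70] + "\n")


def write_sample_sheet(taxon_of: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\ttaxon\n")
        for ind, tax in taxon_of.items():
            fh.write(f"{ind}\t{tax}\n")
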