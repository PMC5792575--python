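"""Sliding-window hotspot scan over a whole-plastome alignment.

Windows are anchored on the reference individual's ungapped coordinates
(default 600 bp, moved by 100 bp), each projected to alignment columns and
scored like a region with the window size as denominator. Each window also
reports its composition: the annotated regions it overlaps, in genome
order, with overlap lengths that sum to the window size when the regions
tile the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alignment import MultipleAlignment
from .errors import StageError
from .genome import Region
from . import barcode, variation


@dataclass
class WindowRecord:
    start: int  # reference coordinates, 0-based half-open
    end: int
    n_snp: int
    n_indel: int
    p_v: float
    pi: float
    n_identified: Optional[int] = None
    pct_identified: Optional[float] = None
    composition: tuple[tuple[str, int], ...] = ()

    @property
    def pic(self) -> int:
        return self.n_snp + self.n_indel


def window_composition(
    window: tuple[int, int], regions: Sequence[Region]
) -> list[tuple[str, int]]:
    """Ordered (region label, overlap bp) pairs for a reference interval.

    Overlaps are listed in genome order; zero-overlap regions are omitted.
    When the regions tile the genome the overlaps sum to the window length.
    """
    s, e = window
    hits: list[tuple[int, str, int]] = []
    for r in regions:
        for ps, pe in r.parts:
            ov = min(e, pe) - max(s, ps)
            if ov > 0:
                hits.append((max(s, ps), r.label, ov))
    hits.sort()
    # merge adjacent parts of the same region (spliced genes)
    merged: list[tuple[str, int]] = []
    for _, label, ov in hits:
        if merged and merged[-1][0] == label:
            merged[-1] = (label, merged[-1][1] + ov)
        else:
            merged.append((label, ov))
    return merged


def scan_windows(
    aln: MultipleAlignment,
    regions: Optional[Sequence[Region]] = None,
    window: int = 600,
    step: int = 100,
    discriminate: bool = True,
    compute_pi: bool = True,
) -> list[WindowRecord]:
    """Score fixed-size windows at 0, step, 2*step, ... (final partial window dropped)."""
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    N = aln.reference_length
    if window > N:
        raise StageError(f"window ({window} bp) exceeds genome length ({N} bp)")
    starts = np.arange(0, N - window + 1, step)
    bounds = [aln.columns_for(int(s), int(s) + window) for s in starts]
    a_cols = np.array([b[0] for b in bounds])
    b_cols = np.array([b[1] for b in bounds])

    st = aln.stats
    n_snp = st.csum_snp[b_cols] - st.csum_snp[a_cols]
    n_indel = st.csum_run_start[b_cols] - st.csum_run_start[a_cols]
    n_indel += st.eligible[a_cols] & ~st.run_start[a_cols]

    pis = np.zeros(len(starts))
    if compute_pi:
        n = aln.n_individuals
        npairs = n * (n - 1) // 2
        czeros = lambda a: np.concatenate([[0], np.cumsum(a, dtype=np.int64)])
        for i in range(n):
            vi = st.valid[i]
            mi = aln.matrix[i]
            for j in range(i + 1, n):
                both = vi & st.valid[j]
                cv = czeros(both)
                cd = czeros((mi != aln.matrix[j]) & both)
                comp = cv[b_cols] - cv[a_cols]
                diff = cd[b_cols] - cd[a_cols]
                with np.errstate(invalid="ignore", divide="ignore"):
                    ratio = np.where(comp > 0, diff / np.maximum(comp, 1), 0.0)
                pis += ratio
        pis /= npairs

    records: list[WindowRecord] = []
    do_disc = discriminate and aln.n_taxa >= 2
    for w, s in enumerate(starts):
        s = int(s)
        rec = WindowRecord(
            start=s,
            end=s + window,
            n_snp=int(n_snp[w]),
            n_indel=int(n_indel[w]),
            p_v=variation.percent_variation(int(n_snp[w]), int(n_indel[w]), window),
            pi=float(pis[w]),
        )
        if do_disc:
            disc = barcode.identified_taxa(
                aln, (int(a_cols[w]), int(b_cols[w])), locus=f"window:{s}"
            )
            rec.n_identified = disc.n_identified
            rec.pct_identified = disc.pct_identified
        if regions is not None:
            rec.composition = tuple(window_composition((s, s + window), regions))
        records.append(rec)
    return records


def rank_windows(
    records: Sequence[WindowRecord], top_k: Optional[int] = None
) -> list[WindowRecord]:
    """Sort by P_V desc, then identified taxa desc, then pi desc, then start asc."""
    ranked = sorted(
        records,
        key=lambda r: (-r.p_v, -(r.n_identified or 0), -r.pi, r.start),
    )
    return ranked[:top_k] if top_k is not None else ranked


def write_track(
    records: Sequence[WindowRecord],
    path,
    value: str = "n_snp",
    name: str = "plastome",
) -> None:
    """4-column plain-text track (name, start, end, value), Circos-style."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{name}\t{r.start}\t{r.end}\t{getattr(r, value)}\n")
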