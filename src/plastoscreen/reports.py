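"""Table-style report writers.

All tables are TSV (UTF-8, '.' decimal separator); P_V is printed to two
decimals and pi to six, matching the conventions of hotspot tables in the
comparative-plastome literature. Reports contain no arithmetic of their
own: every number is taken from the stage results.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .barcode import DiscriminationResult
from .variation import VariationSummary
from .windows import WindowRecord


def _identified_cell(s) -> str:
    if s.n_identified is None:
        return ""
    return f"{s.n_identified} ({s.pct_identified:.2f}%)"


def region_report(
    summaries: Sequence[VariationSummary],
    min_length: int = 100,
    min_pic: int = 3,
) -> pd.DataFrame:
    """Hotspot table: most polymorphic coding and non-coding regions.

    Regions are filtered to those over ``min_length`` bp carrying at least
    ``min_pic`` polymorphic characters (SNP sites + indel events), split
    into a coding section (protein genes only) and a non-coding section
    (introns and spacers), each sorted by P_V descending (ties: pi
    descending, then name). tRNA/rRNA gene bodies are not scored.
    """
    rows = []
    for s in summaries:
        if s.length_bp < min_length or s.pic < min_pic:
            continue
        if s.kind == "coding" and not s.is_protein:
            continue
        section = "coding" if s.kind == "coding" else "non-coding"
        rows.append(
            {
                "section": section,
                "region": s.name,
                "length_bp": s.length_bp,
                "snp": s.n_snp,
                "indel": s.n_indel,
                "p_v": f"{s.p_v:.2f}",
                "pi": f"{s.pi:.6f}",
                "identified_taxa": _identified_cell(s),
                "_pv": s.p_v,
                "_pi": s.pi,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["section", "region", "length_bp", "snp", "indel", "p_v", "pi",
                 "identified_taxa", "_pv", "_pi"],
    )
    if not df.empty:
        df["_sec"] = (df["section"] == "non-coding").astype(int)
        df = df.sort_values(
            by=["_sec", "_pv", "_pi", "region"],
            ascending=[True, False, False, True],
            kind="mergesort",
        )
        df = df.drop(columns=["_sec"])
    return df.drop(columns=["_pv", "_pi"]).reset_index(drop=True)


def composition_string(composition: Sequence[tuple[str, int]]) -> str:
    return ", ".join(f"{name} ({bp})" for name, bp in composition)


def window_report(records: Sequence[WindowRecord]) -> pd.DataFrame:
    """Ranked sliding-window table (ranges printed 0-based half-open)."""
    rows = []
    for r in records:
        rows.append(
            {
                "comprised_regions": composition_string(r.composition),
                "range": f"{r.start}–{r.end}",
                "snp": r.n_snp,
                "indel": r.n_indel,
                "p_v": f"{r.p_v:.2f}",
                "pi": f"{r.pi:.6f}",
                "identified_taxa": (
                    f"{r.n_identified} ({r.pct_identified:.2f}%)"
                    if r.n_identified is not None
                    else ""
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["comprised_regions", "range", "snp", "indel", "p_v", "pi",
                 "identified_taxa"],
    )


def discrimination_report(result: DiscriminationResult) -> pd.DataFrame:
    rows = [
        {"taxon": t, "status": "identified" if t in result.identified else "failed"}
        for t in sorted(result.identified | result.failures)
    ]
    return pd.DataFrame(rows, columns=["taxon", "status"])


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_pairwise_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="individual")
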