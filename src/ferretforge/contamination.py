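"""Ribosomal-protein marker screening for cross-contamination (RP63).

Cultured transcriptomes are prone to carry-over of sequences from
co-cultured or neighbouring samples. The screen exploits ribosomal
proteins — ubiquitously transcribed, phylogenetically informative
markers: Pfam families specific to ribosomal proteins and present in
more than 90% of candidate entries are selected as markers, each
marker sequence is placed on the taxonomy by bitscore-banded LCA over
its alignment hits, placements are rolled up into lineage bins, and the
fraction of markers landing outside the entry's expected bin estimates
its contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import BestAnnotation
from .formats import AlignmentHit, _open_text
from .taxonomy import (
    BinSet,
    OTHER_BIN,
    TaxonomyTree,
    UNKNOWN_BIN,
    assign_bin,
    lca_from_hits,
)

__all__ = [
    "ContamReport",
    "select_marker_pfams",
    "marker_sequences",
    "estimate_contamination",
    "contam_report_frame",
    "write_contam_reports",
]


@dataclass
class ContamReport:
    """Per-entry marker-based contamination estimate.

    ``bin_counts`` holds one count per report category, in BinSet
    column order (taxon bins, then Other, then Unknown), and sums to
    ``n_seqs``. ``contam_pct`` is ``None`` when no marker could be
    placed (denominator zero).
    """

    entry_id: int
    tax_id: int
    n_seqs: int
    n_pfams: int
    tax_group: str
    contam_pct: float | None
    bin_counts: dict[str, int]
    marferret_name: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def entry_handle(self) -> str:
        return f"{self.entry_id}_{self.marferret_name}" if self.marferret_name else str(self.entry_id)


def select_marker_pfams(
    best: Iterable[BestAnnotation],
    name_patterns: Sequence[str] = ("Ribosomal",),
    prevalence_min: float = 0.90,
) -> set[str]:
    """Select marker families across the candidate corpus.

    A family qualifies when its name starts with one of
    ``name_patterns`` (the operational reading of "specific to
    ribosomal proteins") AND it appears in strictly more than
    ``prevalence_min`` of the entries contributing annotations.
    """
    if not name_patterns:
        raise ValueError("name_patterns must be non-empty")
    entries: set[int] = set()
    presence: dict[str, set[int]] = {}
    names: dict[str, str] = {}
    for b in best:
        entries.add(b.entry_id)
        presence.setdefault(b.pfam_id, set()).add(b.entry_id)
        names.setdefault(b.pfam_id, b.pfam_name)
    if not entries:
        raise ValueError("no annotations supplied")
    n_entries = len(entries)
    markers = {
        pfam_id
        for pfam_id, seen in presence.items()
        if any(names[pfam_id].startswith(p) for p in name_patterns)
        and len(seen) / n_entries > prevalence_min
    }
    return markers


def marker_sequences(
    entry_best: Iterable[BestAnnotation],
    markers: set[str],
) -> set[str]:
    """Sequence ids whose *best* annotation is a marker family.

    A sequence best-annotated to a non-marker family is excluded even
    if it had a weaker marker hit upstream.
    """
    return {b.aa_id for b in entry_best if b.pfam_id in markers}


def estimate_contamination(
    entry_id: int,
    tax_id: int,
    entry_best: Sequence[BestAnnotation],
    markers: set[str],
    hits_by_query: Mapping[str, Sequence[AlignmentHit]],
    tree: TaxonomyTree,
    bins: BinSet,
    *,
    evalue_max: float = 1e-5,
    top_frac: float = 0.10,
    unknown_policy: str = "exclude",
    marferret_name: str = "",
) -> ContamReport:
    """Estimate one entry's cross-contamination percentage.

    Each marker sequence is placed by LCA over its hits and assigned a
    lineage bin; markers without hits fall in Unknown. The estimate is
    ``100 x (markers in bins other than the expected bin) / (markers in
    any bin)``. Under the default ``unknown_policy="exclude"`` Unknown
    markers enter neither numerator nor denominator — unplaced markers
    reflect reference incompleteness, not contamination; with
    ``"count"`` they are treated as outside the expected lineage.
    """
    if unknown_policy not in ("exclude", "count"):
        raise ValueError(f"unknown unknown_policy {unknown_policy!r}")
    marker_best = [b for b in entry_best if b.pfam_id in markers]
    marker_ids = sorted({b.aa_id for b in marker_best})
    n_pfams = len({b.pfam_id for b in marker_best})

    expected = assign_bin(tree, tax_id, bins)
    warnings: list[str] = []
    if expected == OTHER_BIN:
        warnings.append(
            f"entry {entry_id}: tax_id {tax_id} falls in no configured bin; "
            "expected lineage is 'Other'"
        )

    counts = {name: 0 for name in bins.column_names}
    for aa_id in marker_ids:
        hits = hits_by_query.get(aa_id)
        if not hits:
            counts[UNKNOWN_BIN] += 1
            continue
        placement = lca_from_hits(tree, hits, evalue_max=evalue_max, top_frac=top_frac)
        counts[assign_bin(tree, placement, bins)] += 1

    n_unknown = counts[UNKNOWN_BIN]
    denom = len(marker_ids) - (0 if unknown_policy == "count" else n_unknown)
    outside = sum(
        c for name, c in counts.items() if name not in (expected, UNKNOWN_BIN)
    )
    if unknown_policy == "count":
        outside += n_unknown
    contam_pct = 100.0 * outside / denom if denom > 0 else None

    return ContamReport(
        entry_id=entry_id,
        tax_id=tax_id,
        n_seqs=len(marker_ids),
        n_pfams=n_pfams,
        tax_group=expected,
        contam_pct=contam_pct,
        bin_counts=counts,
        marferret_name=marferret_name,
        warnings=warnings,
    )


REPORT_FIXED_COLUMNS = (
    "entry_handle",
    "entry_id",
    "tax_id",
    "n_seqs",
    "n_pfams",
    "tax_group",
    "contam_pct",
)


def contam_report_frame(
    reports: Iterable[ContamReport],
    bins: BinSet,
) -> pd.DataFrame:
    """Assemble reports into the published RP63 table layout: seven
    fixed columns followed by one count column per report category."""
    rows = []
    for r in reports:
        row: dict[str, object] = {
            "entry_handle": r.entry_handle,
            "entry_id": r.entry_id,
            "tax_id": r.tax_id,
            "n_seqs": r.n_seqs,
            "n_pfams": r.n_pfams,
            "tax_group": r.tax_group,
            "contam_pct": r.contam_pct,
        }
        for name in bins.column_names:
            row[name] = r.bin_counts.get(name, 0)
        rows.append(row)
    columns = list(REPORT_FIXED_COLUMNS) + list(bins.column_names)
    return pd.DataFrame(rows, columns=columns)


def write_contam_reports(
    reports: Iterable[ContamReport],
    bins: BinSet,
    path: str | Path,
) -> None:
    df = contam_report_frame(reports, bins)
    with _open_text(path, "wt") as handle:
        df.to_csv(handle, index=False, float_format="%.4f")
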