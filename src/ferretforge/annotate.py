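"""Post-processing of Pfam domain-table hits.

Raw hmmsearch hits are reduced to curated annotations in two steps:
hits below their family's trusted cutoff (the highest-stringency,
Pfam-curated sequence bitscore threshold) are removed, and each protein
keeps only its best-scoring surviving annotation. Per-entry summaries
feed the QC metrics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats import PfamHit, PfamThresholds, _open_text

__all__ = [
    "BestAnnotation",
    "FilterTally",
    "filter_trusted",
    "best_per_sequence",
    "best_annotations",
    "entry_pfam_summary",
    "count_entry_pfams",
    "write_best_pfam",
    "read_best_pfam",
    "write_entry_pfam_sums",
]

BEST_PFAM_COLUMNS = ("aa_id", "entry_id", "source_defline", "pfam_name", "pfam_id")


@dataclass(frozen=True)
class BestAnnotation:
    """Best-scoring Pfam annotation of one protein sequence."""

    aa_id: str
    entry_id: int
    pfam_id: str
    pfam_name: str
    source_defline: str = ""


@dataclass
class FilterTally:
    """Accounting for trusted-cutoff filtering: hits rejected below
    their cutoff and hits dropped for lack of any cutoff."""

    n_below_cutoff: int = 0
    n_missing_threshold: int = 0
    missing_families: set[str] = field(default_factory=set)


def filter_trusted(
    hits: Iterable[PfamHit],
    thresholds: PfamThresholds | Mapping[str, float],
    tally: FilterTally | None = None,
) -> list[PfamHit]:
    """Keep exactly the hits scoring at or above their family's trusted
    cutoff.

    Hits whose family has no cutoff are dropped and counted in
    ``tally`` (a warning condition, not an error). Idempotent.
    """
    kept: list[PfamHit] = []
    for hit in hits:
        cutoff = thresholds.get(hit.pfam_id)
        if cutoff is None:
            if tally is not None:
                tally.n_missing_threshold += 1
                tally.missing_families.add(hit.pfam_id)
            continue
        if hit.bitscore >= cutoff:
            kept.append(hit)
        elif tally is not None:
            tally.n_below_cutoff += 1
    return kept


def best_per_sequence(hits: Iterable[PfamHit]) -> dict[str, PfamHit]:
    """One winning hit per sequence: highest bitscore, ties broken by
    lower E-value then lexicographic Pfam accession.

    Returns a dict keyed by seq_id, insertion-ordered by first
    appearance of each sequence in the input.
    """
    best: dict[str, PfamHit] = {}
    for hit in hits:
        cur = best.get(hit.seq_id)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.seq_id] = hit
    return best


def _hit_rank(hit: PfamHit) -> tuple[float, float, str]:
    return (-hit.bitscore, hit.evalue, hit.pfam_id)


def best_annotations(
    hits: Iterable[PfamHit],
    entry_id: int,
    deflines: Mapping[str, str] | None = None,
) -> list[BestAnnotation]:
    """Wrap :func:`best_per_sequence` winners as entry-tagged rows."""
    deflines = deflines or {}
    return [
        BestAnnotation(
            aa_id=seq_id,
            entry_id=entry_id,
            pfam_id=hit.pfam_id,
            pfam_name=hit.pfam_name,
            source_defline=deflines.get(seq_id, ""),
        )
        for seq_id, hit in best_per_sequence(hits).items()
    ]


def entry_pfam_summary(best: Iterable[BestAnnotation]) -> pd.DataFrame:
    """Group best annotations into (entry_id, pfam_id, pfam_name,
    n_seqs) counts; n_seqs sums to the number of annotated sequences of
    each entry."""
    rows = [(b.entry_id, b.pfam_id, b.pfam_name) for b in best]
    df = pd.DataFrame(rows, columns=["entry_id", "pfam_id", "pfam_name"])
    if df.empty:
        return pd.DataFrame(columns=["entry_id", "pfam_id", "pfam_name", "n_seqs"])
    out = (
        df.groupby(["entry_id", "pfam_id", "pfam_name"], sort=True)
        .size()
        .reset_index(name="n_seqs")
    )
    return out.sort_values(["entry_id", "pfam_id"], ignore_index=True)


def count_entry_pfams(
    best: Iterable[BestAnnotation],
    count_mode: str = "families",
) -> dict[int, int]:
    """Per-entry Pfam count consumed by QC.

    ``families`` counts distinct Pfam accessions among the entry's best
    annotations; ``hits`` counts annotated sequences instead. The
    distinct-family mode matches the curation-table semantics.
    """
    if count_mode not in ("families", "hits"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    per_entry: dict[int, set[str] | int] = {}
    counts: dict[int, int] = {}
    if count_mode == "hits":
        for b in best:
            counts[b.entry_id] = counts.get(b.entry_id, 0) + 1
        return counts
    fams: dict[int, set[str]] = {}
    for b in best:
        fams.setdefault(b.entry_id, set()).add(b.pfam_id)
    return {entry: len(s) for entry, s in fams.items()}


def write_best_pfam(best: Iterable[BestAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (b.aa_id, b.entry_id, b.source_defline, b.pfam_name, b.pfam_id)
            for b in best
        ],
        columns=list(BEST_PFAM_COLUMNS),
    )
    with _open_text(path, "wt") as handle:
        df.to_csv(handle, index=False)


def read_best_pfam(path: str | Path) -> list[BestAnnotation]:
    with _open_text(path) as handle:
        df = pd.read_csv(handle, keep_default_na=False)
    missing = [c for c in BEST_PFAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        BestAnnotation(
            aa_id=str(r.aa_id),
            entry_id=int(r.entry_id),
            pfam_id=str(r.pfam_id),
            pfam_name=str(r.pfam_name),
            source_defline=str(r.source_defline),
        )
        for r in df.itertuples()
    ]


def write_entry_pfam_sums(summary: pd.DataFrame, path: str | Path) -> None:
    cols = ["entry_id", "pfam_id", "pfam_name", "n_seqs"]
    with _open_text(path, "wt") as handle:
        summary[cols].to_csv(handle, index=False)
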