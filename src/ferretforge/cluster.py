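"""Intra-taxon protein pooling, identity clustering and stable ids.

Accepted entries sharing an NCBI taxid are pooled so that strain-level
diversity is kept, then redundancy is removed by greedy clustering at a
high amino-acid identity threshold (default 99%): sequences are
processed longest-first and each either joins the first existing
cluster whose representative it matches at or above the threshold —
with the shorter sequence covering at least 80% of the longer — or
founds a new cluster. Identity is exact-residue matches over the
columns of a global alignment (BLOSUM62, affine gaps: open 11,
extend 1). Cluster representatives receive stable, zero-padded
``mft``-prefixed identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .formats import SequenceRecord, _open_text, write_fasta

__all__ = [
    "PooledSeq",
    "ProteinCluster",
    "pool_by_taxid",
    "global_identity",
    "greedy_cluster",
    "assign_ids",
    "write_proteins",
    "write_proteins_info",
    "write_taxonomies",
]


@dataclass(frozen=True)
class PooledSeq:
    """A protein sequence tagged with its source entry and pool order."""

    entry_id: int
    record: SequenceRecord
    index: int  # position within the taxid pool, for tie-breaking


@dataclass
class ProteinCluster:
    """One identity cluster within a taxid pool; the representative is
    always a member."""

    tax_id: int
    representative: PooledSeq
    members: list[PooledSeq]
    threshold: float


def pool_by_taxid(
    seqs_by_entry: Mapping[int, Sequence[SequenceRecord]],
    metadata: pd.DataFrame,
) -> dict[int, list[PooledSeq]]:
    """Combine accepted entries' proteins into per-taxid pools.

    Rejected entries contribute nothing. Terminal stop symbols are
    stripped before pooling. Pool order follows metadata row order,
    then sequence order within each entry.
    """
    pools: dict[int, list[PooledSeq]] = {}
    for row in metadata.itertuples():
        if row.accepted != "Y":
            continue
        if int(row.entry_id) not in seqs_by_entry:
            continue
        tax_id = int(row.tax_id)
        if tax_id <= 0:
            raise ValueError(f"entry {row.entry_id}: missing or invalid taxid")
        pool = pools.setdefault(tax_id, [])
        for rec in seqs_by_entry[int(row.entry_id)]:
            residues = rec.residues.rstrip("*")
            if not residues:
                continue
            if residues != rec.residues:
                rec = SequenceRecord(
                    rec.seq_id, rec.description, rec.alphabet, residues
                )
            pool.append(PooledSeq(int(row.entry_id), rec, len(pool)))
    return pools


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


# residues outside the BLOSUM62 alphabet are treated as unknown
_SANITIZE = str.maketrans({"J": "X", "U": "X", "O": "X"})


def global_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Fraction of identical residues over all columns of the best
    global alignment of ``a`` and ``b`` (gap columns count against
    identity)."""
    if aligner is None:
        aligner = _make_aligner()
    alignment = aligner.align(a.translate(_SANITIZE), b.translate(_SANITIZE))[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def greedy_cluster(
    pool: Sequence[PooledSeq] | Sequence[SequenceRecord],
    threshold: float = 0.99,
    coverage: float = 0.8,
    tax_id: int = 0,
) -> list[ProteinCluster]:
    """Greedy longest-first identity clustering of one taxid pool.

    Sequences are visited in descending length (ties: pool order); a
    sequence joins the first cluster whose representative matches it at
    identity >= ``threshold`` with shorter/longer length ratio >=
    ``coverage``, otherwise it founds a new cluster. Deterministic for
    a given input order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    items: list[PooledSeq] = [
        p
        if isinstance(p, PooledSeq)
        else PooledSeq(entry_id=0, record=p, index=i)
        for i, p in enumerate(pool)
    ]
    if not items:
        return []
    aligner = _make_aligner()
    order = sorted(items, key=lambda p: (-len(p.record), p.index))
    clusters: list[ProteinCluster] = []
    # exact-duplicate fast path: residues -> cluster index
    by_residues: dict[str, int] = {}
    min_ratio = max(threshold, coverage)
    for item in order:
        residues = item.record.residues
        hit = by_residues.get(residues)
        if hit is not None:
            clusters[hit].members.append(item)
            continue
        joined = False
        for ci, cluster in enumerate(clusters):
            rep = cluster.representative.record.residues
            short, long_ = sorted((len(residues), len(rep)))
            # identity <= short/long and coverage = short/long, so the
            # length ratio bounds both tests
            if short / long_ < min_ratio:
                continue
            if global_identity(residues, rep, aligner) >= threshold:
                cluster.members.append(item)
                joined = True
                break
        if not joined:
            clusters.append(
                ProteinCluster(
                    tax_id=tax_id,
                    representative=item,
                    members=[item],
                    threshold=threshold,
                )
            )
            by_residues[residues] = len(clusters) - 1
    return clusters


def assign_ids(clusters: Sequence[ProteinCluster]) -> dict[str, str]:
    """Assign stable ``mft`` identifiers to cluster representatives.

    Ids are "mft" plus a ten-digit zero-padded integer, consecutive
    from mft0000000001, ordered by (tax_id, representative's entry_id,
    pool order). The mapping representative seq_id -> mft id is a
    bijection.
    """
    ordered = sorted(
        clusters,
        key=lambda c: (
            c.tax_id,
            c.representative.entry_id,
            c.representative.index,
        ),
    )
    if len(ordered) > 10**10 - 1:
        raise ValueError("mft identifier space exhausted")
    ids: dict[str, str] = {}
    for i, cluster in enumerate(ordered, start=1):
        seq_id = cluster.representative.record.seq_id
        if seq_id in ids:
            raise ValueError(f"duplicate representative id {seq_id}")
        ids[seq_id] = f"mft{i:010d}"
    return ids


def write_proteins(
    clusters: Sequence[ProteinCluster],
    ids: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write clustered representative proteins; deflines are the mft id
    only, in id order."""
    records = []
    for cluster in clusters:
        rep = cluster.representative.record
        records.append(
            SequenceRecord(ids[rep.seq_id], "", "aa", rep.residues)
        )
    records.sort(key=lambda r: r.seq_id)
    write_fasta(records, path)


def write_proteins_info(
    clusters: Sequence[ProteinCluster],
    ids: Mapping[str, str],
    path: str | Path,
) -> None:
    """Tab-separated aa_id / entry_id / source_defline map for the
    representatives."""
    rows = []
    for cluster in clusters:
        rep = cluster.representative
        defline = rep.record.seq_id
        if rep.record.description:
            defline += " " + rep.record.description
        rows.append((ids[rep.record.seq_id], rep.entry_id, defline))
    rows.sort()
    with _open_text(path, "wt") as handle:
        handle.write("aa_id\tentry_id\tsource_defline\n")
        for row in rows:
            handle.write("\t".join(str(v) for v in row) + "\n")


def write_taxonomies(
    clusters: Sequence[ProteinCluster],
    ids: Mapping[str, str],
    path: str | Path,
) -> None:
    """Four-column accession map for LCA-capable aligners: accession
    and gi are NA; accession.version carries the mft id and taxid the
    cluster's taxid."""
    rows = []
    for cluster in clusters:
        rows.append((ids[cluster.representative.record.seq_id], cluster.tax_id))
    rows.sort()
    with _open_text(path, "wt") as handle:
        handle.write("accession\taccession.version\ttaxid\tgi\n")
        for mft_id, tax_id in rows:
            handle.write(f"NA\t{mft_id}\t{tax_id}\tNA\n")
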