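"""Readers and writers for the standard formats the pipeline touches.

Covers FASTA (gzip-transparent), the NCBI taxdump dialect
(nodes.dmp/names.dmp/merged.dmp), HMMER3 ``--domtblout`` domain tables,
HMMER3 text HMM profiles (for per-family trusted cutoffs), BLAST-style
tabular hit tables, and the entry metadata CSV schema.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .taxonomy import TaxNode, TaxonomyTree

__all__ = [
    "SequenceRecord",
    "PfamHit",
    "PfamThresholds",
    "AlignmentHit",
    "HitTable",
    "read_fasta",
    "write_fasta",
    "parse_taxdump",
    "parse_domtbl",
    "parse_hmm_thresholds",
    "parse_hit_table",
    "read_metadata",
    "write_metadata",
    "REQUIRED_METADATA_COLUMNS",
    "strip_pfam_version",
]

NUCLEOTIDE_SYMBOLS = frozenset("ACGTURYSWKMBDHVN")
AMINO_ACID_SYMBOLS = frozenset("ACDEFGHIKLMNPQRSTVWYBJZUOX*")

_PFAM_ID_RE = re.compile(r"^PF\d{5}$")
_VERSION_SUFFIX_RE = re.compile(r"\.\d+$")


def strip_pfam_version(accession: str) -> str:
    """Drop a trailing ``.N`` release suffix from a Pfam accession so
    hits join thresholds regardless of Pfam release."""
    return _VERSION_SUFFIX_RE.sub("", accession)


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record, nucleotide or amino-acid.

    ``alphabet`` is ``"nt"`` or ``"aa"``; residues are upper-case IUPAC
    symbols, with ``*`` (stop) and ``X`` (unknown) legal for amino
    acids.
    """

    seq_id: str
    description: str
    alphabet: str
    residues: str

    def __post_init__(self) -> None:
        if not self.seq_id or any(c.isspace() for c in self.seq_id):
            raise ValueError(f"invalid seq_id {self.seq_id!r}")
        if not self.residues:
            raise ValueError(f"record {self.seq_id}: empty sequence")
        if self.alphabet not in ("nt", "aa"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        legal = NUCLEOTIDE_SYMBOLS if self.alphabet == "nt" else AMINO_ACID_SYMBOLS
        bad = set(self.residues) - legal
        if bad:
            raise ValueError(
                f"record {self.seq_id}: illegal {self.alphabet} symbol(s) "
                + ", ".join(sorted(bad))
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PfamHit:
    """One domain-table hit: full-sequence score and E-value of a
    protein against one Pfam family."""

    seq_id: str
    pfam_id: str
    pfam_name: str
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if not _PFAM_ID_RE.match(self.pfam_id):
            raise ValueError(f"malformed Pfam accession {self.pfam_id!r}")
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass
class PfamThresholds:
    """Per-family trusted-cutoff (TC) sequence bitscores.

    ``missing`` lists profiles encountered without a TC line; looking
    one of those up raises ``KeyError``.
    """

    cutoffs: dict[str, float] = field(default_factory=dict)
    missing: list[str] = field(default_factory=list)

    def __contains__(self, pfam_id: str) -> bool:
        return pfam_id in self.cutoffs

    def __len__(self) -> int:
        return len(self.cutoffs)

    def __getitem__(self, pfam_id: str) -> float:
        try:
            return self.cutoffs[pfam_id]
        except KeyError:
            raise KeyError(f"no trusted cutoff for {pfam_id}") from None

    def get(self, pfam_id: str, default=None):
        return self.cutoffs.get(pfam_id, default)


@dataclass(frozen=True)
class AlignmentHit:
    """One protein-alignment hit with its subject resolved to a taxid."""

    query_id: str
    subject_taxid: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.subject_taxid <= 0:
            raise ValueError("subject_taxid must be positive")
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass
class HitTable:
    """Parsed hit table plus the count of rows dropped because their
    subject could not be mapped to a taxid."""

    hits: list[AlignmentHit]
    n_dropped: int = 0

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)

    def by_query(self) -> dict[str, list[AlignmentHit]]:
        grouped: dict[str, list[AlignmentHit]] = {}
        for hit in self.hits:
            grouped.setdefault(hit.query_id, []).append(hit)
        return grouped


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, alphabet: str) -> list[SequenceRecord]:
    """Parse a (possibly gzipped) FASTA file.

    ``seq_id`` is the first whitespace-delimited header token and the
    remainder of the header becomes the description. Residues are
    upper-cased and validated against the declared alphabet.
    """
    records: list[SequenceRecord] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(
                SequenceRecord(
                    seq_id=rec.id,
                    description=desc,
                    alphabet=alphabet,
                    residues=str(rec.seq).upper(),
                )
            )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        SeqIO.write(
            (
                _BioSeqRecord(
                    Seq(r.residues), id=r.seq_id, description=r.description
                )
                for r in records
            ),
            handle,
            "fasta",
        )


def _taxdump_rows(path: str | Path) -> Iterable[list[str]]:
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            yield [f.strip() for f in line.split("\t|\t")]


def parse_taxdump(
    nodes_path: str | Path,
    names_path: str | Path,
    merged_path: str | Path | None = None,
) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from NCBI taxdump-dialect files.

    ``nodes.dmp`` supplies taxid/parent/rank; ``names.dmp`` supplies
    scientific names; an optional ``merged.dmp`` supplies retired-taxid
    redirects. Duplicate taxids and parents absent from the node table
    are errors.
    """
    names: dict[int, str] = {}
    for fields in _taxdump_rows(names_path):
        if len(fields) < 4:
            raise ValueError(f"malformed names.dmp row: {fields}")
        if fields[3] == "scientific name":
            names[int(fields[0])] = fields[1]
    nodes: list[TaxNode] = []
    for fields in _taxdump_rows(nodes_path):
        if len(fields) < 3:
            raise ValueError(f"malformed nodes.dmp row: {fields}")
        taxid = int(fields[0])
        nodes.append(
            TaxNode(
                taxid=taxid,
                parent=int(fields[1]),
                rank=fields[2],
                name=names.get(taxid, ""),
            )
        )
    merged: dict[int, int] = {}
    if merged_path is not None:
        for fields in _taxdump_rows(merged_path):
            if len(fields) < 2:
                raise ValueError(f"malformed merged.dmp row: {fields}")
            merged[int(fields[0])] = int(fields[1])
    return TaxonomyTree(nodes, merged=merged)


def parse_domtbl(path: str | Path) -> list[PfamHit]:
    """Parse a HMMER3 ``--domtblout`` table into full-sequence hits.

    Comment lines start with '#'. Each data row has 22 whitespace-
    delimited fields plus a free-text target description; the target
    name, query (family) name, query accession, full-sequence E-value
    and full-sequence score columns are retained. One hit is emitted
    per data row, in file order.
    """
    hits: list[PfamHit] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split(None, 22)
            if len(fields) < 22:
                raise ValueError(
                    f"{path}: line {lineno}: expected 22 fields, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    PfamHit(
                        seq_id=fields[0],
                        pfam_name=fields[3],
                        pfam_id=strip_pfam_version(fields[4]),
                        evalue=float(fields[6]),
                        bitscore=float(fields[7]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return hits


def parse_hmm_thresholds(path: str | Path) -> PfamThresholds:
    """Extract trusted cutoffs from a text HMM profile flatfile.

    For each profile the accession (``ACC`` line, version stripped) is
    mapped to the first value of its ``TC`` line, the sequence-level
    trusted cutoff. Profiles lacking a TC line are recorded in
    ``missing``.
    """
    result = PfamThresholds()
    acc: str | None = None
    tc: float | None = None

    def close_profile() -> None:
        nonlocal acc, tc
        if acc is not None:
            if tc is None:
                result.missing.append(acc)
            else:
                result.cutoffs[acc] = tc
        acc, tc = None, None

    with _open_text(path) as handle:
        for line in handle:
            if line.startswith("ACC"):
                acc = strip_pfam_version(line.split()[1])
            elif line.startswith("TC"):
                tc = float(line.split()[1].rstrip(";"))
            elif line.startswith("//"):
                close_profile()
    close_profile()  # tolerate a missing trailing separator
    return result


def parse_hit_table(
    path: str | Path,
    taxid_map: Mapping[str, int] | None = None,
) -> HitTable:
    """Parse a tabular alignment hit table.

    Two dialects are accepted, detected from the first data row:

    * 4 columns ``query taxid bitscore evalue`` (the LCA-style triple
      plus E-value);
    * 12-column BLAST tabular, which additionally requires
      ``taxid_map`` to resolve subject ids to taxids. Rows whose
      subject is absent from the map are dropped and counted.

    Rows that fail numeric parsing are errors, never silently skipped.
    """
    hits: list[AlignmentHit] = []
    n_dropped = 0
    ncols: int | None = None
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if ncols is None:
                if len(fields) == 4:
                    ncols = 4
                elif len(fields) == 12:
                    ncols = 12
                    if taxid_map is None:
                        raise ValueError(
                            f"{path}: 12-column hit table requires a "
                            "subject-to-taxid map"
                        )
                else:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 4 or 12 columns, "
                        f"got {len(fields)}"
                    )
            if len(fields) != ncols:
                raise ValueError(
                    f"{path}: line {lineno}: expected {ncols} columns, "
                    f"got {len(fields)}"
                )
            try:
                if ncols == 4:
                    hits.append(
                        AlignmentHit(
                            query_id=fields[0],
                            subject_taxid=int(fields[1]),
                            bitscore=float(fields[2]),
                            evalue=float(fields[3]),
                        )
                    )
                else:
                    subject = fields[1]
                    if subject not in taxid_map:  # type: ignore[operator]
                        n_dropped += 1
                        continue
                    hits.append(
                        AlignmentHit(
                            query_id=fields[0],
                            subject_taxid=int(taxid_map[subject]),  # type: ignore[index]
                            bitscore=float(fields[11]),
                            evalue=float(fields[10]),
                        )
                    )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return HitTable(hits=hits, n_dropped=n_dropped)


#: Columns every entry metadata table must provide; extra columns are
#: carried through untouched.
REQUIRED_METADATA_COLUMNS = (
    "entry_id",
    "marferret_name",
    "tax_id",
    "data_type",
    "seq_type",
    "n_seqs_raw",
    "accepted",
)

_DATA_TYPES = frozenset({"TSA", "genome", "SAG", "SAT"})
_SEQ_TYPES = frozenset({"nt", "aa"})


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate an entry metadata CSV.

    The schema follows the published metadata record: required columns
    must be present, entry ids unique, and the data/sequence type
    enumerations respected. Unknown extra columns are preserved.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {missing}")
    if df["entry_id"].duplicated().any():
        dupes = sorted(df.loc[df["entry_id"].duplicated(), "entry_id"])
        raise ValueError(f"{path}: duplicate entry_id(s) {dupes}")
    bad_dt = set(df["data_type"]) - _DATA_TYPES
    if bad_dt:
        raise ValueError(f"{path}: unknown data_type value(s) {sorted(bad_dt)}")
    bad_st = set(df["seq_type"]) - _SEQ_TYPES
    if bad_st:
        raise ValueError(f"{path}: unknown seq_type value(s) {sorted(bad_st)}")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
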