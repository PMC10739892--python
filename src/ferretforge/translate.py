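"""Six-frame translation and longest-ORF frame selection.

Transcriptome contigs arrive without reading-frame information; each
nucleotide record is translated in all six frames under the standard
genetic code and the frame containing the longest open reading frame is
retained. ORFs are maximal stop-free peptide runs — no start codon is
required, because assembled transcripts are frequently 5'-truncated.

Frame numbering is fixed and length-independent: frames 1-3 are the
forward strand at offsets 0-2, frames 4-6 the reverse complement at
offsets 0-2.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Data import CodonTable

from .formats import SequenceRecord

__all__ = [
    "FrameTranslation",
    "reverse_complement",
    "six_frame_translate",
    "longest_orf_len",
    "longest_orf",
    "select_frame",
]

# IUPAC nucleotide ambiguity expansions (U treated as T).
_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVN",
    "TGCAAYRSWMKVHDBN",
)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _code_tables(table: str | int) -> tuple[dict[str, str], frozenset[str]]:
    if isinstance(table, int):
        code = CodonTable.unambiguous_dna_by_id[table]
    else:
        code = CodonTable.unambiguous_dna_by_name[table.capitalize()]
    return dict(code.forward_table), frozenset(code.stop_codons)


@lru_cache(maxsize=None)
def _translate_codon(codon: str, table: str | int) -> str:
    """Translate one (possibly degenerate) codon.

    All IUPAC completions of the codon are enumerated: if every
    completion is a stop the codon renders '*'; if every completion
    encodes a single amino acid it renders that amino acid; any mixture
    renders 'X'.
    """
    forward, stops = _code_tables(table)
    aas: set[str] = set()
    for a in _AMBIG[codon[0]]:
        for b in _AMBIG[codon[1]]:
            for c in _AMBIG[codon[2]]:
                concrete = a + b + c
                aas.add("*" if concrete in stops else forward[concrete])
    if len(aas) == 1:
        return aas.pop()
    return "X"


def _translate_offset(seq: str, offset: int, table: str | int) -> str:
    peptide = []
    for i in range(offset, len(seq) - 2, 3):
        peptide.append(_translate_codon(seq[i : i + 3], table))
    return "".join(peptide)


@dataclass(frozen=True)
class FrameTranslation:
    """Peptide of one reading frame and the length of its longest ORF."""

    frame: int
    peptide: str
    longest_orf_len: int

    def __post_init__(self) -> None:
        if not 1 <= self.frame <= 6:
            raise ValueError(f"frame must be 1..6, got {self.frame}")
        if self.longest_orf_len > len(self.peptide):
            raise ValueError("longest_orf_len exceeds peptide length")


def longest_orf_len(peptide: str) -> int:
    """Length of the longest maximal stop-free run ('X' does not break
    a run); 0 for all-stop peptides."""
    best = run = 0
    for aa in peptide:
        if aa == "*":
            run = 0
        else:
            run += 1
            if run > best:
                best = run
    return best


def longest_orf(peptide: str) -> str:
    """The longest stop-free substring itself (first one on ties)."""
    best_start = best_len = 0
    start = run = 0
    for i, aa in enumerate(peptide):
        if aa == "*":
            run = 0
            start = i + 1
        else:
            run += 1
            if run > best_len:
                best_len = run
                best_start = start
    return peptide[best_start : best_start + best_len]


def six_frame_translate(
    record: SequenceRecord | str,
    table: str | int = "standard",
) -> list[FrameTranslation]:
    """Translate a nucleotide sequence in all six frames.

    Frames 1-3 read the forward strand at offsets 0-2; frames 4-6 read
    the reverse complement at offsets 0-2. The peptide of the frame at
    offset ``k`` on a strand of length ``L`` has ``(L - k) // 3``
    residues.
    """
    seq = record.residues if isinstance(record, SequenceRecord) else record
    seq = seq.upper()
    if not seq:
        raise ValueError("cannot translate an empty sequence")
    bad = set(seq) - set(_AMBIG)
    if bad:
        raise ValueError(f"illegal nucleotide symbol(s) {sorted(bad)}")
    frames: list[FrameTranslation] = []
    for strand_index, strand in enumerate((seq, reverse_complement(seq))):
        for offset in range(3):
            peptide = _translate_offset(strand, offset, table)
            frames.append(
                FrameTranslation(
                    frame=3 * strand_index + offset + 1,
                    peptide=peptide,
                    longest_orf_len=longest_orf_len(peptide),
                )
            )
    return frames


def select_frame(
    record: SequenceRecord | str,
    table: str | int = "standard",
) -> FrameTranslation:
    """Pick the frame whose peptide contains the longest ORF.

    Ties are broken by the lowest frame number. The returned peptide is
    the full frame translation, not trimmed to the ORF; pair with
    :func:`longest_orf` when only the ORF substring is wanted.
    """
    frames = six_frame_translate(record, table)
    return max(frames, key=lambda f: (f.longest_orf_len, -f.frame))
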