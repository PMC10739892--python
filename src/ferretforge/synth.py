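"""Deterministic synthetic fixtures for every input the pipeline reads.

The generators emit a toy taxonomy in taxdump dialect, per-entry
proteomes with planted Pfam domain content (as HMMER-style domain
tables whose scores straddle the trusted cutoffs), marker hit tables
mixed at a known contamination fraction, and nucleotide records with a
stop-free coding sequence planted in a known frame — each with its
ground truth recorded, so the whole pipeline is testable without
downloading reference data.

Every generator is a pure function of the :class:`FixtureSpec`: a
single integer seed drives an independent, splittable pseudo-random
stream per generator, so outputs are byte-identical per seed and
adding a generator never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import (
    AlignmentHit,
    PfamThresholds,
    SequenceRecord,
    write_fasta,
    write_metadata,
)
from .taxonomy import BinSet, DEFAULT_BIN_NAMES, TaxNode, TaxonomyTree
from .translate import reverse_complement, six_frame_translate

__all__ = [
    "FixtureSpec",
    "FamilyDef",
    "EntryCorpus",
    "make_taxonomy",
    "write_taxdump",
    "make_entries",
    "make_marker_hits",
    "make_cds_fixture",
    "make_corpus",
]

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NT4 = np.array(list("ACGT"))

# per-generator stream indices; never renumber
_STREAMS = {"entries": 1, "hits": 2, "cds": 3}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic corpus.

    The defaults describe a desk-scale corpus: a few lineages, a few
    species each, two entries per taxon, and entries large enough to
    clear the QC floors when scaled thresholds are used in tests.
    """

    seed: int = 0
    n_lineages: int = 2
    species_per_lineage: int = 3
    strains_per_species: int = 1
    entries_per_taxon: int = 2
    seqs_per_entry: int = 40
    markers_per_entry: int = 10
    n_marker_families: int = 8
    n_other_families: int = 12
    subthreshold_per_entry: int = 2
    contamination_rho: float = 0.0
    contaminant_lineage: int = 1
    cds_len: int = 300
    flank_len: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination_rho <= 1.0:
            raise ValueError("contamination_rho must lie in [0, 1]")
        for name in (
            "n_lineages",
            "species_per_lineage",
            "strains_per_species",
            "entries_per_taxon",
            "seqs_per_entry",
            "n_marker_families",
            "n_other_families",
            "cds_len",
            "flank_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_lineages > len(DEFAULT_BIN_NAMES):
            raise ValueError("too many lineages for the default bin names")
        if not 0 <= self.contaminant_lineage < self.n_lineages:
            raise ValueError("contaminant_lineage must index a populated lineage")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _STREAMS[stream]])
        )


@dataclass(frozen=True)
class FamilyDef:
    """A synthetic Pfam family: accession, name, trusted cutoff."""

    pfam_id: str
    name: str
    trusted_cutoff: float
    is_marker: bool


# ---------------------------------------------------------------------------
# taxonomy

_BIN_BASE = 10
_SPECIES_BASE = 1000


def make_taxonomy(spec: FixtureSpec) -> tuple[TaxonomyTree, BinSet]:
    """Toy taxonomy: a root, one bin node for every report lineage, and
    species (plus optional strain) leaves under the first
    ``n_lineages`` bins. Purely structural — no randomness needed."""
    nodes = [TaxNode(1, 1, "no rank", "root")]
    bins = []
    for i, name in enumerate(DEFAULT_BIN_NAMES):
        taxid = _BIN_BASE + i
        nodes.append(TaxNode(taxid, 1, "clade", name))
        bins.append((name, taxid))
    for li in range(spec.n_lineages):
        for sj in range(spec.species_per_lineage):
            sp = _SPECIES_BASE + 100 * li + sj
            nodes.append(
                TaxNode(
                    sp,
                    _BIN_BASE + li,
                    "species",
                    f"{DEFAULT_BIN_NAMES[li]} sp{sj + 1}",
                )
            )
            for sk in range(spec.strains_per_species):
                if spec.strains_per_species == 1:
                    continue
                nodes.append(
                    TaxNode(
                        sp * 10 + sk,
                        sp,
                        "strain",
                        f"{DEFAULT_BIN_NAMES[li]} sp{sj + 1} strain{sk + 1}",
                    )
                )
    return TaxonomyTree(nodes), BinSet(tuple(bins))


def write_taxdump(tree: TaxonomyTree, out_dir: str | Path) -> None:
    """Write the tree as nodes.dmp / names.dmp in taxdump dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "nodes.dmp", "w") as nodes_f:
        for taxid in sorted(tree):
            n = tree.node(taxid)
            nodes_f.write(f"{n.taxid}\t|\t{n.parent}\t|\t{n.rank}\t|\n")
    with open(out_dir / "names.dmp", "w") as names_f:
        for taxid in sorted(tree):
            n = tree.node(taxid)
            names_f.write(
                f"{n.taxid}\t|\t{n.name}\t|\t\t|\tscientific name\t|\n"
            )


def entry_taxids(spec: FixtureSpec, tree: TaxonomyTree) -> list[int]:
    """Leaf taxids that carry entries, in deterministic order."""
    leaves = []
    for li in range(spec.n_lineages):
        for sj in range(spec.species_per_lineage):
            sp = _SPECIES_BASE + 100 * li + sj
            if spec.strains_per_species > 1:
                leaves.extend(sp * 10 + sk for sk in range(spec.strains_per_species))
            else:
                leaves.append(sp)
    return leaves


# ---------------------------------------------------------------------------
# proteomes and domain tables

_OTHER_FAMILY_NAMES = (
    "Pkinase", "Helicase_C", "WD40", "Ank_2", "RRM_1", "EF-hand_1",
    "ABC_tran", "Mito_carr", "Ras", "HSP70", "Cyclin_N", "SET",
    "Thioredoxin", "Aldedh", "Aminotran_1_2", "GTP_EFTU",
)


def _make_families(spec: FixtureSpec, rng: np.random.Generator) -> list[FamilyDef]:
    families: list[FamilyDef] = []
    for k in range(spec.n_marker_families):
        families.append(
            FamilyDef(
                pfam_id=f"PF9{k:04d}",
                name=f"Ribosomal_{'SL'[k % 2]}{k + 2}",
                trusted_cutoff=round(float(rng.uniform(20.0, 30.0)), 2),
                is_marker=True,
            )
        )
    for k in range(spec.n_other_families):
        families.append(
            FamilyDef(
                pfam_id=f"PF8{k:04d}",
                name=_OTHER_FAMILY_NAMES[k % len(_OTHER_FAMILY_NAMES)],
                trusted_cutoff=round(float(rng.uniform(20.0, 30.0)), 2),
                is_marker=False,
            )
        )
    return families


def _random_protein(rng: np.random.Generator, lo: int = 80, hi: int = 300) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(_AA20, size=length))


def _domtbl_row(seq_id: str, tlen: int, fam: FamilyDef, score: float, evalue: float) -> str:
    # 22 whitespace-delimited fields + description, hmmsearch layout
    fields = [
        seq_id, "-", str(tlen), fam.name, f"{fam.pfam_id}.17", "120",
        f"{evalue:.1e}", f"{score:.1f}", "0.1", "1", "1",
        f"{evalue:.1e}", f"{evalue:.1e}", f"{score:.1f}", "0.1",
        "1", "120", "1", str(tlen), "1", str(tlen), "0.90",
        "synthetic fixture",
    ]
    return " ".join(fields) + "\n"


def hmm_flatfile_text(families: Sequence[FamilyDef]) -> str:
    """Minimal text-HMM flatfile carrying NAME/ACC/TC headers for each
    family, enough for trusted-cutoff extraction."""
    blocks = []
    for fam in families:
        blocks.append(
            "HMMER3/f [3.3 | synthetic]\n"
            f"NAME  {fam.name}\n"
            f"ACC   {fam.pfam_id}.17\n"
            "LENG  120\n"
            f"TC    {fam.trusted_cutoff:.2f} {fam.trusted_cutoff:.2f};\n"
            "//\n"
        )
    return "".join(blocks)


@dataclass
class EntryCorpus:
    """Generated entries with their ground truth.

    ``truth`` maps entry_id -> seq_id -> (pfam_id, above_cutoff).
    """

    metadata: pd.DataFrame
    seqs_by_entry: dict[int, list[SequenceRecord]]
    nt_seqs_by_entry: dict[int, list[SequenceRecord]]
    domtbl_by_entry: dict[int, str]
    families: list[FamilyDef]
    thresholds: PfamThresholds
    truth: dict[int, dict[str, tuple[str, bool]]]

    @property
    def marker_family_ids(self) -> set[str]:
        return {f.pfam_id for f in self.families if f.is_marker}


def make_entries(
    spec: FixtureSpec,
    tree: TaxonomyTree,
    nt_entries: Sequence[int] = (),
) -> EntryCorpus:
    """Generate per-entry proteomes, domain tables and metadata.

    Each entry plants marker families in its first ``markers_per_entry``
    sequences (cycling over the marker set) and other families in the
    rest; ``subthreshold_per_entry`` of the non-marker sequences score
    just below their family's trusted cutoff and must vanish after
    filtering. Entries listed in ``nt_entries`` are additionally
    reverse-translated into nucleotide records (clean frame-1 CDS plus
    stop) for translation-stage testing, and carry seq_type "nt".
    """
    rng = spec.rng("entries")
    families = _make_families(spec, rng)
    markers = [f for f in families if f.is_marker]
    others = [f for f in families if not f.is_marker]
    thresholds = PfamThresholds(
        cutoffs={f.pfam_id: f.trusted_cutoff for f in families}
    )

    meta_rows = []
    seqs_by_entry: dict[int, list[SequenceRecord]] = {}
    nt_seqs_by_entry: dict[int, list[SequenceRecord]] = {}
    domtbl_by_entry: dict[int, str] = {}
    truth: dict[int, dict[str, tuple[str, bool]]] = {}

    entry_id = 0
    for tax_id in entry_taxids(spec, tree):
        for _ in range(spec.entries_per_taxon):
            entry_id += 1
            name = tree.name(tax_id).replace(" ", "_")
            records: list[SequenceRecord] = []
            rows: list[str] = []
            entry_truth: dict[str, tuple[str, bool]] = {}
            for j in range(spec.seqs_per_entry):
                seq_id = f"e{entry_id}_s{j + 1}"
                residues = _random_protein(rng)
                records.append(
                    SequenceRecord(seq_id, f"synthetic {name}", "aa", residues)
                )
                if j < spec.markers_per_entry:
                    fam = markers[j % len(markers)]
                    above = True
                else:
                    fam = others[(j + entry_id) % len(others)]
                    # the last few non-marker sequences score sub-cutoff
                    above = j < spec.seqs_per_entry - spec.subthreshold_per_entry
                delta = float(rng.uniform(1.0, 15.0))
                score = fam.trusted_cutoff + (delta if above else -delta)
                rows.append(
                    _domtbl_row(seq_id, len(residues), fam, score, 1e-20)
                )
                # occasional secondary, weaker hit to another family
                if above and j % 7 == 3:
                    alt = others[(j + entry_id + 1) % len(others)]
                    rows.append(
                        _domtbl_row(
                            seq_id, len(residues), alt,
                            max(score - float(rng.uniform(2.0, 8.0)), alt.trusted_cutoff),
                            1e-10,
                        )
                    )
                entry_truth[seq_id] = (fam.pfam_id, above)
            seqs_by_entry[entry_id] = records
            truth[entry_id] = entry_truth
            domtbl_by_entry[entry_id] = (
                "# target name        accession   tlen query name\n"
                "# ------------------- ---------- ----- ----------\n"
                "#\n" + "".join(rows) + "#\n" * 10
            )
            seq_type = "nt" if entry_id in set(nt_entries) else "aa"
            if seq_type == "nt":
                nt_seqs_by_entry[entry_id] = [
                    SequenceRecord(
                        r.seq_id,
                        r.description,
                        "nt",
                        _reverse_translate(r.residues, rng) + "TAA",
                    )
                    for r in records
                ]
            meta_rows.append(
                {
                    "entry_id": entry_id,
                    "marferret_name": f"{name}_e{entry_id}",
                    "tax_id": tax_id,
                    "data_type": "TSA",
                    "seq_type": seq_type,
                    "n_seqs_raw": len(records),
                    "accepted": "Y",
                    "source_filename": f"{entry_id}_{name}.fasta",
                }
            )
    metadata = pd.DataFrame(meta_rows)
    return EntryCorpus(
        metadata=metadata,
        seqs_by_entry=seqs_by_entry,
        nt_seqs_by_entry=nt_seqs_by_entry,
        domtbl_by_entry=domtbl_by_entry,
        families=families,
        thresholds=thresholds,
        truth=truth,
    )


_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data import CodonTable

        fwd = CodonTable.unambiguous_dna_by_name["Standard"].forward_table
        for codon, aa in fwd.items():
            _CODONS.setdefault(aa, []).append(codon)
        for aa in _CODONS:
            _CODONS[aa].sort()
    return _CODONS


def _reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    table = _codon_table()
    return "".join(
        table[aa][int(rng.integers(len(table[aa])))] for aa in peptide
    )


# ---------------------------------------------------------------------------
# marker hit tables

def make_marker_hits(
    spec: FixtureSpec,
    tree: TaxonomyTree,
    bins: BinSet,
    tax_id: int,
    marker_ids: Sequence[str],
    rho: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[AlignmentHit], dict[str, bool]]:
    """Emit alignment hits for one entry's marker sequences.

    With probability ``1 - rho`` a marker's top-bitscore band resolves
    (via LCA) inside the entry's own lineage bin, otherwise inside the
    designated contaminant bin. Bitscores are drawn so the retention
    band contains only the intended taxids: a decoy hit to a third bin
    sits below the band and a fourth hit fails the E-value cut. Returns
    the hits and the truth map seq_id -> contaminated?
    """
    rho = spec.contamination_rho if rho is None else rho
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if rng is None:
        rng = spec.rng("hits")
    own_bin_idx = None
    path = set(tree.lineage(tax_id))
    for i in range(spec.n_lineages):
        if _BIN_BASE + i in path:
            own_bin_idx = i
            break
    if own_bin_idx is None:
        raise ValueError(f"tax_id {tax_id} lies under no populated lineage")
    contam_idx = spec.contaminant_lineage
    if contam_idx == own_bin_idx:
        contam_idx = (contam_idx + 1) % spec.n_lineages

    def species_of(lineage_idx: int) -> list[int]:
        return [
            _SPECIES_BASE + 100 * lineage_idx + sj
            for sj in range(spec.species_per_lineage)
        ]

    hits: list[AlignmentHit] = []
    truth: dict[str, bool] = {}
    for seq_id in marker_ids:
        contaminated = bool(rng.random() < rho)
        truth[seq_id] = contaminated
        target_idx = contam_idx if contaminated else own_bin_idx
        decoy_idx = (target_idx + 1) % spec.n_lineages
        if decoy_idx == target_idx:
            decoy_idx = contam_idx
        sp = species_of(target_idx)
        best = float(rng.uniform(90.0, 110.0))
        hits.append(AlignmentHit(seq_id, sp[0], round(best, 1), 1e-30))
        if len(sp) > 1:
            hits.append(
                AlignmentHit(seq_id, sp[1], round(best * 0.95, 1), 1e-28)
            )
        # below the 10% retention band
        hits.append(
            AlignmentHit(
                seq_id, species_of(decoy_idx)[0], round(best * 0.80, 1), 1e-12
            )
        )
        # fails the E-value ceiling
        hits.append(
            AlignmentHit(
                seq_id, species_of(decoy_idx)[-1], round(best * 1.10, 1), 1e-3
            )
        )
    return hits, truth


def hit_table_text(hits: Iterable[AlignmentHit]) -> str:
    """Serialize hits in the 4-column (query, taxid, bitscore, evalue)
    dialect."""
    return "".join(
        f"{h.query_id}\t{h.subject_taxid}\t{h.bitscore:g}\t{h.evalue:g}\n"
        for h in hits
    )


# ---------------------------------------------------------------------------
# planted-CDS nucleotide fixtures

_STOPS = ("TAA", "TAG", "TGA")


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(_NT4, size=3))
        if codon not in _STOPS:
            codons.append(codon)
    return "".join(codons)


def make_cds_fixture(
    spec: FixtureSpec,
    frame: int,
    rng: np.random.Generator | None = None,
    seq_id: str = "cds_fixture",
    max_tries: int = 200,
) -> tuple[SequenceRecord, int]:
    """Plant a stop-free CDS at a given frame inside random flanks.

    The flanks are redrawn until the planted frame's longest ORF is
    strictly longer than every other frame's, so frame recovery has an
    unambiguous truth. Returns the record and the planted frame.
    """
    if not 1 <= frame <= 6:
        raise ValueError("frame must be 1..6")
    if rng is None:
        rng = spec.rng("cds")
    n_codons = spec.cds_len // 3
    cds = _random_cds(rng, n_codons)
    offset = (frame - 1) % 3
    for _ in range(max_tries):
        left = "".join(rng.choice(_NT4, size=spec.flank_len))
        right = "".join(rng.choice(_NT4, size=spec.flank_len))
        trim = (len(left) - offset) % 3
        strand = left[trim:] + cds + right
        seq = strand if frame <= 3 else reverse_complement(strand)
        frames = six_frame_translate(seq)
        planted = frames[frame - 1].longest_orf_len
        if all(
            f.longest_orf_len < planted for f in frames if f.frame != frame
        ):
            return SequenceRecord(seq_id, f"planted frame={frame}", "nt", seq), frame
    raise RuntimeError("could not plant an unambiguous CDS fixture")


# ---------------------------------------------------------------------------
# full corpus on disk

@dataclass
class CorpusPaths:
    """Locations of everything :func:`make_corpus` writes."""

    root: Path
    metadata: Path
    source_dir: Path
    taxdump_dir: Path
    domtbl_dir: Path
    hits: Path
    hmm_file: Path
    bins_config: Path
    lineage_config: Path
    truth: Path


def make_corpus(spec: FixtureSpec, out_dir: str | Path) -> CorpusPaths:
    """Emit the full toy corpus: FASTA per entry, metadata CSV, taxdump
    files, domain tables, an HMM flatfile with trusted cutoffs, a
    marker hit table mixed at the spec's contamination fraction, bin
    and lineage configs, and a ground-truth JSON."""
    root = Path(out_dir)
    paths = CorpusPaths(
        root=root,
        metadata=root / "metadata.csv",
        source_dir=root / "source_seqs",
        taxdump_dir=root / "taxdump",
        domtbl_dir=root / "domtbl",
        hits=root / "marker_hits.tsv",
        hmm_file=root / "profiles.hmm",
        bins_config=root / "bins.cfg",
        lineage_config=root / "lineages.cfg",
        truth=root / "truth.json",
    )
    paths.source_dir.mkdir(parents=True, exist_ok=True)
    paths.domtbl_dir.mkdir(parents=True, exist_ok=True)

    tree, bins = make_taxonomy(spec)
    write_taxdump(tree, paths.taxdump_dir)
    bins.to_config(paths.bins_config)
    with open(paths.lineage_config, "w") as fh:
        for i in range(spec.n_lineages):
            fh.write(f"{DEFAULT_BIN_NAMES[i]}\t{_BIN_BASE + i}\n")

    # the first entry ships as nucleotide so a build exercises the
    # translation stage
    corpus = make_entries(spec, tree, nt_entries=(1,))
    write_metadata(corpus.metadata, paths.metadata)
    paths.hmm_file.write_text(hmm_flatfile_text(corpus.families))

    hits_rng = spec.rng("hits")
    all_hits: list[AlignmentHit] = []
    truth: dict[str, object] = {"contaminated": {}, "planted": {}}
    marker_fams = corpus.marker_family_ids
    for row in corpus.metadata.itertuples():
        entry_id = int(row.entry_id)
        records = corpus.seqs_by_entry[entry_id]
        fasta_path = paths.source_dir / str(row.source_filename)
        if row.seq_type == "nt":
            write_fasta(corpus.nt_seqs_by_entry[entry_id], fasta_path)
        else:
            write_fasta(records, fasta_path)
        (paths.domtbl_dir / f"{entry_id}.domtblout.tab").write_text(
            corpus.domtbl_by_entry[entry_id]
        )
        marker_ids = sorted(
            seq_id
            for seq_id, (fam, above) in corpus.truth[entry_id].items()
            if above and fam in marker_fams
        )
        hits, contam_truth = make_marker_hits(
            spec, tree, bins, int(row.tax_id), marker_ids, rng=hits_rng
        )
        all_hits.extend(hits)
        truth["contaminated"][str(entry_id)] = contam_truth
        truth["planted"][str(entry_id)] = {
            s: {"pfam_id": f, "above_cutoff": a}
            for s, (f, a) in sorted(corpus.truth[entry_id].items())
        }
    paths.hits.write_text(hit_table_text(all_hits))
    paths.truth.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
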