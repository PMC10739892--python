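"""Core transcribed gene (CTG) catalogs and completeness scoring.

For a high-level lineage, the CTGs are the Pfam families observed in
the translated transcriptomes of at least 95% of the species within
that lineage — a transcriptome-oriented analogue of genome-completeness
marker sets. Catalogs are built from accepted transcriptome-derived
entries only (TSA and SAT; genome and SAG entries are excluded),
strain-level taxids are collapsed onto their species-rank ancestors,
and the completeness of any annotated taxon bin is the percentage of
catalog families it contains.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotate import BestAnnotation
from .formats import _open_text
from .taxonomy import TaxonomyTree

__all__ = [
    "LineageDef",
    "CTGCatalog",
    "DEFAULT_CTG_LINEAGE_NAMES",
    "build_presence_matrix",
    "derive_ctg",
    "completeness",
    "min_qualifying_count",
    "write_core_genes",
    "read_lineage_config",
]

#: Default lineage catalog set: nine major marine lineages with enough
#: transcriptomic taxa, plus all eukaryotes as one group. Numeric
#: taxids depend on the taxonomy release in use and are supplied via
#: lineage config.
DEFAULT_CTG_LINEAGE_NAMES: tuple[str, ...] = (
    "Bacillariophyta",
    "Ochrophyta",  # excluding the Bacillariophyta subclade
    "Dinophyceae",
    "Chlorophyta",
    "Haptophyta",
    "Cryptophyceae",
    "Opisthokonta",
    "Rhizaria",
    "Amoebozoa",
    "Eukaryota",
)

#: Transcriptome-derived data types that contribute to CTG catalogs.
TRANSCRIPTOME_TYPES = frozenset({"TSA", "SAT"})


@dataclass(frozen=True)
class LineageDef:
    """A catalog lineage: an include taxid and optional excluded
    subclades (e.g. Ochrophyta minus Bacillariophyta)."""

    name: str
    taxid: int
    exclude: tuple[int, ...] = ()


@dataclass
class CTGCatalog:
    """Per-lineage Pfam frequency table at the inclusion threshold.

    ``table`` has one row per catalog family: pfam_id,
    n_taxa_observed, frequency (= n_taxa_observed / n_taxa). Exactly
    the families with frequency >= threshold are present.
    """

    lineage: str
    taxid: int
    n_taxa: int
    threshold: float
    table: pd.DataFrame

    @property
    def families(self) -> set[str]:
        return set(self.table["pfam_id"])


def min_qualifying_count(n_taxa: int, threshold: float = 0.95) -> int:
    """Smallest integer count k with k / n_taxa >= threshold."""
    if n_taxa <= 0:
        raise ValueError("n_taxa must be positive")
    return math.ceil(threshold * n_taxa - 1e-12)


def _species_ancestor(tree: TaxonomyTree, taxid: int) -> int:
    species = tree.rank_ancestor(taxid, "species")
    if species is None:
        _warnings.warn(
            f"taxid {taxid} has no species-rank ancestor; using it as-is",
            stacklevel=2,
        )
        return taxid
    return species


def build_presence_matrix(
    metadata: pd.DataFrame,
    best: Iterable[BestAnnotation],
    tree: TaxonomyTree,
    lineage: LineageDef,
    data_types: frozenset[str] | set[str] = TRANSCRIPTOME_TYPES,
    accepted_only: bool = True,
) -> pd.DataFrame:
    """Species-by-Pfam presence matrix for one lineage.

    Entries are restricted to accepted transcriptome-derived entries
    whose taxid lies under the lineage's include taxid and under none
    of its excluded subclades. Strain-level taxids collapse to their
    species-rank ancestors, and a cell is 1 iff any collapsed entry of
    that species carries at least one sequence best-annotated to the
    family.
    """
    fams_by_entry: dict[int, set[str]] = {}
    for b in best:
        fams_by_entry.setdefault(b.entry_id, set()).add(b.pfam_id)

    species_fams: dict[int, set[str]] = {}
    for row in metadata.itertuples():
        if accepted_only and row.accepted != "Y":
            continue
        if row.data_type not in data_types:
            continue
        taxid = tree.resolve(int(row.tax_id))
        path = set(tree.lineage(taxid))
        if lineage.taxid not in path:
            continue
        if any(x in path for x in lineage.exclude):
            continue
        species = _species_ancestor(tree, taxid)
        species_fams.setdefault(species, set()).update(
            fams_by_entry.get(int(row.entry_id), set())
        )
    if not species_fams:
        raise ValueError(
            f"lineage {lineage.name!r} (taxid {lineage.taxid}): no qualifying entries"
        )
    all_fams = sorted(set().union(*species_fams.values()))
    data = {
        fam: [int(fam in fams) for _, fams in sorted(species_fams.items())]
        for fam in all_fams
    }
    return pd.DataFrame(data, index=sorted(species_fams), dtype=int)


def derive_ctg(
    matrix: pd.DataFrame,
    threshold: float = 0.95,
    lineage: str = "",
    taxid: int = 0,
) -> CTGCatalog:
    """Derive the catalog: families present in at least ``threshold``
    of the matrix's species."""
    if matrix.empty:
        raise ValueError("presence matrix is empty")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    n_taxa = len(matrix.index)
    observed = matrix.sum(axis=0)
    frequency = observed / n_taxa
    keep = frequency >= threshold
    table = pd.DataFrame(
        {
            "pfam_id": observed.index[keep],
            "n_taxa_observed": observed[keep].astype(int).values,
            "frequency": frequency[keep].values,
        }
    ).sort_values("pfam_id", ignore_index=True)
    return CTGCatalog(
        lineage=lineage,
        taxid=taxid,
        n_taxa=n_taxa,
        threshold=threshold,
        table=table,
    )


def completeness(bin_families: Iterable[str], catalog: CTGCatalog) -> float:
    """Percentage of the lineage's catalog families observed in a taxon
    bin's Pfam set."""
    families = catalog.families
    if not families:
        raise ValueError("catalog is empty")
    return 100.0 * len(set(bin_families) & families) / len(families)


def write_core_genes(catalogs: Sequence[CTGCatalog], path: str | Path) -> None:
    """Write catalogs in the published core-genes layout: lineage,
    n_taxa, pfam_id, frequency."""
    frames = []
    for cat in catalogs:
        df = cat.table.copy()
        df.insert(0, "lineage", cat.lineage)
        df.insert(1, "n_taxa", cat.n_taxa)
        frames.append(df[["lineage", "n_taxa", "pfam_id", "frequency"]])
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["lineage", "n_taxa", "pfam_id", "frequency"])
    )
    with _open_text(path, "wt") as handle:
        out.to_csv(handle, index=False, float_format="%.6f")


def read_lineage_config(path: str | Path) -> list[LineageDef]:
    """Load lineage definitions from a plain-text config.

    One lineage per line: ``name<ws>taxid[<ws>exclude_taxid,...]``;
    '#' starts a comment.
    """
    lineages: list[LineageDef] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (2, 3):
            raise ValueError(f"malformed lineage config line: {raw!r}")
        exclude = (
            tuple(int(x) for x in fields[2].split(",")) if len(fields) == 3 else ()
        )
        lineages.append(LineageDef(fields[0], int(fields[1]), exclude))
    return lineages
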