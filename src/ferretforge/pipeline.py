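"""End-to-end reference-library build over a directory of entries.

Stages: translate nucleotide entries and select frames; filter and
reduce Pfam domain hits; validate entries (sequence/Pfam floors,
external contamination flags, the marker-based screen); pool accepted
entries by taxid, cluster and assign stable ids; derive core
transcribed gene catalogs. Every stage reads its inputs from and
writes its outputs to the build directory, so an interrupted build
resumes from the last completed stage when re-run with an unchanged
configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import annotate as ann
from . import cluster as clu
from . import contamination as contam
from . import ctg as ctgmod
from . import qc as qcmod
from .formats import (
    parse_domtbl,
    parse_hit_table,
    parse_hmm_thresholds,
    parse_taxdump,
    read_fasta,
    read_metadata,
    write_fasta,
    write_metadata,
    SequenceRecord,
)
from .taxonomy import BinSet
from .translate import select_frame

__all__ = ["BuildConfig", "run_build", "STAGES"]

STAGES = ("translate", "annotate", "validate", "cluster", "ctg")


@dataclass
class BuildConfig:
    """Paths and every numeric threshold of the build."""

    metadata: Path
    source_dir: Path
    taxdump_dir: Path
    domtbl_dir: Path
    hits: Path
    hmm_file: Path
    bins_config: Path
    out_dir: Path
    lineage_config: Path | None = None
    external_flags: Path | None = None
    min_seqs: int = 1200
    min_pfams: int = 500
    contam_flag_pct: float = 50.0
    marker_prevalence: float = 0.90
    marker_name_patterns: tuple[str, ...] = ("Ribosomal",)
    lca_evalue_max: float = 1e-5
    top_bitscore_frac: float = 0.10
    cluster_identity: float = 0.99
    cluster_coverage: float = 0.8
    ctg_frequency: float = 0.95
    unknown_policy: str = "exclude"
    count_mode: str = "families"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "marker_prevalence",
            "top_bitscore_frac",
            "cluster_identity",
            "cluster_coverage",
            "ctg_frequency",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("min_seqs", "min_pfams", "contam_flag_pct", "lca_evalue_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "metadata", "source_dir", "taxdump_dir", "domtbl_dir", "hits",
            "hmm_file", "bins_config", "out_dir", "lineage_config",
            "external_flags",
        ):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BuildConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "marker_name_patterns" in data:
            data["marker_name_patterns"] = tuple(data["marker_name_patterns"])
        return cls(**data)

    def param_hash(self) -> str:
        """Hash of the numeric/semantic parameters only (paths change
        between hosts without invalidating results)."""
        params = {
            k: v
            for k, v in asdict(self).items()
            if not isinstance(v, Path) and v.__class__ is not type(None)
        }
        params.pop("metadata", None)
        blob = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, path: Path, config_hash: str) -> None:
        self.path = path
        self.data: dict = {"config_hash": config_hash, "stages": {}, "counts": {}}
        if path.exists():
            stored = json.loads(path.read_text())
            if stored.get("config_hash") == config_hash:
                self.data = stored

    def done(self, stage: str) -> bool:
        return bool(self.data["stages"].get(stage))

    def mark(self, stage: str, **counts) -> None:
        self.data["stages"][stage] = True
        self.data["counts"].update(counts)
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def run_build(config: BuildConfig) -> Path:
    """Run (or resume) the full build; returns the output directory.

    Any stage failure halts the build with the stage name; rerunning
    with the same configuration resumes from the last completed stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json", config.param_hash())

    metadata = read_metadata(config.metadata)
    taxdump = Path(config.taxdump_dir)
    merged = taxdump / "merged.dmp"
    tree = parse_taxdump(
        taxdump / "nodes.dmp",
        taxdump / "names.dmp",
        merged if merged.exists() else None,
    )
    bins = BinSet.from_config(config.bins_config)
    bins.validate(tree)

    for stage in STAGES:
        if manifest.done(stage):
            continue
        try:
            _STAGE_FUNCS[stage](config, metadata, tree, bins, out, manifest)
        except Exception as exc:
            raise RuntimeError(f"build stage {stage!r} failed: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# stages

def _aa_path(out: Path, entry_id: int) -> Path:
    return out / "aa_seqs" / f"{entry_id}.faa"


def _stage_translate(config, metadata, tree, bins, out: Path, manifest) -> None:
    """Bring every entry into amino-acid space; nucleotide entries go
    through six-frame translation with longest-ORF frame selection."""
    (out / "aa_seqs").mkdir(exist_ok=True)
    n_translated = 0
    for row in metadata.itertuples():
        src = Path(config.source_dir) / str(row.source_filename)
        if row.seq_type == "nt":
            records = read_fasta(src, "nt")
            aa_records = []
            for rec in records:
                ft = select_frame(rec)
                desc = (rec.description + f" frame={ft.frame}").strip()
                aa_records.append(
                    SequenceRecord(rec.seq_id, desc, "aa", ft.peptide)
                )
            n_translated += len(aa_records)
        else:
            aa_records = read_fasta(src, "aa")
        write_fasta(aa_records, _aa_path(out, int(row.entry_id)))
    manifest.mark(
        "translate", n_entries=len(metadata), n_translated_seqs=n_translated
    )


def _stage_annotate(config, metadata, tree, bins, out: Path, manifest) -> None:
    """Trusted-cutoff filtering and best-per-sequence reduction of the
    per-entry domain tables."""
    thresholds = parse_hmm_thresholds(config.hmm_file)
    tally = ann.FilterTally()
    all_best: list[ann.BestAnnotation] = []
    for row in metadata.itertuples():
        entry_id = int(row.entry_id)
        domtbl = Path(config.domtbl_dir) / f"{entry_id}.domtblout.tab"
        hits = ann.filter_trusted(parse_domtbl(domtbl), thresholds, tally)
        deflines = {
            r.seq_id: (r.seq_id + " " + r.description).strip()
            for r in read_fasta(_aa_path(out, entry_id), "aa")
        }
        all_best.extend(ann.best_annotations(hits, entry_id, deflines))
    ann.write_best_pfam(all_best, out / "candidate_best_pfam.csv")
    ann.write_entry_pfam_sums(
        ann.entry_pfam_summary(all_best), out / "entry_pfam_sums.csv"
    )
    manifest.mark(
        "annotate",
        n_annotated_seqs=len(all_best),
        n_below_cutoff=tally.n_below_cutoff,
        n_missing_threshold=tally.n_missing_threshold,
    )


def _stage_validate(config, metadata, tree, bins, out: Path, manifest) -> None:
    """QC flags, marker selection and the contamination screen."""
    all_best = ann.read_best_pfam(out / "candidate_best_pfam.csv")
    n_pfams = ann.count_entry_pfams(all_best, config.count_mode)
    qc_config = qcmod.QCConfig(
        min_seqs=config.min_seqs,
        min_pfams=config.min_pfams,
        contam_flag_pct=config.contam_flag_pct,
    )

    # early staging on sequence/Pfam floors
    prelim = [
        qcmod.apply_flags(
            int(r.entry_id), str(r.marferret_name), int(r.tax_id),
            int(r.n_seqs_raw), n_pfams.get(int(r.entry_id), 0),
            config=qc_config,
        )
        for r in metadata.itertuples()
    ]
    eligible, _early = qcmod.stage_entries(prelim)

    markers = contam.select_marker_pfams(
        all_best,
        name_patterns=config.marker_name_patterns,
        prevalence_min=config.marker_prevalence,
    )
    hits_by_query = parse_hit_table(config.hits).by_query()
    best_by_entry: dict[int, list[ann.BestAnnotation]] = {}
    for b in all_best:
        best_by_entry.setdefault(b.entry_id, []).append(b)

    external = (
        qcmod.read_external_flags(config.external_flags)
        if config.external_flags
        else pd.DataFrame(columns=["entry_id", "flag_name", "value"])
    )
    lasek_ids = set(
        external.loc[external.flag_name == "FLAG_LASEK", "entry_id"].astype(int)
    )
    vv_pct = {
        int(r.entry_id): float(r.value)
        for r in external.loc[external.flag_name == "VV_contam_pct"].itertuples()
    }

    reports: dict[int, contam.ContamReport] = {}
    records: list[qcmod.CurationRecord] = []
    for row in metadata.itertuples():
        entry_id = int(row.entry_id)
        report = None
        if entry_id in eligible:
            report = contam.estimate_contamination(
                entry_id,
                int(row.tax_id),
                best_by_entry.get(entry_id, []),
                markers,
                hits_by_query,
                tree,
                bins,
                evalue_max=config.lca_evalue_max,
                top_frac=config.top_bitscore_frac,
                unknown_policy=config.unknown_policy,
                marferret_name=str(row.marferret_name),
            )
            reports[entry_id] = report
        records.append(
            qcmod.apply_flags(
                entry_id,
                str(row.marferret_name),
                int(row.tax_id),
                int(row.n_seqs_raw),
                n_pfams.get(entry_id, 0),
                rp63=report,
                lasek_flagged=entry_id in lasek_ids,
                vv_contam_pct=vv_pct.get(entry_id),
                config=qc_config,
            )
        )
    contam.write_contam_reports(
        [reports[e] for e in sorted(reports)], bins, out / "RP63_QC_estimates.csv"
    )
    qcmod.write_curation(records, out / "entry_curation.csv")
    manifest.mark(
        "validate",
        n_marker_families=len(markers),
        n_eligible=len(eligible),
        n_accepted=sum(1 for r in records if r.accepted == "Y"),
    )


def _stage_cluster(config, metadata, tree, bins, out: Path, manifest) -> None:
    """Pool accepted entries by taxid, cluster, and rename with stable
    mft identifiers."""
    curation = qcmod.read_curation(out / "entry_curation.csv")
    accepted = {r.entry_id for r in curation if r.accepted == "Y"}
    meta = metadata.copy()
    meta["accepted"] = [
        "Y" if int(e) in accepted else "N" for e in meta["entry_id"]
    ]
    seqs_by_entry = {
        int(r.entry_id): read_fasta(_aa_path(out, int(r.entry_id)), "aa")
        for r in meta.itertuples()
        if int(r.entry_id) in accepted
    }
    pools = clu.pool_by_taxid(seqs_by_entry, meta)
    clusters: list[clu.ProteinCluster] = []
    for tax_id in sorted(pools):
        clusters.extend(
            clu.greedy_cluster(
                pools[tax_id],
                threshold=config.cluster_identity,
                coverage=config.cluster_coverage,
                tax_id=tax_id,
            )
        )
    ids = clu.assign_ids(clusters)
    clu.write_proteins(clusters, ids, out / "proteins.faa")
    clu.write_proteins_info(clusters, ids, out / "proteins_info.tab")
    clu.write_taxonomies(clusters, ids, out / "taxonomies.tab")

    # propagate the representatives' annotations onto the mft ids
    all_best = {b.aa_id: b for b in ann.read_best_pfam(out / "candidate_best_pfam.csv")}
    final_best = []
    for cluster in clusters:
        rep = cluster.representative
        b = all_best.get(rep.record.seq_id)
        if b is None:
            continue
        final_best.append(
            ann.BestAnnotation(
                aa_id=ids[rep.record.seq_id],
                entry_id=b.entry_id,
                pfam_id=b.pfam_id,
                pfam_name=b.pfam_name,
                source_defline=b.source_defline,
            )
        )
    final_best.sort(key=lambda b: b.aa_id)
    ann.write_best_pfam(final_best, out / "best_pfam.csv")
    manifest.mark(
        "cluster",
        n_pooled=sum(len(p) for p in pools.values()),
        n_clusters=len(clusters),
    )


def _stage_ctg(config, metadata, tree, bins, out: Path, manifest) -> None:
    """Core transcribed gene catalogs for the configured lineages."""
    curation = qcmod.read_curation(out / "entry_curation.csv")
    accepted = {r.entry_id for r in curation if r.accepted == "Y"}
    meta = metadata.copy()
    meta["accepted"] = [
        "Y" if int(e) in accepted else "N" for e in meta["entry_id"]
    ]
    all_best = ann.read_best_pfam(out / "candidate_best_pfam.csv")
    if config.lineage_config:
        lineages = ctgmod.read_lineage_config(config.lineage_config)
    else:
        lineages = [ctgmod.LineageDef(name, bins.taxid(name)) for name in bins.names]
    catalogs = []
    for lin in lineages:
        try:
            matrix = ctgmod.build_presence_matrix(meta, all_best, tree, lin)
        except ValueError:
            continue  # lineage with no qualifying entries
        catalogs.append(
            ctgmod.derive_ctg(
                matrix, config.ctg_frequency, lineage=lin.name, taxid=lin.taxid
            )
        )
    ctgmod.write_core_genes(catalogs, out / "core_genes.csv")
    manifest.mark("ctg", n_ctg_lineages=len(catalogs))


_STAGE_FUNCS = {
    "translate": _stage_translate,
    "annotate": _stage_annotate,
    "validate": _stage_validate,
    "cluster": _stage_cluster,
    "ctg": _stage_ctg,
}
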