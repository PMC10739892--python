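"""Entry validation flags and the curation table.

Five metrics decide whether a candidate entry enters the final build:
a raw sequence-count floor (LOW_SEQS, < 1,200 sequences), a Pfam
annotation floor (LOW_PFAMS, < 500 distinct families, only assigned
when LOW_SEQS is absent), two externally reported contamination flags
(FLAG_LASEK for listed ciliate entries; FLAG_VV for external estimates
over 50%), and the marker-based screen of this toolkit (FLAG_RP63,
estimated contamination over 50%). Entries carrying any flag are
nominally rejected; the accepted column remains user-overridable to
customize a build.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .contamination import ContamReport
from .formats import _open_text

__all__ = [
    "QCConfig",
    "CurationRecord",
    "apply_flags",
    "stage_entries",
    "override_accepted",
    "write_curation",
    "read_curation",
    "read_external_flags",
    "CURATION_COLUMNS",
]

#: Entries whose externally reported 100%-contamination calls are
#: suppressed: the external study used the wrong taxid for them.
DEFAULT_VV_OVERRIDE_IDS = frozenset({378, 379, 380, 381, 504, 505, 506, 507})

FLAG_LOW_SEQS = "LOW_SEQS"
FLAG_LOW_PFAMS = "LOW_PFAMS"
FLAG_LASEK = "FLAG_LASEK"
FLAG_VV = "FLAG_VV"
FLAG_RP63 = "FLAG_RP63"


@dataclass(frozen=True)
class QCConfig:
    """Validation thresholds; strict inequalities throughout
    (< min_seqs, < min_pfams, > contam_flag_pct)."""

    min_seqs: int = 1200
    min_pfams: int = 500
    contam_flag_pct: float = 50.0
    vv_override_ids: frozenset[int] = DEFAULT_VV_OVERRIDE_IDS


CURATION_COLUMNS = (
    "entry_id",
    "marferret_name",
    "tax_id",
    "taxID_status",
    "taxID_notes",
    "n_seqs_raw",
    "n_pfams",
    "qc_flag",
    "flag_Lasek",
    "VV_contam_pct",
    "flag_VanVlierberghe",
    "rp63_npfams",
    "rp63_contam_pct",
    "flag_rp63",
    "flag_sum",
    "accepted",
)


@dataclass
class CurationRecord:
    """One row of the entry curation table."""

    entry_id: int
    marferret_name: str
    tax_id: int
    n_seqs_raw: int
    n_pfams: int
    taxID_status: str = ""
    taxID_notes: str = ""
    qc_flag: str = ""
    flag_Lasek: str = ""
    VV_contam_pct: float | None = None
    flag_VanVlierberghe: str = ""
    rp63_npfams: int | None = None
    rp63_contam_pct: float | None = None
    flag_rp63: str = ""
    flag_sum: int = 0
    accepted: str = "Y"

    def flags(self) -> list[str]:
        return [
            f
            for f in (
                self.qc_flag,
                self.flag_Lasek,
                self.flag_VanVlierberghe,
                self.flag_rp63,
            )
            if f
        ]


def apply_flags(
    entry_id: int,
    marferret_name: str,
    tax_id: int,
    n_seqs_raw: int,
    n_pfams: int,
    *,
    rp63: ContamReport | None = None,
    lasek_flagged: bool = False,
    vv_contam_pct: float | None = None,
    config: QCConfig = QCConfig(),
    taxID_status: str = "",
    taxID_notes: str = "",
) -> CurationRecord:
    """Evaluate every validation metric for one entry.

    ``flag_sum`` counts the set flag columns, and ``accepted`` is Y
    exactly when it is zero. LOW_PFAMS is only assigned to entries not
    already flagged LOW_SEQS, so ``qc_flag`` carries at most one value.
    External 100%-contamination reports for entries on the override
    list are suppressed.
    """
    qc_flag = ""
    if n_seqs_raw < config.min_seqs:
        qc_flag = FLAG_LOW_SEQS
    elif n_pfams < config.min_pfams:
        qc_flag = FLAG_LOW_PFAMS

    flag_lasek = FLAG_LASEK if lasek_flagged else ""

    flag_vv = ""
    if (
        vv_contam_pct is not None
        and vv_contam_pct > config.contam_flag_pct
        and entry_id not in config.vv_override_ids
    ):
        flag_vv = FLAG_VV

    rp63_npfams: int | None = None
    rp63_pct: float | None = None
    flag_rp63 = ""
    if rp63 is not None:
        rp63_npfams = rp63.n_pfams
        rp63_pct = rp63.contam_pct
        if rp63_pct is not None and rp63_pct > config.contam_flag_pct:
            flag_rp63 = FLAG_RP63

    record = CurationRecord(
        entry_id=entry_id,
        marferret_name=marferret_name,
        tax_id=tax_id,
        n_seqs_raw=n_seqs_raw,
        n_pfams=n_pfams,
        taxID_status=taxID_status,
        taxID_notes=taxID_notes,
        qc_flag=qc_flag,
        flag_Lasek=flag_lasek,
        VV_contam_pct=vv_contam_pct,
        flag_VanVlierberghe=flag_vv,
        rp63_npfams=rp63_npfams,
        rp63_contam_pct=rp63_pct,
        flag_rp63=flag_rp63,
    )
    record.flag_sum = len(record.flags())
    record.accepted = "Y" if record.flag_sum == 0 else "N"
    return record


def stage_entries(
    records: Iterable[CurationRecord],
) -> tuple[set[int], set[int]]:
    """Split entries into those eligible for marker-based contamination
    estimation and those rejected early on sequence/Pfam floors."""
    eligible: set[int] = set()
    rejected: set[int] = set()
    for r in records:
        if r.qc_flag in (FLAG_LOW_SEQS, FLAG_LOW_PFAMS):
            rejected.add(r.entry_id)
        else:
            eligible.add(r.entry_id)
    return eligible, rejected


def override_accepted(
    record: CurationRecord,
    accepted: str,
    log: list[str] | None = None,
) -> CurationRecord:
    """Apply a user override of the acceptance decision, keeping an
    audit trail of the change."""
    if accepted not in ("Y", "N"):
        raise ValueError("accepted must be 'Y' or 'N'")
    if log is not None and accepted != record.accepted:
        log.append(
            f"entry {record.entry_id}: accepted {record.accepted} -> {accepted}"
            " (user override)"
        )
    new = replace(record)
    new.accepted = accepted
    return new


def _fmt_opt(value: float | int | None) -> object:
    return "" if value is None else value


def write_curation(records: Sequence[CurationRecord], path: str | Path) -> None:
    """Write the curation table with the published column order."""
    rows = []
    for r in records:
        rows.append(
            {
                "entry_id": r.entry_id,
                "marferret_name": r.marferret_name,
                "tax_id": r.tax_id,
                "taxID_status": r.taxID_status,
                "taxID_notes": r.taxID_notes,
                "n_seqs_raw": r.n_seqs_raw,
                "n_pfams": r.n_pfams,
                "qc_flag": r.qc_flag,
                "flag_Lasek": r.flag_Lasek,
                "VV_contam_pct": _fmt_opt(r.VV_contam_pct),
                "flag_VanVlierberghe": r.flag_VanVlierberghe,
                "rp63_npfams": _fmt_opt(r.rp63_npfams),
                "rp63_contam_pct": _fmt_opt(r.rp63_contam_pct),
                "flag_rp63": r.flag_rp63,
                "flag_sum": r.flag_sum,
                "accepted": r.accepted,
            }
        )
    df = pd.DataFrame(rows, columns=list(CURATION_COLUMNS))
    with _open_text(path, "wt") as handle:
        df.to_csv(handle, index=False)


def read_curation(path: str | Path) -> list[CurationRecord]:
    with _open_text(path) as handle:
        df = pd.read_csv(handle, keep_default_na=False)
    missing = [c for c in CURATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")

    def opt_float(v: object) -> float | None:
        return None if v == "" else float(v)

    def opt_int(v: object) -> int | None:
        return None if v == "" else int(float(v))

    records = []
    for r in df.itertuples():
        records.append(
            CurationRecord(
                entry_id=int(r.entry_id),
                marferret_name=str(r.marferret_name),
                tax_id=int(r.tax_id),
                taxID_status=str(r.taxID_status),
                taxID_notes=str(r.taxID_notes),
                n_seqs_raw=int(r.n_seqs_raw),
                n_pfams=int(r.n_pfams),
                qc_flag=str(r.qc_flag),
                flag_Lasek=str(r.flag_Lasek),
                VV_contam_pct=opt_float(r.VV_contam_pct),
                flag_VanVlierberghe=str(r.flag_VanVlierberghe),
                rp63_npfams=opt_int(r.rp63_npfams),
                rp63_contam_pct=opt_float(r.rp63_contam_pct),
                flag_rp63=str(r.flag_rp63),
                flag_sum=int(r.flag_sum),
                accepted=str(r.accepted),
            )
        )
    return records


def read_external_flags(path: str | Path) -> pd.DataFrame:
    """Read an external flag table: CSV with entry_id, flag_name, value
    columns (e.g. reported contamination percentages or listed flags)."""
    df = pd.read_csv(path)
    required = ("entry_id", "flag_name", "value")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df
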