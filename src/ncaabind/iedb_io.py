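"""Reading IEDB-style affinity exports and the filter cascade producing the modeling dataset.

The export is a delimited table whose five columns of interest are
``Name``, ``Qualitative Measurement``, ``Quantitative Measurement``,
``Response Measured`` and ``HLA``.  Records are filtered to a single HLA
allele, a single response type (IC50 in nM), a present quantitative value,
and at least one NCAA in the peptide; the regression target is
log10(IC50 / nM).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .notation import ModifiedPeptide, NotationError, is_ncaa_token, parse_epitope_name, tokenize

__all__ = [
    "AffinityRecord",
    "FilterConfig",
    "FilterReport",
    "AffinityDataset",
    "SchemaError",
    "COLUMNS",
    "read_export",
    "apply_filters",
    "to_target",
    "build_dataset",
]

logger = logging.getLogger(__name__)

#: canonical header names of the five columns of interest
COLUMNS = {
    "name": "Name",
    "qualitative": "Qualitative Measurement",
    "quantitative": "Quantitative Measurement",
    "response_measured": "Response Measured",
    "hla": "HLA",
}

#: accepted aliases per logical column (checked after exact match fails)
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "name": ("Epitope Name", "Description"),
    "qualitative": ("Qualitative Measure",),
    "quantitative": ("Quantitative measurement",),
    "response_measured": ("Assay Response", "Response measured"),
    "hla": ("MHC Restriction", "Allele Name"),
}

IC50_ALIASES = ("IC50", "half maximal inhibitory concentration (IC50)")


class SchemaError(ValueError):
    """Raised when a mandatory column is absent from an export file."""


@dataclass(frozen=True)
class AffinityRecord:
    """One row of an affinity export (pre- or post-filter)."""

    name: str
    hla: str | None = None
    response_measured: str | None = None
    quantitative: float | None = None
    qualitative: str | None = None
    epitope_iri: str | None = None


@dataclass(frozen=True)
class FilterConfig:
    """Selection rules applied to exported records."""

    hla_allele: str = "HLA-A*02:01"
    response_type: str = "IC50"
    unit: str = "nM"
    require_ncaa: bool = True

    def response_matches(self, value: str | None) -> bool:
        if value is None:
            return False
        v = value.strip()
        if self.response_type == "IC50":
            return v in IC50_ALIASES
        return v == self.response_type


@dataclass
class FilterReport:
    """Per-rule removal counts, in cascade order."""

    n_in: int = 0
    removed_no_ncaa: int = 0
    removed_missing_quantitative: int = 0
    removed_wrong_hla: int = 0
    removed_wrong_response: int = 0
    n_kept: int = 0

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class AffinityDataset:
    """Filtered records with their log10(IC50 nM) regression targets."""

    records: list[AffinityRecord]
    targets: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.targets is None:
            self.targets = np.array(
                [to_target(r.quantitative) for r in self.records], dtype=float
            )
        self.targets = np.asarray(self.targets, dtype=float)
        if len(self.records) != self.targets.size:
            raise ValueError("records and targets length mismatch")
        if self.targets.size and not np.all(np.isfinite(self.targets)):
            raise ValueError("non-finite regression target")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def peptides(self) -> list[ModifiedPeptide]:
        return [parse_epitope_name(r.name) for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Name": [r.name for r in self.records],
                "HLA": [r.hla for r in self.records],
                "Response Measured": [r.response_measured for r in self.records],
                "Quantitative Measurement": [r.quantitative for r in self.records],
                "Qualitative Measurement": [r.qualitative for r in self.records],
                "log10_ic50_nm": self.targets,
            }
        )


def _resolve_columns(header: list[str]) -> dict[str, str]:
    resolved = {}
    missing = []
    for logical, canonical in COLUMNS.items():
        if canonical in header:
            resolved[logical] = canonical
            continue
        alias = next((a for a in COLUMN_ALIASES.get(logical, ()) if a in header), None)
        if alias is not None:
            resolved[logical] = alias
        elif logical == "qualitative":
            resolved[logical] = ""  # optional column, carried but unused
        else:
            missing.append(canonical)
    if missing:
        raise SchemaError(
            f"missing mandatory column(s) {missing}; found headers {header}"
        )
    return resolved


def _parse_quantitative(cell: str | None, row_index: int) -> float | None:
    if cell is None:
        return None
    text = str(cell).strip()
    if not text or text.upper() in {"NA", "NAN", "NONE", "NULL"}:
        return None
    if text[0] in "<>":
        logger.warning(
            "row %d: censored quantitative value %r treated as absent", row_index, text
        )
        return None
    try:
        value = float(text.replace(",", ""))
    except ValueError:
        logger.warning(
            "row %d: unparseable quantitative value %r treated as absent",
            row_index,
            text,
        )
        return None
    if not math.isfinite(value) or value <= 0:
        logger.warning(
            "row %d: non-positive quantitative value %r treated as absent",
            row_index,
            text,
        )
        return None
    return value


def read_export(path, delimiter: str | None = None) -> list[AffinityRecord]:
    """Read an IEDB-style export into :class:`AffinityRecord` objects.

    The delimiter is sniffed from the header line (comma vs tab) unless
    given.  Columns are located by exact header match with a small alias
    table; extra columns are ignored; empty cells become absent values.
    """
    with open(path, newline="") as fh:
        head = fh.readline()
        if not head:
            raise SchemaError(f"{path}: empty file, no header row")
        if delimiter is None:
            delimiter = "\t" if head.count("\t") >= head.count(",") else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        cols = _resolve_columns(list(header))
        records = []
        for i, row in enumerate(reader):
            def get(logical: str) -> str | None:
                col = cols.get(logical, "")
                if not col:
                    return None
                cell = row.get(col)
                cell = cell.strip() if isinstance(cell, str) else cell
                return cell or None

            records.append(
                AffinityRecord(
                    name=get("name") or "",
                    hla=get("hla"),
                    response_measured=get("response_measured"),
                    quantitative=_parse_quantitative(row.get(cols["quantitative"]), i),
                    qualitative=get("qualitative"),
                    epitope_iri=(row.get("Epitope IRI") or "").strip() or None,
                )
            )
    return records


def _has_ncaa(name: str) -> bool:
    try:
        return any(is_ncaa_token(t) for t in tokenize(parse_epitope_name(name)))
    except NotationError as exc:
        logger.info("unparseable name %r counted as lacking an NCAA: %s", name, exc)
        return False


def apply_filters(
    records: list[AffinityRecord], config: FilterConfig | None = None
) -> tuple[list[AffinityRecord], FilterReport]:
    """Apply the filter cascade and return (kept records, per-rule report).

    Cascade order: NCAA presence, then non-absent quantitative value, then
    HLA allele, then response type.  Order affects only the per-rule counts,
    never the surviving set.  Input order is preserved.
    """
    config = config or FilterConfig()
    report = FilterReport(n_in=len(records))
    kept = []
    for rec in records:
        if config.require_ncaa and not _has_ncaa(rec.name):
            report.removed_no_ncaa += 1
        elif rec.quantitative is None:
            report.removed_missing_quantitative += 1
        elif (rec.hla or "").strip() != config.hla_allele:
            report.removed_wrong_hla += 1
        elif not config.response_matches(rec.response_measured):
            report.removed_wrong_response += 1
        else:
            kept.append(rec)
    report.n_kept = len(kept)
    return kept, report


def to_target(ic50_nm: float) -> float:
    """log10 of an IC50 in nM — the regression target."""
    if ic50_nm is None or not math.isfinite(ic50_nm) or ic50_nm <= 0:
        raise ValueError(f"IC50 must be positive and finite, got {ic50_nm!r}")
    return math.log10(ic50_nm)


def dedup_median(records: list[AffinityRecord]) -> list[AffinityRecord]:
    """Collapse duplicate (name, HLA) rows to their median quantitative value.

    Off by default: replicate measurements are normally kept as independent
    records.
    """
    groups: dict[tuple[str, str | None], list[AffinityRecord]] = {}
    order: list[tuple[str, str | None]] = []
    for rec in records:
        key = (rec.name, rec.hla)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(rec)
    out = []
    for key in order:
        grp = groups[key]
        med = float(np.median([r.quantitative for r in grp]))
        first = grp[0]
        out.append(
            AffinityRecord(
                name=first.name,
                hla=first.hla,
                response_measured=first.response_measured,
                quantitative=med,
                qualitative=first.qualitative,
                epitope_iri=first.epitope_iri,
            )
        )
    return out


def build_dataset(
    path, config: FilterConfig | None = None, dedup: bool = False
) -> tuple[AffinityDataset, FilterReport]:
    """Read an export, filter it, and attach log10(IC50) targets."""
    records = read_export(path)
    kept, report = apply_filters(records, config)
    if dedup:
        kept = dedup_median(kept)
    return AffinityDataset(kept), report
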