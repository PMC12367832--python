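"""CSV readers/writers and structured configuration.

Conventions: comma-separated UTF-8 with a mandatory header row; column
matching is case-insensitive; unknown extra columns are preserved on read
but ignored (real ToxCast exports carry many fields).  Units are fixed by
schema — AC50 and Cmax in µM, molecular weight in g/mol, CLint in
µL/min/10^6 cells — and never auto-converted.
"""

from __future__ import annotations

import csv
import logging
import tomllib
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence

import pandas as pd

from .datamodel import (
    AssayResult,
    CmaxPrediction,
    EPAAMatrix,
    FrameworkConfig,
    HeadingSet,
    Level,
    ModelPrediction,
    PKParameters,
    Provenance,
    WoEChecklist,
    _cells,
)
from .errors import NamlocError, SchemaError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import ChemicalAssessment

log = logging.getLogger("namloc.io")

_TRUE = {"true", "1", "yes", "t", "y", "active"}
_FALSE = {"false", "0", "no", "f", "n", "inactive"}

ASSAY_COLUMNS = (
    "chem_id", "assay_name", "target_family", "target_subfamily",
    "biological_process", "tissue", "active", "ac50_um",
)


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def _parse_bool(raw: str, where: str) -> bool:
    key = raw.strip().lower()
    if key in _TRUE:
        return True
    if key in _FALSE:
        return False
    raise ValidationError(f"{where}: cannot parse active flag {raw!r}")


def _parse_float(raw: str, where: str, name: str) -> Optional[float]:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise ValidationError(f"{where}: cannot parse {name} {raw!r}") from exc


def read_assay_table(path: str | Path) -> list[AssayResult]:
    """Read an in vitro assay table into :class:`AssayResult` records.

    Inactive rows must carry a blank AC50; active rows must carry a positive
    finite AC50 in µM.  Row numbers (1-based, excluding header) are retained
    for error messages.
    """
    df = _read_table(path, ASSAY_COLUMNS)
    records: list[AssayResult] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        where = f"{path} row {i}"
        active = _parse_bool(getattr(row, "active"), where)
        ac50 = _parse_float(getattr(row, "ac50_um"), where, "ac50_um")
        try:
            rec = AssayResult(
                chem_id=getattr(row, "chem_id").strip(),
                assay_name=getattr(row, "assay_name").strip(),
                target_family=getattr(row, "target_family").strip(),
                target_subfamily=getattr(row, "target_subfamily").strip(),
                biological_process=getattr(row, "biological_process").strip(),
                tissue=getattr(row, "tissue").strip(),
                active=active,
                ac50_um=ac50,
                row=i,
            )
        except ValidationError as exc:
            raise ValidationError(f"{where}: {exc}") from exc
        records.append(rec)
    return records


def write_assay_table(records: Sequence[AssayResult], path: str | Path) -> None:
    """Write assay records in the schema read by :func:`read_assay_table`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ASSAY_COLUMNS)
        for r in records:
            writer.writerow([
                r.chem_id, r.assay_name, r.target_family, r.target_subfamily,
                r.biological_process, r.tissue,
                "true" if r.active else "false",
                "" if r.ac50_um is None else repr(r.ac50_um),
            ])


def read_prediction_table(path: str | Path) -> list[ModelPrediction]:
    """Read per-model (Q)SAR predictions."""
    required = ("chem_id", "model_id", "endpoint", "outcome")
    df = _read_table(path, required)
    optional = ("in_domain", "reliable", "relevant")
    records = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        kwargs = {c: getattr(row, c).strip().lower() for c in optional if c in df.columns}
        rec = ModelPrediction(
            chem_id=getattr(row, "chem_id").strip(),
            model_id=getattr(row, "model_id").strip(),
            endpoint=getattr(row, "endpoint").strip(),
            outcome=getattr(row, "outcome").strip().lower(),
            **kwargs,
        )
        key = (rec.chem_id, rec.model_id, rec.endpoint)
        if key in seen:
            raise ValidationError(f"{path} row {i}: duplicate prediction for {key}")
        seen.add(key)
        records.append(rec)
    return records


def read_tk_table(path: str | Path) -> list[PKParameters]:
    """Read chemical-specific toxicokinetic inputs."""
    required = ("chem_id", "molecular_weight", "clint", "fup")
    df = _read_table(path, required)
    optional = ("input_source", "ka", "vd", "f_abs", "renal_mode")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        where = f"{path} row {i}"
        kwargs = {}
        for c in optional:
            if c in df.columns and getattr(row, c).strip():
                raw = getattr(row, c).strip()
                kwargs[c] = raw if c in ("input_source", "renal_mode") else float(raw)
        try:
            rec = PKParameters(
                chem_id=getattr(row, "chem_id").strip(),
                molecular_weight=float(getattr(row, "molecular_weight")),
                clint=float(getattr(row, "clint")),
                fup=float(getattr(row, "fup")),
                **kwargs,
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{where}: {exc}") from exc
        records.append(rec)
    return records


def read_cmax_table(path: str | Path) -> list[CmaxPrediction]:
    """Read externally supplied per-model Cmax predictions (µM)."""
    required = ("chem_id", "model_name", "cmax_um")
    df = _read_table(path, required)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        src = (getattr(row, "input_source").strip()
               if "input_source" in df.columns and getattr(row, "input_source").strip()
               else "in_vitro")
        try:
            records.append(CmaxPrediction(
                chem_id=getattr(row, "chem_id").strip(),
                model_name=getattr(row, "model_name").strip(),
                cmax_um=float(getattr(row, "cmax_um")),
                input_source=src,
            ))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return records


def read_heading_sets(path: str | Path) -> list[HeadingSet]:
    """Read CLP heading sets: ``chem_id`` plus semicolon-separated ``headings``."""
    df = _read_table(path, ("chem_id", "headings"))
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        headings = [h.strip() for h in getattr(row, "headings").split(";") if h.strip()]
        try:
            records.append(HeadingSet(getattr(row, "chem_id").strip(), frozenset(headings)))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return records


def read_woe_table(path: str | Path) -> dict[str, WoEChecklist]:
    """Read curated weight-of-evidence answers, one row per chemical."""
    from .datamodel import WOE_QUESTIONS
    short = {q.split("_")[0]: q for q in WOE_QUESTIONS}  # q1..q8 aliases
    df = _read_table(path, ("chem_id",))
    out: dict[str, WoEChecklist] = {}
    for row in df.itertuples(index=False):
        answers = {}
        for col in df.columns:
            key = col if col in WOE_QUESTIONS else short.get(col)
            if key:
                answers[key] = getattr(row, col).strip().lower()
        out[getattr(row, "chem_id").strip()] = WoEChecklist(answers)
    return out


# --- configuration ---------------------------------------------------------

def read_config(path: str | Path | None = None) -> FrameworkConfig:
    """Load a TOML config file; unspecified keys take the published defaults.

    The EPAA combination matrix can be overridden with a ``[epaa_matrix]``
    table of nine cells keyed ``"<TD><TK>"`` (e.g. ``HM = "H"``).
    """
    if path is None:
        return FrameworkConfig()
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    kwargs = {}
    for key in ("insilico_uf", "dose_mmol_per_kg", "body_weight_kg",
                "negative_predominance"):
        if key in raw:
            kwargs[key] = float(raw.pop(key))
    for key in ("n_days", "strong_min_endpoints", "outlier_min_concordant"):
        if key in raw:
            kwargs[key] = int(raw.pop(key))
    for key in ("ruleset_name", "woe_raise_policy"):
        if key in raw:
            kwargs[key] = str(raw.pop(key))
    for key in ("potency_cutoffs", "bioavailability_cutoffs", "quantiles"):
        if key in raw:
            lo, hi = raw.pop(key)
            kwargs[key] = (float(lo), float(hi))
    if "epaa_matrix" in raw:
        table = raw.pop("epaa_matrix")
        cells = {}
        for key, val in table.items():
            if len(key) != 2:
                raise NamlocError(f"epaa_matrix key {key!r} must be two letters (TD, TK)")
            cells[(key[0].upper(), key[1].upper())] = str(val).upper()
        kwargs["epaa_matrix"] = EPAAMatrix(_cells(cells))
    if raw:
        log.warning("ignoring unknown config keys: %s", sorted(raw))
    return FrameworkConfig(**kwargs)


# --- reports ---------------------------------------------------------------

REPORT_COLUMNS = (
    "chem_id", "insilico_indication", "bioactivity_loc", "bioavailability",
    "overall", "provenance", "label",
    "q1", "q2", "q3", "q4", "q5", "q6", "q7", "q8",
)


def write_assessment_report(results: Sequence["ChemicalAssessment"],
                            path: str | Path) -> None:
    """Write per-chemical assessment rows as CSV plus a human-readable text
    summary alongside (same stem, ``.txt``).

    Chemicals defaulted to High through lack of evidence are flagged
    ``H (insufficient data)`` in the text rendering.
    """
    if not results:
        raise ValidationError("cannot write an empty assessment report")
    path = Path(path)
    rows = []
    for r in results:
        woe = r.overall_result.woe
        rows.append({
            "chem_id": r.chem_id,
            "insilico_indication": r.indication.band if r.indication else "",
            "bioactivity_loc": r.td_loc.level.value,
            "bioavailability": r.tk_level.value,
            "overall": r.overall_result.overall.level.value,
            "provenance": r.overall_result.overall.provenance.value,
            "label": r.overall_result.overall.label,
            **{f"q{i}": woe.answers[q] for i, q in enumerate(
                sorted(woe.answers), start=1)},
        })
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    txt = path.with_suffix(".txt")
    with open(txt, "w", encoding="utf-8") as fh:
        fh.write("Level-of-concern assessment\n")
        fh.write("=" * 60 + "\n")
        for r in results:
            loc = r.overall_result.overall
            if loc.provenance is Provenance.DEFAULT_INSUFFICIENT_EVIDENCE:
                shown = f"{loc.level.value} (insufficient data)"
            else:
                shown = loc.level.value
            fh.write(f"{r.chem_id:24s} TD={r.td_loc.level.value} "
                     f"TK={r.tk_level.value} overall={shown}\n")
            for line in r.overall_result.audit:
                fh.write(f"    - {line}\n")
    log.info("wrote assessment report for %d chemicals to %s", len(results), path)
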