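"""Reading and writing strain marker tables, survey tables and result reports.

Profile matrices are delimited text (TSV or CSV), one row per strain, one
column per PCR marker, cells coding a tri-state call: present / absent /
unknown.  Unknown is a first-class state distinct from absent — a marker
that was never assayed is not the same as a clean negative — and how the
inference engine treats it is an engine policy, not an I/O decision.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

from .models import GeneMarker, canonical_marker

if TYPE_CHECKING:  # pragma: no cover
    from .engine import ChemotypeResult

logger = logging.getLogger(__name__)

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"

# Cell tokens.  "−" is the Unicode minus that typeset tables use.
_PRESENT_TOKENS = {"+", "1", "present", "p"}
_ABSENT_TOKENS = {"-", "−", "0", "absent", "a"}
_UNKNOWN_TOKENS = {"", "?", "na", "nan", "unknown"}

_CALL_TO_CELL = {PRESENT: "+", ABSENT: "-", UNKNOWN: "?"}

#: Profile table columns that carry strain metadata rather than marker calls.
_META_COLUMNS = {"strain", "host", "location"}


class TableError(ValueError):
    """Malformed input table (bad cell, bad header, broken invariant)."""


@dataclass
class GeneProfile:
    """Tri-state presence/absence calls for one strain."""

    strain_id: str
    calls: dict[str, str]
    host: str | None = None
    location: str | None = None

    def call(self, marker: str) -> str:
        try:
            return self.calls[marker]
        except KeyError:
            raise KeyError(f"strain {self.strain_id}: no call for marker {marker!r}") from None


@dataclass(frozen=True)
class SurveyRecord:
    """One (location, host) field observation."""

    location: str
    host: str
    n_samples: int
    n_infected: int
    n_strains: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_infected", "n_strains"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise TableError(f"{self.location}/{self.host}: {name} must be a non-negative integer, got {v!r}")
        if self.n_infected > self.n_samples:
            raise TableError(
                f"{self.location}/{self.host}: n_infected ({self.n_infected}) exceeds n_samples ({self.n_samples})"
            )


def _parse_cell(token: object, *, strain: str, marker: str) -> str:
    text = str(token).strip()
    low = text.lower()
    if text in _PRESENT_TOKENS or low in _PRESENT_TOKENS:
        return PRESENT
    if text in _ABSENT_TOKENS or low in _ABSENT_TOKENS:
        return ABSENT
    if low in _UNKNOWN_TOKENS:
        return UNKNOWN
    raise TableError(f"illegal cell {text!r} at strain {strain!r}, marker {marker!r}")


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV or CSV into strings; delimiter sniffed from the header."""
    path = Path(path)
    head = path.read_text(encoding="utf-8").splitlines()
    sep = "\t" if (head and head[0].count("\t") >= head[0].count(",")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_profiles(
    path: str | Path,
    markers: Mapping[str, GeneMarker] | None = None,
) -> list[GeneProfile]:
    """Read a strain-by-marker presence/absence table.

    The first column holds the strain id; optional ``host`` / ``location``
    columns are carried as metadata.  Remaining column names are resolved
    through the marker alias map and, when a ``markers`` registry is given,
    must all resolve to registered markers; registered markers missing from
    the table are filled in as *unknown*.
    """
    df = _read_table(path)
    if df.shape[1] == 0:
        raise TableError(f"{path}: empty table")
    first = df.columns[0]
    marker_cols: dict[str, str] = {}  # column name -> canonical marker id
    for col in df.columns[1:]:
        if col.strip().lower() in _META_COLUMNS:
            continue
        marker_cols[col] = canonical_marker(col)

    if markers is not None:
        bad = [col for col, canon in marker_cols.items() if canon not in markers]
        if bad:
            raise TableError(f"{path}: unresolvable marker columns: {bad}")

    meta_cols = {c.strip().lower(): c for c in df.columns[1:] if c.strip().lower() in _META_COLUMNS}

    profiles: list[GeneProfile] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        strain = str(row[first]).strip()
        if not strain:
            raise TableError(f"{path}: empty strain id")
        if strain in seen:
            raise TableError(f"{path}: duplicate strain id {strain!r}")
        seen.add(strain)
        calls = {
            canon: _parse_cell(row[col], strain=strain, marker=canon)
            for col, canon in marker_cols.items()
        }
        if markers is not None:
            for mid in markers:
                calls.setdefault(mid, UNKNOWN)
        for mid, call in calls.items():
            if call == UNKNOWN:
                logger.debug("strain %s: marker %s is unknown", strain, mid)
        profiles.append(
            GeneProfile(
                strain_id=strain,
                calls=calls,
                host=str(row[meta_cols["host"]]).strip() if "host" in meta_cols else None,
                location=str(row[meta_cols["location"]]).strip() if "location" in meta_cols else None,
            )
        )
    return profiles


def write_profiles(profiles: Sequence[GeneProfile], path: str | Path) -> None:
    """Write profiles back to TSV with +/-/? cells (inverse of read_profiles)."""
    path = Path(path)
    marker_ids = sorted({m for p in profiles for m in p.calls})
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["strain", "host", "location", *marker_ids]) + "\n")
        for p in profiles:
            cells = [_CALL_TO_CELL[p.calls.get(m, UNKNOWN)] for m in marker_ids]
            fh.write("\t".join([p.strain_id, p.host or "", p.location or "", *cells]) + "\n")


def read_survey(path: str | Path) -> list[SurveyRecord]:
    """Read a survey count table with columns location, host, n_samples,
    n_infected and optionally n_strains.  Extra columns (coordinates,
    altitude) are carried nowhere: they are opaque and ignored."""
    df = _read_table(path)
    required = {"location", "host", "n_samples", "n_infected"}
    missing = required - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing survey columns {sorted(missing)}")
    records: list[SurveyRecord] = []
    for idx, row in df.iterrows():
        counts = {}
        for name in ("n_samples", "n_infected") + (("n_strains",) if "n_strains" in df.columns else ()):
            raw = str(row[name]).strip()
            try:
                counts[name] = int(raw)
            except ValueError:
                raise TableError(f"{path} row {idx}: non-integer {name} {raw!r}") from None
        records.append(
            SurveyRecord(
                location=str(row["location"]).strip(),
                host=str(row["host"]).strip(),
                n_samples=counts["n_samples"],
                n_infected=counts["n_infected"],
                n_strains=counts.get("n_strains", 0),
            )
        )
    return records


# --- result reports -------------------------------------------------------

RESULT_COLUMNS = (
    "strain",
    "mating_type",
    "ppz_allele",
    "pattern_PPZ",
    "pattern_EAS",
    "pattern_IDT",
    "pattern_LOL",
    "producible",
    "terminal_products",
    "type",
    "category",
    "warnings",
)


def _result_row(r: "ChemotypeResult") -> list[str]:
    return [
        r.strain_id,
        r.mating_type,
        r.ppz_allele,
        r.pattern_codes.get("PPZ", "X"),
        r.pattern_codes.get("EAS", "X"),
        r.pattern_codes.get("IDT", "X"),
        r.pattern_codes.get("LOL", "X"),
        ",".join(r.producible_ordered),
        ",".join(sorted(r.terminal_products)),
        str(r.chem_type),
        r.safety_category,
        ";".join(r.warnings),
    ]


def format_results(results: Sequence["ChemotypeResult"]) -> str:
    """Render results as a TSV string with a fixed, deterministic column
    order; identical inputs yield byte-identical output."""
    buf = _io.StringIO()
    buf.write("\t".join(RESULT_COLUMNS) + "\n")
    for r in results:
        buf.write("\t".join(_result_row(r)) + "\n")
    return buf.getvalue()


def write_results(results: Sequence["ChemotypeResult"], path: str | Path) -> None:
    if not results:
        raise TableError("no results to write")
    Path(path).write_text(format_results(results), encoding="utf-8", newline="\n")


def write_results_json(results: Sequence["ChemotypeResult"], path: str | Path) -> None:
    payload = [r.to_dict() for r in results]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


# --- bundled fixtures -----------------------------------------------------

def fixture_path(name: str) -> Path:
    """Path to a bundled data file (e.g. 'strain_profiles.tsv', 'survey.tsv')."""
    return Path(str(resources.files("endochem.data") / name))


def load_fixture_profiles(markers: Mapping[str, GeneMarker] | None = None) -> list[GeneProfile]:
    """The bundled 20-strain field-survey marker table."""
    return read_profiles(fixture_path("strain_profiles.tsv"), markers)


def load_fixture_survey() -> list[SurveyRecord]:
    """The bundled six-row infection survey table."""
    return read_survey(fixture_path("survey.tsv"))
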