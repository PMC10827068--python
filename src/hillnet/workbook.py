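"""Read/write the two-sheet model workbook; Cytoscape and CSV exports.

The workbook dialect has a "species" sheet and a "reactions" sheet.
Header rows are found by content (a row containing "ID" plus "Yinit" or
"Rule"), not by position, because published workbooks carry decorative
preamble rows.  Recognized columns:

    species:   module, ID, name, Yinit, Ymax, tau, notes, refs
    reactions: module, ID, Rule, Weight, n, EC50, notes, refs

Anything else is preserved verbatim as metadata and written back on
export.  Blank parameter cells take the dialect defaults (tau=1, ymax=1,
yinit=0, w=1, n=1.4, ec50=0.5).  Rule cells may carry a leading
apostrophe so spreadsheet software does not treat "=>" as a formula; it
is stripped on read and re-added on write.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from . import model as M
from .dynamics import TimeCourse
from .model import NetworkModel, Reaction, RuleParseError, Species

__all__ = [
    "WorkbookError",
    "read_model_workbook",
    "write_model_workbook",
    "export_cytoscape_edges",
    "write_timecourse",
    "read_timecourse",
]


class WorkbookError(ValueError):
    """Structural or validation failure while reading a model workbook.

    Carries 1-based sheet/row coordinates in its messages.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


_SPECIES_HEADERS = {
    "module": "module_tag",
    "id": "id",
    "name": "name",
    "yinit": "y_init",
    "ymax": "y_max",
    "tau": "tau",
    "notes": "notes",
    "refs": "refs",
}
_REACTION_HEADERS = {
    "module": "module_tag",
    "id": "id",
    "rule": "rule_text",
    "weight": "w",
    "n": "n",
    "ec50": "ec50",
    "notes": "notes",
    "refs": "refs",
}


def _cell_str(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v).strip()


def _find_sheet(wb, name: str):
    for sheet in wb.worksheets:
        if sheet.title.strip().lower() == name:
            return sheet
    return None


def _find_header(rows: list[tuple], required: set[str]) -> int | None:
    """Index of the first row whose lowercased cells cover ``required``."""
    for i, row in enumerate(rows):
        cells = {_cell_str(c).lower() for c in row}
        if required <= cells:
            return i
    return None


def _number(cell, default: float, sheet: str, row: int, col: str, problems: list[str]) -> float:
    s = _cell_str(cell)
    if s == "":
        return default
    try:
        return float(s)
    except ValueError:
        problems.append(f"sheet {sheet!r} row {row}: column {col!r} has non-numeric value {s!r}")
        return default


def read_model_workbook(path) -> NetworkModel:
    """Parse a two-sheet workbook into a validated :class:`NetworkModel`.

    All structural problems and validation errors are aggregated into a
    single :class:`WorkbookError` with sheet/row coordinates; validation
    warnings (e.g. y_init above y_max) do not block loading.
    """
    import openpyxl

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    wb = openpyxl.load_workbook(path, data_only=True)
    problems: list[str] = []

    sp_sheet = _find_sheet(wb, "species")
    rx_sheet = _find_sheet(wb, "reactions")
    if sp_sheet is None:
        problems.append("workbook has no 'species' sheet")
    if rx_sheet is None:
        problems.append("workbook has no 'reactions' sheet")
    if problems:
        raise WorkbookError(problems)

    species = _read_species(sp_sheet, problems)
    reactions = _read_reactions(rx_sheet, problems)
    if problems:
        raise WorkbookError(problems)

    mdl = NetworkModel(species, reactions)
    errors = [i for i in M.validate_model(mdl) if i.severity == "error"]
    if errors:
        raise WorkbookError([f"validation: {i.location}: {i.message}" for i in errors])
    return mdl


def _read_species(sheet, problems: list[str]) -> list[Species]:
    rows = [tuple(r) for r in sheet.iter_rows(values_only=True)]
    hdr = _find_header(rows, {"id", "yinit"})
    if hdr is None:
        problems.append(f"sheet {sheet.title!r}: no header row containing 'ID' and 'Yinit'")
        return []
    headers = [_cell_str(c) for c in rows[hdr]]
    out: list[Species] = []
    for offset, row in enumerate(rows[hdr + 1 :], start=hdr + 2):
        cells = dict(zip(headers, row))
        fields: dict = {}
        extra: list[tuple[str, str]] = []
        for h in headers:
            key = _SPECIES_HEADERS.get(h.lower())
            if key is None and h and _cell_str(cells.get(h)) != "":
                extra.append((h, _cell_str(cells.get(h))))
        sid = _cell_str(cells.get(_header_for(headers, "id")))
        if sid == "":
            continue  # blank row
        fields["id"] = sid
        fields["name"] = _cell_str(cells.get(_header_for(headers, "name")))
        fields["module_tag"] = _cell_str(cells.get(_header_for(headers, "module")))
        fields["notes"] = _cell_str(cells.get(_header_for(headers, "notes")))
        fields["refs"] = _cell_str(cells.get(_header_for(headers, "refs")))
        fields["y_init"] = _number(
            cells.get(_header_for(headers, "yinit")), M.DEFAULT_YINIT, sheet.title, offset, "Yinit", problems
        )
        fields["y_max"] = _number(
            cells.get(_header_for(headers, "ymax")), M.DEFAULT_YMAX, sheet.title, offset, "Ymax", problems
        )
        fields["tau"] = _number(
            cells.get(_header_for(headers, "tau")), M.DEFAULT_TAU, sheet.title, offset, "tau", problems
        )
        out.append(Species(extra=tuple(extra), **fields))
    return out


def _read_reactions(sheet, problems: list[str]) -> list[Reaction]:
    rows = [tuple(r) for r in sheet.iter_rows(values_only=True)]
    hdr = _find_header(rows, {"id", "rule"})
    if hdr is None:
        problems.append(f"sheet {sheet.title!r}: no header row containing 'ID' and 'Rule'")
        return []
    headers = [_cell_str(c) for c in rows[hdr]]
    out: list[Reaction] = []
    for offset, row in enumerate(rows[hdr + 1 :], start=hdr + 2):
        cells = dict(zip(headers, row))
        rid = _cell_str(cells.get(_header_for(headers, "id")))
        rule = _cell_str(cells.get(_header_for(headers, "rule")))
        if rid == "" and rule == "":
            continue
        extra = tuple(
            (h, _cell_str(cells.get(h)))
            for h in headers
            if h
            and _REACTION_HEADERS.get(h.lower()) is None
            and _cell_str(cells.get(h)) != ""
        )
        try:
            terms, target = M.parse_rule(rule)
        except RuleParseError as e:
            problems.append(f"sheet {sheet.title!r} row {offset}: {e}")
            continue
        rule_clean = rule[1:].strip() if rule.startswith("'") else rule
        out.append(
            Reaction(
                id=rid,
                rule_text=rule_clean,
                terms=terms,
                target_id=target,
                w=_number(cells.get(_header_for(headers, "weight")), M.DEFAULT_WEIGHT, sheet.title, offset, "Weight", problems),
                n=_number(cells.get(_header_for(headers, "n")), M.DEFAULT_N, sheet.title, offset, "n", problems),
                ec50=_number(cells.get(_header_for(headers, "ec50")), M.DEFAULT_EC50, sheet.title, offset, "EC50", problems),
                module_tag=_cell_str(cells.get(_header_for(headers, "module"))),
                notes=_cell_str(cells.get(_header_for(headers, "notes"))),
                refs=_cell_str(cells.get(_header_for(headers, "refs"))),
                extra=extra,
            )
        )
    return out


def _header_for(headers: list[str], lowered: str) -> str | None:
    for h in headers:
        if h.lower() == lowered:
            return h
    return None


# ---------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------

def write_model_workbook(model: NetworkModel, path) -> Path:
    """Write the two-sheet workbook layout; round-trips losslessly."""
    import openpyxl

    path = Path(path)
    wb = openpyxl.Workbook()
    sp = wb.active
    sp.title = "species"
    sp_extra = _extra_columns(s.extra for s in model.species)
    sp.append(["module", "ID", "name", "Yinit", "Ymax", "tau", "notes", "refs", *sp_extra])
    for s in model.species:
        extras = dict(s.extra)
        sp.append(
            [s.module_tag, s.id, s.name, s.y_init, s.y_max, s.tau, s.notes, s.refs]
            + [extras.get(c, "") for c in sp_extra]
        )

    rx = wb.create_sheet("reactions")
    rx_extra = _extra_columns(r.extra for r in model.reactions)
    rx.append(["module", "ID", "Rule", "Weight", "n", "EC50", "notes", "refs", *rx_extra])
    for r in model.reactions:
        rule = "'" + r.rule_text if r.rule_text.startswith("=") else r.rule_text
        extras = dict(r.extra)
        rx.append(
            [r.module_tag, r.id, rule, r.w, r.n, r.ec50, r.notes, r.refs]
            + [extras.get(c, "") for c in rx_extra]
        )
    wb.save(path)
    return path


def _extra_columns(extras_iter) -> list[str]:
    cols: list[str] = []
    for extras in extras_iter:
        for name, _ in extras:
            if name not in cols:
                cols.append(name)
    return cols


# ---------------------------------------------------------------------
# Cytoscape export
# ---------------------------------------------------------------------

def export_cytoscape_edges(model: NetworkModel, out_prefix) -> tuple[Path, Path]:
    """Write a SIF edge file and an edge-attribute TSV for Cytoscape.

    One SIF line per rule term, ``SOURCE<TAB>activates|inhibits<TAB>TARGET``;
    input reactions appear as pseudo-source nodes ``INPUT_<target>`` so
    stimuli stay visible in the rendered network.  Line order follows
    reaction order, then term order, so the export is deterministic.
    """
    out_prefix = Path(out_prefix)
    sif_path = out_prefix.with_suffix(".sif")
    tsv_path = out_prefix.parent / (out_prefix.name + "_edges.tsv")

    sif_lines: list[str] = []
    attr_rows: list[list[str]] = []
    for r in model.reactions:
        if r.is_input:
            edges = [(f"INPUT_{r.target_id}", "activates", r.target_id)]
        else:
            edges = [
                (t.species_id, "activates" if t.sign > 0 else "inhibits", r.target_id)
                for t in r.terms
            ]
        for src, kind, dst in edges:
            sif_lines.append(f"{src}\t{kind}\t{dst}")
            attr_rows.append([f"{src} ({kind}) {dst}", r.id, repr(r.w), repr(r.n), repr(r.ec50)])

    sif_path.write_text("".join(line + "\n" for line in sif_lines))
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["edge", "reaction", "weight", "n", "ec50"])
        writer.writerows(attr_rows)
    return sif_path, tsv_path


# ---------------------------------------------------------------------
# time-course CSV
# ---------------------------------------------------------------------

def write_timecourse(tc: TimeCourse, path) -> Path:
    """Tidy CSV: a "time" column then one column per species.

    Segment boundaries go into a ``#`` comment header so staged
    protocols remain reconstructible from the file alone.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(
            "# segment_boundaries: "
            + ",".join(repr(b) for b in tc.segment_boundaries)
            + "\n"
        )
        writer = csv.writer(fh)
        writer.writerow(["time", *tc.species_ids])
        for t, row in zip(tc.times, tc.activities):
            writer.writerow([repr(float(t)), *(repr(float(v)) for v in row)])
    return path


def read_timecourse(path) -> TimeCourse:
    """Inverse of :func:`write_timecourse` (exact round-trip)."""
    path = Path(path)
    boundaries: tuple[float, ...] = ()
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                _, _, payload = line.partition(":")
                payload = payload.strip()
                if "segment_boundaries" in line:
                    boundaries = tuple(float(x) for x in payload.split(",") if x)
                continue
            rows.extend(csv.reader([line]))
    if not rows:
        raise WorkbookError(f"time-course file {path} is empty")
    header, *data = rows
    if header[0] != "time":
        raise WorkbookError(f"time-course file {path}: first column must be 'time'")
    arr = np.array([[float(v) for v in row] for row in data])
    return TimeCourse(
        times=arr[:, 0],
        activities=arr[:, 1:],
        species_ids=tuple(header[1:]),
        segment_boundaries=boundaries,
    )
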