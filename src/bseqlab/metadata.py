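"""Three-spreadsheet project metadata: master registry, experiment, lab.

A *project* is described by one row of a master CSV registry (one project
per row, RADAR-style descriptive fields plus pointers to the project's
folder and files), an experiment CSV (one row per animal test, linking to
the data file and carrying the grouping columns), and a lab CSV (the light
schedule).  Reading the master row is enough for the software to locate
every data file, which is what makes a project machine-readable.

All dates are ISO-8601; times of day are 24-hour ``HH:MM``.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path, PurePosixPath

import pandas as pd

from .errors import (
    MetadataParseError,
    MissingMetadataFileError,
    UnknownProjectError,
)

__all__ = [
    "MasterRecord",
    "ExperimentRow",
    "LabRecord",
    "ProjectBundle",
    "ValidationIssue",
    "load_project",
    "validate_project",
    "write_master",
    "is_excluded",
]

#: master-registry fields, in canonical column order
MASTER_FIELDS = (
    "identifier",
    "proj_name",
    "title",
    "creator",
    "contributors",
    "creator_email",
    "publisher",
    "publication_year",
    "production_year",
    "subject_area",
    "resource",
    "rights",
    "rights_holder",
    "description_comments",
    "funder",
    "video_acquisition",
    "video_analysis",
    "group_by",
    "confound_by",
    "source_data",
    "folder_path",
    "raw_data_folder",
    "video_folder",
    "animal_metadata",
    "lab_metadata",
    "identifier_metadata",
)

_REQUIRED_MASTER = (
    "identifier",
    "proj_name",
    "group_by",
    "folder_path",
    "animal_metadata",
    "lab_metadata",
)

# registry headers seen in the wild -> canonical names (incl. a historical
# misspelling of the identifier-metadata pointer)
_HEADER_ALIASES = {
    "funder_information": "funder",
    "description": "description_comments",
    "indentificator_metadata": "identifier_metadata",
    "identificator_metadata": "identifier_metadata",
}

_DATA_KINDS = ("events", "minute_summary", "hour_summary")


def _norm_header(name: str) -> str:
    key = re.sub(r"[^0-9a-z]+", "_", str(name).strip().lower()).strip("_")
    return _HEADER_ALIASES.get(key, key)


def _safe_relpath(value: str, field: str) -> str:
    """Reject absolute paths and parent-escape components."""
    p = PurePosixPath(str(value).replace("\\", "/"))
    if p.is_absolute() or any(part == ".." for part in p.parts):
        raise MetadataParseError(f"{field}: unsafe path {value!r}")
    return str(p)


@dataclass
class MasterRecord:
    """One row of the master registry describing a whole project."""

    identifier: str
    proj_name: str
    group_by: str
    folder_path: str
    animal_metadata: str
    lab_metadata: str
    title: str = ""
    creator: str = ""
    contributors: str = ""
    creator_email: str = ""
    publisher: str = ""
    publication_year: str = ""
    production_year: str = ""
    subject_area: str = ""
    resource: str = ""
    rights: str = ""
    rights_holder: str = ""
    description_comments: str = ""
    funder: str = ""
    video_acquisition: str = ""
    video_analysis: str = ""
    confound_by: str = ""
    source_data: str = ""
    raw_data_folder: str = ""
    video_folder: str = ""
    identifier_metadata: str = ""

    def __post_init__(self) -> None:
        for name in _REQUIRED_MASTER:
            if not str(getattr(self, name)).strip():
                raise MetadataParseError(f"master field {name!r} must be non-empty")
        for name in ("folder_path", "raw_data_folder", "video_folder",
                     "animal_metadata", "lab_metadata", "identifier_metadata"):
            value = getattr(self, name)
            if value:
                setattr(self, name, _safe_relpath(value, name))


@dataclass
class ExperimentRow:
    """One animal test: identity, grouping values, and the data file."""

    animal_id: str
    test_id: str
    group: str
    recording_start: dt.datetime
    data_file: str
    data_kind: str = "events"
    confound: str = ""
    birth_date: dt.date | None = None
    exclude: str = ""
    extra: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data_kind not in _DATA_KINDS:
            raise MetadataParseError(
                f"data_kind {self.data_kind!r} not one of {_DATA_KINDS}"
            )
        self.data_file = _safe_relpath(self.data_file, "data_file")


@dataclass
class LabRecord:
    """Lab conditions: the daily light schedule."""

    lab_id: str
    light_off_time: dt.time
    light_on_time: dt.time
    timezone: str = ""

    def __post_init__(self) -> None:
        if self.light_off_time == self.light_on_time:
            raise MetadataParseError("light_off_time must differ from light_on_time")

    @property
    def night_length_minutes(self) -> int:
        off = self.light_off_time.hour * 60 + self.light_off_time.minute
        on = self.light_on_time.hour * 60 + self.light_on_time.minute
        return (on - off) % (24 * 60)


@dataclass
class ProjectBundle:
    """A fully resolved project: master row, experiment rows, lab record."""

    master: MasterRecord
    experiments: list[ExperimentRow]
    lab: LabRecord
    root: Path  # directory of the master file

    @property
    def project_dir(self) -> Path:
        return self.root / self.master.folder_path

    def data_path(self, row: ExperimentRow) -> Path:
        base = self.project_dir
        if self.master.raw_data_folder:
            base = base / self.master.raw_data_folder
        return base / row.data_file

    def active_experiments(self) -> list[ExperimentRow]:
        return [r for r in self.experiments if not is_excluded(r)]


def is_excluded(row: ExperimentRow) -> bool:
    """A test is excluded when the flag is non-empty and not 0/false/no."""
    return str(row.exclude).strip().lower() not in ("", "0", "false", "no", "nan")


def _parse_datetime(value: str, field: str) -> dt.datetime:
    try:
        return dt.datetime.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise MetadataParseError(f"{field}: cannot parse date-time {value!r}") from exc


def _parse_date(value: str) -> dt.date | None:
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return None
    try:
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise MetadataParseError(f"birth_date: cannot parse date {value!r}") from exc


def _parse_time(value: str, field: str) -> dt.time:
    text = str(value).strip()
    try:
        hh, mm = text.split(":")[:2]
        return dt.time(int(hh), int(mm))
    except (ValueError, IndexError) as exc:
        raise MetadataParseError(f"{field}: cannot parse time-of-day {value!r}") from exc


def _read_csv(path: Path, what: str) -> pd.DataFrame:
    if not path.exists():
        raise MissingMetadataFileError(f"{what} file not found: {path}")
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_experiments(path: Path, group_by: str, confound_by: str = "") -> list[ExperimentRow]:
    """Read the experiment CSV; unknown columns are preserved verbatim."""
    table = _read_csv(path, "experiment metadata")
    cols = {_norm_header(c): c for c in table.columns}
    rows: list[ExperimentRow] = []
    known = {"animal_id", "test_id", "birth_date", "recording_start",
             "data_file", "data_kind", "exclude"}
    for _, rec in table.iterrows():
        def get(name: str, default: str = "") -> str:
            col = cols.get(name)
            return str(rec[col]) if col is not None else default

        group_col = cols.get(_norm_header(group_by))
        group = str(rec[group_col]) if group_col is not None else ""
        confound_col = cols.get(_norm_header(confound_by)) if confound_by else None
        extra = {
            orig: str(rec[orig])
            for norm, orig in cols.items()
            if norm not in known and norm != _norm_header(group_by)
            and (not confound_by or norm != _norm_header(confound_by))
        }
        rows.append(ExperimentRow(
            animal_id=get("animal_id"),
            test_id=get("test_id"),
            group=group,
            confound=str(rec[confound_col]) if confound_col is not None else "",
            birth_date=_parse_date(get("birth_date")),
            recording_start=_parse_datetime(get("recording_start"), "recording_start"),
            data_file=get("data_file"),
            data_kind=get("data_kind", "events") or "events",
            exclude=get("exclude"),
            extra=extra,
        ))
    seen: set[tuple[str, str]] = set()
    for row in rows:
        key = (row.animal_id, row.test_id)
        if key in seen:
            raise MetadataParseError(f"duplicate (animal_id, test_id): {key}")
        seen.add(key)
    return rows


def read_lab(path: Path) -> LabRecord:
    table = _read_csv(path, "lab metadata")
    cols = {_norm_header(c): c for c in table.columns}
    if table.empty:
        raise MetadataParseError(f"lab metadata file {path} has no rows")
    rec = table.iloc[0]

    def get(name: str, default: str = "") -> str:
        col = cols.get(name)
        return str(rec[col]) if col is not None else default

    return LabRecord(
        lab_id=get("lab_id", "lab"),
        light_off_time=_parse_time(get("light_off_time"), "light_off_time"),
        light_on_time=_parse_time(get("light_on_time"), "light_on_time"),
        timezone=get("timezone"),
    )


def load_project(master_file: str | Path, project_id: str) -> ProjectBundle:
    """Load a project by identifier (or project name) from the master registry.

    Relative paths inside the master row are resolved against the project
    folder, itself relative to the master file's directory.
    """
    master_path = Path(master_file)
    table = _read_csv(master_path, "master metadata")
    renamed = table.rename(columns={c: _norm_header(c) for c in table.columns})
    hit = renamed[
        (renamed.get("identifier", "") == project_id)
        | (renamed.get("proj_name", "") == project_id)
    ]
    if hit.empty:
        raise UnknownProjectError(
            f"project {project_id!r} not found in {master_path}"
        )
    rec = hit.iloc[0]
    kwargs = {f: str(rec[f]) for f in MASTER_FIELDS if f in renamed.columns}
    master = MasterRecord(**kwargs)

    root = master_path.parent
    proj_dir = root / master.folder_path
    experiments = read_experiments(
        proj_dir / master.animal_metadata, master.group_by, master.confound_by
    )
    lab = read_lab(proj_dir / master.lab_metadata)
    return ProjectBundle(master=master, experiments=experiments, lab=lab, root=root)


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    field: str
    message: str


def validate_project(bundle: ProjectBundle) -> list[ValidationIssue]:
    """Check every invariant of a loaded project against the filesystem.

    Problems are returned as report entries, never raised; an empty report
    means the project is internally consistent and every data file exists.
    """
    issues: list[ValidationIssue] = []
    master = bundle.master
    if not bundle.project_dir.is_dir():
        issues.append(ValidationIssue(
            "error", "folder_path", f"project folder missing: {bundle.project_dir}"
        ))
    animal_path = bundle.project_dir / master.animal_metadata
    if animal_path.exists():
        table = pd.read_csv(animal_path, dtype=str, keep_default_na=False)
        norm_cols = {_norm_header(c) for c in table.columns}
        if _norm_header(master.group_by) not in norm_cols:
            issues.append(ValidationIssue(
                "error", "group_by",
                f"grouping column {master.group_by!r} absent from experiment metadata",
            ))
        if master.confound_by and _norm_header(master.confound_by) not in norm_cols:
            issues.append(ValidationIssue(
                "error", "confound_by",
                f"confound column {master.confound_by!r} absent from experiment metadata",
            ))
    else:
        issues.append(ValidationIssue(
            "error", "animal_metadata", f"experiment metadata missing: {animal_path}"
        ))
    if not (bundle.project_dir / master.lab_metadata).exists():
        issues.append(ValidationIssue(
            "error", "lab_metadata",
            f"lab metadata missing: {bundle.project_dir / master.lab_metadata}",
        ))
    for row in bundle.experiments:
        path = bundle.data_path(row)
        if not path.exists():
            issues.append(ValidationIssue(
                "error", "data_file",
                f"data file for animal {row.animal_id} test {row.test_id} "
                f"missing: {path}",
            ))
    groups = {r.group for r in bundle.active_experiments()}
    if len(groups) < 2:
        issues.append(ValidationIssue(
            "warning", "group_by",
            f"only {len(groups)} distinct group value(s); group tests need 2-3",
        ))
    return issues


def write_master(records: list[MasterRecord], path: str | Path) -> None:
    """Write a master registry CSV (one project per row, canonical headers)."""
    frame = pd.DataFrame(
        [{f: getattr(rec, f) for f in MASTER_FIELDS} for rec in records]
    )
    frame.to_csv(path, index=False)
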