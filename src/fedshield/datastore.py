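"""Project-scoped tabular storage with parquet at rest.

Cohort servers organize harmonized data into *projects* (directories on
the file system). Tables arrive as CSV or parquet and are always
persisted as a single parquet file per table; CSV ingest infers column
kinds (integer, numeric, boolean, categorical, string) and turns empty
fields into missing values. Data managers can derive variable subsets
from an uploaded table so that researchers only ever see the variables
their data-use agreement covers.

Layout on disk::

    <root>/<project>/<folder>/<name>.parquet
    <root>/<project>/.project.json     # metadata sidecar

All dataframes use pandas nullable dtypes so missing values survive the
round trip for every column kind.
"""

from __future__ import annotations

import csv
import io
import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pyarrow.parquet  # noqa: F401  (ensures parquet engine present)

from .errors import ConflictError, IngestError, NotFoundError, ValidationError

PROJECT_NAME_RE = re.compile(r"^[a-z0-9][a-z0-9-]{0,62}$")

#: column kinds recognised by the schema model
KINDS = ("numeric", "integer", "boolean", "categorical", "string")

_TRUE = {"true"}
_FALSE = {"false"}


@dataclass(frozen=True)
class TableRef:
    """Reference to one stored table: location, size and schema."""

    project: str
    folder: str
    name: str
    n_rows: int
    schema: tuple[tuple[str, str], ...]  # ordered (column, kind)

    @property
    def columns(self) -> list[str]:
        return [c for c, _ in self.schema]

    def to_payload(self) -> dict:
        return {
            "project": self.project,
            "folder": self.folder,
            "name": self.name,
            "n_rows": self.n_rows,
            "schema": [[c, k] for c, k in self.schema],
        }


@dataclass
class Project:
    name: str
    created_at: float = field(default_factory=time.time)


@dataclass
class SubsetManifest:
    """Rows of ``(source_folder, source_table, variable)``; duplicates collapse."""

    rows: list[tuple[str, str, str]]

    def __post_init__(self):
        seen: list[tuple[str, str, str]] = []
        for folder, table, var in self.rows:
            if not var:
                raise ValidationError("manifest variable name must be non-empty")
            row = (folder, table, var)
            if row not in seen:
                seen.append(row)
        self.rows = seen

    @classmethod
    def from_csv(cls, text: str) -> "SubsetManifest":
        """Parse the ``source_folder,source_table,variable`` CSV format."""
        reader = csv.reader(io.StringIO(text))
        try:
            header = next(reader)
        except StopIteration:
            raise IngestError("empty manifest")
        expected = ["source_folder", "source_table", "variable"]
        if [h.strip() for h in header] != expected:
            raise IngestError(f"manifest header must be {','.join(expected)}")
        rows = []
        for line in reader:
            if not line or all(not f.strip() for f in line):
                continue
            if len(line) != 3:
                raise IngestError(f"malformed manifest row: {line!r}")
            rows.append((line[0].strip(), line[1].strip(), line[2].strip()))
        return cls(rows)

    def variables_for(self, folder: str, table: str) -> list[str]:
        return [v for f, t, v in self.rows if f == folder and t == table]


def _infer_column(raw: pd.Series) -> pd.Series:
    """Infer a typed column from string data: int -> float -> bool -> string."""
    present = raw[raw.notna()]
    if len(present) == 0:
        return raw.astype("Float64")
    values = present.astype(str)
    try:
        ints = values.astype("int64")
        out = pd.Series(pd.NA, index=raw.index, dtype="Int64")
        out[present.index] = ints
        return out
    except (ValueError, TypeError):
        pass
    try:
        floats = values.astype("float64")
        out = pd.Series(pd.NA, index=raw.index, dtype="Float64")
        out[present.index] = floats
        return out
    except (ValueError, TypeError):
        pass
    lowered = values.str.lower()
    if lowered.isin(_TRUE | _FALSE).all():
        out = pd.Series(pd.NA, index=raw.index, dtype="boolean")
        out[present.index] = lowered.isin(_TRUE)
        return out
    return raw.astype("string")


def ingest_csv(text: str, categorical_max_levels: int = 20) -> pd.DataFrame:
    """Parse CSV text into a typed dataframe.

    Empty fields become missing. String columns with at most
    ``categorical_max_levels`` distinct values are stored as categorical.
    """
    buf = io.StringIO(text)
    try:
        header_line = buf.readline()
        header = next(csv.reader(io.StringIO(header_line)))
    except (StopIteration, csv.Error):
        raise IngestError("cannot parse CSV header")
    if len(header) != len(set(header)):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise IngestError(f"duplicated column names: {', '.join(dupes)}")
    if any(not c.strip() for c in header):
        raise IngestError("empty column name in header")
    buf.seek(0)
    try:
        df = pd.read_csv(buf, dtype=str, keep_default_na=False, na_values=[""])
    except Exception as exc:  # malformed CSV body
        raise IngestError(f"cannot parse CSV payload: {exc}")
    out = {}
    for col in df.columns:
        typed = _infer_column(df[col])
        if typed.dtype == "string":
            n_levels = typed.dropna().nunique()
            if 0 < n_levels <= categorical_max_levels:
                typed = typed.astype("category")
        out[col] = typed
    return pd.DataFrame(out, columns=list(df.columns))


def schema_of(df: pd.DataFrame) -> tuple[tuple[str, str], ...]:
    """Map pandas dtypes onto the five schema kinds."""
    entries = []
    for col in df.columns:
        dtype = df[col].dtype
        if isinstance(dtype, pd.CategoricalDtype):
            kind = "categorical"
        elif pd.api.types.is_bool_dtype(dtype):
            kind = "boolean"
        elif pd.api.types.is_integer_dtype(dtype):
            kind = "integer"
        elif pd.api.types.is_float_dtype(dtype):
            kind = "numeric"
        else:
            kind = "string"
        entries.append((str(col), kind))
    return tuple(entries)


class DataStore:
    """File-system datastore: projects of parquet tables.

    Parameters
    ----------
    root:
        Storage root directory; created if absent.
    preview_cap:
        Maximum number of rows a preview may return.
    categorical_max_levels:
        CSV ingest stores string columns with at most this many distinct
        values as categorical.
    """

    def __init__(self, root, preview_cap: int = 10, categorical_max_levels: int = 20):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.preview_cap = int(preview_cap)
        self.categorical_max_levels = int(categorical_max_levels)

    # -- projects ----------------------------------------------------

    def _project_dir(self, name: str) -> Path:
        return self.root / name

    def _meta_path(self, name: str) -> Path:
        return self._project_dir(name) / ".project.json"

    def create_project(self, name: str) -> Project:
        if not PROJECT_NAME_RE.match(name or ""):
            raise ValidationError(
                f"invalid project name {name!r}: must be lowercase "
                "alphanumeric/hyphen, starting with a letter or digit"
            )
        pdir = self._project_dir(name)
        if pdir.exists():
            raise ConflictError(f"project {name!r} already exists")
        pdir.mkdir(parents=True)
        project = Project(name=name)
        self._meta_path(name).write_text(
            json.dumps({"name": name, "created_at": project.created_at})
        )
        return project

    def project_exists(self, name: str) -> bool:
        return self._meta_path(name).exists()

    def _require_project(self, name: str) -> Path:
        if not self.project_exists(name):
            raise NotFoundError(f"unknown project {name!r}")
        return self._project_dir(name)

    def list_projects(self) -> list[str]:
        return sorted(p.name for p in self.root.iterdir() if (p / ".project.json").exists())

    def delete_project(self, name: str) -> None:
        pdir = self._require_project(name)
        for path in sorted(pdir.rglob("*"), reverse=True):
            if path.is_file():
                path.unlink()
            else:
                path.rmdir()
        pdir.rmdir()

    # -- tables ------------------------------------------------------

    def _table_path(self, project: str, folder: str, name: str) -> Path:
        for part in (folder, name):
            if not part or "/" in part or part.startswith("."):
                raise ValidationError(f"invalid path component {part!r}")
        return self._project_dir(project) / folder / f"{name}.parquet"

    def upload_table(
        self,
        project: str,
        folder: str,
        name: str,
        payload,
        fmt: str = "csv",
        overwrite: bool = False,
    ) -> TableRef:
        """Persist ``payload`` as one parquet file and return its reference.

        ``fmt`` is ``"csv"`` (payload: text), ``"parquet"`` (payload:
        bytes) or ``"pandas"`` (payload: DataFrame). CSV is converted on
        ingest so everything at rest is parquet.
        """
        self._require_project(project)
        path = self._table_path(project, folder, name)
        if path.exists() and not overwrite:
            raise ConflictError(f"table {folder}/{name} already exists in {project!r}")
        if fmt == "csv":
            df = ingest_csv(payload, self.categorical_max_levels)
        elif fmt == "parquet":
            try:
                df = pd.read_parquet(io.BytesIO(payload))
            except Exception as exc:
                raise IngestError(f"cannot parse parquet payload: {exc}")
        elif fmt == "pandas":
            df = payload.copy()
        else:
            raise ValidationError(f"unknown upload format {fmt!r}")
        if len(set(df.columns)) != len(df.columns):
            raise IngestError("duplicated column names")
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_parquet(path, index=False)
        return TableRef(project, folder, name, len(df), schema_of(df))

    def read_table(self, project: str, folder: str, name: str) -> pd.DataFrame:
        self._require_project(project)
        path = self._table_path(project, folder, name)
        if not path.exists():
            raise NotFoundError(f"unknown table {folder}/{name} in {project!r}")
        return pd.read_parquet(path)

    def table_ref(self, project: str, folder: str, name: str) -> TableRef:
        df = self.read_table(project, folder, name)
        return TableRef(project, folder, name, len(df), schema_of(df))

    def list_objects(self, project: str) -> list[TableRef]:
        pdir = self._require_project(project)
        refs = []
        for path in sorted(pdir.rglob("*.parquet")):
            folder = path.parent.relative_to(pdir).as_posix()
            refs.append(self.table_ref(project, folder, path.stem))
        return refs

    def delete_object(self, project: str, folder: str, name: str) -> None:
        self._require_project(project)
        path = self._table_path(project, folder, name)
        if not path.exists():
            raise NotFoundError(f"unknown table {folder}/{name} in {project!r}")
        path.unlink()

    # -- subsets & previews ------------------------------------------

    def create_subset(
        self,
        project: str,
        source: tuple[str, str],
        variables: list[str],
        target: tuple[str, str],
        overwrite: bool = False,
    ) -> TableRef:
        """Project a stored table onto ``variables`` (DUA subsetting).

        Keeps all rows and the source's column order for the selected
        variables; duplicate requests for a variable collapse to one
        column. Unknown variables are all reported at once.
        """
        df = self.read_table(project, source[0], source[1])
        wanted = list(dict.fromkeys(variables))
        missing = [v for v in wanted if v not in df.columns]
        if missing:
            raise ValidationError(
                f"unknown variables in {source[0]}/{source[1]}: {', '.join(missing)}",
                missing=missing,
            )
        ordered = [c for c in df.columns if c in wanted]
        return self.upload_table(
            project, target[0], target[1], df[ordered], fmt="pandas", overwrite=overwrite
        )

    def create_subsets_from_manifest(
        self, project: str, manifest: SubsetManifest, target_folder: str,
        overwrite: bool = False,
    ) -> list[TableRef]:
        """Apply a manifest: one subset per (source_folder, source_table)."""
        refs = []
        sources = list(dict.fromkeys((f, t) for f, t, _ in manifest.rows))
        for folder, table in sources:
            variables = manifest.variables_for(folder, table)
            refs.append(
                self.create_subset(
                    project, (folder, table), variables,
                    (target_folder, table), overwrite=overwrite,
                )
            )
        return refs

    def preview(self, project: str, folder: str, name: str) -> list[dict]:
        """First ``preview_cap`` rows in storage order, JSON-safe."""
        df = self.read_table(project, folder, name).head(self.preview_cap)
        rows = []
        for _, row in df.iterrows():
            rows.append(
                {c: (None if pd.isna(v) else (v.item() if hasattr(v, "item") else v))
                 for c, v in row.items()}
            )
        return rows
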