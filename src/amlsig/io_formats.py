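"""Readers and writers for the tabular formats the pipeline touches.

All files are UTF-8, tab-delimited, '.' decimal. Gene-symbol case is preserved
exactly as read: mouse (Title-case) and human (UPPER-case) symbols are never
auto-converted — orthology is established only through an explicit
:class:`OrthologMap`. Expression matrices are validated fail-fast: any missing
or non-finite value is rejected rather than imputed.

Supported formats
-----------------
* expression matrices: plain TSV (first column ``probe_id``, remaining columns
  sample ids) or GCT version 1.2;
* sample / probe annotation, ortholog map, DEG list and survival tables as TSV
  with schema-specific required columns;
* gene-set collections as standard GMT (name, description, members).
"""

from __future__ import annotations


import io
import os
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of log2 intensities with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, one column per sample id. All values
        must be finite.
    sample_meta
        Optional DataFrame indexed by sample id with columns ``dataset``,
        ``cohort`` and optionally ``subtype``. When present it must cover
        every sample of ``values``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        validate_expression_values(self.values)
        if self.sample_meta is not None:
            missing = [s for s in self.values.columns if s not in self.sample_meta.index]
            if missing:
                raise ValidationError(
                    f"samples absent from sample annotation: {missing[:5]}"
                )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Return a copy carrying ``values`` but the same metadata."""
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[
                [s for s in self.sample_meta.index if s in values.columns]
            ]
        return ExpressionMatrix(values=values, sample_meta=meta)


@dataclass(frozen=True)
class ProbeAnnotation:
    """Mapping probe id -> gene symbol (many probes may share one gene)."""

    mapping: Mapping[str, str]

    def probes_for(self, gene_symbol: str) -> list[str]:
        return sorted(p for p, g in self.mapping.items() if g == gene_symbol)

    def genes(self) -> set[str]:
        return set(self.mapping.values())

    def gene_to_probes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for probe, gene in self.mapping.items():
            out.setdefault(gene, []).append(probe)
        return {g: sorted(ps) for g, ps in out.items()}


@dataclass(frozen=True)
class OrthologMap:
    """Mouse symbol -> set of human symbols (empty set = unmapped)."""

    mapping: Mapping[str, frozenset[str]]

    def human_orthologs(self, mouse_symbol: str) -> frozenset[str]:
        return self.mapping.get(mouse_symbol, frozenset())


@dataclass
class DEGList:
    """Differentially expressed genes from an upstream pairwise comparison.

    ``entries`` has columns ``gene`` (mouse symbol), ``direction`` (+1/-1),
    ``lfc`` and ``adj_p``. The provenance thresholds record how the list was
    produced upstream (|LFC| >= 1.5, adjusted p < 0.05); :meth:`significant`
    re-applies them as a view.
    """

    entries: pd.DataFrame
    lfc_threshold: float = 1.5
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        e = self.entries
        if (e["gene"].astype(str).str.len() == 0).any():
            raise ValidationError("DEG list contains an empty gene symbol")
        if not e["direction"].isin([1, -1]).all():
            raise ValidationError("DEG direction must be +1 or -1")
        bad = e[(e["adj_p"] < 0) | (e["adj_p"] > 1)]
        if len(bad):
            raise ValidationError(f"adj_p outside [0,1] for genes {list(bad['gene'])[:5]}")

    def significant(self) -> pd.DataFrame:
        e = self.entries
        keep = (e["adj_p"] < self.q_threshold) & (e["lfc"].abs() >= self.lfc_threshold)
        return e[keep].reset_index(drop=True)

    def genes(self) -> list[str]:
        return list(self.entries["gene"])


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics); set names unique, members non-empty."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate gene-set names: {dup}")
        for s in self.sets:
            if not s.members:
                raise ValidationError(f"gene set {s.name!r} has no members")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class SurvivalTable:
    """Per-patient right-censored survival with an expression covariate.

    Columns: ``patient_id`` (unique), ``time_days`` (>= 0), ``event``
    (1 = death observed, 0 = censored), ``expression``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if d["patient_id"].duplicated().any():
            dup = d.loc[d["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise ValidationError(f"duplicate patient_id {dup!r}")
        if not d["event"].isin([0, 1]).all():
            bad = d.loc[~d["event"].isin([0, 1]), "event"].iloc[0]
            raise ValidationError(f"event must be 0 or 1, found {bad!r}")
        if (d["time_days"] < 0).any():
            raise ValidationError("negative survival time")

    def __len__(self) -> int:
        return len(self.data)


# --------------------------------------------------------------------------
# Validation helpers
# --------------------------------------------------------------------------


def validate_expression_values(values: pd.DataFrame) -> None:
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise FormatError(f"duplicate probe id {dup!r}")
    if values.columns.duplicated().any():
        dup = values.columns[values.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id {dup!r}")
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError("expression matrix contains non-numeric values")
    if not np.isfinite(arr).all():
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise ValidationError(
            f"non-finite value at probe {values.index[i]!r}, sample {values.columns[j]!r}"
        )


# --------------------------------------------------------------------------
# Expression matrices
# --------------------------------------------------------------------------


def _parse_numeric_body(raw: pd.DataFrame, path: str | os.PathLike) -> pd.DataFrame:
    """Convert string cells to floats, pinpointing the first bad cell."""
    out = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        if bad.any():
            row = bad.idxmax()
            raise FormatError(
                f"{path}: non-numeric cell at probe {row!r}, column {col!r}: "
                f"{raw.loc[row, col]!r}"
            )
        missing = converted.isna()
        if missing.any():
            row = missing.idxmax()
            raise ValidationError(f"{path}: missing value at probe {row!r}, column {col!r}")
        out[col] = converted
    return pd.DataFrame(out, index=raw.index)


def _check_header_duplicates(sample_ids: Iterable[str], path: str | os.PathLike) -> None:
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise FormatError(f"{path}: duplicate sample id {s!r} in header")
        seen.add(s)


def read_expression_matrix(
    path: str | os.PathLike,
    format: str = "tsv",
    sample_meta: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Read a probes x samples log2 expression matrix.

    ``format`` is ``"tsv"`` (header of sample ids, first column the probe id)
    or ``"gct"`` (GCT version 1.2 only). ``sample_meta`` may attach a
    companion sample annotation; otherwise metadata is left blank for later
    attachment.
    """
    if format not in ("tsv", "gct"):
        raise ValueError(f"unknown expression format {format!r}")
    with open(path, encoding="utf-8") as fh:
        if format == "gct":
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: unsupported GCT version line {version!r}")
            dims = fh.readline().split("\t")
            if len(dims) < 2:
                raise FormatError(f"{path}: malformed GCT dimension line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            header = fh.readline().rstrip("\n").split("\t")
            _check_header_duplicates(header[2:], path)
            raw = pd.read_csv(
                io.StringIO(fh.read()), sep="\t", dtype=str, header=None,
                names=header, index_col=0,
            )
            # GCT carries a Description column between ids and data
            raw = raw.iloc[:, 1:]
            if raw.shape != (n_rows, n_cols):
                raise FormatError(
                    f"{path}: GCT dimension line says {(n_rows, n_cols)}, "
                    f"body is {raw.shape}"
                )
        else:
            header = fh.readline().rstrip("\n").split("\t")
            _check_header_duplicates(header[1:], path)
            raw = pd.read_csv(
                io.StringIO(fh.read()), sep="\t", dtype=str, header=None,
                names=header, index_col=0,
            )
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe id {dup!r}")
    raw.index = raw.index.astype(str)
    raw.index.name = "probe_id"
    values = _parse_numeric_body(raw, path)
    return ExpressionMatrix(values=values, sample_meta=sample_meta)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    df = matrix.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


# --------------------------------------------------------------------------
# Typed metadata tables
# --------------------------------------------------------------------------

_SCHEMAS = {
    "sample_annotation": ["sample_id", "dataset", "cohort"],
    "probe_annotation": ["probe_id", "gene_symbol"],
    "ortholog_map": ["mouse_symbol", "human_symbol"],
    "deg_list": ["gene", "direction", "lfc", "adj_p"],
    "survival": ["patient_id", "time_days", "event", "expression"],
}


def read_tabular_metadata(path: str | os.PathLike, schema: str):
    """Read one of the typed TSV tables; ``schema`` selects validation.

    Returns a type matching the schema: a DataFrame indexed by sample id for
    ``sample_annotation``, :class:`ProbeAnnotation`, :class:`OrthologMap`,
    :class:`DEGList` or :class:`SurvivalTable`. Unknown extra columns are
    preserved where the return type is a DataFrame-backed object.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = _SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; schema {schema!r} "
            f"expects {required}"
        )
    if schema == "sample_annotation":
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"{path}: duplicate sample_id {dup!r}")
        return df.set_index("sample_id")
    if schema == "probe_annotation":
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"{path}: duplicate probe_id {dup!r}")
        return ProbeAnnotation(dict(zip(df["probe_id"], df["gene_symbol"])))
    if schema == "ortholog_map":
        mapping: dict[str, set[str]] = {}
        for mouse, human in zip(df["mouse_symbol"], df["human_symbol"]):
            mapping.setdefault(mouse, set())
            if isinstance(human, str) and human:
                mapping[mouse].add(human)
        return OrthologMap({m: frozenset(h) for m, h in mapping.items()})
    if schema == "deg_list":
        entries = df.assign(
            direction=pd.to_numeric(df["direction"]).astype(int),
            lfc=pd.to_numeric(df["lfc"]),
            adj_p=pd.to_numeric(df["adj_p"]),
        )
        return DEGList(entries=entries)
    # survival
    data = df.assign(
        time_days=pd.to_numeric(df["time_days"]),
        event=pd.to_numeric(df["event"], errors="coerce"),
        expression=pd.to_numeric(df["expression"]),
    )
    if data["event"].isna().any() or not data["event"].isin([0, 1]).all():
        bad = data.loc[~data["event"].isin([0, 1]), "event"].iloc[0]
        raise ValidationError(f"{path}: event must be 0 or 1, found {bad!r}")
    data["event"] = data["event"].astype(int)
    return SurvivalTable(data=data)


# --------------------------------------------------------------------------
# GMT gene sets
# --------------------------------------------------------------------------


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file: one set per line — name, description, members."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "need name, description and at least one member"
                )
            members: list[str] = []
            seen: set[str] = set()
            for m in fields[2:]:
                if m and m not in seen:
                    members.append(m)
                    seen.add(m)
            sets.append(GeneSet(fields[0], fields[1], tuple(members)))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# --------------------------------------------------------------------------
# Result tables
# --------------------------------------------------------------------------


def write_results(
    tables: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike
) -> dict[str, str]:
    """Write each named table to ``<out_dir>/<name>.tsv``.

    Output is deterministic: fixed column order (as given), '.' decimal,
    ``\\n`` line endings — identical inputs yield identical bytes.
    """
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir!r} is not writable")
    paths = {}
    for name, table in tables.items():
        p = os.path.join(out_dir, f"{name}.tsv")
        table.to_csv(p, sep="\t", index=False, lineterminator="\n")
        paths[name] = p
    return paths


def read_result_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
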