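"""Readers and writers for every external representation the pipeline touches.

All tabular formats are plain TSV.  Genomic coordinates are kept 0-based
half-open (BED native) throughout the package.  Readers validate and reject
malformed input rather than coercing it; writers are deterministic
byte-for-byte for identical in-memory data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParseError, PairingError

FLAG_VALUES = ("Present", "Marginal", "Absent")
BIOTYPES = ("lncRNA", "protein_coding")
TISSUES = ("T", "NT")
ENCAPSULATION_VALUES = ("complete", "incomplete", "none")

CLINICAL_COLUMNS = (
    "patient_id",
    "tumor_size_cm",
    "vascular_invasion",
    "stage",
    "grade",
    "encapsulation",
    "invasion",
    "os_time",
    "os_event",
)


@dataclass
class ExpressionMatrix:
    """Log2 intensities for features (rows) by samples (columns).

    ``flags`` optionally carries per-cell detection calls
    (Present/Marginal/Absent) on exactly the same grid.  Values must be
    numeric and non-infinite; NaN marks a missing measurement and is
    excluded per-analysis downstream.
    """

    values: pd.DataFrame
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].tolist()[0]
            raise ParseError(f"duplicate feature id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].tolist()[0]
            raise ParseError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("expression values must be numeric")
        if np.isinf(arr).any():
            raise ParseError("expression values must be finite")
        if self.flags is not None:
            f = self.flags
            if not f.index.equals(v.index) or not f.columns.equals(v.columns):
                raise ParseError("detection flags do not cover the expression grid")
            bad = set(map(str, np.unique(f.to_numpy()))) - set(FLAG_VALUES)
            if bad:
                raise ParseError(f"unknown detection flag value(s): {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_features(self, ids) -> "ExpressionMatrix":
        ids = list(ids)
        flags = self.flags.loc[ids] if self.flags is not None else None
        return ExpressionMatrix(self.values.loc[ids], flags)

    def subset_samples(self, ids) -> "ExpressionMatrix":
        ids = list(ids)
        flags = self.flags[ids] if self.flags is not None else None
        return ExpressionMatrix(self.values[ids], flags)


# ---------------------------------------------------------------------------
# expression matrix + sample design


def _read_grid_tsv(path, numeric: bool) -> pd.DataFrame:
    """Parse a features-by-samples TSV with strict shape checking.

    Reports the 1-based line number of any ragged or non-numeric row.
    """
    feature_ids: list[str] = []
    rows: list[list] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty or headerless file")
        columns = header.rstrip("\n").split("\t")[1:]
        width = len(columns)
        for lineno, line in enumerate(fh, start=2):
            if line == "\n":
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != width + 1:
                raise ParseError(
                    f"{path}:{lineno}: ragged row "
                    f"({len(parts)} fields, expected {width + 1})"
                )
            feature_ids.append(parts[0])
            if numeric:
                try:
                    rows.append(
                        [math.nan if x == "" else float(x) for x in parts[1:]]
                    )
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric expression value"
                    ) from None
            else:
                rows.append(parts[1:])
    data = np.asarray(rows, dtype=float if numeric else object)
    if numeric:
        data = data.reshape(len(feature_ids), width)
    return pd.DataFrame(data, index=feature_ids, columns=columns)


def read_expression(path, design_path=None, flags_path=None, paired: bool = False):
    """Read an expression TSV (and optionally its design and flag grids).

    Returns ``(ExpressionMatrix, SampleDesign-or-None)``.  When a design is
    given, every design sample must exist in the matrix; with
    ``paired=True`` the design must pair one T with one NT per patient.
    """
    values = _read_grid_tsv(path, numeric=True)
    flags = _read_grid_tsv(flags_path, numeric=False) if flags_path else None
    matrix = ExpressionMatrix(values, flags)
    design = None
    if design_path is not None:
        design = read_design(design_path)
        unknown = set(design["sample_id"]) - set(matrix.sample_ids)
        if unknown:
            raise ParseError(
                f"design references unknown sample(s): {sorted(unknown)}"
            )
        if paired:
            validate_paired(design)
    return matrix, design


def write_expression(matrix: ExpressionMatrix, path, flags_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")
    if flags_path is not None:
        if matrix.flags is None:
            raise ParseError("matrix carries no detection flags to write")
        matrix.flags.to_csv(flags_path, sep="\t", index_label="feature_id")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "tissue"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: design needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicate sample id in design: {dup!r}")
    bad = set(df["tissue"]) - set(TISSUES)
    if bad:
        raise ParseError(f"tissue must be one of {TISSUES}, got {sorted(bad)}")
    return df[["sample_id", "patient_id", "tissue"]]


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def validate_paired(design: pd.DataFrame) -> None:
    """Require exactly one T and one NT sample per patient."""
    counts = design.pivot_table(
        index="patient_id", columns="tissue", values="sample_id", aggfunc="count"
    ).reindex(columns=list(TISSUES)).fillna(0)
    bad = counts.index[(counts["T"] != 1) | (counts["NT"] != 1)].tolist()
    if bad:
        raise PairingError(
            f"patients without exactly one T and one NT sample: {bad}"
        )


def paired_columns(design: pd.DataFrame):
    """Return ``(patients, tumor_samples, nontumor_samples)`` aligned by patient."""
    validate_paired(design)
    t = design[design["tissue"] == "T"].set_index("patient_id")["sample_id"]
    nt = design[design["tissue"] == "NT"].set_index("patient_id")["sample_id"]
    patients = sorted(t.index)
    return patients, [t[p] for p in patients], [nt[p] for p in patients]


def tumor_sample_map(design: pd.DataFrame) -> dict:
    """Map patient_id -> tumor sample_id."""
    t = design[design["tissue"] == "T"]
    return dict(zip(t["patient_id"], t["sample_id"]))


# ---------------------------------------------------------------------------
# clinical table


def _parse_bool(value, field, lineno):
    s = str(value).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise ParseError(f"line {lineno}: {field} must be boolean, got {value!r}")


def read_clinical(path) -> pd.DataFrame:
    """Read the per-patient clinical table; any field other than
    ``patient_id`` may be missing (empty cell)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "patient_id" not in df.columns:
        raise ParseError(f"{path}: clinical table needs a patient_id column")
    out = {"patient_id": df["patient_id"].tolist()}
    n = len(df)
    for col in CLINICAL_COLUMNS[1:]:
        if col not in df.columns:
            continue
        parsed = []
        for i, raw in enumerate(df[col]):
            lineno = i + 2
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw) == "":
                parsed.append(None)
                continue
            if col in ("vascular_invasion", "invasion", "os_event"):
                parsed.append(_parse_bool(raw, col, lineno))
            elif col in ("stage", "grade"):
                try:
                    v = int(float(raw))
                except ValueError:
                    raise ParseError(f"line {lineno}: {col} must be integer") from None
                if v not in (1, 2, 3, 4):
                    raise ParseError(f"line {lineno}: {col} must be in 1..4, got {v}")
                parsed.append(v)
            elif col == "encapsulation":
                if raw not in ENCAPSULATION_VALUES:
                    raise ParseError(
                        f"line {lineno}: encapsulation must be one of "
                        f"{ENCAPSULATION_VALUES}, got {raw!r}"
                    )
                parsed.append(raw)
            else:  # tumor_size_cm, os_time
                try:
                    v = float(raw)
                except ValueError:
                    raise ParseError(f"line {lineno}: {col} must be numeric") from None
                if col == "os_time" and v <= 0:
                    raise ParseError(f"line {lineno}: os_time must be > 0")
                parsed.append(v)
        out[col] = parsed
    result = pd.DataFrame(out)
    if result["patient_id"].duplicated().any():
        dup = result.loc[result["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ParseError(f"duplicate patient id: {dup!r}")
    return result


def write_clinical(clinical: pd.DataFrame, path) -> None:
    df = clinical.copy()
    for col in ("vascular_invasion", "invasion", "os_event"):
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: "" if v is None or v is pd.NA else str(int(bool(v)))
            )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature annotation (BED6 + biotype [+ symbol])


def read_bed(path) -> pd.DataFrame:
    """Read BED6+1(+1) feature annotation.

    Columns: chrom, start, end, name (= feature_id), score, strand, biotype,
    optional symbol.  Coordinates stay 0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 7:
                raise ParseError(f"{path}:{lineno}: expected >= 7 BED fields")
            chrom, start, end, name, _score, strand, biotype = parts[:7]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed coordinate") from None
            if start_i >= end_i:
                raise ParseError(
                    f"{path}:{lineno}: start must be < end ({start_i} >= {end_i})"
                )
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if biotype not in BIOTYPES:
                raise ParseError(f"{path}:{lineno}: unknown biotype {biotype!r}")
            symbol = parts[7] if len(parts) > 7 else name
            rows.append((name, biotype, chrom, start_i, end_i, strand, symbol))
    df = pd.DataFrame(
        rows,
        columns=["feature_id", "biotype", "chrom", "start", "end", "strand", "symbol"],
    )
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ParseError(f"duplicate feature id in annotation: {dup!r}")
    return df


def write_bed(annotation: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in annotation.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.feature_id}\t0\t"
                f"{row.strand}\t{row.biotype}\t{row.symbol}\n"
            )


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> dict:
    """Read a GMT file into an ordered ``{set_name: [members]}`` mapping."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: gene set has no members")
            name = parts[0]
            members = [m for m in parts[2:] if m]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen = set()
            sets[name] = [m for m in members if not (m in seen or seen.add(m))]
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# SIF network export


def write_sif(edges, path, annotation: pd.DataFrame | None = None) -> None:
    """Write lncRNA-mRNA edges as ``lnc<TAB>coexp<TAB>mrna`` lines.

    Edges are sorted lexicographically for diffability.  When an annotation
    table is supplied, edges referencing unknown features are rejected.
    """
    edges = sorted((str(a), str(b)) for a, b in edges)
    if annotation is not None:
        known = set(annotation["feature_id"])
        for a, b in edges:
            missing = {a, b} - known
            if missing:
                raise ParseError(f"SIF edge references unknown feature(s): {sorted(missing)}")
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\tcoexp\t{b}\n")


def read_sif(path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 SIF fields")
            edges.append((parts[0], parts[2]))
    return sorted(set(edges))


# ---------------------------------------------------------------------------
# misc


def write_results(tables: dict, outdir) -> None:
    """Write a mapping of name -> DataFrame as ``<outdir>/<name>.tsv``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t", index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
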