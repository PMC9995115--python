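"""Reading, validation and normalization of clonotype tables.

Clonotype identity conventions used by every downstream stage live here: at
ingestion a clonotype is keyed by (junction_aa, v_call, j_call); all
cross-sample comparisons (overlap, Venn, networks, p_gen) first collapse to
the amino-acid junction alone, because clone sharing is defined on the amino
acid sequence. Frequencies are always recomputed from counts, never trusted
from the file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._codons import AMINO_ACIDS
from .errors import FormatError, ValidationError

COMPARTMENTS = ("SF_LEFT", "SF_RIGHT", "PB")
SUBSETS = ("TREG", "NON_TREG")

#: junction alphabet accepted at ingestion; '*' (stop) and 'X' (ambiguous)
#: are retained but flagged non-productive and excluded from p_gen / network
#: stages.
JUNCTION_ALPHABET = frozenset(AMINO_ACIDS) | {"*", "X"}

# accepted column dialects, tried in order
_DIALECTS: tuple[Mapping[str, str], ...] = (
    {"junction_aa": "junction_aa", "v_call": "v_call", "j_call": "j_call", "count": "duplicate_count"},
    {"junction_aa": "cdr3aa", "v_call": "v", "j_call": "j", "count": "count"},
)

_ANNOTATION_FIELDS = ("sample_id", "patient", "compartment", "subset", "visit")


@dataclass(frozen=True, order=True)
class Clonotype:
    """One distinct receptor in one sample."""

    junction_aa: str
    v_call: str | None = None
    j_call: str | None = None
    count: int = 1
    frequency: float = 0.0

    @property
    def key(self) -> tuple:
        return (self.junction_aa, self.v_call, self.j_call)

    @property
    def productive(self) -> bool:
        return "*" not in self.junction_aa and "X" not in self.junction_aa


@dataclass(frozen=True)
class Repertoire:
    """A labeled multiset of clonotypes for one (patient, compartment, subset, visit)."""

    sample_id: str
    patient: str
    compartment: str
    subset: str
    visit: int
    clonotypes: tuple[Clonotype, ...]

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(f"unknown compartment {self.compartment!r} (expected one of {COMPARTMENTS})")
        if self.subset not in SUBSETS:
            raise ValidationError(f"unknown subset {self.subset!r} (expected one of {SUBSETS})")
        if self.visit < 0:
            raise ValidationError("visit must be a non-negative integer")

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clonotypes)

    @property
    def annotations(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "patient": self.patient,
            "compartment": self.compartment,
            "subset": self.subset,
            "visit": self.visit,
        }

    def __len__(self) -> int:
        return len(self.clonotypes)

    def junction_set(self, productive_only: bool = False) -> set[str]:
        return {c.junction_aa for c in self.clonotypes if not productive_only or c.productive}

    def junction_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.clonotypes:
            out[c.junction_aa] = out.get(c.junction_aa, 0) + c.count
        return out

    def junction_frequencies(self) -> dict[str, float]:
        total = self.total_count
        return {j: n / total for j, n in self.junction_counts().items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "junction_aa": [c.junction_aa for c in self.clonotypes],
                "v_call": [c.v_call for c in self.clonotypes],
                "j_call": [c.j_call for c in self.clonotypes],
                "duplicate_count": [c.count for c in self.clonotypes],
                "frequency": [c.frequency for c in self.clonotypes],
            }
        )


def _normalize(records: Iterable[tuple[str, str | None, str | None, int]], annotations: Mapping) -> Repertoire:
    """Merge identical keys, recompute frequencies, deterministic ordering."""
    merged: dict[tuple, int] = {}
    for junction, v, j, count in records:
        key = (junction, v, j)
        merged[key] = merged.get(key, 0) + int(count)
    if not merged:
        raise ValidationError("repertoire has no clonotypes")
    total = sum(merged.values())
    clones = tuple(
        Clonotype(junction_aa=k[0], v_call=k[1], j_call=k[2], count=n, frequency=n / total)
        for k, n in sorted(merged.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1] or "", kv[0][2] or ""))
    )
    ann = dict(annotations)
    return Repertoire(
        sample_id=str(ann.get("sample_id", "sample")),
        patient=str(ann.get("patient", "NA")),
        compartment=str(ann.get("compartment", "PB")),
        subset=str(ann.get("subset", "TREG")),
        visit=int(ann.get("visit", 0)),
        clonotypes=clones,
    )


def repertoire_from_counts(
    records: Iterable[tuple[str, str | None, str | None, int]],
    **annotations,
) -> Repertoire:
    """Build a normalized Repertoire from (junction_aa, v_call, j_call, count) rows."""
    rows = list(records)
    for i, (junction, _v, _j, count) in enumerate(rows, start=1):
        _check_row(junction, count, i)
    return _normalize(rows, annotations)


def _check_row(junction: str, count, row: int) -> None:
    if not junction or not isinstance(junction, str):
        raise ValidationError(f"row {row}: empty junction_aa")
    bad = set(junction) - JUNCTION_ALPHABET
    if bad:
        raise ValidationError(f"row {row}: invalid junction characters {sorted(bad)} in {junction!r}")
    try:
        count = int(count)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: count {count!r} is not an integer") from None
    if count <= 0:
        raise ValidationError(f"row {row}: non-positive count {count}")


def read_clonotype_table(
    path,
    sample_annotations: Mapping | None = None,
    column_map: Mapping[str, str] | None = None,
    min_count: int = 1,
) -> Repertoire:
    """Read a tab-separated clonotype table into a normalized Repertoire.

    Accepts AIRR Rearrangement column names (junction_aa, v_call, j_call,
    duplicate_count) or the simple dialect (cdr3aa, v, j, count); an explicit
    ``column_map`` with keys junction_aa/count (and optionally v_call/j_call)
    overrides both. ``#``-prefixed ``key=value`` header lines are parsed as
    sample annotations, overridden by ``sample_annotations``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    header_annotations: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        skip = 0
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            text = line[1:].strip()
            if "=" in text:
                k, _, v = text.partition("=")
                header_annotations[k.strip()] = v.strip()
    try:
        df = pd.read_csv(path, sep="\t", skiprows=skip, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty table") from None

    if column_map is not None:
        mapping = dict(column_map)
        missing = [c for c in (mapping.get("junction_aa"), mapping.get("count")) if c is None or c not in df.columns]
        if "junction_aa" not in mapping or "count" not in mapping or missing:
            raise FormatError(f"{path}: column_map must name junction and count columns present in the header")
    else:
        mapping = None
        for dialect in _DIALECTS:
            if dialect["junction_aa"] in df.columns and dialect["count"] in df.columns:
                mapping = dict(dialect)
                break
        if mapping is None:
            wanted = " or ".join(f"({d['junction_aa']}, {d['count']})" for d in _DIALECTS)
            raise FormatError(f"{path}: missing required junction/count columns; expected {wanted}")
    if df.empty:
        raise ValidationError(f"{path}: empty table")

    junction_col = mapping["junction_aa"]
    count_col = mapping["count"]
    v_col = mapping.get("v_call") if mapping.get("v_call") in df.columns else None
    j_col = mapping.get("j_call") if mapping.get("j_call") in df.columns else None

    junctions = df[junction_col].tolist()
    counts = df[count_col].tolist()
    vs = df[v_col].tolist() if v_col else [None] * len(df)
    js = df[j_col].tolist() if j_col else [None] * len(df)
    records = []
    for i, (junction, count, v, j) in enumerate(zip(junctions, counts, vs, js), start=1):
        _check_row(junction, count, i)
        if int(count) < min_count:
            continue
        v = None if v is None or pd.isna(v) else str(v)
        j = None if j is None or pd.isna(j) else str(j)
        records.append((str(junction), v, j, int(count)))
    if not records:
        raise ValidationError(f"{path}: no clonotypes left after filtering (min_count={min_count})")
    annotations = {**header_annotations, **dict(sample_annotations or {})}
    return _normalize(records, annotations)


def write_clonotype_table(rep: Repertoire, path) -> None:
    """Write a Repertoire as an annotated AIRR-style tab-separated table."""
    with open(path, "w", encoding="utf-8") as fh:
        for k in _ANNOTATION_FIELDS:
            fh.write(f"# {k}={rep.annotations[k]}\n")
        fh.write("junction_aa\tv_call\tj_call\tduplicate_count\tfrequency\n")
        for c in rep.clonotypes:
            fh.write(
                f"{c.junction_aa}\t{c.v_call or ''}\t{c.j_call or ''}\t{c.count}\t{c.frequency:.10g}\n"
            )


def collapse_by_junction_aa(rep: Repertoire) -> Repertoire:
    """Merge clonotypes sharing an amino-acid junction; V/J calls are dropped."""
    return _normalize(
        ((c.junction_aa, None, None, c.count) for c in rep.clonotypes),
        rep.annotations,
    )


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    """Read a tab-separated manifest (sample_id, patient, compartment, subset, visit, path)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["sample_id", "patient", "compartment", "subset", "visit", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet is missing columns {missing}")
    df["visit"] = df["visit"].astype(int)
    return df


def load_cohort(sheet_path, min_count: int = 1) -> list[Repertoire]:
    """Load every repertoire named in a sample sheet (paths relative to the sheet)."""
    sheet = read_sample_sheet(sheet_path)
    base = os.path.dirname(os.path.abspath(sheet_path))
    reps = []
    for row in sheet.itertuples(index=False):
        table = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        annotations = {
            "sample_id": row.sample_id,
            "patient": row.patient,
            "compartment": row.compartment,
            "subset": row.subset,
            "visit": int(row.visit),
        }
        reps.append(read_clonotype_table(table, annotations, min_count=min_count))
    return reps


def write_sample_sheet(reps: Sequence[Repertoire], paths: Sequence[str], sheet_path) -> None:
    with open(sheet_path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tpatient\tcompartment\tsubset\tvisit\tpath\n")
        for rep, p in zip(reps, paths):
            a = rep.annotations
            fh.write(f"{a['sample_id']}\t{a['patient']}\t{a['compartment']}\t{a['subset']}\t{a['visit']}\t{p}\n")
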