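"""Readers and writers for every external format the pipeline touches.

All downstream modules operate on the validated in-memory containers built
here.  Formats are deliberately plain: delimited text (TSV by default, CSV
accepted) for identification tables, edge lists, long-format FRAP traces and
viability grids; GMT for gene-set collections; JSON for fit and graph
summaries.

The canonical identification header is
``accession, gene_symbol, unique_peptides, psms, ms_score``.  Other layouts
(e.g. a Proteome Discoverer protein export) are absorbed through a *dialect*
mapping from canonical to actual column names.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

CONDITIONS = ("trap", "reference")

IDENTIFICATION_COLUMNS = (
    "accession",
    "gene_symbol",
    "unique_peptides",
    "psms",
    "ms_score",
)

#: Column names of a Proteome Discoverer protein-level export, offered as a
#: ready-made dialect.
PROTEOME_DISCOVERER_DIALECT = {
    "accession": "Accession",
    "gene_symbol": "Gene Symbol",
    "unique_peptides": "# Unique Peptides",
    "psms": "# PSMs",
    "ms_score": "Score",
}


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One protein's identification evidence in one sample."""

    accession: str
    gene_symbol: str
    unique_peptides: int
    psms: int
    ms_score: float

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("accession must be non-empty")
        for name in ("unique_peptides", "psms"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise ValidationError(
                    f"{name} must be an integer, got {value!r} "
                    f"(accession {self.accession})"
                )
            if value < 0:
                raise ValidationError(
                    f"{name} must be >= 0, got {value} (accession {self.accession})"
                )
        if self.psms >= 1 and self.unique_peptides < 1:
            raise ValidationError(
                f"unique_peptides must be >= 1 when psms >= 1 "
                f"(accession {self.accession})"
            )
        if not (self.ms_score >= 0) or math.isnan(self.ms_score):
            raise ValidationError(
                f"ms_score must be a nonnegative number, got {self.ms_score!r} "
                f"(accession {self.accession})"
            )


@dataclass
class IdentificationTable:
    """A set of protein identifications from one sample (or pooled replicates)."""

    sample_id: str
    bait: str
    condition: str
    replicate: int
    records: dict[str, ProteinRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        for accession, record in self.records.items():
            if accession != record.accession:
                raise ValidationError(
                    f"record keyed by {accession!r} carries accession "
                    f"{record.accession!r}"
                )

    @classmethod
    def from_records(
        cls,
        records: Iterable[ProteinRecord],
        *,
        sample_id: str,
        bait: str,
        condition: str,
        replicate: int = 1,
    ) -> "IdentificationTable":
        mapping: dict[str, ProteinRecord] = {}
        for record in records:
            if record.accession in mapping:
                raise ValidationError(
                    f"duplicate accession {record.accession!r} in sample {sample_id!r}"
                )
            mapping[record.accession] = record
        return cls(
            sample_id=sample_id,
            bait=bait,
            condition=condition,
            replicate=replicate,
            records=mapping,
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self.records

    def get(self, accession: str) -> ProteinRecord | None:
        return self.records.get(accession)

    def accessions(self) -> list[str]:
        return list(self.records)

    def replace_records(self, records: Iterable[ProteinRecord]) -> "IdentificationTable":
        """A copy of this table carrying ``records`` instead of the current ones."""
        return IdentificationTable.from_records(
            records,
            sample_id=self.sample_id,
            bait=self.bait,
            condition=self.condition,
            replicate=self.replicate,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self]
        return pd.DataFrame(rows, columns=list(IDENTIFICATION_COLUMNS))


@dataclass(frozen=True)
class FrapTrace:
    """One photobleaching recovery trace.

    ``times`` are seconds with t = 0 at the first post-bleach frame;
    ``intensities`` are arbitrary units unless the trace has been normalized
    (then prebleach_value == 1 and postbleach_value == 0).
    """

    trace_id: str
    times: tuple[float, ...]
    intensities: tuple[float, ...]
    prebleach_value: float
    postbleach_value: float

    def __post_init__(self) -> None:
        if len(self.times) != len(self.intensities):
            raise ValidationError(
                f"trace {self.trace_id}: times and intensities differ in length"
            )
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"trace {self.trace_id}: times must be strictly increasing"
            )

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def is_normalized(self) -> bool:
        return self.prebleach_value == 1.0 and self.postbleach_value == 0.0


# ---------------------------------------------------------------------------
# identification tables
# ---------------------------------------------------------------------------

_METADATA_KEYS = ("sample_id", "bait", "condition", "replicate")


def _sniff_frame(path: str | Path) -> pd.DataFrame:
    """Read a delimited text file, autodetecting comma vs tab.

    Leading full-line ``#`` comments (our metadata header) are skipped; ``#``
    elsewhere is data (column names like ``# PSMs`` are common in exports).
    """
    skip = 0
    with open(path, "rt", encoding="utf-8") as handle:
        for line in handle:
            if line.startswith("#"):
                skip += 1
            else:
                break
    return pd.read_csv(path, sep=None, engine="python", skiprows=skip, dtype=str)


def _read_comment_metadata(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                if key.strip() in _METADATA_KEYS:
                    meta[key.strip()] = value.strip()
    return meta


def read_identifications(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    sample_id: str | None = None,
    bait: str | None = None,
    condition: str | None = None,
    replicate: int | None = None,
) -> IdentificationTable:
    """Read a protein-identification table from delimited text.

    ``dialect`` maps canonical column names to the names used in the file;
    omitted entries default to the canonical name itself.  Sample metadata is
    taken from keyword arguments, falling back to ``# key=value`` comment
    lines written by :func:`write_identifications`.
    """
    dialect = dict(dialect or {})
    colmap = {c: dialect.get(c, c) for c in IDENTIFICATION_COLUMNS}

    frame = _sniff_frame(path)
    missing = [src for src in colmap.values() if src not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; "
            f"present: {list(frame.columns)}"
        )

    meta = _read_comment_metadata(path)
    sample_id = sample_id if sample_id is not None else meta.get("sample_id")
    bait = bait if bait is not None else meta.get("bait")
    condition = condition if condition is not None else meta.get("condition")
    if replicate is None:
        replicate = int(meta["replicate"]) if "replicate" in meta else 1
    if sample_id is None or bait is None or condition is None:
        raise ValidationError(
            f"{path}: sample_id, bait and condition must be supplied via keyword "
            "arguments or '# key=value' comment lines"
        )

    records: list[ProteinRecord] = []
    for index, row in enumerate(frame.itertuples(index=False), start=2):
        values = dict(zip(frame.columns, row))
        try:
            records.append(
                ProteinRecord(
                    accession=str(values[colmap["accession"]]).strip(),
                    gene_symbol=_clean_symbol(values[colmap["gene_symbol"]]),
                    unique_peptides=_parse_count(
                        values[colmap["unique_peptides"]], "unique_peptides"
                    ),
                    psms=_parse_count(values[colmap["psms"]], "psms"),
                    ms_score=float(values[colmap["ms_score"]]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {index}: {exc}") from None
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: row {index}: {exc}") from None
    return IdentificationTable.from_records(
        records,
        sample_id=sample_id,
        bait=bait,
        condition=condition,
        replicate=replicate,
    )


def _clean_symbol(value: object) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    text = str(value).strip()
    if text.lower() in ("", "nan", "none", "na"):
        return ""
    return text.upper()


def _parse_count(value: object, name: str) -> int:
    number = float(value)
    if not number.is_integer():
        raise ValidationError(f"{name} must be an integer, got {value!r}")
    return int(number)


def write_identifications(table: IdentificationTable, path: str | Path) -> None:
    """Write a table as TSV with its metadata embedded as comment lines."""
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write(f"# sample_id={table.sample_id}\n")
        handle.write(f"# bait={table.bait}\n")
        handle.write(f"# condition={table.condition}\n")
        handle.write(f"# replicate={table.replicate}\n")
        table.to_frame().to_csv(handle, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into ``{set_name: {SYMBOL, ...}}``.

    Members are uppercased and de-duplicated; sets that end up empty are
    dropped with a logged warning.
    """
    sets: dict[str, set[str]] = {}
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT lines need at least "
                    f"name, description and one member ({len(fields)} fields found)"
                )
            name = fields[0].strip()
            members = {m.strip().upper() for m in fields[2:] if m.strip()}
            if not members:
                logger.warning("%s: line %d: gene set %r is empty, dropped",
                               path, lineno, name)
                continue
            sets[name] = members
    return sets


# ---------------------------------------------------------------------------
# weighted edge lists
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ("symbol_a", "symbol_b", "score")


def read_edge_scores(path: str | Path) -> pd.DataFrame:
    """Read a weighted edge list (symbol_a, symbol_b, combined score).

    Scores may be on [0, 1] or on STRING's integer [0, 1000] scale; the
    latter is detected (any score > 1, all integral) and divided by 1000.
    Self-edges are dropped and duplicate unordered pairs keep the maximum
    score.  Returns a data frame with columns ``symbol_a, symbol_b, score``
    (symbols uppercased, pairs ordered lexicographically, rows sorted).
    """
    frame = _sniff_frame(path)
    if frame.shape[1] < 3:
        raise FormatError(f"{path}: edge list needs at least three columns")
    cols = list(frame.columns[:3])
    scores = pd.to_numeric(frame[cols[2]], errors="raise").to_numpy(dtype=float)
    if np.any(scores < 0):
        raise ValidationError(f"{path}: negative interaction score")
    if np.any(scores > 1):
        integral = np.all(np.isclose(scores, np.round(scores)))
        if not integral or np.any(scores > 1000):
            raise ValidationError(
                f"{path}: scores exceed 1 but are not on the integer [0, 1000] scale"
            )
        scores = scores / 1000.0

    a = frame[cols[0]].astype(str).str.strip().str.upper()
    b = frame[cols[1]].astype(str).str.strip().str.upper()
    edges: dict[tuple[str, str], float] = {}
    for sym_a, sym_b, score in zip(a, b, scores):
        if sym_a == sym_b:
            continue
        key = (sym_a, sym_b) if sym_a < sym_b else (sym_b, sym_a)
        if score > edges.get(key, -1.0):
            edges[key] = float(score)
    result = pd.DataFrame(
        [(k[0], k[1], v) for k, v in sorted(edges.items())],
        columns=list(EDGE_COLUMNS),
    )
    return result


def write_edge_scores(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FRAP traces (long format)
# ---------------------------------------------------------------------------

FRAP_COLUMNS = ("trace_id", "time_s", "intensity", "phase")
FRAP_PHASES = ("pre", "bleach", "post")


def read_frap_traces(path: str | Path) -> list[FrapTrace]:
    """Read long-format traces (trace_id, time_s, intensity, phase).

    ``prebleach_value`` is the last ``pre``-phase intensity and
    ``postbleach_value`` the last ``bleach``-phase intensity (falling back to
    the first ``post`` frame when no explicit bleach frame is present);
    post-bleach times are re-zeroed at the first post-bleach frame.
    """
    frame = _sniff_frame(path)
    missing = [c for c in FRAP_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    bad = set(frame["phase"]) - set(FRAP_PHASES)
    if bad:
        raise ValidationError(f"{path}: unknown phase value(s) {sorted(bad)}")
    traces = []
    for trace_id, group in frame.groupby("trace_id", sort=True):
        group = group.assign(
            time_s=pd.to_numeric(group["time_s"]),
            intensity=pd.to_numeric(group["intensity"]),
        ).sort_values("time_s")
        pre = group[group["phase"] == "pre"]
        bleach = group[group["phase"] == "bleach"]
        post = group[group["phase"] == "post"]
        if pre.empty or post.empty:
            raise ValidationError(
                f"{path}: trace {trace_id!r} needs both pre and post phases"
            )
        postbleach = (
            float(bleach["intensity"].iloc[-1])
            if not bleach.empty
            else float(post["intensity"].iloc[0])
        )
        t0 = float(post["time_s"].iloc[0])
        traces.append(
            FrapTrace(
                trace_id=str(trace_id),
                times=tuple(float(t) - t0 for t in post["time_s"]),
                intensities=tuple(float(v) for v in post["intensity"]),
                prebleach_value=float(pre["intensity"].iloc[-1]),
                postbleach_value=postbleach,
            )
        )
    return traces


def write_frap_traces(traces: Sequence[FrapTrace], path: str | Path) -> None:
    """Write traces in the long format accepted by :func:`read_frap_traces`.

    The pre- and post-bleach reference values are emitted as explicit ``pre``
    and ``bleach`` frames so a read/write round trip preserves the trace.
    """
    rows = []
    for trace in traces:
        rows.append((trace.trace_id, -2.0, trace.prebleach_value, "pre"))
        rows.append((trace.trace_id, -1.0, trace.postbleach_value, "bleach"))
        for t, i in zip(trace.times, trace.intensities):
            rows.append((trace.trace_id, t, i, "post"))
    pd.DataFrame(rows, columns=list(FRAP_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# viability grids (long format)
# ---------------------------------------------------------------------------

VIABILITY_COLUMNS = ("dose_a", "dose_b", "replicate", "signal")


def read_viability_long(path: str | Path) -> pd.DataFrame:
    frame = _sniff_frame(path)
    missing = [c for c in VIABILITY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    frame = frame.assign(
        dose_a=pd.to_numeric(frame["dose_a"]),
        dose_b=pd.to_numeric(frame["dose_b"]),
        replicate=pd.to_numeric(frame["replicate"]).astype(int),
        signal=pd.to_numeric(frame["signal"]),
    )
    if (frame["signal"] < 0).any():
        raise ValidationError(f"{path}: negative signal values")
    return frame[list(VIABILITY_COLUMNS)]


def write_viability_long(frame: pd.DataFrame, path: str | Path) -> None:
    frame[list(VIABILITY_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic result writer
# ---------------------------------------------------------------------------


def _jsonify(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(value).items()}
    if isinstance(value, Mapping):
        return {str(k): _jsonify(v) for k, v in value.items()}
    if isinstance(value, (list, tuple, set, frozenset)):
        return [_jsonify(v) for v in sorted(value)] if isinstance(
            value, (set, frozenset)
        ) else [_jsonify(v) for v in value]
    return value


def write_results(obj, path: str | Path) -> None:
    """Write any documented pipeline product.

    Tabular products (identification tables, data frames, lists of dataclass
    rows) become TSV with a fixed column order; everything else becomes
    indented JSON.
    """
    path = Path(path)
    if isinstance(obj, IdentificationTable):
        write_identifications(obj, path)
        return
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False)
        return
    if isinstance(obj, (list, tuple)) and obj and dataclasses.is_dataclass(obj[0]):
        rows = [_jsonify(dataclasses.asdict(r)) for r in obj]
        frame = pd.DataFrame(rows)
        frame = frame.map(
            lambda v: ",".join(map(str, v)) if isinstance(v, (list, tuple)) else v
        )
        frame.to_csv(path, sep="\t", index=False)
        return
    with open(path, "wt", encoding="utf-8") as handle:
        json.dump(_jsonify(obj), handle, indent=2, sort_keys=True)
        handle.write("\n")
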