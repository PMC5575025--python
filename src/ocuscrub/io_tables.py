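"""Table I/O and cross-table validation for low-biomass amplicon experiments.

A study is described by four plain-text tables:

* an OTU count table (integer reads, samples x OTUs),
* per-sample metadata (sample type, subject, time point),
* an OTU taxonomy map (phylum..genus lineages), and
* per-sample PCR band luminosities (a surrogate for target biomass).

All tables travel as tab-delimited UTF-8 text with a header row and
unquoted identifiers (mothur shared-file style).  A minimal BIOM v1 (JSON)
reader is provided as a convenience for count tables exported by other
toolchains.

Everything downstream assumes these tables have been validated, so the
readers here are strict: duplicate identifiers, negative or fractional
counts, unknown sample types and inconsistent cross-references are all
rejected up front rather than silently repaired.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUBJECT",
    "BLANK_CONTROL",
    "WATER_CONTROL",
    "SAMPLE_TYPES",
    "RANKS",
    "UNCLASSIFIED",
    "DEFAULT_TIME_POINTS",
    "SAMPLES_IN_ROWS",
    "OTUS_IN_ROWS",
    "ParseError",
    "ValidationError",
    "CountTable",
    "SampleMetadata",
    "TaxonomyMap",
    "LuminosityTable",
    "ValidationReport",
    "read_count_table",
    "read_count_table_biom",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_luminosity",
    "write_luminosity",
    "validate_experiment",
]

# ---------------------------------------------------------------------------
# Constants

SUBJECT = "subject"
BLANK_CONTROL = "blank_control"
WATER_CONTROL = "water_control"
SAMPLE_TYPES = (SUBJECT, BLANK_CONTROL, WATER_CONTROL)

#: Fixed taxonomic ranks below domain; lineages are always stored at these
#: five ranks, padded with :data:`UNCLASSIFIED` where the classifier gave up.
RANKS = ("phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"

DEFAULT_TIME_POINTS = ("baseline", "month1", "month3")

SAMPLES_IN_ROWS = "samples_in_rows"
OTUS_IN_ROWS = "otus_in_rows"
_ORIENTATIONS = (SAMPLES_IN_ROWS, OTUS_IN_ROWS)

_DOMAIN_NAMES = {"root", "bacteria", "archaea", "eukaryota", "unknown"}


class ParseError(ValueError):
    """A file could not be parsed as the expected TSV/JSON dialect."""


class ValidationError(ValueError):
    """A table parsed but violates a structural invariant."""


# ---------------------------------------------------------------------------
# Count table


@dataclass(eq=False)
class CountTable:
    """Integer read counts in canonical samples x OTUs orientation.

    ``data`` is a pandas DataFrame indexed by sample id with one column per
    OTU.  Counts are validated to be non-negative integers; identifiers on
    both axes must be unique and non-empty.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValidationError("count table needs at least one sample and one OTU")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate sample identifier {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate OTU identifier {dup!r}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValidationError("count table contains missing or non-finite cells")
            if np.any(arr != np.floor(arr)):
                bad = np.argwhere(arr != np.floor(arr))[0]
                raise ValidationError(
                    f"non-integral count {arr[bad[0], bad[1]]!r} for sample "
                    f"{df.index[bad[0]]!r}, OTU {df.columns[bad[1]]!r}"
                )
        if (arr < 0).any():
            bad = np.argwhere(np.asarray(arr) < 0)[0]
            raise ValidationError(
                f"negative count for sample {df.index[bad[0]]!r}, "
                f"OTU {df.columns[bad[1]]!r}"
            )
        df = df.astype(np.int64)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = "sample_id"
        df.columns.name = "otu_id"
        self.data = df

    # -- convenience accessors ------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        """Total reads per sample (sequencing depth after upstream QC)."""
        return self.data.sum(axis=1)

    def sorted(self) -> "CountTable":
        """Copy with lexicographically sorted sample and OTU axes."""
        return CountTable(self.data.sort_index(axis=0).sort_index(axis=1))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data)


def read_count_table(path, orientation: str = SAMPLES_IN_ROWS) -> CountTable:
    """Read a TSV count table, transposing to samples x OTUs if needed.

    ``orientation`` declares what the file's *rows* are: ``samples_in_rows``
    (default) or ``otus_in_rows``.  Reading a transposed file with the
    flipped flag yields an identical :class:`CountTable`.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}, got {orientation!r}")
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    labels = header[1:]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate identifier {lab!r} in header of {path.name}")
        seen.add(lab)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc. carry a line number
        raise ParseError(f"{path.name}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate identifier {dup!r} in first column of {path.name}")
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path.name} line {i + 2}: cell for row {df.index[i]!r}, "
            f"column {df.columns[j]!r} is not a number ({df.iloc[i, j]!r})"
        )
    if orientation == OTUS_IN_ROWS:
        numeric = numeric.T
    return CountTable(numeric)


def read_count_table_biom(path) -> CountTable:
    """Read a BIOM format v1 (JSON) table; rows are observations (OTUs).

    Supports both ``dense`` and ``sparse`` matrix types.  This is a
    convenience entry point; TSV remains the canonical interchange format.
    """
    path = Path(path)
    try:
        with path.open("r", encoding="utf-8") as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path.name}: not valid BIOM v1 JSON ({exc})") from exc
    try:
        otus = [row["id"] for row in obj["rows"]]
        samples = [col["id"] for col in obj["columns"]]
        n_rows, n_cols = obj["shape"]
        matrix_type = obj.get("matrix_type", "dense")
        data = obj["data"]
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path.name}: missing BIOM v1 field ({exc})") from exc
    mat = np.zeros((n_rows, n_cols))
    if matrix_type == "sparse":
        for r, c, v in data:
            mat[r, c] = v
    else:
        mat = np.asarray(data, dtype=float)
    df = pd.DataFrame(mat, index=otus, columns=samples)
    return CountTable(df.T)


def write_count_table(table: CountTable, path) -> None:
    table.data.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata


@dataclass(eq=False)
class SampleMetadata:
    """Per-sample type, subject and time point.

    Subject samples must carry ``subject_id`` and a ``time_point`` drawn from
    the ordered set ``time_points``; control samples (blank swab or
    nuclease-free water) must carry neither.
    """

    data: pd.DataFrame
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = {"sample_type", "subject_id", "time_point"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate sample identifier {dup!r} in metadata")
        self.time_points = tuple(self.time_points)

        def _blank(v) -> bool:
            return pd.isna(v) or (isinstance(v, str) and v.strip() == "")

        for sid, row in df.iterrows():
            stype = row["sample_type"]
            if stype not in SAMPLE_TYPES:
                raise ValidationError(
                    f"unknown sample_type {stype!r} for sample {sid!r} "
                    f"(expected one of {SAMPLE_TYPES})"
                )
            if stype == SUBJECT:
                if _blank(row["subject_id"]):
                    raise ValidationError(f"subject sample {sid!r} is missing subject_id")
                if _blank(row["time_point"]):
                    raise ValidationError(f"subject sample {sid!r} is missing time_point")
                if row["time_point"] not in self.time_points:
                    raise ValidationError(
                        f"unknown time_point {row['time_point']!r} for sample {sid!r} "
                        f"(expected one of {self.time_points})"
                    )
            else:
                if not _blank(row["subject_id"]) or not _blank(row["time_point"]):
                    raise ValidationError(
                        f"control sample {sid!r} must not carry subject_id or time_point"
                    )
        # normalise blanks to pd.NA so equality survives a write/read cycle
        for col in ("subject_id", "time_point"):
            df[col] = df[col].map(lambda v: pd.NA if _blank(v) else v)
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
        self.data = df[["sample_type", "subject_id", "time_point"]]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def samples_of_type(self, sample_type: str) -> list[str]:
        if sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample type {sample_type!r}")
        return list(self.data.index[self.data["sample_type"] == sample_type])

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.data.loc[self.data["sample_type"] == SUBJECT, "subject_id"]:
            seen.setdefault(v)
        return list(seen)

    def sample_type(self, sample_id: str) -> str:
        return self.data.at[sample_id, "sample_type"]

    def subject_and_time(self, sample_id: str) -> tuple[str, str]:
        row = self.data.loc[sample_id]
        return row["subject_id"], row["time_point"]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        return self.time_points == other.time_points and self.data.equals(other.data)


def read_metadata(path, time_points: Sequence[str] = DEFAULT_TIME_POINTS) -> SampleMetadata:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    if "sample_id" not in df.columns:
        raise ParseError(f"{path.name}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    return SampleMetadata(df, tuple(time_points))


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.data.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# Taxonomy


@dataclass(eq=False)
class TaxonomyMap:
    """OTU -> (phylum, class, order, family, genus) lineage map.

    Unclassified ranks hold the literal sentinel ``"unclassified"`` (RDP
    style); a rank is never simply absent.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = set(RANKS) - set(df.columns)
        if missing:
            raise ValidationError(f"taxonomy missing rank columns: {sorted(missing)}")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate OTU identifier {dup!r} in taxonomy")
        for rank in RANKS:
            df[rank] = df[rank].map(
                lambda v: UNCLASSIFIED
                if pd.isna(v) or (isinstance(v, str) and v.strip() == "")
                else str(v)
            )
        df.index = df.index.astype(str)
        df.index.name = "otu_id"
        self.data = df[list(RANKS)]

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    def lineage(self, otu_id: str) -> tuple[str, ...]:
        if otu_id not in self.data.index:
            raise KeyError(f"OTU {otu_id!r} not in taxonomy")
        return tuple(self.data.loc[otu_id])

    def rank_labels(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r} (expected one of {RANKS})")
        return self.data[rank]

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.data.index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyMap):
            return NotImplemented
        return self.data.equals(other.data)


_CONFIDENCE_RE = re.compile(r"\(\d+\)")


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Parse a semicolon-delimited lineage string into the five fixed ranks.

    Handles mothur/RDP conventions: trailing semicolons, per-rank bootstrap
    confidences like ``Corynebacterium(100)``, and an optional leading domain
    token (``Bacteria``...), which is dropped.  Missing trailing ranks are
    filled with the unclassified sentinel.
    """
    cleaned = _CONFIDENCE_RE.sub("", lineage).strip().strip(";")
    tokens = [tok.strip() for tok in cleaned.split(";")] if cleaned else []
    if tokens and tokens[0].lower() in _DOMAIN_NAMES:
        tokens = tokens[1:]
    tokens = [tok if tok else UNCLASSIFIED for tok in tokens]
    if len(tokens) > len(RANKS):
        tokens = tokens[: len(RANKS)]
    tokens += [UNCLASSIFIED] * (len(RANKS) - len(tokens))
    return tuple(tokens)


def read_taxonomy(path) -> TaxonomyMap:
    """Read a two-column TSV of ``otu_id`` and semicolon-delimited lineage."""
    path = Path(path)
    rows: dict[str, tuple[str, ...]] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path.name}: expected two tab-separated columns")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path.name} line {lineno}: expected two columns")
            otu_id, lineage = parts[0], parts[1]
            if otu_id in rows:
                raise ValidationError(f"duplicate OTU identifier {otu_id!r} in {path.name}")
            rows[otu_id] = parse_lineage(lineage)
    if not rows:
        raise ValidationError(f"{path.name}: no taxonomy rows")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    return TaxonomyMap(df)


def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("otu_id\ttaxonomy\n")
        for otu_id, row in taxonomy.data.iterrows():
            fh.write(f"{otu_id}\t{';'.join(row)}\n")


# ---------------------------------------------------------------------------
# Luminosity


@dataclass(eq=False)
class LuminosityTable:
    """Per-sample PCR band luminosity (arbitrary units, non-negative).

    Band luminosity is the surrogate measure of per-sample target DNA
    concentration; at least one sample must have a positive value, otherwise
    the luminosity weighting of the filter is undefined.
    """

    values: pd.Series

    def __post_init__(self) -> None:
        s = self.values.astype(float).copy()
        if s.index.duplicated().any():
            dup = s.index[s.index.duplicated()][0]
            raise ValidationError(f"duplicate sample identifier {dup!r} in luminosity table")
        if s.isna().any():
            sid = s.index[s.isna()][0]
            raise ValidationError(f"missing luminosity for sample {sid!r}")
        if (s < 0).any():
            sid = s.index[s < 0][0]
            raise ValidationError(f"negative luminosity for sample {sid!r}")
        if len(s) == 0 or not (s > 0).any():
            raise ValidationError("all luminosities are zero; weighting is undefined")
        s.index = s.index.astype(str)
        s.index.name = "sample_id"
        s.name = "luminosity"
        self.values = s

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LuminosityTable):
            return NotImplemented
        return self.values.equals(other.values)


def read_luminosity(path) -> LuminosityTable:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path.name}: expected sample_id and luminosity columns")
    sample_col, value_col = df.columns[0], df.columns[1]
    values = []
    for i, raw in enumerate(df[value_col]):
        try:
            # Python's float() is correctly rounded, so a write/read cycle
            # reproduces the exact double (pandas' fast parser is not)
            values.append(float(raw))
        except (TypeError, ValueError):
            raise ParseError(
                f"{path.name} line {i + 2}: luminosity {raw!r} is not a number"
            ) from None
    series = pd.Series(values, index=df[sample_col].astype(str), dtype=float)
    return LuminosityTable(series)


def write_luminosity(luminosity: LuminosityTable, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tluminosity\n")
        for sid, value in luminosity.values.items():
            fh.write(f"{sid}\t{float(value)!r}\n")  # repr: shortest round-trip float


# ---------------------------------------------------------------------------
# Cross-table validation


@dataclass
class ValidationReport:
    """Outcome of cross-table consistency checks.

    ``errors`` are conditions under which the filtering pipeline cannot run;
    ``warnings`` are reported but tolerated (e.g. samples enrolled in the
    metadata that were never sequenced).
    """

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_errors(self) -> None:
        if self.errors:
            raise ValidationError("; ".join(self.errors))


def validate_experiment(
    counts: CountTable,
    metadata: SampleMetadata,
    luminosity: LuminosityTable | None = None,
) -> ValidationReport:
    """Check that counts, metadata and luminosity describe the same samples.

    Samples present in the metadata but absent from the count table are
    warnings, not errors: studies legitimately drop enrolled samples.  A
    missing metadata row for a counted sample, a counted sample without a
    luminosity entry, or the absence of either control type are errors —
    the regression passes need blank-swab controls (steps against the blank
    predictor) and water controls (the final water-control pass).
    """
    report = ValidationReport()
    meta_ids = set(metadata.sample_ids)
    count_ids = set(counts.sample_ids)
    for sid in counts.sample_ids:
        if sid not in meta_ids:
            report.errors.append(f"sample {sid!r} in counts has no metadata row")
    for sid in metadata.sample_ids:
        if sid not in count_ids:
            report.warnings.append(f"sample {sid!r} in metadata is absent from counts")
    if luminosity is not None:
        lum_ids = set(luminosity.sample_ids)
        for sid in counts.sample_ids:
            if sid in meta_ids and sid not in lum_ids:
                stype = metadata.sample_type(sid)
                report.errors.append(
                    f"{stype} sample {sid!r} has no luminosity entry"
                )
    counted_types = {
        metadata.sample_type(sid) for sid in counts.sample_ids if sid in meta_ids
    }
    if SUBJECT not in counted_types:
        report.errors.append("no subject samples in the count table")
    if BLANK_CONTROL not in counted_types:
        report.errors.append(
            "no blank_control samples: blank-swab regression passes cannot run"
        )
    if WATER_CONTROL not in counted_types:
        report.errors.append(
            "no water_control samples: water-control regression pass (step i) cannot run"
        )
    return report
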