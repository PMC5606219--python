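"""Peak-file and expression-table ingest.

Supported peak formats are the BED family: BED3-BED6, ENCODE broadPeak
(BED6+3: signalValue, pValue, qValue) and ENCODE narrowPeak (BED6+4: adds the
summit offset).  Malformed lines never abort a parse — they are skipped and
reported with their line number and reason, so that
``len(peaks) + len(parse_reports)`` equals the number of non-comment lines.

Missing numeric fields written as ``.`` map to ``None`` ("not provided"),
never to zero; the BED score column is the one exception (absent -> 0, per
the BED display convention).  Scores above the nominal 1000 cap occur in real
ENCODE files and are accepted with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import isfinite, inf
from pathlib import Path

__all__ = [
    "Peak",
    "TrackKey",
    "PeakSet",
    "ExpressionTable",
    "PeakParseError",
    "read_peaks",
    "write_peaks",
    "auto_map_attributes",
    "read_expression",
    "write_expression",
    "apply_cutoffs",
]

_COMMENT_PREFIXES = ("#", "track", "browser")


class PeakParseError(ValueError):
    """Fatal feature-file problem (unreadable, or zero well-formed lines)."""


@dataclass(frozen=True)
class Peak:
    """One enrichment interval, 0-based half-open.

    ``signal_value`` / ``p_value_neglog10`` / ``q_value_neglog10`` are None
    when the file said "not provided" (``.`` or ``-1``); ``summit_offset`` is
    the narrowPeak column-10 offset from ``start`` (-1 = not provided).
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."
    signal_value: float | None = None
    p_value_neglog10: float | None = None
    q_value_neglog10: float | None = None
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start >= end")
        if self.start < 0:
            raise ValueError("negative start")
        if self.score < 0:
            raise ValueError("negative score")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")
        if not (self.summit_offset == -1 or 0 <= self.summit_offset < self.size):
            raise ValueError("summit offset outside peak")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class TrackKey:
    """(cell type, mark) identity of one feature track."""

    cell_type: str
    mark: str

    def __post_init__(self) -> None:
        if not self.cell_type or not self.mark:
            raise ValueError("cell_type and mark must be non-empty")

    def __str__(self) -> str:
        return f"{self.cell_type}/{self.mark}"


@dataclass
class PeakSet:
    key: TrackKey
    peaks: list[Peak]
    source: str = ""
    parse_reports: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class ExpressionTable:
    """Per-cell-type gene expression (FPKM-like, non-negative)."""

    cell_type: str
    values: dict[str, float]
    source: str = ""
    parse_reports: list[tuple[int, str]] = field(default_factory=list)

    def get(self, *identifiers: str) -> float | None:
        """Look up the first identifier present (case-insensitive)."""
        for ident in identifiers:
            v = self.values.get(ident)
            if v is None:
                v = self._lower.get(ident.lower())
            if v is not None:
                return v
        return None

    def __post_init__(self) -> None:
        self._lower = {k.lower(): v for k, v in self.values.items()}


def auto_map_attributes(
    filename: str | Path, manifest: dict[str, tuple[str, str]] | None = None
) -> TrackKey:
    """Derive (cell_type, mark) from a file name.

    A manifest entry (keyed by base name or full path) overrides the default
    rule: split the stem on the first underscore into cell type and mark.
    With no delimiter and no manifest entry the whole stem becomes the cell
    type and the mark is "unknown", with a warning.
    """
    p = Path(filename)
    if manifest:
        for key in (str(p), p.name):
            if key in manifest:
                cell, mark = manifest[key]
                return TrackKey(cell, mark)
    stem = p.stem
    if "_" in stem:
        cell, mark = stem.split("_", 1)
        if cell and mark:
            return TrackKey(cell, mark)
    warnings.warn(
        f"cannot auto-map attributes from {p.name!r}; "
        f"using cell_type={stem!r}, mark='unknown'",
        stacklevel=2,
    )
    return TrackKey(stem, "unknown")


def _optnum(tok: str) -> float | None:
    if tok in (".", "-1", "-1.0"):
        return None
    v = float(tok)
    return None if v == -1 else v


def _parse_peak_fields(fields: list[str], fmt: str) -> Peak:
    if len(fields) < 3:
        raise ValueError("fewer than 3 columns")
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    name = fields[3] if len(fields) > 3 else ""
    score = 0.0
    if len(fields) > 4 and fields[4] != ".":
        score = float(fields[4])
    strand = fields[5] if len(fields) > 5 else "."
    if strand not in ("+", "-", "."):
        raise ValueError(f"bad strand {strand!r}")
    signal = pval = qval = None
    summit = -1
    if fmt in ("broadPeak", "narrowPeak"):
        if fmt == "broadPeak" and len(fields) < 9:
            raise ValueError("broadPeak requires 9 columns")
        if fmt == "narrowPeak" and len(fields) < 10:
            raise ValueError("narrowPeak requires 10 columns")
        signal = _optnum(fields[6])
        pval = _optnum(fields[7])
        qval = _optnum(fields[8])
        if fmt == "narrowPeak":
            summit = int(fields[9])
    peak = Peak(
        chrom=chrom,
        start=start,
        end=end,
        name=name,
        score=score,
        strand=strand,
        signal_value=signal,
        p_value_neglog10=pval,
        q_value_neglog10=qval,
        summit_offset=summit,
    )
    if peak.score > 1000:
        warnings.warn(
            f"peak {name or chrom}:{start}-{end} has score {peak.score} > 1000",
            stacklevel=3,
        )
    return peak


def _infer_format(path: Path, first_fields: list[str]) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix == "narrowpeak":
        return "narrowPeak"
    if suffix == "broadpeak":
        return "broadPeak"
    if suffix == "bed":
        return "bed"
    n = len(first_fields)
    if n >= 10:
        return "narrowPeak"
    if n == 9:
        return "broadPeak"
    return "bed"


def read_peaks(
    path: str | Path,
    format: str = "auto",
    key: TrackKey | None = None,
    manifest: dict[str, tuple[str, str]] | None = None,
) -> PeakSet:
    """Parse a BED / broadPeak / narrowPeak file into a :class:`PeakSet`.

    ``format="auto"`` infers the dialect from the extension, falling back to
    the column count of the first data line.  Lines starting with ``#``,
    ``track`` or ``browser`` are headers, not data.  Raises
    :class:`PeakParseError` if the file is unreadable or yields zero
    well-formed peaks.
    """
    path = Path(path)
    if format not in ("auto", "bed", "broadPeak", "narrowPeak"):
        raise ValueError(f"unknown format {format!r}")
    try:
        text = path.read_text()
    except OSError as exc:
        raise PeakParseError(f"cannot read {path}: {exc}") from exc
    if key is None:
        key = auto_map_attributes(path, manifest)
    peaks: list[Peak] = []
    reports: list[tuple[int, str]] = []
    fmt = None if format == "auto" else format
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped or any(stripped.startswith(p) for p in _COMMENT_PREFIXES):
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = stripped.split()
        if fmt is None:
            fmt = _infer_format(path, fields)
        try:
            peaks.append(_parse_peak_fields(fields, fmt))
        except (ValueError, IndexError) as exc:
            msg = str(exc)
            if "start >= end" in msg:
                msg = "start >= end"
            reports.append((lineno, msg))
    if not peaks:
        raise PeakParseError(f"no well-formed peaks in {path}")
    return PeakSet(key=key, peaks=peaks, source=str(path), parse_reports=reports)


def _fmtnum(v: float | None) -> str:
    if v is None:
        return "."
    return repr(int(v)) if float(v).is_integer() else repr(v)


def write_peaks(ps: PeakSet, path: str | Path, format: str = "narrowPeak") -> None:
    """Serialize a PeakSet back to BED / broadPeak / narrowPeak text."""
    lines = []
    for i, p in enumerate(ps.peaks):
        base = [p.chrom, str(p.start), str(p.end), p.name or f"peak{i}",
                _fmtnum(p.score), p.strand]
        if format == "bed":
            row = base
        elif format in ("broadPeak", "narrowPeak"):
            row = base + [
                _fmtnum(p.signal_value),
                _fmtnum(p.p_value_neglog10),
                _fmtnum(p.q_value_neglog10),
            ]
            if format == "narrowPeak":
                row.append(str(p.summit_offset))
        else:
            raise ValueError(f"unknown format {format!r}")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression(path: str | Path, cell_type: str) -> ExpressionTable:
    """Load a two-column (identifier TAB value) expression table.

    Values must be finite and non-negative; duplicates keep the maximum value
    with a warning; malformed lines are skipped and reported.  Zero valid
    rows is fatal.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise PeakParseError(f"cannot read {path}: {exc}") from exc
    values: dict[str, float] = {}
    reports: list[tuple[int, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            parts = line.split()
        if len(parts) < 2:
            reports.append((lineno, "expected two columns"))
            continue
        ident = parts[0].strip()
        try:
            value = float(parts[1])
        except ValueError:
            reports.append((lineno, f"non-numeric value {parts[1]!r}"))
            continue
        if not isfinite(value):
            reports.append((lineno, "non-finite value"))
            continue
        if value < 0:
            reports.append((lineno, "negative value"))
            continue
        if ident in values:
            warnings.warn(
                f"duplicate expression entry for {ident!r}; keeping maximum",
                stacklevel=2,
            )
            values[ident] = max(values[ident], value)
        else:
            values[ident] = value
    if not values:
        raise PeakParseError(f"no valid expression rows in {path}")
    return ExpressionTable(
        cell_type=cell_type, values=values, source=str(path), parse_reports=reports
    )


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    lines = [f"{gid}\t{_fmtnum(v)}" for gid, v in table.values.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def apply_cutoffs(
    ps: PeakSet,
    min_score: float = 0.0,
    min_size: int = 0,
    max_size: float = inf,
) -> PeakSet:
    """Quality filter: keep peaks with score >= min_score and size within
    [min_size, max_size].  Returns a new PeakSet; the input is untouched."""
    if not (0 <= min_size <= max_size):
        raise ValueError("require 0 <= min_size <= max_size")
    kept = [
        p for p in ps.peaks
        if p.score >= min_score and min_size <= p.size <= max_size
    ]
    return replace(ps, peaks=kept)
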