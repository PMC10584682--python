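"""Readers, writers and in-memory containers for the genomic/tabular formats the
pipeline touches.

All internal coordinates are 0-based half-open.  GFF3 (1-based, closed) is
converted at the boundary: ``internal_start = gff_start - 1``,
``internal_end = gff_end``.  BED-family files and bedGraph are already 0-based
half-open and pass through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("broaddomain")

__all__ = [
    "GeneModel",
    "Peak",
    "PeakSet",
    "CoverageTrack",
    "CountMatrix",
    "FormatError",
    "read_gff3",
    "write_gff3",
    "read_peaks",
    "write_peaks",
    "read_bedgraph",
    "write_bedgraph",
    "read_counts",
    "write_counts",
    "read_condition_map",
    "write_condition_map",
]


class FormatError(ValueError):
    """Raised for malformed records in any of the supported file formats."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene interval.

    The transcription start/end sites are derived from the strand: on ``+``
    the TSS is ``start`` and the TES is ``end``; on ``-`` they swap.  Unknown
    strand ``.`` is rejected because metagene profiles require orientation.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A called peak interval, optionally with a score and a summit offset
    (narrowPeak column 10; offset relative to ``start``)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"peak {self.name}: start ({self.start}) must be < end ({self.end})"
            )
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise FormatError(
                f"peak {self.name}: summit offset {self.summit_offset} outside "
                f"[0, {self.end - self.start})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


class PeakSet:
    """An ordered collection of :class:`Peak` records."""

    def __init__(self, peaks: Iterable[Peak] = ()) -> None:
        self.peaks: list[Peak] = list(peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PeakSet) and self.peaks == other.peaks

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out


class CoverageTrack:
    """Stepwise per-base signal over a genome.

    Steps are stored per chromosome as parallel arrays ``(starts, ends,
    values)``, sorted, non-overlapping, with adjacent equal-valued steps merged
    and zero-valued steps dropped (positions outside any step read as 0).
    ``total_mapped_reads`` is carried for RPM scaling and is an explicit input:
    coverage mass depends on read length, so it cannot be inferred from the
    steps themselves.
    """

    def __init__(
        self,
        steps: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
        total_mapped_reads: int = 0,
    ) -> None:
        self.steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.total_mapped_reads = int(total_mapped_reads)
        if steps:
            for chrom, (s, e, v) in steps.items():
                self._set_chrom(chrom, np.asarray(s), np.asarray(e), np.asarray(v))

    def _set_chrom(self, chrom: str, s: np.ndarray, e: np.ndarray, v: np.ndarray) -> None:
        s = np.asarray(s, dtype=np.int64)
        e = np.asarray(e, dtype=np.int64)
        v = np.asarray(v, dtype=float)
        if np.any(e <= s):
            raise FormatError(f"{chrom}: step with end <= start")
        if np.any(~np.isfinite(v)) or np.any(v < 0):
            raise FormatError(f"{chrom}: step values must be finite and >= 0")
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if np.any(e[:-1] > s[1:]):
            raise FormatError(f"{chrom}: overlapping coverage steps")
        # run-length canonicalization: merge runs of abutting equal-valued steps
        if len(s) > 1:
            joined = (s[1:] == e[:-1]) & (v[1:] == v[:-1])
            group = np.concatenate(([0], np.cumsum(~joined)))
            firsts = np.flatnonzero(np.diff(group, prepend=-1))
            lasts = np.concatenate((firsts[1:] - 1, [len(s) - 1]))
            s, e, v = s[firsts], e[lasts], v[firsts]
        nz = v > 0
        self.steps[chrom] = (s[nz], e[nz], v[nz])

    def chroms(self) -> list[str]:
        return sorted(self.steps)

    def total_mass(self) -> float:
        """Sum of value x step length over the whole track."""
        return float(
            sum(((e - s) * v).sum() for s, e, v in self.steps.values())
        )

    def values_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal over ``[start, end)``; 0 outside any step.

        ``start`` may be negative or run past the last step; out-of-range bases
        read 0 (the caller decides how to treat off-chromosome positions).
        """
        if end <= start:
            return np.zeros(0)
        out = np.zeros(end - start)
        if chrom not in self.steps:
            return out
        s, e, v = self.steps[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        for i in range(lo, hi):
            a = max(s[i], start) - start
            b = min(e[i], end) - start
            if b > a:
                out[a:b] = v[i]
        return out

    def scaled(self, factor: float) -> "CoverageTrack":
        out = CoverageTrack(total_mapped_reads=self.total_mapped_reads)
        for chrom, (s, e, v) in self.steps.items():
            out.steps[chrom] = (s.copy(), e.copy(), v * factor)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if self.total_mapped_reads != other.total_mapped_reads:
            return False
        if set(self.steps) != set(other.steps):
            return False
        return all(
            all(np.array_equal(a, b) for a, b in zip(self.steps[c], other.steps[c]))
            for c in self.steps
        )


@dataclass
class CountMatrix:
    """An integer count matrix (features x samples) with a condition label per
    sample (``control`` / ``mutant``)."""

    counts: pd.DataFrame
    sample_condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        if self.counts.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise FormatError("counts must be >= 0")
        missing = [s for s in self.counts.columns if s not in self.sample_condition]
        if missing:
            raise FormatError(f"samples missing from condition map: {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_condition[s] == condition]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Read GeneModels from a GFF3 file, converting 1-based closed intervals to
    the internal 0-based half-open convention."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns, got {len(cols)}")
            if cols[2] != feature_type:
                continue
            try:
                gstart, gend = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from exc
            attrs = _parse_gff3_attributes(cols[8])
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if gene_id is None:
                raise FormatError(f"{path}: line {lineno}: missing ID attribute")
            if gene_id in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            try:
                genes.append(
                    GeneModel(
                        gene_id=gene_id,
                        chrom=cols[0],
                        start=gstart - 1,
                        end=gend,
                        strand=cols[6],
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path, feature_type: str = "gene") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tbroaddomain\t{feature_type}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED6 / narrowPeak
# ---------------------------------------------------------------------------


def read_peaks(path: str | Path, dialect: str = "bed6") -> PeakSet:
    """Read peaks from a BED6 or ENCODE narrowPeak file (0-based half-open).

    narrowPeak summit values of -1 are recorded as absent.
    """
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    want = 6 if dialect == "bed6" else 10
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < want:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= {want} columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from exc
            score = None if cols[4] in (".", "") else float(cols[4])
            summit = None
            if dialect == "narrowPeak":
                summit_raw = int(cols[9])
                summit = None if summit_raw == -1 else summit_raw
            try:
                peaks.append(
                    Peak(
                        chrom=cols[0],
                        start=start,
                        end=end,
                        name=cols[3],
                        score=score,
                        summit_offset=summit,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return PeakSet(peaks)


def write_peaks(peaks: PeakSet, path: str | Path, dialect: str = "bed6") -> None:
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for p in peaks:
            score = "." if p.score is None else f"{p.score:g}"
            row = [p.chrom, str(p.start), str(p.end), p.name, score, "."]
            if dialect == "narrowPeak":
                summit = -1 if p.summit_offset is None else p.summit_offset
                row += ["0", "-1", "-1", str(summit)]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(path: str | Path, total_mapped_reads: int) -> CoverageTrack:
    """Read a bedGraph file into a canonical :class:`CoverageTrack`.

    Overlapping steps and negative values are rejected; abutting equal-valued
    steps are merged.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            try:
                start, end, value = int(cols[1]), int(cols[2]), float(cols[3])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: malformed record") from exc
            if value < 0:
                raise FormatError(f"{path}: line {lineno}: negative value")
            per_chrom.setdefault(cols[0], []).append((start, end, value))
    track = CoverageTrack(total_mapped_reads=total_mapped_reads)
    for chrom, rows in per_chrom.items():
        arr = np.array(rows, dtype=float)
        track._set_chrom(chrom, arr[:, 0], arr[:, 1], arr[:, 2])
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            s, e, v = track.steps[chrom]
            for i in range(len(s)):
                fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:g}\n")


# ---------------------------------------------------------------------------
# Count matrices + condition maps
# ---------------------------------------------------------------------------


def read_condition_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "condition"]:
        raise FormatError(f"{path}: expected columns 'sample' and 'condition'")
    return dict(zip(df["sample"], df["condition"]))


def write_condition_map(sample_condition: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcondition\n")
        for s, c in sample_condition.items():
            fh.write(f"{s}\t{c}\n")


def read_counts(path: str | Path, condition_map: str | Path) -> CountMatrix:
    """Read a TSV count matrix (first column feature ids, header sample ids)
    and attach per-sample conditions from a two-column map file."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cond = read_condition_map(condition_map)
    missing = [s for s in df.columns if s not in cond]
    if missing:
        raise FormatError(f"{path}: samples absent from condition map: {missing}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: non-integer counts")
    return CountMatrix(counts=df, sample_condition={s: cond[s] for s in df.columns})


def write_counts(matrix: CountMatrix, path: str | Path, feature_col: str = "feature_id") -> None:
    matrix.counts.rename_axis(feature_col).to_csv(path, sep="\t")
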