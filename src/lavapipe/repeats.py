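"""Repeat-annotation handling: RepeatMasker ``.out`` parsing, full-length copy
selection, and track integration.

The central use case is building a custom annotation for a lineage-specific
retrotransposon family (e.g. LAVA, a ~1,300 bp composite element found only in
small-ape genomes): full-length and nearly full-length copies are selected by
their footprint on the family consensus (``repStart``/``repEnd``) and merged
into a base RepeatMasker track, discarding any pre-existing annotation that
overlaps a selected copy.

Coordinates are 0-based half-open internally; RepeatMasker ``.out`` files are
read and written in their native 1-based inclusive convention.  Consensus
coordinates are 1-based inclusive bases on the family consensus and are always
stored in consensus orientation (``rep_start <= rep_end``), regardless of the
genomic strand of the hit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from intervaltree import IntervalTree

__all__ = [
    "RepeatCopy",
    "RepeatTrack",
    "RepeatParseError",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
    "select_full_length",
    "integrate_copies",
]

# Default thresholds for full-length copy selection against a 1,300 bp
# consensus: keep copies starting before base 100 and ending after base 1,200.
MAX_REP_START = 100
MIN_REP_END = 1200


class RepeatParseError(ValueError):
    """Raised on a malformed RepeatMasker .out body row."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class RepeatCopy:
    """One annotated repeat copy.

    ``start``/``end`` are 0-based half-open genomic coordinates;
    ``rep_start``/``rep_end`` are 1-based inclusive consensus coordinates in
    consensus orientation.  ``rep_left`` is the number of consensus bases
    beyond ``rep_end`` (RepeatMasker's parenthesised column).
    """

    chrom: str
    start: int
    end: int
    strand: str
    family: str
    class_family: str = "Unknown"
    rep_start: int | None = None
    rep_end: int | None = None
    rep_left: int = 0
    score: float = 0.0
    divergence: float = 0.0
    deletion: float = 0.0
    insertion: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"repeat copy {self.family} on {self.chrom}: start {self.start} "
                f">= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.rep_start is not None and self.rep_end is not None:
            if not (1 <= self.rep_start <= self.rep_end):
                raise ValueError(
                    f"consensus coordinates must satisfy 1 <= repStart <= repEnd, "
                    f"got ({self.rep_start}, {self.rep_end})"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "RepeatCopy") -> bool:
        """Strand-agnostic test for >= 1 shared genomic base."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


class RepeatTrack:
    """An ordered collection of :class:`RepeatCopy`, sorted by (chrom, start)."""

    def __init__(self, copies: Iterable[RepeatCopy] = ()):
        self._copies = sorted(copies, key=lambda c: (c.chrom, c.start, c.end, c.family))

    def __len__(self) -> int:
        return len(self._copies)

    def __iter__(self) -> Iterator[RepeatCopy]:
        return iter(self._copies)

    def __getitem__(self, i):
        return self._copies[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, RepeatTrack) and self._copies == other._copies

    def __repr__(self) -> str:
        fams = sorted({c.family for c in self._copies})
        shown = ", ".join(fams[:4]) + ("..." if len(fams) > 4 else "")
        return f"RepeatTrack({len(self._copies)} copies; families: {shown})"

    @property
    def copies(self) -> Sequence[RepeatCopy]:
        return tuple(self._copies)

    def families(self) -> list[str]:
        return sorted({c.family for c in self._copies})

    def interval_trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees of copy indices for overlap queries."""
        trees: dict[str, IntervalTree] = {}
        for i, c in enumerate(self._copies):
            trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end, i)
        return trees

    def to_bed(self, handle: IO[str] | str | Path) -> None:
        """Write the track as BED6 (0-based half-open)."""
        with _maybe_open(handle, "w") as fh:
            for c in self._copies:
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\t{c.family}\t"
                    f"{int(round(c.score))}\t{c.strand}\n"
                )


def _maybe_open(handle, mode="r"):
    if isinstance(handle, (str, Path)):
        return open(handle, mode)
    # wrap a file-like so the with-statement does not close the caller's handle
    return _NonClosing(handle)


class _NonClosing:
    def __init__(self, fh):
        self._fh = fh

    def __enter__(self):
        return self._fh

    def __exit__(self, *exc):
        return False


_OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)     ID\n"
    "\n"
)


def _parse_paren(token: str, lineno: int) -> int:
    token = token.strip()
    if token.startswith("(") and token.endswith(")"):
        token = token[1:-1]
    try:
        return int(token)
    except ValueError as exc:
        raise RepeatParseError(f"expected integer coordinate, got {token!r}", lineno) from exc


def parse_repeatmasker_out(source: IO[str] | str | Path) -> RepeatTrack:
    """Parse a RepeatMasker ``.out`` stream into a :class:`RepeatTrack`.

    Header lines (anything before rows starting with a numeric score) are
    skipped.  Complement rows ('C') are normalised: strand becomes '-',
    and the consensus columns — which RepeatMasker stores in the order
    (repLeft) repEnd repStart for complement hits — are reordered so that
    ``rep_start <= rep_end`` always holds.  Genomic coordinates are
    converted from 1-based inclusive to 0-based half-open.

    An empty body yields an empty track.
    """
    if isinstance(source, (str, Path)) and "\n" in str(source):
        source = io.StringIO(str(source))
    copies: list[RepeatCopy] = []
    with _maybe_open(source) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            # header rows begin with 'SW'/'score'; body rows with a number
            try:
                score = float(fields[0])
            except ValueError:
                if copies:
                    raise RepeatParseError("non-numeric score in body", lineno)
                continue  # header
            if len(fields) < 14:
                raise RepeatParseError(
                    f"expected >=14 whitespace-separated columns, got {len(fields)}",
                    lineno,
                )
            try:
                div, dele, ins = (float(x) for x in fields[1:4])
                chrom = fields[4]
                qbegin = int(fields[5])
                qend = int(fields[6])
                orient = fields[8]
                family = fields[9]
                class_family = fields[10]
                c1 = _parse_paren(fields[11], lineno)
                c2 = _parse_paren(fields[12], lineno)
                c3 = _parse_paren(fields[13], lineno)
            except RepeatParseError:
                raise
            except (ValueError, IndexError) as exc:
                raise RepeatParseError(str(exc), lineno) from exc
            if orient == "+":
                strand, rep_start, rep_end, rep_left = "+", c1, c2, c3
            elif orient in ("C", "-"):
                # complement rows store (repLeft) repEnd repStart
                strand, rep_left, rep_end, rep_start = "-", c1, c2, c3
            else:
                raise RepeatParseError(f"unknown orientation {orient!r}", lineno)
            try:
                copies.append(
                    RepeatCopy(
                        chrom=chrom,
                        start=qbegin - 1,  # 1-based inclusive -> 0-based half-open
                        end=qend,
                        strand=strand,
                        family=family,
                        class_family=class_family,
                        rep_start=rep_start,
                        rep_end=rep_end,
                        rep_left=rep_left,
                        score=score,
                        divergence=div,
                        deletion=dele,
                        insertion=ins,
                    )
                )
            except ValueError as exc:
                raise RepeatParseError(str(exc), lineno) from exc
    return RepeatTrack(copies)


def write_repeatmasker_out(track: RepeatTrack, handle: IO[str] | str | Path) -> None:
    """Write a track in RepeatMasker ``.out`` layout (3 header lines, 1-based
    inclusive genomic coordinates, complement consensus-column order)."""
    with _maybe_open(handle, "w") as fh:
        fh.write(_OUT_HEADER)
        for i, c in enumerate(track, start=1):
            rs = c.rep_start if c.rep_start is not None else 1
            re_ = c.rep_end if c.rep_end is not None else c.length
            if c.strand == "+":
                orient, p1, p2, p3 = "+", str(rs), str(re_), f"({c.rep_left})"
            else:
                orient, p1, p2, p3 = "C", f"({c.rep_left})", str(re_), str(rs)
            fh.write(
                f"{c.score:7.0f} {c.divergence:5.1f} {c.deletion:4.1f} {c.insertion:4.1f}  "
                f"{c.chrom:<12s} {c.start + 1:>8d} {c.end:>8d} (0) "
                f"{orient} {c.family:<18s} {c.class_family:<18s} "
                f"{p1:>6s} {p2:>5s} {p3:>7s} {i:>6d}\n"
            )


def select_full_length(
    track: RepeatTrack,
    max_rep_start: int = MAX_REP_START,
    min_rep_end: int = MIN_REP_END,
) -> RepeatTrack:
    """Select full-length and nearly full-length copies by consensus footprint.

    A copy is retained iff ``rep_start < max_rep_start`` and
    ``rep_end > min_rep_end`` (both strict).  With the defaults (100, 1200)
    against a 1,300 bp consensus this keeps copies missing at most ~100 bp at
    either consensus end.

    Raises ``ValueError`` if any copy lacks consensus coordinates.
    """
    missing = [c for c in track if c.rep_start is None or c.rep_end is None]
    if missing:
        c = missing[0]
        raise ValueError(
            f"copy {c.family} at {c.chrom}:{c.start}-{c.end} lacks consensus "
            f"coordinates (repStart/repEnd) required for full-length selection"
        )
    return RepeatTrack(
        c for c in track if c.rep_start < max_rep_start and c.rep_end > min_rep_end
    )


def integrate_copies(base: RepeatTrack, new_copies: RepeatTrack) -> RepeatTrack:
    """Add ``new_copies`` to ``base``, discarding base annotations they overlap.

    Overlap means >= 1 shared genomic base, tested strand-agnostically.  Every
    new copy is kept; a base copy survives only if it overlaps none of the new
    copies.  The result is coordinate-sorted.
    """
    trees = new_copies.interval_trees()
    kept = [
        c
        for c in base
        if c.chrom not in trees or not trees[c.chrom].overlap(c.start, c.end)
    ]
    return RepeatTrack(list(new_copies) + kept)
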