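"""Ingest of aligned paired-end SAM records into fragment midpoints.

One record per proper pair is retained (the mate carrying the positive
template length), pairs are stratified into fragment-size classes defined
as a nominal length ± 20 %, and each retained fragment is reduced to its
midpoint coordinate.  Internal coordinates are 0-based; the 1-based SAM
convention is converted exactly once, here.

The reader is deliberately tolerant: a malformed record line is skipped
with a logged line number rather than aborting the run, because MNase-seq
SAM files in the wild frequently contain stray truncated lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

# SAM FLAG bits consulted here
_FLAG_UNMAPPED = 0x4
_FLAG_MATE_UNMAPPED = 0x8
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800


class SamFormatError(ValueError):
    """Fatal SAM-level problem (e.g. a record on a chromosome absent from the header)."""


@dataclass(frozen=True)
class AlignedPairRecord:
    """One mapped read pair: the mate with positive template length.

    Attributes
    ----------
    chrom : reference sequence name.
    pos : leftmost mapped position, 1-based (SAM POS).
    tlen : signed template length in bp (SAM TLEN/ISIZE); always > 0 for
        retained records.
    """

    chrom: str
    pos: int
    tlen: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (got {self.pos})")


@dataclass(frozen=True)
class SizeClassSpec:
    """A fragment-size class: nominal length ± a fractional tolerance.

    The mono-nucleosome class is 150 bp ± 20 %, i.e. inclusive bounds
    [120, 180] bp.  Bounds are rounded to the nearest integer bp.
    """

    nominal_bp: int
    tolerance_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.nominal_bp <= 0:
            raise ValueError("nominal_bp must be positive")
        if not 0.0 <= self.tolerance_fraction < 1.0:
            raise ValueError("tolerance_fraction must be in [0, 1)")
        if self.lower_bp <= 0:
            raise ValueError("size class lower bound must be positive")

    @property
    def half_width_bp(self) -> int:
        return round(self.tolerance_fraction * self.nominal_bp)

    @property
    def lower_bp(self) -> int:
        return self.nominal_bp - self.half_width_bp

    @property
    def upper_bp(self) -> int:
        return self.nominal_bp + self.half_width_bp

    def contains(self, tlen: int) -> bool:
        return self.lower_bp <= tlen <= self.upper_bp

    def __str__(self) -> str:  # e.g. "150±30bp"
        return f"{self.nominal_bp}±{self.half_width_bp}bp"


@dataclass(frozen=True)
class ParticleMidpoint:
    """Fragment midpoint of one chromatin particle (0-based bp)."""

    chrom: str
    coord: int
    size_class: SizeClassSpec | None = None

    def __post_init__(self) -> None:
        if self.coord < 0:
            raise ValueError(f"coord must be >= 0 (got {self.coord})")


@dataclass
class SamFile:
    """Result of reading a SAM stream: retained pair records plus header info."""

    records: list[AlignedPairRecord]
    chrom_lengths: dict[str, int]
    n_skipped: int = 0
    skipped_lines: list[int] = field(default_factory=list)


def _open_lines(source: str | Path | IO[str]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8", errors="replace") as fh:
            yield from fh
    else:
        yield from source


def read_sam(source: str | Path | IO[str]) -> SamFile:
    """Read a SAM stream, keeping one :class:`AlignedPairRecord` per proper pair.

    Retention rule: the record must be mapped with a mapped mate, be a
    primary (non-secondary, non-supplementary) alignment, and carry
    TLEN > 0 — so of the two mates of a pair exactly the left one is kept
    and single-end or degenerate (TLEN = 0) records are dropped.

    Records are returned grouped by chromosome in header order; input
    order is preserved within a chromosome.  A malformed record line is
    skipped (logged with its line number); a record naming a chromosome
    with no ``@SQ`` header line is fatal.
    """
    chrom_lengths: dict[str, int] = {}
    per_chrom: dict[str, list[AlignedPairRecord]] = {}
    n_skipped = 0
    skipped_lines: list[int] = []

    for lineno, line in enumerate(_open_lines(source), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("@"):
            if line.startswith("@SQ"):
                name = None
                length = None
                for tag in line.split("\t")[1:]:
                    if tag.startswith("SN:"):
                        name = tag[3:]
                    elif tag.startswith("LN:"):
                        length = int(tag[3:])
                if name is None or length is None:
                    raise SamFormatError(
                        f"line {lineno}: @SQ header missing SN or LN tag"
                    )
                chrom_lengths[name] = length
            continue

        fields = line.split("\t")
        if len(fields) < 11:
            n_skipped += 1
            skipped_lines.append(lineno)
            logger.warning("skipping malformed SAM line %d: fewer than 11 fields", lineno)
            continue
        try:
            flag = int(fields[1])
            pos = int(fields[3])
            tlen = int(fields[8])
        except ValueError:
            n_skipped += 1
            skipped_lines.append(lineno)
            logger.warning("skipping malformed SAM line %d: non-integer FLAG/POS/TLEN", lineno)
            continue
        rname = fields[2]

        if rname == "*" or flag & (
            _FLAG_UNMAPPED | _FLAG_MATE_UNMAPPED | _FLAG_SECONDARY | _FLAG_SUPPLEMENTARY
        ):
            continue
        if tlen <= 0:
            continue
        if rname not in chrom_lengths:
            raise SamFormatError(
                f"line {lineno}: record on chromosome {rname!r} with no @SQ header entry"
            )
        per_chrom.setdefault(rname, []).append(
            AlignedPairRecord(chrom=rname, pos=pos, tlen=tlen)
        )

    if n_skipped:
        logger.warning("skipped %d malformed SAM line(s)", n_skipped)

    records: list[AlignedPairRecord] = []
    for chrom in chrom_lengths:  # header order
        records.extend(per_chrom.get(chrom, []))
    return SamFile(
        records=records,
        chrom_lengths=chrom_lengths,
        n_skipped=n_skipped,
        skipped_lines=skipped_lines,
    )


def read_aligned_pairs(source: str | Path | IO[str]) -> list[AlignedPairRecord]:
    """Convenience wrapper around :func:`read_sam` returning only the records."""
    return read_sam(source).records


def fragment_midpoint(record: AlignedPairRecord) -> ParticleMidpoint:
    """Map a retained pair to its fragment midpoint (0-based).

    The midpoint is the 0-based leftmost coordinate plus ``floor(tlen/2)``.
    The sub-bin rounding choice is immaterial at 10-bp resolution but is
    fixed so results are exactly reproducible.
    """
    if record.tlen <= 0:
        raise ValueError(f"fragment_midpoint requires tlen > 0 (got {record.tlen})")
    return ParticleMidpoint(
        chrom=record.chrom, coord=(record.pos - 1) + record.tlen // 2
    )


def stratify(
    records: Iterable[AlignedPairRecord], spec: SizeClassSpec
) -> list[ParticleMidpoint]:
    """Retain pairs whose TLEN falls inside the size class (inclusive bounds)
    and reduce them to midpoints tagged with the class."""
    out: list[ParticleMidpoint] = []
    for rec in records:
        if spec.contains(rec.tlen):
            mid = fragment_midpoint(rec)
            out.append(
                ParticleMidpoint(chrom=mid.chrom, coord=mid.coord, size_class=spec)
            )
    return out


def write_midpoints(midpoints: Sequence[ParticleMidpoint], path: str | Path) -> None:
    """Write midpoints as 2-column TSV (chrom, 0-based coord)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for m in midpoints:
            fh.write(f"{m.chrom}\t{m.coord}\n")


def read_midpoints(path: str | Path) -> list[ParticleMidpoint]:
    """Read midpoints written by :func:`write_midpoints`."""
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            chrom, coord = line.split()
            out.append(ParticleMidpoint(chrom=chrom, coord=int(coord)))
    return out
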