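"""Minimal genomic interval algebra.

Coordinates are 1-based closed intervals throughout, mirroring the
conventions of the GRanges ecosystem: an interval covers every base from
``start`` to ``end`` inclusive, and two intervals on the same chromosome
overlap iff ``q.start <= s.end and s.start <= q.end``.  BED input (0-based
half-open) is converted on read.

Overlap search is a per-chromosome sort-and-sweep, adequate at the scale
this package targets and easy to audit against the all-pairs definition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import RegionParseError, ValidationError

_STRANDS = ("+", "-", "*")

_REGION_RE = re.compile(
    r"^(?P<seq>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)(?::(?P<strand>[+\-*]))?$"
)


@dataclass(frozen=True)
class GenomicRanges:
    """Parallel vectors of chromosome-anchored intervals.

    Parameters
    ----------
    seqnames : chromosome name per interval.
    starts, ends : 1-based inclusive bounds; ``starts >= 1`` and
        ``ends >= starts`` elementwise.
    strands : ``+``, ``-`` or ``*`` (unstranded) per interval.
    """

    seqnames: tuple[str, ...]
    starts: tuple[int, ...]
    ends: tuple[int, ...]
    strands: tuple[str, ...] = field(default=())

    def __post_init__(self):
        n = len(self.seqnames)
        strands = self.strands if self.strands else tuple("*" for _ in range(n))
        object.__setattr__(self, "strands", strands)
        if not (len(self.starts) == len(self.ends) == len(strands) == n):
            raise ValidationError(
                "seqnames/starts/ends/strands must be parallel vectors "
                f"(got lengths {n}, {len(self.starts)}, {len(self.ends)}, "
                f"{len(strands)})"
            )
        for i in range(n):
            if self.starts[i] < 1:
                raise ValidationError(
                    f"interval {i}: start {self.starts[i]} < 1 (coordinates are 1-based)"
                )
            if self.ends[i] < self.starts[i]:
                raise ValidationError(
                    f"interval {i}: end {self.ends[i]} < start {self.starts[i]}"
                )
            if strands[i] not in _STRANDS:
                raise ValidationError(
                    f"interval {i}: strand {strands[i]!r} not one of {_STRANDS}"
                )

    def __len__(self) -> int:
        return len(self.seqnames)

    def take(self, positions) -> "GenomicRanges":
        """Reorder/subset by 0-based positions (duplicates allowed)."""
        pos = [int(p) for p in positions]
        return GenomicRanges(
            seqnames=tuple(self.seqnames[p] for p in pos),
            starts=tuple(self.starts[p] for p in pos),
            ends=tuple(self.ends[p] for p in pos),
            strands=tuple(self.strands[p] for p in pos),
        )

    def __getitem__(self, i: int) -> tuple[str, int, int, str]:
        return (self.seqnames[i], self.starts[i], self.ends[i], self.strands[i])


def parse_region(text: str) -> GenomicRanges:
    """Parse ``"chr1:100-200"`` or ``"chr1:100-200:+"`` into a 1-interval set.

    The strand defaults to ``*``.  Raises :class:`RegionParseError` on
    malformed text or ``start > end``.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise RegionParseError(
            f"region {text!r} does not match 'seq:start-end[:strand]'"
        )
    start, end = int(m.group("start")), int(m.group("end"))
    if start < 1:
        raise RegionParseError(f"region {text!r}: start must be >= 1 (1-based)")
    if start > end:
        raise RegionParseError(f"region {text!r}: start {start} > end {end}")
    return GenomicRanges(
        (m.group("seq"),), (start,), (end,), (m.group("strand") or "*",)
    )


def read_bed(path) -> GenomicRanges:
    """Read intervals from a BED file (first 3 or 6 columns).

    BED is 0-based half-open; this converts to the internal 1-based closed
    convention (``start + 1``, ``end`` unchanged).
    """
    seqs, starts, ends, strands = [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise RegionParseError(f"BED line has fewer than 3 fields: {line!r}")
            seqs.append(parts[0])
            starts.append(int(parts[1]) + 1)
            ends.append(int(parts[2]))
            strands.append(parts[5] if len(parts) >= 6 and parts[5] in _STRANDS else "*")
    return GenomicRanges(tuple(seqs), tuple(starts), tuple(ends), tuple(strands))


def _strands_compatible(a: str, b: str) -> bool:
    return a == "*" or b == "*" or a == b


def find_overlaps(query: GenomicRanges, subject: GenomicRanges,
                  strand_aware: bool = False) -> list[tuple[int, int]]:
    """All (query_index, subject_index) pairs of overlapping intervals.

    A pair is reported iff the chromosome names match, the closed intervals
    intersect, and — when ``strand_aware`` — the strands are compatible
    (``*`` matches both).  Pairs are sorted by (query_index, subject_index).

    Sort-and-sweep per chromosome: both sides are sorted by start; for each
    query we advance past subjects that end before the query starts, then
    scan subjects until one starts beyond the query end.
    """
    by_chrom: dict[str, list[int]] = {}
    for j, name in enumerate(subject.seqnames):
        by_chrom.setdefault(name, []).append(j)
    for name in by_chrom:
        by_chrom[name].sort(key=lambda j: subject.starts[j])

    pairs: list[tuple[int, int]] = []
    for i in range(len(query)):
        subj_idx = by_chrom.get(query.seqnames[i])
        if not subj_idx:
            continue
        q_start, q_end, q_strand = query.starts[i], query.ends[i], query.strands[i]
        for j in subj_idx:
            if subject.starts[j] > q_end:
                break  # sorted by start: nothing further can overlap
            if subject.ends[j] < q_start:
                continue
            if strand_aware and not _strands_compatible(q_strand, subject.strands[j]):
                continue
            pairs.append((i, j))
    pairs.sort()
    return pairs


def overlaps_any(subject: GenomicRanges, query: GenomicRanges,
                 strand_aware: bool = False) -> np.ndarray:
    """Boolean mask over ``subject``: True where any query interval overlaps."""
    mask = np.zeros(len(subject), dtype=bool)
    for _, j in find_overlaps(query, subject, strand_aware=strand_aware):
        mask[j] = True
    return mask
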