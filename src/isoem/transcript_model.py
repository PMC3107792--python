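"""Transcript annotation model and genome/transcript coordinate mapping.

All coordinates are 0-based half-open. Transcript coordinates run 5'->3'
along the isoform strand; positions at or beyond the exonic length address
the appended poly(A) tail (if any).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: sentinel returned when an alignment cannot originate from an isoform
INCOMPATIBLE = None

Interval = tuple[int, int]


@dataclass(frozen=True)
class Isoform:
    """A known transcript isoform with its genome exon structure.

    ``exons`` are genome intervals, 0-based half-open, non-overlapping and
    sorted by genome coordinate. ``length`` includes the poly(A) tail.
    """

    id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[Interval, ...]
    polya_tail: int = 0
    adjusted_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.id}")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon [{s},{e}) in {self.id}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"exons overlap or touch in {self.id}")
            prev_end = e

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def length(self) -> int:
        """l(j): exonic length plus poly(A) tail."""
        return self.exonic_length + self.polya_tail

    @property
    def effective_annotated_length(self) -> int:
        """Length used for coverage normalization (repeat-adjusted if set)."""
        return self.adjusted_length if self.adjusted_length is not None else self.length

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def three_prime_terminal(self) -> int:
        """Genome coordinate of the base adjacent to the 3' end (exclusive bound
        on '+', inclusive-start bound on '-')."""
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    def _cum_offsets(self) -> list[int]:
        offs = [0]
        for s, e in self.exons:
            offs.append(offs[-1] + (e - s))
        return offs


@dataclass
class Transcriptome:
    """The set of known isoforms partitioned into gene clusters."""

    isoforms: list[Isoform]
    gene_clusters: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise ValueError("no transcripts")
        ids = [iso.id for iso in self.isoforms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate isoform ids")
        if not self.gene_clusters:
            self.gene_clusters = _cluster_by_gene(self.isoforms)
        self._by_id = {iso.id: iso for iso in self.isoforms}

    def __len__(self) -> int:
        return len(self.isoforms)

    def __contains__(self, iso_id: str) -> bool:
        return iso_id in self._by_id

    def __getitem__(self, iso_id: str) -> Isoform:
        return self._by_id[iso_id]

    @property
    def ids(self) -> list[str]:
        return [iso.id for iso in self.isoforms]

    def gene_of(self, iso_id: str) -> str:
        return self._by_id[iso_id].gene_id


def _cluster_by_gene(isoforms: Sequence[Isoform]) -> dict[str, list[str]]:
    clusters: dict[str, list[str]] = {}
    for iso in isoforms:
        clusters.setdefault(iso.gene_id, []).append(iso.id)
    return clusters


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, val = part.partition(" ")
            out[key] = val.strip().strip('"')
    return out


def load_annotation(
    annotation: str,
    gene_map: Mapping[str, str] | None = None,
) -> Transcriptome:
    """Load a transcriptome from a GTF file.

    Only ``exon`` features are used; each must carry ``transcript_id`` and
    ``gene_id`` attributes. Exons are sorted and merged per transcript.
    ``gene_map`` optionally remaps annotation gene ids to external cluster
    ids (e.g. expression-atlas gene clusters).

    Raises
    ------
    ValueError
        If the file contains no transcripts.
    """
    exons: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(annotation) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            chrom, _, _, start, end, _, strand, _, attr = fields[:9]
            attrs = _parse_gtf_attributes(attr)
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id", tid)
            if tid is None:
                continue
            exons.setdefault(tid, []).append((int(start) - 1, int(end)))
            meta[tid] = (gid, chrom, strand)

    isoforms = []
    for tid, blocks in exons.items():
        gid, chrom, strand = meta[tid]
        merged = merge_intervals(blocks)
        if not merged:
            logger.warning("transcript %s has zero exons; skipped", tid)
            continue
        if gene_map is not None:
            gid = gene_map.get(gid, gid)
        isoforms.append(
            Isoform(id=tid, gene_id=gid, chrom=chrom, strand=strand, exons=tuple(merged))
        )
    if not isoforms:
        raise ValueError("no transcripts")
    isoforms.sort(key=lambda iso: (iso.chrom, iso.start, iso.id))
    return Transcriptome(isoforms=isoforms)


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping or touching half-open intervals."""
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if e <= s:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def transcript_interval(
    isoform: Isoform,
    blocks: Sequence[Interval],
    tail: int = 0,
) -> Interval | None:
    """Map genome-space alignment blocks to a transcript-space interval.

    Returns the half-open transcript-coordinate interval covered iff every
    block base lies in exons of the isoform and inter-block gaps coincide
    exactly with complete introns; otherwise :data:`INCOMPATIBLE` (``None``).
    ``tail`` bases extend past the isoform's 3' end into the poly(A) tail;
    such an alignment is compatible only if its exonic part abuts the 3' end
    and the tail fits within ``isoform.polya_tail``.
    """
    if not blocks:
        raise ValueError("blocks must be non-empty")
    for i in range(1, len(blocks)):
        if blocks[i][0] < blocks[i - 1][1]:
            raise ValueError("blocks must be sorted and disjoint")

    exons = isoform.exons
    starts = [s for s, _ in exons]
    offs = isoform._cum_offsets()

    j = bisect_right(starts, blocks[0][0]) - 1
    if j < 0:
        return INCOMPATIBLE
    plus_start = offs[j] + blocks[0][0] - exons[j][0]
    for idx, (s, e) in enumerate(blocks):
        if idx > 0:
            # gap must be exactly one complete intron
            if blocks[idx - 1][1] != exons[j][1]:
                return INCOMPATIBLE
            j += 1
            if j >= len(exons) or s != exons[j][0]:
                return INCOMPATIBLE
        if s < exons[j][0] or e > exons[j][1]:
            return INCOMPATIBLE
    plus_end = offs[j] + blocks[-1][1] - exons[j][0]

    el = isoform.exonic_length
    if isoform.strand == "+":
        t_start, t_end = plus_start, plus_end
    else:
        t_start, t_end = el - plus_end, el - plus_start
    if tail:
        if t_end != el or tail > isoform.polya_tail:
            return INCOMPATIBLE
        t_end += tail
    return (t_start, t_end)


def genome_blocks(
    isoform: Isoform, t_start: int, t_end: int
) -> tuple[list[Interval], int]:
    """Inverse of :func:`transcript_interval`: project a transcript-space
    interval onto genome blocks.

    Returns ``(blocks, tail)`` where ``tail`` is the number of interval bases
    falling in the poly(A) tail (no genome coordinates).
    """
    if not (0 <= t_start < t_end <= isoform.length):
        raise ValueError("interval out of transcript bounds")
    el = isoform.exonic_length
    tail = max(0, t_end - el)
    t_end_ex = min(t_end, el)
    if t_start >= el:  # entirely inside the tail
        return [], t_end - t_start
    if isoform.strand == "+":
        p_start, p_end = t_start, t_end_ex
    else:
        p_start, p_end = el - t_end_ex, el - t_start
    offs = isoform._cum_offsets()
    blocks: list[Interval] = []
    for i, (s, e) in enumerate(isoform.exons):
        lo = max(p_start, offs[i])
        hi = min(p_end, offs[i + 1])
        if lo < hi:
            blocks.append((s + lo - offs[i], s + hi - offs[i]))
    return blocks, tail


def extend_poly_a(transcriptome: Transcriptome, tail: int) -> Transcriptome:
    """Return a transcriptome whose isoforms carry a poly(A) tail of ``tail``
    bases; transcript coordinates beyond the last exon are 'A' positions."""
    if tail < 0:
        raise ValueError("tail must be >= 0")
    if tail == 0:
        return transcriptome
    isoforms = [replace(iso, polya_tail=tail) for iso in transcriptome.isoforms]
    return Transcriptome(isoforms=isoforms, gene_clusters=dict(transcriptome.gene_clusters))


class RepeatMask:
    """Genome repeat intervals with fast per-chromosome overlap queries."""

    def __init__(self, intervals_by_chrom: Mapping[str, Iterable[Interval]]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, ivs in intervals_by_chrom.items():
            merged = merge_intervals(ivs)
            self._by_chrom[chrom] = ([s for s, _ in merged], [e for _, e in merged])

    @classmethod
    def from_bed(cls, path: str) -> "RepeatMask":
        by_chrom: dict[str, list[Interval]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                by_chrom.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
        return cls(by_chrom)

    def overlaps(self, chrom: str, blocks: Sequence[Interval]) -> bool:
        """True iff any base of any block overlaps a repeat."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        for s, e in blocks:
            i = bisect_right(starts, e - 1) - 1
            if i >= 0 and ends[i] > s:
                return True
        return False

    def overlapping_intervals(self, chrom: str, lo: int, hi: int) -> list[Interval]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends = entry
        out = []
        i = bisect_right(starts, lo) - 1
        i = max(i, 0)
        while i < len(starts) and starts[i] < hi:
            if ends[i] > lo:
                out.append((max(starts[i], lo), min(ends[i], hi)))
            i += 1
        return out


def apply_repeat_mask(
    transcriptome: Transcriptome, repeats: RepeatMask, read_len: int
) -> Transcriptome:
    """Adjust isoform lengths for repeat masking.

    The adjusted length of isoform j is l(j) minus the number of transcript
    start positions s such that a read of ``read_len`` starting at s would
    overlap a repeat (such reads are discarded upstream). Returns a new
    transcriptome with ``adjusted_length`` set; pair it with
    ``repeats.overlaps`` as the read-discard predicate.
    """
    isoforms = []
    for iso in transcriptome.isoforms:
        masked = _masked_start_positions(iso, repeats, read_len)
        isoforms.append(replace(iso, adjusted_length=iso.length - masked))
    return Transcriptome(isoforms=isoforms, gene_clusters=dict(transcriptome.gene_clusters))


def _masked_start_positions(iso: Isoform, repeats: RepeatMask, read_len: int) -> int:
    l = iso.length
    if read_len > l:
        return 0
    # project repeat overlaps into transcript coordinates
    offs = iso._cum_offsets()
    el = iso.exonic_length
    t_repeats: list[Interval] = []
    for i, (s, e) in enumerate(iso.exons):
        for rs, re_ in repeats.overlapping_intervals(iso.chrom, s, e):
            p_lo = offs[i] + rs - s
            p_hi = offs[i] + re_ - s
            if iso.strand == "+":
                t_repeats.append((p_lo, p_hi))
            else:
                t_repeats.append((el - p_hi, el - p_lo))
    if not t_repeats:
        return 0
    # start positions s in [0, l - read_len] whose window [s, s+read_len)
    # hits any repeat base
    masked = merge_intervals(
        (max(0, lo - read_len + 1), min(l - read_len + 1, hi)) for lo, hi in t_repeats
    )
    return sum(e - s for s, e in masked)
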