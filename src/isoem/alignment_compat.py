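"""Read-isoform compatibility weights w_{r,j} = sum_a Q_a * F_a * O_a.

Alignments are parsed from SAM/BAM (against transcript sequences or the
genome), expressed in genome space, and matched to candidate isoforms with a
coordinate-sorted line sweep. For each read r and isoform j the weight sums,
over the read's alignments compatible with j, the product of the base-quality
term Q_a, the fragment-length term F_a and the orientation term O_a.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

from isoem.fragment_model import FragmentLengthDist
from isoem.transcript_model import (
    INCOMPATIBLE,
    Interval,
    Isoform,
    Transcriptome,
    genome_blocks,
    transcript_interval,
)

logger = logging.getLogger(__name__)

EPS_FLOOR = 1e-4
EPS_CAP = 0.75
DEFAULT_PHRED = 30

_ALLOWED_CIGAR_OPS = {0, 7, 8}  # M, =, X — ungapped alignments only


@dataclass(frozen=True, slots=True)
class MateAln:
    """One mate's alignment: exonic genome blocks plus optional poly(A)
    overhang. ``strand`` is the genome strand the mate aligned to. For
    alignments entirely inside a poly(A) tail, ``blocks`` is empty and
    ``anchor`` holds the genome coordinate of the source isoform's 3'
    terminus (tails have no genome coordinates of their own)."""

    blocks: tuple[Interval, ...]
    strand: str
    tail: int = 0
    tail_offset: int = 0
    anchor: int | None = None

    @property
    def start(self) -> int:
        return self.blocks[0][0] if self.blocks else self.anchor  # type: ignore[return-value]

    @property
    def span_end(self) -> int:
        return self.blocks[-1][1] if self.blocks else self.anchor  # type: ignore[return-value]


@dataclass(frozen=True, slots=True)
class Alignment:
    """One candidate origin of a read or pair: mates in mate order plus the
    precomputed base-quality probability Q_a."""

    chrom: str
    mates: tuple[MateAln, ...]
    q: float

    @property
    def start(self) -> int:
        return min(m.start for m in self.mates)


@dataclass(slots=True)
class AlignmentGroup:
    """All genome-space alignments of one read (or read pair)."""

    read_id: str
    alignments: list[Alignment]
    paired: bool = False
    hexamer: str | None = None  # first six bases of the (first) mate


@dataclass(slots=True)
class WeightedCompatibility:
    """Sparse weight vector of one read over the isoforms it may come from."""

    read_id: str
    entries: list[tuple[str, float]]


@dataclass
class ParseStats:
    mapped_groups: int = 0
    unmapped_records: int = 0
    rejected_records: int = 0  # gapped/clipped alignments
    repeat_discarded: int = 0


def alignment_base_prob(match: Sequence[bool], eps: Sequence[float]) -> float:
    """Q_a: product over aligned bases of (1 - eps_k) for matches and eps_k
    for mismatches. For pairs, concatenate both mates' bases."""
    q = 1.0
    for m, e in zip(match, eps):
        q *= (1.0 - e) if m else e
    return q


def phred_to_eps(qual: Sequence[int] | None, n: int) -> list[float]:
    """Per-base error probabilities from Phred scores, clamped to
    [1e-4, 0.75]; missing qualities default to Phred 30."""
    if qual is None:
        return [10.0 ** (-DEFAULT_PHRED / 10.0)] * n
    return [min(EPS_CAP, max(EPS_FLOOR, 10.0 ** (-q / 10.0))) for q in qual]


def orientation_factor(
    alignment: Alignment,
    isoform: Isoform,
    paired: bool,
    directional: bool,
    t_intervals: Sequence[Interval] | None = None,
) -> int:
    """O_a: 1 iff the alignment's orientation is consistent with isoform j.

    Single-end nondirectional reads come off either fragment end, so O_a is
    always 1; directional single reads must match the isoform strand. Paired
    mates must lie on opposite strands and point to each other (the 5'-most
    mate in transcript coordinates is the sense one); directional protocols
    additionally require the first mate to be sense.
    """
    if not paired:
        if not directional:
            return 1
        return 1 if alignment.mates[0].strand == isoform.strand else 0
    m1, m2 = alignment.mates
    if m1.strand == m2.strand:
        return 0
    sense_idx = 0 if m1.strand == isoform.strand else 1
    if directional and sense_idx != 0:
        return 0
    if t_intervals is None:
        t_intervals = []
        for m in alignment.mates:
            ti = _mate_interval(m, isoform)
            if ti is INCOMPATIBLE:
                return 0
            t_intervals.append(ti)
    sense, anti = t_intervals[sense_idx], t_intervals[1 - sense_idx]
    # mates point to each other: sense mate is 5'-most, fragment end at the
    # antisense mate's 3' end
    if sense[0] > anti[0] or sense[1] > anti[1]:
        return 0
    return 1


def single_end_length_bound(t_interval: Interval, mate_sense: bool, l: int) -> int:
    """u: upper bound on the fragment length implied by a single-end
    alignment occupying ``t_interval`` of an isoform of length ``l``. Sense
    reads count from the read's 5' end to the isoform 3' end; antisense
    reads to the isoform 5' end (both inclusive of the read's 5' base)."""
    if mate_sense:
        return l - t_interval[0]
    return t_interval[1]


def fragment_factor_single(dist: FragmentLengthDist, u: int) -> float:
    """F_a for single reads: probability of a fragment of u bases or fewer."""
    return dist.cdf(u)


def fragment_factor_paired(dist: FragmentLengthDist, k: int) -> float:
    """F_a for pairs: p(k) for the implied fragment length k."""
    return dist.p(k)


def _mate_interval(mate: MateAln, isoform: Isoform) -> Interval | None:
    """Transcript-space interval of one mate, handling poly(A) overhangs."""
    if not mate.blocks:
        # alignment entirely inside a poly(A) tail: compatible with any
        # isoform whose 3' terminus matches the anchor and whose tail is
        # long enough
        if isoform.polya_tail <= 0 or mate.anchor != isoform.three_prime_terminal:
            return INCOMPATIBLE
        if mate.tail_offset + mate.tail > isoform.polya_tail:
            return INCOMPATIBLE
        el = isoform.exonic_length
        return (el + mate.tail_offset, el + mate.tail_offset + mate.tail)
    return transcript_interval(isoform, mate.blocks, tail=mate.tail)


def weight_term(
    alignment: Alignment,
    isoform: Isoform,
    dist: FragmentLengthDist,
    directional: bool = False,
) -> float:
    """Q_a * F_a * O_a for one alignment against one isoform (0 if the
    alignment is not compatible with the isoform)."""
    paired = len(alignment.mates) == 2
    t_intervals = []
    for m in alignment.mates:
        ti = _mate_interval(m, isoform)
        if ti is INCOMPATIBLE:
            return 0.0
        t_intervals.append(ti)
    o = orientation_factor(alignment, isoform, paired, directional, t_intervals)
    if o == 0:
        return 0.0
    if paired:
        k = max(t[1] for t in t_intervals) - min(t[0] for t in t_intervals)
        f = fragment_factor_paired(dist, k)
    else:
        mate_sense = alignment.mates[0].strand == isoform.strand
        u = single_end_length_bound(t_intervals[0], mate_sense, isoform.length)
        f = fragment_factor_single(dist, u)
    return alignment.q * f


# ---------------------------------------------------------------------------
# SAM/BAM parsing
# ---------------------------------------------------------------------------


def _record_match_eps(
    rec: pysam.AlignedSegment, ref_seq: str | None
) -> tuple[list[bool], list[float]]:
    seq = rec.query_sequence
    n = len(seq) if seq else (rec.query_length or 0)
    eps = phred_to_eps(rec.query_qualities, n)
    if seq is None or ref_seq is None:
        return [True] * n, eps
    ref = ref_seq.upper()
    qry = seq.upper()
    if qry == ref:
        return [True] * n, eps
    match = [a == b for a, b in zip(qry, ref)]
    match += [True] * (n - len(match))
    return match, eps


def _transcript_ref_segment(seq: str | None, iso: Isoform, start: int, end: int) -> str | None:
    """Reference bases for a transcript-space alignment; positions beyond the
    stored sequence (poly(A) tail) read as 'A'."""
    if seq is None:
        return None
    core = seq[start:end]
    if len(core) < end - start:
        core += "A" * (end - start - len(core))
    return core


def parse_alignments(
    alignment_file: str,
    transcriptome: Transcriptome,
    transcript_seqs: Mapping[str, str] | None = None,
    stats: ParseStats | None = None,
) -> list[AlignmentGroup]:
    """Parse SAM/BAM into genome-space alignment groups.

    References naming isoforms are treated as transcript-space and converted
    to genome blocks through the annotation; other references are taken as
    genome chromosomes (with pre-spliced blocks from the CIGAR). Alignments
    of one read that are identical in genome space are merged. Gapped or
    clipped records are rejected; unmapped records are dropped and counted.
    """
    if stats is None:
        stats = ParseStats()
    per_read: dict[str, dict] = {}
    known_chroms = {iso.chrom for iso in transcriptome.isoforms}

    with pysam.AlignmentFile(alignment_file, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name is None:
                stats.unmapped_records += 1
                continue
            if rec.reference_name not in transcriptome and rec.reference_name not in known_chroms:
                raise ValueError(
                    f"alignment reference {rec.reference_name!r} matches neither a "
                    "transcript nor a chromosome of the annotation"
                )
            if rec.cigartuples is None or any(
                op not in _ALLOWED_CIGAR_OPS for op, _ in rec.cigartuples
            ):
                stats.rejected_records += 1
                continue
            ref = rec.reference_name
            entry = per_read.setdefault(
                rec.query_name, {"mates": {1: [], 2: []}, "paired": rec.is_paired, "hex": None}
            )
            mate_no = 2 if (rec.is_paired and rec.is_read2) else 1
            if entry["hex"] is None and mate_no == 1 and rec.query_sequence:
                s = rec.query_sequence
                entry["hex"] = s[:6] if not rec.is_reverse else _revcomp(s)[:6]

            aln_start = rec.reference_start
            aln_end = rec.reference_end
            if ref in transcriptome:
                iso = transcriptome[ref]
                ref_seq = None
                if transcript_seqs is not None and ref in transcript_seqs:
                    ref_seq = _transcript_ref_segment(
                        transcript_seqs[ref], iso, aln_start, aln_end
                    )
                match, eps = _record_match_eps(rec, ref_seq)
                if aln_end > iso.length:
                    stats.rejected_records += 1
                    continue
                blocks, tail = genome_blocks(iso, aln_start, aln_end)
                tail_offset = max(0, aln_start - iso.exonic_length)
                anchor = iso.three_prime_terminal if not blocks else None
                # reverse flag is relative to the transcript: forward means sense
                strand = iso.strand if not rec.is_reverse else _flip(iso.strand)
                chrom = iso.chrom
            else:
                match, eps = _record_match_eps(
                    rec,
                    rec.get_reference_sequence() if rec.has_tag("MD") else None,
                )
                blocks = tuple(rec.get_blocks())
                tail, tail_offset, anchor = 0, 0, None
                strand = "-" if rec.is_reverse else "+"
                chrom = ref
            q = alignment_base_prob(match, eps)
            entry["mates"][mate_no].append(
                (
                    chrom,
                    MateAln(tuple(blocks), strand, tail, tail_offset, anchor),
                    q,
                    (ref, rec.reference_start),
                    (rec.next_reference_name, rec.next_reference_start)
                    if rec.is_paired and rec.next_reference_start >= 0
                    else None,
                )
            )

    groups: list[AlignmentGroup] = []
    for read_id, entry in per_read.items():
        alns = _assemble_alignments(entry)
        if not alns:
            continue
        groups.append(
            AlignmentGroup(
                read_id=read_id,
                alignments=alns,
                paired=entry["paired"],
                hexamer=entry["hex"],
            )
        )
        stats.mapped_groups += 1
    if not groups:
        logger.warning("no mapped reads in input")
    return groups


def _assemble_alignments(entry: dict) -> list[Alignment]:
    """Pair mates and deduplicate alignments identical in genome space."""
    alns: list[Alignment] = []
    if not entry["paired"]:
        for chrom, mate, q, _start, _pnext in entry["mates"][1]:
            alns.append(Alignment(chrom=chrom, mates=(mate,), q=q))
    else:
        m2_pool = list(entry["mates"][2])
        for chrom, mate1, q1, _loc1, pnext1 in entry["mates"][1]:
            best = None
            for i, (chrom2, _mate2, _q2, loc2, _pnext2) in enumerate(m2_pool):
                if chrom2 != chrom:
                    continue
                if pnext1 is not None and loc2 != pnext1:
                    continue
                best = i
                break
            if best is None:
                continue
            _, mate2, q2, _, _ = m2_pool.pop(best)
            alns.append(Alignment(chrom=chrom, mates=(mate1, mate2), q=q1 * q2))
    seen: set = set()
    unique = []
    for a in alns:
        key = (
            a.chrom,
            tuple((m.blocks, m.strand, m.tail, m.tail_offset, m.anchor) for m in a.mates),
        )
        if key in seen:
            continue
        seen.add(key)
        unique.append(a)
    return unique


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


# ---------------------------------------------------------------------------
# Line sweep
# ---------------------------------------------------------------------------


def compute_weights(
    groups: Iterable[AlignmentGroup],
    transcriptome: Transcriptome,
    dist: FragmentLengthDist,
    directional: bool = False,
    discard: "callable | None" = None,
) -> tuple[list[WeightedCompatibility], int]:
    """Weights w_{r,j} for every read via a coordinate-sorted line sweep.

    Isoform genome spans and alignment start points are swept per chromosome;
    each alignment is tested against the isoforms active at its start point.
    ``discard`` is an optional predicate (chrom, blocks) -> bool marking reads
    to drop (repeat masking). Returns the weight vectors of reads with at
    least one positive-weight isoform, plus the number of dropped reads.
    """
    groups = list(groups)
    weights: list[dict[str, float]] = [dict() for _ in groups]
    discarded = [False] * len(groups)

    # bucket isoforms and alignment queries by chromosome
    iso_by_chrom: dict[str, list[Isoform]] = {}
    tail_anchors: dict[tuple[str, int], list[Isoform]] = {}
    for iso in transcriptome.isoforms:
        iso_by_chrom.setdefault(iso.chrom, []).append(iso)
        if iso.polya_tail > 0:
            tail_anchors.setdefault((iso.chrom, iso.three_prime_terminal), []).append(iso)

    queries: dict[str, list[tuple[int, int, Alignment]]] = {}
    for gi, group in enumerate(groups):
        for aln in group.alignments:
            if discard is not None:
                all_blocks = [b for m in aln.mates for b in m.blocks]
                if all_blocks and discard(aln.chrom, all_blocks):
                    discarded[gi] = True
                    continue
            if all(not m.blocks for m in aln.mates):
                # pure poly(A) alignment: resolve by 3'-terminus anchor
                for iso in tail_anchors.get((aln.chrom, aln.mates[0].anchor), []):
                    _accumulate(weights[gi], aln, iso, dist, directional)
                continue
            queries.setdefault(aln.chrom, []).append((aln.start, gi, aln))

    for chrom, chrom_queries in queries.items():
        isoforms = iso_by_chrom.get(chrom, [])
        events: list[tuple[int, int, object]] = []
        for iso in isoforms:
            events.append((iso.start, 1, iso))
            events.append((iso.end, 0, iso))
        for start, gi, aln in chrom_queries:
            events.append((start, 2, (gi, aln)))
        events.sort(key=lambda ev: (ev[0], ev[1]))
        active: dict[str, Isoform] = {}
        for _pos, kind, payload in events:
            if kind == 1:
                active[payload.id] = payload  # type: ignore[union-attr]
            elif kind == 0:
                active.pop(payload.id, None)  # type: ignore[union-attr]
            else:
                gi, aln = payload  # type: ignore[misc]
                for iso in active.values():
                    _accumulate(weights[gi], aln, iso, dist, directional)

    out: list[WeightedCompatibility] = []
    dropped = 0
    for gi, group in enumerate(groups):
        entries = [(j, w) for j, w in weights[gi].items() if w > 0.0]
        if not entries or discarded[gi]:
            dropped += 1
            continue
        entries.sort()
        out.append(WeightedCompatibility(read_id=group.read_id, entries=entries))
    return out, dropped


def _accumulate(
    acc: dict[str, float],
    aln: Alignment,
    iso: Isoform,
    dist: FragmentLengthDist,
    directional: bool,
) -> None:
    term = weight_term(aln, iso, dist, directional)
    if term > 0.0:
        acc[iso.id] = acc.get(iso.id, 0.0) + term


def compute_weights_bruteforce(
    groups: Iterable[AlignmentGroup],
    transcriptome: Transcriptome,
    dist: FragmentLengthDist,
    directional: bool = False,
) -> tuple[list[WeightedCompatibility], int]:
    """All-pairs reference implementation of :func:`compute_weights` (no
    sweep, no discard predicate); used as a correctness oracle."""
    out: list[WeightedCompatibility] = []
    dropped = 0
    for group in groups:
        acc: dict[str, float] = {}
        for aln in group.alignments:
            for iso in transcriptome.isoforms:
                if iso.chrom != aln.chrom:
                    continue
                _accumulate(acc, aln, iso, dist, directional)
        entries = sorted((j, w) for j, w in acc.items() if w > 0.0)
        if not entries:
            dropped += 1
            continue
        out.append(WeightedCompatibility(read_id=group.read_id, entries=entries))
    return out, dropped
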