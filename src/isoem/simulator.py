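"""Synthetic transcriptomes, true expression vectors and simulated reads.

Transcripts are built as genes with shared exons and alternative exon
inclusion, so isoforms genuinely overlap and reads are ambiguous. True
isoform frequencies combine per-gene abundances with a uniform or truncated
geometric (ratio 1/2) within-gene split. Fragments are sampled jointly over
(isoform, length) in proportion to f(j) * p(k) * (l(j) - k + 1) — the
expected-count model the quantifier assumes — with uniform start positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from isoem.fragment_model import FragmentLengthDist
from isoem.transcript_model import Isoform, Transcriptome

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class SyntheticTranscriptome:
    transcriptome: Transcriptome
    sequences: dict[str, str]  # transcript id -> sequence (5'->3', no tail)

    def write_gtf(self, path: str) -> None:
        with open(path, "w") as fh:
            for iso in self.transcriptome.isoforms:
                for s, e in iso.exons:
                    attrs = f'gene_id "{iso.gene_id}"; transcript_id "{iso.id}";'
                    fh.write(
                        f"{iso.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{iso.strand}\t.\t{attrs}\n"
                    )

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for iso in self.transcriptome.isoforms:
                fh.write(f">{iso.id}\n")
                seq = self.sequences[iso.id]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


def simulate_transcriptome(
    n_genes: int,
    max_isoforms: int = 5,
    seed: int = 0,
    exon_count_range: tuple[int, int] = (4, 10),
    exon_len_range: tuple[int, int] = (100, 400),
    intron_len_range: tuple[int, int] = (100, 800),
    min_isoform_length: int = 400,
) -> SyntheticTranscriptome:
    """Random multi-isoform genes on one synthetic chromosome.

    Each gene's first isoform uses all exons; additional isoforms drop random
    internal exons, so isoforms of a gene overlap and share sequence. The
    number of isoforms per gene is uniform on 1..max_isoforms. Deterministic
    for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    isoforms: list[Isoform] = []
    sequences: dict[str, str] = {}
    chrom = "chrS"
    cursor = 1000
    for g in range(n_genes):
        gene_id = f"G{g:05d}"
        n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons: list[tuple[int, int]] = []
        pos = cursor
        for _ in range(n_exons):
            ln = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
            exons.append((pos, pos + ln))
            pos += ln + int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
        gene_start, gene_end = exons[0][0], exons[-1][1]
        gene_seq = "".join(
            _BASES[rng.integers(0, 4, size=gene_end - gene_start)].astype("U1")
        )

        k = int(rng.integers(1, max_isoforms + 1))
        chosen: list[tuple[tuple[int, int], ...]] = [tuple(exons)]
        attempts = 0
        while len(chosen) < k and attempts < 50 * k:
            attempts += 1
            if n_exons <= 2:
                break
            keep = [True] * n_exons
            for i in range(1, n_exons - 1):
                keep[i] = rng.random() >= 0.4
            if all(keep):
                keep[int(rng.integers(1, n_exons - 1))] = False
            subset = tuple(ex for ex, kp in zip(exons, keep) if kp)
            if subset in chosen:
                continue
            if sum(e - s for s, e in subset) < min_isoform_length:
                continue
            chosen.append(subset)

        for t, subset in enumerate(chosen):
            tid = f"{gene_id}.T{t + 1}"
            iso = Isoform(id=tid, gene_id=gene_id, chrom=chrom, strand=strand, exons=subset)
            seq = "".join(gene_seq[s - gene_start : e - gene_start] for s, e in subset)
            if strand == "-":
                seq = _revcomp(seq)
            isoforms.append(iso)
            sequences[tid] = seq
        cursor = gene_end + 5000
    tr = Transcriptome(isoforms=isoforms)
    return SyntheticTranscriptome(transcriptome=tr, sequences=sequences)


def assign_true_frequencies(
    transcriptome: Transcriptome,
    mode: str = "geometric",
    gene_abundances: Mapping[str, float] | None = None,
    seed: int = 0,
    lognormal_sigma: float = 1.5,
) -> pd.DataFrame:
    """Truth table with one row per isoform.

    Within a k-isoform gene the split is uniform (p(j) = 1/k) or truncated
    geometric with ratio 1/2 (p(j) = 1/2^j for j < k, p(k) = 1/2^(k-1));
    which isoform gets which rank is randomized by ``seed``. Gene abundances
    default to a log-normal draw and are normalized so true frequencies sum
    to 1. Columns: isoform_id, gene_id, gene_abundance, isoform_prob,
    true_freq.
    """
    if mode not in ("uniform", "geometric"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    genes = sorted(transcriptome.gene_clusters)
    if gene_abundances is None:
        draws = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=len(genes))
        gene_abundances = dict(zip(genes, draws))
    else:
        if any(v <= 0 for v in gene_abundances.values()):
            raise ValueError("gene abundances must be positive")
    total_a = sum(gene_abundances[g] for g in genes)

    rows = []
    for g in genes:
        members = list(transcriptome.gene_clusters[g])
        k = len(members)
        if mode == "uniform":
            probs = [1.0 / k] * k
        else:
            probs = [1.0 / 2**j for j in range(1, k)] + [1.0 / 2 ** (k - 1)]
        order = rng.permutation(k)
        a = gene_abundances[g] / total_a
        for rank, mi in enumerate(order):
            rows.append(
                {
                    "isoform_id": members[mi],
                    "gene_id": g,
                    "gene_abundance": a,
                    "isoform_prob": probs[rank],
                    "true_freq": a * probs[rank],
                }
            )
    df = pd.DataFrame(rows).sort_values("isoform_id", ignore_index=True)
    return df


@dataclass
class ReadSet:
    """Simulated reads plus provenance."""

    reads: list[tuple[str, str, str]]  # (read_id, sequence, quality) mate 1
    mates: list[tuple[str, str, str]] | None  # mate 2 when paired
    origin: pd.DataFrame  # read_id, isoform_id, t_start, frag_len, sense
    sam_records: list[str]
    sam_header: list[str]

    def write_fastq(self, path: str, mate_path: str | None = None) -> None:
        with open(path, "w") as fh:
            for rid, seq, qual in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        if self.mates is not None:
            if mate_path is None:
                raise ValueError("paired reads need a second FASTQ path")
            with open(mate_path, "w") as fh:
                for rid, seq, qual in self.mates:
                    fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")

    def write_sam(self, path: str) -> None:
        """True alignments against the transcript library (align-free mode)."""
        with open(path, "w") as fh:
            fh.write("\n".join(self.sam_header) + "\n")
            fh.write("\n".join(self.sam_records) + "\n")


def simulate_reads(
    synthetic: SyntheticTranscriptome,
    truth: pd.DataFrame,
    n_reads: int,
    read_len: int,
    dist: FragmentLengthDist,
    paired: bool = False,
    directional: bool = False,
    error_rate: float = 0.001,
    polya: int = 0,
    seed: int = 0,
) -> ReadSet:
    """Sample fragments and emit reads with substitution errors.

    The (isoform, fragment length) pair is drawn with probability
    proportional to f(j) * p(k) * max(l(j) - k + 1, 0), then the start is
    uniform among valid positions. Single-end nondirectional reads come off a
    random fragment end. Also records the true transcript-space alignment of
    every read as SAM lines.
    """
    if read_len > dist.k_min:
        raise ValueError("read length exceeds minimum fragment length")
    rng = np.random.default_rng(seed)
    tr = synthetic.transcriptome
    iso_ids = truth["isoform_id"].tolist()
    f = truth["true_freq"].to_numpy(dtype=float)
    seqs = {i: synthetic.sequences[i] + "A" * polya for i in iso_ids}
    lengths = np.array([len(seqs[i]) for i in iso_ids])

    # joint law over (isoform, fragment length)
    ks = dist.lengths
    valid = np.maximum(lengths[:, None] - ks[None, :] + 1, 0).astype(float)
    joint = f[:, None] * dist.pmf[None, :] * valid
    flat = joint.ravel()
    total = flat.sum()
    if total <= 0:
        raise ValueError("no isoform can produce a fragment under this distribution")
    cum = np.cumsum(flat / total)
    picks = np.searchsorted(cum, rng.random(n_reads), side="right")
    iso_idx = picks // len(ks)
    frag_len = ks[picks % len(ks)]
    starts = np.floor(
        rng.random(n_reads) * (lengths[iso_idx] - frag_len + 1)
    ).astype(int)

    phred = max(2, min(41, int(round(-10 * np.log10(max(error_rate, 1e-9))))))
    qual = chr(33 + phred) * read_len
    n_err1 = rng.binomial(read_len, error_rate, size=n_reads)
    n_err2 = rng.binomial(read_len, error_rate, size=n_reads) if paired else None
    if paired:
        sense_first = (
            np.ones(n_reads, dtype=bool)
            if directional
            else rng.random(n_reads) < 0.5
        )
    else:
        sense_read = (
            np.ones(n_reads, dtype=bool)
            if directional
            else rng.random(n_reads) < 0.5
        )

    reads: list[tuple[str, str, str]] = []
    mates: list[tuple[str, str, str]] | None = [] if paired else None
    origin_rows = []
    sam: list[str] = []

    def mutate(seq: str, n_err: int) -> str:
        if n_err == 0:
            return seq
        pos = rng.choice(read_len, size=min(n_err, read_len), replace=False)
        chars = list(seq)
        for p in pos:
            alt = "ACGT".replace(chars[p], "") or "ACGT"
            chars[p] = alt[int(rng.integers(0, len(alt)))]
        return "".join(chars)

    for i in range(n_reads):
        iso = iso_ids[iso_idx[i]]
        t0 = int(starts[i])
        k = int(frag_len[i])
        fragment = seqs[iso][t0 : t0 + k]
        rid = f"r{i:07d}"
        if paired:
            m1_sense = bool(sense_first[i])
            sense_seq = mutate(fragment[:read_len], int(n_err1[i]))
            anti_seq = mutate(_revcomp(fragment[-read_len:]), int(n_err2[i]))  # type: ignore[index]
            if m1_sense:
                s1, s2 = sense_seq, anti_seq
            else:
                s1, s2 = anti_seq, sense_seq
            reads.append((rid, s1, qual))
            mates.append((rid, s2, qual))  # type: ignore[union-attr]
            origin_rows.append((rid, iso, t0, k, m1_sense))
            p_sense = t0 + 1
            p_anti = t0 + k - read_len + 1
            flag_sense = 0x1 | 0x2 | 0x20 | (0x40 if m1_sense else 0x80)
            flag_anti = 0x1 | 0x2 | 0x10 | (0x80 if m1_sense else 0x40)
            sam.append(
                f"{rid}\t{flag_sense}\t{iso}\t{p_sense}\t60\t{read_len}M\t=\t{p_anti}\t{k}\t{sense_seq}\t{qual}"
            )
            sam.append(
                f"{rid}\t{flag_anti}\t{iso}\t{p_anti}\t60\t{read_len}M\t=\t{p_sense}\t{-k}\t{_revcomp(anti_seq)}\t{qual}"
            )
        else:
            sense = bool(sense_read[i])
            if sense:
                seq = mutate(fragment[:read_len], int(n_err1[i]))
                pos = t0 + 1
                flag = 0
                sam_seq = seq
            else:
                seq = mutate(_revcomp(fragment[-read_len:]), int(n_err1[i]))
                pos = t0 + k - read_len + 1
                flag = 0x10
                sam_seq = _revcomp(seq)
            reads.append((rid, seq, qual))
            origin_rows.append((rid, iso, t0, k, sense))
            sam.append(
                f"{rid}\t{flag}\t{iso}\t{pos}\t60\t{read_len}M\t*\t0\t0\t{sam_seq}\t{qual}"
            )

    header = ["@HD\tVN:1.6\tSO:unsorted"] + [
        f"@SQ\tSN:{i}\tLN:{len(seqs[i])}" for i in iso_ids
    ]
    origin = pd.DataFrame(
        origin_rows, columns=["read_id", "isoform_id", "t_start", "frag_len", "mate1_sense"]
    )
    return ReadSet(reads=reads, mates=mates, origin=origin, sam_records=sam, sam_header=header)
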