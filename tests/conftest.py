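"""Shared fixtures and random-instance generators."""

from __future__ import annotations

import numpy as np
import pytest

from isoem.em_core import ComponentProblem
from isoem.read_classes import ReadClass, canonical_signature
from isoem.transcript_model import Isoform, Transcriptome


@pytest.fixture
def two_exon_isoform() -> Isoform:
    return Isoform(
        id="T1", gene_id="G1", chrom="chr1", strand="+", exons=((100, 200), (300, 400))
    )


@pytest.fixture
def two_exon_minus(two_exon_isoform) -> Isoform:
    return Isoform(
        id="T1m", gene_id="G1", chrom="chr1", strand="-", exons=two_exon_isoform.exons
    )


def random_isoform(rng: np.random.Generator, iso_id: str = "T", gene_id: str = "G") -> Isoform:
    n_exons = int(rng.integers(1, 6))
    pos = int(rng.integers(0, 1000))
    exons = []
    for _ in range(n_exons):
        ln = int(rng.integers(20, 300))
        exons.append((pos, pos + ln))
        pos += ln + int(rng.integers(10, 500))
    strand = "+" if rng.random() < 0.5 else "-"
    return Isoform(id=iso_id, gene_id=gene_id, chrom="chr1", strand=strand, exons=tuple(exons))


def random_component_problem(
    rng: np.random.Generator, max_isoforms: int = 3, max_reads: int = 200
) -> ComponentProblem:
    """A random connected EM problem with unit-free weights in (0, 1]."""
    k = int(rng.integers(1, max_isoforms + 1))
    isoforms = [f"I{i}" for i in range(k)]
    lengths = rng.uniform(200.0, 2000.0, size=k)
    n_reads = int(rng.integers(k, max_reads + 1))
    classes: dict = {}
    for _ in range(n_reads):
        size = int(rng.integers(1, k + 1))
        members = rng.choice(k, size=size, replace=False)
        entries = [(isoforms[m], float(rng.uniform(0.1, 1.0))) for m in sorted(members)]
        sig = canonical_signature(entries)
        if sig in classes:
            classes[sig].multiplicity += 1.0
        else:
            classes[sig] = ReadClass(1.0, sig)
    # force connectivity so the likelihood has a unique interior structure
    if k > 1:
        entries = [(iso, 0.5) for iso in isoforms]
        sig = canonical_signature(entries)
        if sig in classes:
            classes[sig].multiplicity += 1.0
        else:
            classes[sig] = ReadClass(1.0, sig)
    return ComponentProblem(
        isoforms=isoforms, eff_lengths=lengths, classes=list(classes.values())
    )


def make_transcriptome(*isoforms: Isoform) -> Transcriptome:
    return Transcriptome(isoforms=list(isoforms))
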