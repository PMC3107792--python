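# isoem

Isoform- and gene-level expression estimation from RNA-Seq alignments using
expectation-maximization over read equivalence classes, plus a read simulator
and accuracy metrics for benchmarking.

## What it does

Given a transcript annotation (GTF) and read alignments against the
transcript library or genome (SAM/BAM), `isoem quantify`:

1. converts all alignments to genome coordinates and groups them per read;
2. computes read-isoform weights `w(r,j) = sum_a Q_a * F_a * O_a` via a
   coordinate-sorted line sweep, where `Q_a` comes from base qualities,
   `F_a` from the fragment-length distribution (exact insert probability for
   pairs, tail probability of the length upper bound for single reads), and
   `O_a` from strand/orientation consistency;
3. collapses equivalent reads into read classes while simultaneously finding
   connected components of the read-isoform compatibility graph with an
   online union-find (classes stored at the LCA of their isoforms' nodes);
4. runs EM independently per component: the E-step allocates class
   multiplicities proportionally to `f(j) * w`, the M-step renormalizes
   length-normalized coverages `c(j) = n(j) / l_eff(j)` where
   `l_eff(j) = sum_k p(k) * max(l(j) - k + 1, 0)`;
5. assembles global frequencies and sums them per gene.

Optional corrections: poly(A) tail extension (`--polyA`), repeat masking with
read discarding and length adjustment (`--repeats`), and hexamer-priming
bias reweighting of read multiplicities (`--hexamer-bias --reads r.fastq`).

## CLI

```sh
# synthetic dataset: GTF + FASTA + FASTQ + truth table + true-alignment SAM
isoem simulate --n-genes 500 --n-reads 500000 --read-len 25 --seed 7 -o out/ds

# quantify (single-end, nondirectional defaults; see --help for all flags)
isoem quantify --gtf out/ds.gtf --alignments out/ds.true.sam \
    --fasta out/ds.fasta --frag-mean 250 --frag-sd 25 -o out/ds

# compare against the truth (r^2, median percent error, error fractions)
isoem evaluate --truth out/ds.truth.tsv --estimates out/ds.isoforms.tsv

# all three chained
isoem bench --n-genes 500 --n-reads 500000 --seed 7 -o out/bench
```

`quantify` writes `<prefix>.isoforms.tsv` (frequency, expected count,
effective length, FPKM per isoform), `<prefix>.genes.tsv` and
`<prefix>.run.json` (serialized config + run statistics). Exit codes:
0 ok, 2 bad input, 3 internal error.

## Layout

- `src/isoem/transcript_model.py` — annotation model, genome/transcript
  coordinate mapping, poly(A) extension, repeat masking
- `src/isoem/fragment_model.py` — fragment-length distribution, effective
  lengths
- `src/isoem/alignment_compat.py` — SAM parsing, weight model, line sweep
- `src/isoem/read_classes.py` — online union-find, read-class collapsing
- `src/isoem/em_core.py` — per-component EM, grid-search oracle
- `src/isoem/bias_correction.py` — hexamer bias reweighting
- `src/isoem/simulator.py` — synthetic transcriptomes, truth tables, reads
- `src/isoem/metrics.py` — relative error, EF_tau, MPE, r^2
- `src/isoem/cli.py` — `isoem` command-line interface
- `tests/` — unit, property and acceptance tests (`tests/test_acceptance.py`)
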