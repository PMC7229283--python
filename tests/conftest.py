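"""Shared fixtures.

The heavyweight session fixtures run the full seeded 100 kb benchmark
(train on one simulated genome, polish a disjoint one) exactly once; the
acceptance tests and the pipeline invariant tests all read from them.
"""

from __future__ import annotations

import numpy as np
import pytest

from polishnet import benchmark, pileup, simgen


@pytest.fixture(scope="session")
def bench_model():
    """Model trained on the seeded 100 kb training scenario (<= 10 epochs)."""
    scenario = benchmark.make_scenario(101)
    model, _reports = benchmark.train_model(scenario, epochs=10, seed=1)
    return model


@pytest.fixture(scope="session")
def bench_scenario():
    """The disjoint seeded 100 kb evaluation scenario."""
    return benchmark.make_scenario(202)


@pytest.fixture(scope="session")
def bench_polish(bench_model, bench_scenario):
    """Two polish iterations on the evaluation scenario, plus the baseline."""
    return benchmark.run_polish_benchmark(bench_model, bench_scenario, iterations=2)


@pytest.fixture(scope="session")
def bench_diploid(bench_model):
    """Seeded synthetic diploid benchmark (100 kb, het SNV rate 0.001, 30x)."""
    return benchmark.run_diploid_benchmark(bench_model, seed=303)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_reads(rng, contig: str, n_reads: int, max_len: int = 12):
    """Small random M/I/D alignments over a contig, for pileup fuzzing."""
    reads = []
    L = len(contig)
    for i in range(n_reads):
        start = int(rng.integers(0, L))
        pos = start
        cigar = []
        seq = []
        while pos < L and rng.random() < 0.9 and (pos - start) < max_len:
            u = rng.random()
            if u < 0.65:
                cigar.append(("M", 1))
                seq.append("ACGT"[rng.integers(4)])
                pos += 1
            elif u < 0.85:
                cigar.append(("D", 1))
                pos += 1
            elif pos > start:
                cigar.append(("I", 1))
                seq.append("ACGT"[rng.integers(4)])
        if not any(op == "M" for op, _ in cigar):
            if pos >= L:
                cigar = []
                seq = []
                pos = start
            cigar.append(("M", 1))
            seq.append("ACGT"[rng.integers(4)])
            pos += 1
        merged = []
        for op, ln in cigar:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + ln)
            else:
                merged.append((op, ln))
        reads.append(
            pileup.AlignedRead(
                read_id=f"r{i}",
                contig_id="contig",
                start=start,
                strand="+" if rng.random() < 0.5 else "-",
                cigar=merged,
                sequence="".join(seq),
            )
        )
    return reads


@pytest.fixture()
def tiny_genome():
    return simgen.simulate_genome(2000, 0.5, seed=42)
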