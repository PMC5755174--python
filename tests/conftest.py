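import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from pirnakit.io_formats import CollapsedRead


def random_genome(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_genome(rng):
    """A 10 kb single-chromosome random genome."""
    return {"chr1": random_genome(rng, 10_000)}


def make_reads(seqs_counts) -> list[CollapsedRead]:
    """CollapsedReads from (sequence, count) pairs (or bare sequences)."""
    reads = []
    for i, item in enumerate(seqs_counts):
        seq, count = item if isinstance(item, tuple) else (item, 1)
        reads.append(CollapsedRead(id=f"u{i:06d}", sequence=seq, count=count))
    return reads


def write_fastq_file(path, records):
    """records: (name, seq, qual_string) triples."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return path
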