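import numpy as np
import pytest

from genomesizer import synth


@pytest.fixture(scope="session")
def small_genome():
    """Haploid 50 kb genome shared by counting tests."""
    return synth.make_genome(50_000, gc=0.42, het_rate=0.0, seed=101)


@pytest.fixture(scope="session")
def clean_readset(small_genome):
    """Error-free 30x reads from the shared genome."""
    return synth.simulate_reads(small_genome, coverage=30, read_length=100,
                                error_rate=0.0, seed=202)


def naive_kmer_counts(seqs, k):
    """Brute-force window-enumeration oracle for canonical k-mer counting."""
    comp = str.maketrans("ACGT", "TGCA")
    counts = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if any(c not in "ACGT" for c in w):
                continue
            rc = w.translate(comp)[::-1]
            canon = w if w <= rc else rc
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def gaussian_se(sd, n):
    return sd / np.sqrt(n)
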