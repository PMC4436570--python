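"""Synthetic genomes, shotgun reads, and flow-cytometry event streams.

Everything downstream of this module (k-mer counting, spectrum peak
detection, fluorescence peak fitting) is validated against data produced
here, where the ground truth is known exactly.  All randomness flows
through :class:`numpy.random.Generator` (PCG64) seeded with a single
explicit integer per operation, so identical parameters and seeds yield
byte-identical FASTA/FASTQ/CSV output.

The generators deliberately model only the features the estimators
consume:

* genomes are i.i.d. base strings with a tunable GC fraction and a second
  haplotype carrying binomially distributed substitutions (heterozygosity);
* reads are single-end, uniform-coverage, with uniform substitution
  errors and constant placeholder qualities;
* cytometry events are Gaussian nuclei populations (sd = mean x CV/100)
  over an exponential low-channel debris background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimGenome:
    """A diploid genome as two equal-length haplotype strings.

    ``haplotype_b`` differs from ``haplotype_a`` by ``Binomial(length,
    het_rate)`` substitutions at uniformly chosen positions, emulating an
    outbred diploid; ``het_rate = 0`` gives a haploid/inbred genome.
    """

    haplotype_a: str
    haplotype_b: str
    het_rate: float
    seed: int

    @property
    def length(self) -> int:
        return len(self.haplotype_a)


def make_genome(length: int, gc: float = 0.4, het_rate: float = 0.0,
                seed: int = 0) -> SimGenome:
    """Draw a random genome of ``length`` bases with the given GC fraction.

    Parameters
    ----------
    length : target haploid genome length in bases (>= 1000).
    gc : stationary G+C fraction, strictly inside (0, 1).
    het_rate : per-base substitution rate between the two haplotypes,
        in [0, 0.05].
    seed : integer RNG seed; the same seed reproduces the genome exactly.
    """
    if length < 1000:
        raise ValueError(f"genome length must be >= 1000, got {length}")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must lie strictly in (0, 1), got {gc}")
    if not 0.0 <= het_rate <= 0.05:
        raise ValueError(f"het_rate must lie in [0, 0.05], got {het_rate}")

    rng = np.random.default_rng(seed)
    at, gcp = (1.0 - gc) / 2.0, gc / 2.0
    codes = rng.choice(4, size=length, p=[at, gcp, gcp, at]).astype(np.uint8)

    codes_b = codes.copy()
    n_subs = rng.binomial(length, het_rate)
    if n_subs:
        pos = rng.choice(length, size=n_subs, replace=False)
        # substitute with one of the three other bases, uniformly
        shift = rng.integers(1, 4, size=n_subs).astype(np.uint8)
        codes_b[pos] = (codes_b[pos] + shift) % 4

    hap_a = _BASES[codes].tobytes().decode("ascii")
    hap_b = _BASES[codes_b].tobytes().decode("ascii")
    return SimGenome(hap_a, hap_b, het_rate, seed)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimReadSet:
    reads: list[str]
    coverage: float
    read_length: int
    error_rate: float
    seed: int


def simulate_reads(genome: SimGenome, coverage: float, read_length: int,
                   error_rate: float = 0.0, seed: int = 0) -> SimReadSet:
    """Sample single-end shotgun reads uniformly over positions and haplotypes.

    The number of reads is ``round(coverage * length / read_length)`` so the
    total read bases match the requested fold-coverage of one haploid genome
    to within one read.  Errors are uniform random substitutions applied
    independently per base at ``error_rate``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_length > genome.length:
        raise ValueError(
            f"read_length {read_length} exceeds genome length {genome.length}")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * genome.length / read_length))

    haps = np.stack([
        np.frombuffer(genome.haplotype_a.encode("ascii"), dtype=np.uint8),
        np.frombuffer(genome.haplotype_b.encode("ascii"), dtype=np.uint8),
    ])
    code_of = np.zeros(256, dtype=np.uint8)
    code_of[_BASES] = np.arange(4, dtype=np.uint8)

    which = rng.integers(0, 2, size=n_reads)
    starts = rng.integers(0, genome.length - read_length + 1, size=n_reads)
    offsets = np.arange(read_length)
    mat = haps[which[:, None], starts[:, None] + offsets]  # ASCII bytes

    if error_rate > 0:
        err = rng.random(mat.shape) < error_rate
        n_err = int(err.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            codes = code_of[mat[err]]
            mat[err] = _BASES[(codes + shift) % 4]

    reads = [row.tobytes().decode("ascii") for row in mat]
    return SimReadSet(reads, coverage, read_length, error_rate, seed)


# ---------------------------------------------------------------------------
# flow-cytometry events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimFcmRun:
    """Specification of one simulated cytometer acquisition.

    ``populations`` lists ``(label, mean_channel, cv_percent, n_events)``
    tuples; each population is Gaussian with ``sd = mean * cv/100``.
    Debris is drawn from an exponential concentrated at low channels and
    makes up ``debris_fraction`` of all recorded events.
    """

    populations: Sequence[tuple[str, float, float, int]]
    debris_fraction: float = 0.0
    channel_range: tuple[float, float] = (0.0, 262144.0)
    debris_scale: float | None = None
    seed: int = 0


def simulate_fcm_events(run: SimFcmRun) -> np.ndarray:
    """Generate the fluorescence value of every recorded event, shuffled.

    Total events = ``round(sum(n_events) / (1 - debris_fraction))``; the
    excess over the population counts is debris.  Values are clipped to
    ``channel_range``.
    """
    if not run.populations:
        raise ValueError("populations list must not be empty")
    if not 0.0 <= run.debris_fraction < 1.0:
        raise ValueError("debris_fraction must lie in [0, 1)")
    lo, hi = run.channel_range
    for label, mean, cv, n in run.populations:
        if not lo <= mean <= hi:
            raise ValueError(f"population {label!r}: mean {mean} outside "
                             f"channel range {run.channel_range}")
        if cv <= 0:
            raise ValueError(f"population {label!r}: cv_percent must be > 0")

    rng = np.random.default_rng(run.seed)
    parts = []
    n_pop = 0
    for _, mean, cv, n in run.populations:
        parts.append(rng.normal(mean, mean * cv / 100.0, size=n))
        n_pop += n

    n_total = int(round(n_pop / (1.0 - run.debris_fraction)))
    n_debris = n_total - n_pop
    if n_debris > 0:
        scale = run.debris_scale
        if scale is None:
            scale = 0.15 * min(m for _, m, _, _ in run.populations)
        parts.append(lo + rng.exponential(scale, size=n_debris))

    events = np.concatenate(parts)
    np.clip(events, lo, hi, out=events)
    rng.shuffle(events)
    return events


# ---------------------------------------------------------------------------
# ground truth + writers
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground-truth parameters of a synthetic dataset, for recovery tests."""

    params: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.params, indent=2, sort_keys=True)
                              + "\n")


def write_fasta(genome: SimGenome, path: str | Path, line_width: int = 70
                ) -> None:
    with open(path, "w") as fh:
        for name, seq in (("haplotype_A", genome.haplotype_a),
                          ("haplotype_B", genome.haplotype_b)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


def write_fastq(readset: SimReadSet, path: str | Path) -> None:
    """Write reads as FASTQ with constant placeholder qualities (Q40, 'I')."""
    with open(path, "w") as fh:
        qual = "I" * readset.read_length
        for i, seq in enumerate(readset.reads):
            fh.write(f"@read_{i}\n{seq}\n+\n{qual}\n")


def write_events_csv(events: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fluorescence\n")
        for v in events:
            fh.write(f"{v:.6f}\n")
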