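"""Flow-cytometry fluorescence to nuclear DNA content and genome size.

Under propidium-iodide staining, peak fluorescence channel is proportional
to nuclear DNA content, so a single-point reference standard of known 2C
content calibrates channel units to picograms:

    content_pg = (sample peak channel / standard peak channel) x standard 2C pg

Genome size follows from 1 pg DNA = 980 Mbp, with the 1C (haploid) value
obtained by dividing the measured per-nucleus content by the ploidy of
the measured nuclei (haplodiploid insects: males 1, females 2).

Peak positions are obtained by least-squares fitting of a sum of
Gaussians to the gated channel histogram.  A fitted peak is considered a
valid measurement only when its coefficient of variation (100 x sd/mean)
is below 5%, the conventional quality threshold for PI histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, signal

PG_PER_MBP = 980.0  # 1 pg DNA = 980 Mbp
CV_VALID_LIMIT = 5.0  # percent


@dataclass(frozen=True)
class ChannelHistogram:
    edges: np.ndarray   # strictly increasing bin edges, channel units
    counts: np.ndarray  # events per bin
    n_events: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class GaussianPeak:
    """One fitted fluorescence peak with its CV-based validity flag."""

    mean_channel: float
    sd: float
    mass: float  # fitted event count under the Gaussian

    @property
    def cv_percent(self) -> float:
        return 100.0 * self.sd / self.mean_channel

    @property
    def valid(self) -> bool:
        return self.cv_percent < CV_VALID_LIMIT


@dataclass(frozen=True)
class ReferenceStandard:
    """Standard organism of known 2C DNA content, e.g. D. melanogaster
    (1C = 0.18 pg, so 2C = 0.36 pg)."""

    name: str
    content_2c_pg: float
    peak_channel: float | None = None  # None: internal (same-tube) standard

    def __post_init__(self) -> None:
        if self.content_2c_pg <= 0:
            raise ValueError("standard 2C content must be positive")


@dataclass(frozen=True)
class DNAContentResult:
    """Per-group nuclear DNA content and 1C genome size."""

    label: str
    ploidy: int
    content_pg: float       # per measured nucleus
    mode: str = "external"  # "external" | "internal" standard

    @property
    def content_1c_pg(self) -> float:
        return self.content_pg / self.ploidy

    @property
    def size_1c_mbp(self) -> float:
        return pg_to_mbp(self.content_1c_pg)


class FitError(RuntimeError):
    """Gaussian peak fitting failed (non-convergence or missing maxima)."""


# ---------------------------------------------------------------------------
# histogram + fitting
# ---------------------------------------------------------------------------

def build_histogram(events: np.ndarray, n_bins: int = 256,
                    gate_min: float = 0.0) -> ChannelHistogram:
    """Bin fluorescence events above the debris gate.

    Events below ``gate_min`` are excluded; the remainder are binned
    uniformly over [gate_min, max event].
    """
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValueError("no events")
    if n_bins < 16:
        raise ValueError("n_bins must be >= 16")
    kept = events[events >= gate_min]
    if kept.size == 0:
        raise ValueError(f"all {events.size} events fall below the debris "
                         f"gate at {gate_min}")
    hi = float(kept.max())
    if hi == gate_min:
        hi = gate_min + 1.0
    counts, edges = np.histogram(kept, bins=n_bins, range=(gate_min, hi))
    return ChannelHistogram(edges, counts.astype(np.int64), int(kept.size))


def _sum_of_gaussians(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        a, mu, sd = params[i:i + 3]
        y = y + a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return y


def fit_peaks(hist: ChannelHistogram, expected_peaks: int | None = None,
              min_prominence: float = 0.05, smooth_bins: int = 3
              ) -> list[GaussianPeak]:
    """Fit a sum of Gaussians to the histogram, one per detected maximum.

    Candidate peaks are local maxima of the lightly smoothed counts with
    prominence at least ``min_prominence`` of the tallest bin; if
    ``expected_peaks`` is given, the that many most prominent candidates
    are kept (an error is raised if fewer exist).  All Gaussians are then
    refined jointly by least squares.  Returned sorted by mean channel.
    """
    x = hist.centers
    y = hist.counts.astype(float)
    if smooth_bins > 1:
        kern = np.ones(smooth_bins) / smooth_bins
        ys = np.convolve(y, kern, mode="same")
    else:
        ys = y

    prom = min_prominence * ys.max()
    idx, props = signal.find_peaks(ys, prominence=prom)
    if idx.size == 0:
        raise FitError("no local maxima found in histogram")
    if expected_peaks is not None:
        if idx.size < expected_peaks:
            raise FitError(f"found {idx.size} candidate peaks, "
                           f"expected {expected_peaks}")
        order = np.argsort(props["prominences"])[::-1][:expected_peaks]
        idx = np.sort(idx[order])

    bin_w = float(hist.edges[1] - hist.edges[0])
    p0, lower, upper = [], [], []
    for i in idx:
        mu0 = float(x[i])
        p0 += [float(ys[i]), mu0, max(0.04 * mu0, bin_w)]
        lower += [0.0, float(x[0]), bin_w / 4.0]
        upper += [np.inf, float(x[-1]), float(x[-1] - x[0])]
    try:
        popt, _ = optimize.curve_fit(_sum_of_gaussians, x, y, p0=p0,
                                     bounds=(lower, upper), maxfev=20000)
    except RuntimeError as exc:
        means = ", ".join(f"{x[i]:.1f}" for i in idx)
        raise FitError(f"Gaussian fit did not converge for peaks "
                       f"near channels [{means}]") from exc

    peaks = []
    for i in range(0, len(popt), 3):
        a, mu, sd = popt[i:i + 3]
        mass = a * sd * np.sqrt(2.0 * np.pi) / bin_w
        peaks.append(GaussianPeak(float(mu), float(sd), float(mass)))
    peaks.sort(key=lambda p: p.mean_channel)
    return peaks


# ---------------------------------------------------------------------------
# content arithmetic
# ---------------------------------------------------------------------------

def estimate_dna_content(sample_peak: float, standard: ReferenceStandard
                         ) -> float:
    """DNA content (pg) by linear channel ratio against the standard."""
    if standard.peak_channel is None or standard.peak_channel <= 0:
        raise ValueError("standard peak channel must be a positive number")
    if sample_peak <= 0:
        raise ValueError("sample peak channel must be positive")
    return sample_peak / standard.peak_channel * standard.content_2c_pg


def pg_to_mbp(content_pg: float) -> float:
    """Convert DNA mass to length: 1 pg = 980 Mbp."""
    if content_pg < 0:
        raise ValueError("DNA content cannot be negative")
    return content_pg * PG_PER_MBP


def haploid_size(content_pg: float, ploidy: int, label: str = "",
                 mode: str = "external") -> DNAContentResult:
    """1C content and genome size from measured per-nucleus content.

    ``ploidy`` is the ploidy of the measured nuclei (1 for haplodiploid
    males, 2 for females); it is supplied by the user, never inferred.
    """
    if ploidy not in (1, 2):
        raise ValueError(f"ploidy must be 1 or 2, got {ploidy}")
    if content_pg <= 0:
        raise ValueError("content_pg must be positive")
    return DNAContentResult(label=label, ploidy=ploidy,
                            content_pg=content_pg, mode=mode)


@dataclass(frozen=True)
class PloidyCheck:
    ratio: float
    consistent: bool


def ploidy_consistency(female_content_pg: float, male_content_pg: float,
                       tolerance: float = 0.05) -> PloidyCheck:
    """Check the 2-fold female/male content ratio expected of haplodiploids.

    Passes when |ratio - 2| <= 2 * tolerance (default 5%).
    """
    if female_content_pg <= 0 or male_content_pg <= 0:
        raise ValueError("contents must be positive")
    ratio = female_content_pg / male_content_pg
    return PloidyCheck(ratio=ratio,
                       consistent=abs(ratio - 2.0) <= 2.0 * tolerance)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_events_csv(path: str | Path) -> np.ndarray:
    """Read per-event fluorescence values from a one-column CSV."""
    df = pd.read_csv(path)
    if "fluorescence" not in df.columns:
        raise ValueError(f"{path}: expected a 'fluorescence' column")
    return df["fluorescence"].to_numpy(dtype=float)
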