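"""Orchestration of the two estimation pipelines into reproducible runs.

A run is fully described by a :class:`RunConfig`; replaying the same
config (same inputs, same seeds) rewrites byte-identical outputs, since
no timestamps enter data files.  Each stage logs one structured line with
an output checksum so silent drift between runs is detectable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fcm, kmer, stats

log = logging.getLogger("genomesizer")

# exit codes used by the CLI layer
EXIT_INPUT_ERROR = 2
EXIT_NO_PEAK = 3
EXIT_VALIDITY = 4


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (raised before computing)."""


@dataclass
class RunConfig:
    """Serializable parameters of one pipeline run.

    Thresholds carry the conventional defaults: CV validity gate 5%,
    heterozygous-shoulder detection at 10% of the main peak height,
    Tukey alpha 0.05.
    """

    # k-mer stage
    reads: str | None = None
    spectrum: str | None = None
    k: int = 17
    max_depth: int = 1000
    smooth: int = 3
    het_min_fraction: float = 0.1
    policy: str = "error_excluded"
    # fcm stage
    groups: list = field(default_factory=list)  # {label, ploidy, events: [csv...]}
    standard: dict = field(default_factory=dict)
    n_bins: int = 256
    gate_min: float = 0.0
    alpha: float = 0.05
    # bookkeeping
    out_prefix: str = "run"
    version: str = "0.1.0"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()[:12]


def _log_stage(stage: str, out: Path | None = None, **info) -> None:
    extra = dict(info)
    if out is not None:
        extra["out"] = str(out)
        extra["md5"] = _checksum(out)
    log.info("stage=%s %s", stage,
             " ".join(f"{k}={v}" for k, v in extra.items()))


# ---------------------------------------------------------------------------
# k-mer pipeline
# ---------------------------------------------------------------------------

def run_kmer_pipeline(config: RunConfig) -> kmer.KmerGenomeEstimate:
    """reads (or precomputed spectrum) -> spectrum -> peaks -> estimate.

    Writes ``<out_prefix>.spectrum.tsv`` and ``<out_prefix>.kmer.json``.
    The no-coverage-peak condition propagates as
    :class:`genomesizer.kmer.NoCoveragePeakError`.
    """
    if config.reads is None and config.spectrum is None:
        raise ConfigError("k-mer pipeline needs 'reads' or 'spectrum'")

    if config.spectrum is not None:
        spectrum = kmer.KmerSpectrum.from_tsv(config.spectrum, k=config.k)
        _log_stage("load_spectrum", Path(config.spectrum))
    else:
        seqs = kmer.read_sequences(config.reads)
        if not seqs:
            raise ConfigError(f"no reads in {config.reads}")
        table = kmer.count_kmers(seqs, kmer.KmerParams(k=config.k))
        _log_stage("count_kmers", n_distinct=table.n_distinct,
                   n_instances=table.n_instances)
        spectrum = kmer.spectrum_from_table(table)

    peaks = kmer.find_peaks(spectrum, smoothing_window=config.smooth,
                            het_min_fraction=config.het_min_fraction,
                            max_depth=config.max_depth)
    estimate = kmer.estimate_genome_size(spectrum, peaks, config.policy)

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_suffix(".spectrum.tsv")
    spectrum.to_tsv(tsv)
    _log_stage("spectrum", tsv)
    rep = prefix.with_suffix(".kmer.json")
    estimate.to_json(rep)
    _log_stage("estimate", rep, genome_size=estimate.genome_size,
               peak_depth=estimate.peak_depth)
    return estimate


# ---------------------------------------------------------------------------
# fcm pipeline
# ---------------------------------------------------------------------------

def _standard_from_config(config: RunConfig) -> fcm.ReferenceStandard:
    std = config.standard
    if not std or "content_2c_pg" not in std:
        raise ConfigError("missing standard definition "
                          "({name, content_2c_pg, peak_channel|'internal'})")
    channel = std.get("peak_channel")
    internal = channel in (None, "internal")
    return fcm.ReferenceStandard(
        name=std.get("name", "standard"),
        content_2c_pg=float(std["content_2c_pg"]),
        peak_channel=None if internal else float(channel))


def _replicate_peaks(events: np.ndarray, config: RunConfig, internal: bool
                     ) -> tuple[float, float | None, float]:
    """Fit one replicate; return (sample channel, standard channel, cv)."""
    hist = fcm.build_histogram(events, n_bins=config.n_bins,
                               gate_min=config.gate_min)
    n_expected = 2 if internal else 1
    peaks = fcm.fit_peaks(hist, expected_peaks=n_expected)
    if internal:
        std_peak, sample = peaks[0], peaks[-1]  # standard at lower channel
        return sample.mean_channel, std_peak.mean_channel, sample.cv_percent
    return peaks[0].mean_channel, None, peaks[0].cv_percent


def run_fcm_pipeline(config: RunConfig) -> dict:
    """events -> histograms -> peaks -> contents -> sizes -> letters -> report.

    Each group lists per-replicate event CSVs (or in-memory arrays under
    an ``events_data`` key) plus its nuclei ploidy.  Writes a Table-1
    style TSV and a JSON equivalent to ``<out_prefix>.fcm.{tsv,json}``.
    """
    standard = _standard_from_config(config)
    internal = standard.peak_channel is None
    if not config.groups:
        raise ConfigError("no groups configured")
    for g in config.groups:
        if "label" not in g or "ploidy" not in g:
            raise ConfigError("each group needs 'label' and 'ploidy'")
        if "events" not in g and "events_data" not in g:
            raise ConfigError(f"group {g.get('label')!r}: no event data")

    rows = []
    size_groups = []
    for g in config.groups:
        label, ploidy = g["label"], int(g["ploidy"])
        reps = (g.get("events_data")
                or [fcm.read_events_csv(p) for p in g["events"]])
        channels, cvs, sizes, contents = [], [], [], []
        for events in reps:
            ch, std_ch, cv = _replicate_peaks(np.asarray(events, dtype=float),
                                              config, internal)
            rep_std = (standard if not internal else
                       fcm.ReferenceStandard(standard.name,
                                             standard.content_2c_pg, std_ch))
            content = fcm.estimate_dna_content(ch, rep_std)
            result = fcm.haploid_size(content, ploidy, label,
                                      "internal" if internal else "external")
            channels.append(ch)
            cvs.append(cv)
            contents.append(content)
            sizes.append(result.size_1c_mbp)
        invalid = [cv for cv in cvs if cv >= fcm.CV_VALID_LIMIT]
        row = {
            "group": label,
            "ploidy": ploidy,
            "n_replicates": len(reps),
            "fluorescence_mean": float(np.mean(channels)),
            "fluorescence_se": float(np.std(channels, ddof=1)
                                     / np.sqrt(len(channels)))
            if len(channels) > 1 else 0.0,
            "cv_min": float(np.min(cvs)),
            "cv_max": float(np.max(cvs)),
            "cv_valid": not invalid,
            "content_pg_mean": float(np.mean(contents)),
            "content_pg_se": float(np.std(contents, ddof=1)
                                   / np.sqrt(len(contents)))
            if len(contents) > 1 else 0.0,
            "size_1c_mbp": float(np.mean(sizes)),
            "mode": "internal" if internal else "external",
        }
        rows.append(row)
        if len(sizes) > 1:
            size_groups.append(stats.GroupSample(label, tuple(sizes)))
        _log_stage("group", label=label, size_1c_mbp=f"{row['size_1c_mbp']:.3f}",
                   cv_valid=row["cv_valid"])

    letters = {}
    comparison = None
    if len(size_groups) >= 1 and len(size_groups) == len(rows):
        comparison = stats.tukey_letters(size_groups, alpha=config.alpha)
        letters = comparison.letters
    for row in rows:
        row["letters"] = letters.get(row["group"], "")

    report = {
        "standard": {"name": standard.name,
                     "content_2c_pg": standard.content_2c_pg,
                     "mode": "internal" if internal else "external"},
        "rows": rows,
        "anova": None if comparison is None else {
            "F": comparison.F, "df_between": comparison.anova.df_between,
            "df_within": comparison.anova.df_within, "p": comparison.p,
            "alpha": comparison.alpha},
    }

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_suffix(".fcm.tsv")
    with open(tsv, "w") as fh:
        fh.write("group\tfluorescence_mean_se\tcv_range\t"
                 "dna_content_pg_se\tsize_1c_mbp\tletters\n")
        for row in rows:
            fh.write("\t".join([
                row["group"],
                f"{row['fluorescence_mean']:.3f} ± "
                f"{row['fluorescence_se']:.3f}",
                f"{row['cv_min']:.1f}-{row['cv_max']:.1f}",
                f"{row['content_pg_mean']:.3f} ± "
                f"{row['content_pg_se']:.3f}",
                f"{row['size_1c_mbp']:.3f}",
                row["letters"]]) + "\n")
    _log_stage("table", tsv)
    rep = prefix.with_suffix(".fcm.json")
    rep.write_text(json.dumps(report, indent=2) + "\n")
    _log_stage("report", rep)
    return report
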