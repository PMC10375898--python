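"""Synthetic data generation with known ground truth.

The generator emulates the statistical structure a covalent pull-down
enrichment analysis assumes: per-nucleotide "input" (pre-pull-down)
coverage around a target depth, "output" (post-pull-down) coverage whose
expected ratio to the input is log-normally distributed under the null,
spiked intervals with a known true enrichment fold (the ground truth the
caller must recover), an optional repeat locus with read dropout on both
library sides (emulating reads that cannot be aligned to a reference
lacking the expansion), and expression / percent-spliced-in matrices
with a dysregulated gene set partially restored by treatment.

Counts are Poisson: input coverage ~ Poisson(depth), output coverage
~ Poisson(depth x true_ratio), independently per replicate; the latent
true ratio is a property of the nucleotide and is shared across
replicates (consistent enrichment is what the replicate filter tests).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .coverage_io import Annotation, CoverageTrack, Transcript, write_bed, write_gtf
from .exceptions import ConfigError

__all__ = [
    "SpikeSpec",
    "RepeatSpec",
    "SimulationConfig",
    "RescueSimConfig",
    "RescueSimResult",
    "generate_annotation",
    "simulate_coverage",
    "simulate_rescue_matrices",
    "write_fixture",
]


@dataclass(frozen=True)
class SpikeSpec:
    """A ground-truth enriched interval (0-based, half-open) on one transcript."""

    transcript_id: str
    start: int
    end: int
    fold: float

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ConfigError(f"spike on {self.transcript_id!r}: empty interval")
        if self.fold <= 0:
            raise ConfigError(f"spike on {self.transcript_id!r}: fold must be > 0")


@dataclass(frozen=True)
class RepeatSpec:
    """A repeat locus where a fraction of coverage is lost on both sides.

    Emulates the alignment dropout of a pure-repeat segment: reads
    consisting solely of the repeat cannot be placed on a reference that
    lacks the expansion, depressing observed coverage symmetrically in
    input and output libraries.
    """

    transcript_id: str
    start: int
    end: int
    dropout_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise ConfigError("dropout_fraction must be in [0, 1]")
        if self.end - self.start <= 0:
            raise ConfigError("repeat locus: empty interval")


@dataclass
class SimulationConfig:
    """Conditions for one simulated pull-down experiment.

    background_mu / background_sigma are the mean and sd of ln(ratio)
    under the null. The default sigma of 0.1 keeps library-level
    pull-down variability modest relative to Poisson counting noise at
    the default 30x depth, which dominates the per-nucleotide spread.
    """

    n_transcripts: int = 100
    transcript_length_range: tuple[int, int] = (2000, 8000)
    n_replicates: int = 3
    depth_input: float = 30.0
    background_mu: float = 0.0
    background_sigma: float = 0.1
    spikes: list[SpikeSpec] = field(default_factory=list)
    repeat_locus: RepeatSpec | None = None
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.transcript_length_range
        if lo > hi or lo <= 0:
            raise ConfigError(f"invalid transcript_length_range ({lo}, {hi})")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.depth_input <= 0:
            raise ConfigError("depth_input must be > 0")
        if self.background_sigma <= 0:
            raise ConfigError("background_sigma must be > 0")
        if self.n_transcripts < 1:
            raise ConfigError("n_transcripts must be >= 1")


@dataclass
class RescueSimConfig:
    """Conditions for the expression / splicing rescue simulation.

    effect_size and noise_sd are in log2 units in expression mode and in
    raw percent-spliced-in units in splicing mode.
    """

    n_genes: int = 5000
    n_dysregulated: int = 200
    true_rescue_fraction: float = 0.8
    effect_size: float = 2.0
    noise_sd: float = 0.3
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_dysregulated > self.n_genes:
            raise ConfigError("n_dysregulated must be <= n_genes")
        if not 0.0 <= self.true_rescue_fraction <= 1.0:
            raise ConfigError("true_rescue_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")


def generate_annotation(config: SimulationConfig) -> Annotation:
    """Generate a toy transcriptome: one contig per transcript.

    Lengths are drawn uniformly (inclusive) from
    ``transcript_length_range``; each transcript occupies its whole
    contig, named by its transcript_id. Deterministic per seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.transcript_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_transcripts)
    width = len(str(config.n_transcripts))
    transcripts = [
        Transcript(
            transcript_id=(tid := f"tx{str(i + 1).zfill(width)}"),
            gene_id=f"gene{str(i + 1).zfill(width)}",
            contig=tid,
            start=0,
            end=int(lengths[i]),
        )
        for i in range(config.n_transcripts)
    ]
    return Annotation(transcripts)


def _true_ratio_fields(
    annotation: Annotation, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Latent per-nucleotide true enrichment ratio, one field per contig."""
    by_id = {t.transcript_id: t for t in annotation}
    for spike in config.spikes:
        if spike.transcript_id not in by_id:
            raise ConfigError(f"spike on unknown transcript {spike.transcript_id!r}")
        host = by_id[spike.transcript_id]
        if spike.start < host.start or spike.end > host.end:
            raise ConfigError(
                f"spike [{spike.start}, {spike.end}) outside transcript "
                f"{spike.transcript_id!r} span [{host.start}, {host.end})"
            )
    if config.repeat_locus is not None:
        rep = config.repeat_locus
        if rep.transcript_id not in by_id:
            raise ConfigError(f"repeat locus on unknown transcript {rep.transcript_id!r}")
        host = by_id[rep.transcript_id]
        if rep.start < host.start or rep.end > host.end:
            raise ConfigError("repeat locus outside transcript span")

    fields = {}
    for t in annotation:
        length = t.end - t.start
        ratio = np.exp(
            config.background_mu + config.background_sigma * rng.standard_normal(length)
        )
        fields[t.contig] = ratio
    for spike in config.spikes:
        host = by_id[spike.transcript_id]
        fields[host.contig][spike.start - host.start : spike.end - host.start] *= spike.fold
    return fields


def simulate_coverage(
    annotation: Annotation, config: SimulationConfig
) -> dict[tuple[int, str], dict[str, CoverageTrack]]:
    """Simulate per-replicate input/output coverage tracks.

    Returns ``{(replicate, side): {contig: CoverageTrack}}`` with side in
    ``{"input", "output"}``. Zero-coverage nucleotides are recorded as 0,
    not masked, so downstream pseudocount handling is exercised.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ratio_fields = _true_ratio_fields(annotation, config, rng)

    keep = {t.contig: np.ones(t.end - t.start) for t in annotation}
    if config.repeat_locus is not None:
        rep = config.repeat_locus
        host = annotation.by_id(rep.transcript_id)
        keep[host.contig][rep.start - host.start : rep.end - host.start] = (
            1.0 - rep.dropout_fraction
        )

    tracks: dict[tuple[int, str], dict[str, CoverageTrack]] = {}
    for repl in range(config.n_replicates):
        inp: dict[str, CoverageTrack] = {}
        out: dict[str, CoverageTrack] = {}
        for t in annotation:
            lam_in = config.depth_input * keep[t.contig]
            lam_out = config.depth_input * ratio_fields[t.contig] * keep[t.contig]
            inp[t.contig] = CoverageTrack(t.contig, rng.poisson(lam_in))
            out[t.contig] = CoverageTrack(t.contig, rng.poisson(lam_out))
        tracks[(repl, "input")] = inp
        tracks[(repl, "output")] = out
    return tracks


@dataclass
class RescueSimResult:
    """Simulated group matrices plus the ground truth behind them."""

    wt_vehicle: pd.DataFrame
    dm1_vehicle: pd.DataFrame
    dm1_treated: pd.DataFrame
    truth: pd.DataFrame  # columns: dysregulated, rescued, direction


def simulate_rescue_matrices(
    config: RescueSimConfig, mode: str = "expression"
) -> RescueSimResult:
    """Simulate WT-vehicle / DM1-vehicle / DM1-treated matrices.

    In expression mode values are TPM, constructed so that
    log2(TPM + 1) = baseline + effect + N(0, noise_sd); baselines are
    uniform on [3, 10] log2 units. In splicing mode values are
    percent-spliced-in on [0, 1] with uniform baselines on [0.15, 0.85],
    clipped after adding noise. Dysregulated genes are offset by
    +/- effect_size in DM1-vehicle; a true_rescue_fraction of them
    return to the WT mean in DM1-treated. Deterministic per seed.
    """
    config.validate()
    if mode not in ("expression", "psi"):
        raise ConfigError(f"unknown rescue simulation mode {mode!r}")
    rng = np.random.default_rng(config.seed)
    n, k = config.n_genes, config.n_replicates
    genes = [f"gene{str(i + 1).zfill(len(str(n)))}" for i in range(n)]

    if mode == "expression":
        baseline = rng.uniform(3.0, 10.0, size=n)
    else:
        baseline = rng.uniform(0.15, 0.85, size=n)

    dys_idx = rng.choice(n, size=config.n_dysregulated, replace=False)
    direction = np.zeros(n)
    direction[dys_idx] = rng.choice([-1.0, 1.0], size=config.n_dysregulated)
    n_rescued = int(round(config.true_rescue_fraction * config.n_dysregulated))
    rescued_idx = rng.choice(dys_idx, size=n_rescued, replace=False)
    rescued = np.zeros(n, dtype=bool)
    rescued[rescued_idx] = True

    effect = direction * config.effect_size
    mean_wt = baseline
    mean_vehicle = baseline + effect
    mean_treated = np.where(rescued, baseline, mean_vehicle)

    def draw(mean: np.ndarray) -> pd.DataFrame:
        vals = mean[:, None] + config.noise_sd * rng.standard_normal((n, k))
        if mode == "expression":
            vals = np.exp2(vals) - 1.0  # back to TPM; log2(TPM+1) is Gaussian
            vals = np.clip(vals, 0.0, None)
        else:
            vals = np.clip(vals, 0.0, 1.0)
        return pd.DataFrame(
            vals, index=genes, columns=[f"rep{j + 1}" for j in range(k)]
        )

    truly_dys = effect != 0  # effect_size == 0 means nothing is dysregulated
    truth = pd.DataFrame(
        {
            "dysregulated": truly_dys,
            "rescued": rescued & truly_dys,
            "direction": direction,
        },
        index=genes,
    )
    return RescueSimResult(
        wt_vehicle=draw(mean_wt),
        dm1_vehicle=draw(mean_vehicle),
        dm1_treated=draw(mean_treated),
        truth=truth,
    )


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["transcript_length_range"] = list(config.transcript_length_range)
    return d


def write_fixture(
    outdir: str | os.PathLike,
    config: SimulationConfig,
    condition: str = "sim",
) -> Annotation:
    """Generate annotation + coverage and write a complete fixture directory.

    Writes a GTF, one BedGraph per (replicate, side), a ground-truth BED
    of spiked intervals, and a YAML copy of the configuration.
    """
    os.makedirs(outdir, exist_ok=True)
    annotation = generate_annotation(config)
    tracks = simulate_coverage(annotation, config)

    from .coverage_io import write_bedgraph

    write_gtf(annotation, os.path.join(outdir, "annotation.gtf"))
    for (repl, side), trackset in tracks.items():
        name = f"{condition}_rep{repl + 1}_{side}.bedgraph"
        write_bedgraph(trackset, os.path.join(outdir, name))

    truth_rows = []
    by_id = {t.transcript_id: t for t in annotation}
    for spike in config.spikes:
        host = by_id[spike.transcript_id]
        truth_rows.append(
            (host.contig, spike.start, spike.end, spike.transcript_id, spike.fold, "+")
        )
    write_bed(truth_rows, os.path.join(outdir, "true_spikes.bed"))

    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(
            {"condition": condition, **_config_to_dict(config)}, fh, sort_keys=False
        )
    return annotation
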