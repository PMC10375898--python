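"""Region compilation and the four-stage filter cascade.

Adjacent nucleotides whose -log10(p) exceeds the significance cutoff are
compiled into candidate regions, which are then triaged by (i) a minimum
area-under-curve, (ii) a length range matching the fragment sizes the
pull-down produces, (iii) a minimum read count, and (iv) consistent
enrichment in every replicate at a minimum log2 fold change.

"Area under curve" for a thresholded region is ambiguous; the default
here is the area *above* the cutoff, sum(max(0, nlp_i - cutoff)), which
is zero exactly at threshold and is the stricter reading. The raw sum
of -log10(p) over the region is available via ``auc_mode="raw"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage_io import TrackSet, library_total
from .enrichment import EnrichmentProfile

__all__ = ["FilterConfig", "CandidateRegion", "call_regions", "apply_filters"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the significance cutoff and the filter cascade.

    Defaults are the pull-down analysis' published operating point:
    -log10(p) > 10 to seed regions, minimum AUC 200, length within
    400-1000 nt (the fragment range after pull-down), at least 10 reads,
    and a log2 fold enrichment of at least 0.8 in every replicate.
    ``max_gap`` > 0 allows merging runs separated by that many masked or
    sub-threshold nucleotides (default 0: strict adjacency).
    """

    p_cutoff: float = 10.0
    min_auc: float = 200.0
    length_min: int = 400
    length_max: int = 1000
    min_reads: float = 10.0
    min_log2fc: float = 0.8
    max_gap: int = 0
    auc_mode: str = "above_cutoff"  # or "raw"
    reads_side: str = "output"  # or "input": which library the read filter counts
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.length_min > self.length_max:
            raise ValueError("length_min must be <= length_max")
        if min(self.p_cutoff, self.min_auc, self.min_reads, self.max_gap) < 0:
            raise ValueError("thresholds must be >= 0")
        if self.auc_mode not in ("above_cutoff", "raw"):
            raise ValueError(f"unknown auc_mode {self.auc_mode!r}")
        if self.reads_side not in ("output", "input"):
            raise ValueError(f"unknown reads_side {self.reads_side!r}")


@dataclass
class CandidateRegion:
    """A contiguous significant interval (0-based, half-open)."""

    contig: str
    start: int
    end: int
    auc: float
    max_neglog10p: float
    reads_input: float = float("nan")
    reads_output: float = float("nan")
    per_replicate_log2fc: list[float] = field(default_factory=list)
    filter_verdicts: dict[str, bool] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def passing(self) -> bool:
        return bool(self.filter_verdicts) and all(self.filter_verdicts.values())


def call_regions(
    profile: EnrichmentProfile,
    config: FilterConfig = FilterConfig(),
    pooled_input: TrackSet | None = None,
    pooled_output: TrackSet | None = None,
) -> list[CandidateRegion]:
    """Compile maximal runs of nucleotides with -log10(p) > cutoff.

    Runs separated by <= ``max_gap`` sub-threshold (or masked)
    nucleotides are merged. Each region carries its AUC (per
    ``auc_mode``), length and maximum -log10(p); pooled read sums are
    filled when pooled tracks are supplied (``apply_filters`` fills them
    otherwise).
    """
    if profile.neglog10p is None:
        raise ValueError("profile has no -log10 p track; run pvalue_track first")
    nlp = np.nan_to_num(profile.neglog10p, nan=-np.inf)
    above = nlp > config.p_cutoff
    if not above.any():
        return []

    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[0::2], edges[1::2]

    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] <= config.max_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    regions = []
    for s, e in merged:
        seg = profile.neglog10p[s:e]
        finite = np.nan_to_num(seg, nan=0.0)
        if config.auc_mode == "above_cutoff":
            auc = float(np.maximum(finite - config.p_cutoff, 0.0).sum())
        else:
            auc = float(finite.sum())
        region = CandidateRegion(
            contig=profile.contig,
            start=s + profile.offset,
            end=e + profile.offset,
            auc=auc,
            max_neglog10p=float(np.nanmax(seg)),
        )
        if pooled_input is not None and pooled_output is not None:
            region.reads_input = _region_reads(region, pooled_input)
            region.reads_output = _region_reads(region, pooled_output)
        regions.append(region)
    return regions


def _region_reads(region: CandidateRegion, tracks: TrackSet) -> float:
    track = tracks[region.contig]
    s = max(region.start - track.offset, 0)
    e = min(region.end - track.offset, len(track))
    return float(track.values[s:e].sum())


def apply_filters(
    regions: Sequence[CandidateRegion],
    replicate_pairs: Sequence[tuple[TrackSet, TrackSet]],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[CandidateRegion], pd.DataFrame]:
    """Apply the four-stage cascade; keep every verdict for reporting.

    ``replicate_pairs`` is one (input, output) library pair per
    replicate. Per-replicate log2 fold change over a region is
    log2(((sum O + pc) / N_O) / ((sum I + pc) / N_I)) with per-replicate
    library totals N. A region passes iff AUC >= min_auc, length within
    [length_min, length_max], pooled reads (on ``reads_side``)
    >= min_reads, and every replicate's log2fc >= min_log2fc.

    Returns the passing regions and the full verdict table (failures
    retained with reasons).
    """
    if not replicate_pairs:
        raise ValueError("need at least one replicate (input, output) pair")
    n_rep = len(replicate_pairs)
    lib_totals = [
        (library_total(inp), library_total(out)) for inp, out in replicate_pairs
    ]
    pc = config.pseudocount

    annotated: list[CandidateRegion] = []
    rows = []
    for region in regions:
        reads_in = sum(_region_reads(region, inp) for inp, _ in replicate_pairs)
        reads_out = sum(_region_reads(region, out) for _, out in replicate_pairs)
        log2fc = []
        for (inp, out), (n_in, n_out) in zip(replicate_pairs, lib_totals):
            o = (_region_reads(region, out) + pc) / n_out
            i = (_region_reads(region, inp) + pc) / n_in
            log2fc.append(float(np.log2(o / i)))

        reads_for_filter = reads_out if config.reads_side == "output" else reads_in
        verdicts = {
            "auc": region.auc >= config.min_auc,
            "length": config.length_min <= region.length <= config.length_max,
            "reads": reads_for_filter >= config.min_reads,
            "replicates": all(fc >= config.min_log2fc for fc in log2fc),
        }
        annotated.append(
            replace(
                region,
                reads_input=reads_in,
                reads_output=reads_out,
                per_replicate_log2fc=log2fc,
                filter_verdicts=verdicts,
            )
        )
        row = {
            "contig": region.contig,
            "start": region.start,
            "end": region.end,
            "length": region.length,
            "auc": region.auc,
            "max_neglog10p": region.max_neglog10p,
            "reads_input": reads_in,
            "reads_output": reads_out,
        }
        row.update({f"log2fc_rep{k + 1}": log2fc[k] for k in range(n_rep)})
        row.update({f"pass_{name}": ok for name, ok in verdicts.items()})
        row["pass_all"] = all(verdicts.values())
        rows.append(row)

    columns = (
        ["contig", "start", "end", "length", "auc", "max_neglog10p",
         "reads_input", "reads_output"]
        + [f"log2fc_rep{k + 1}" for k in range(n_rep)]
        + ["pass_auc", "pass_length", "pass_reads", "pass_replicates", "pass_all"]
    )
    verdict_table = pd.DataFrame(rows, columns=columns)
    passing = [r for r in annotated if r.passing]
    return passing, verdict_table
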