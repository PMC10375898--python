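"""End-to-end orchestration: replicate tracks in, transcript hits out.

One call per condition: pool replicates, compute depth-normalized
ratios, fit the genome-wide log-normal null, attach -log10 p-values,
compile significant regions, run the filter cascade, and aggregate
passing regions into transcript-level hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .coverage_io import Annotation, CoverageTrack, TrackSet
from .enrichment import (
    EnrichmentProfile,
    NullModel,
    compute_ratio_set,
    fit_null,
    pool_replicates,
    pvalue_track,
)
from .regions import CandidateRegion, FilterConfig, apply_filters, call_regions
from .transcripts import (
    RegionAssignment,
    TranscriptHit,
    aggregate_transcripts,
    assign_regions,
)

__all__ = ["EnrichmentResult", "run_enrichment", "run_transcript_hits"]


@dataclass
class EnrichmentResult:
    """Everything one condition's enrichment analysis produced."""

    null: NullModel
    profiles: dict[str, EnrichmentProfile]
    regions: list[CandidateRegion]  # all candidates, pre-filter
    passing: list[CandidateRegion]
    verdicts: pd.DataFrame
    pooled_input: dict[str, CoverageTrack]
    pooled_output: dict[str, CoverageTrack]


def run_enrichment(
    replicate_pairs: Sequence[tuple[TrackSet, TrackSet]],
    config: FilterConfig = FilterConfig(),
    pseudocount: float = 1.0,
    min_input: int = 1,
    null_method: str = "robust",
    refit_excluding_regions: bool = True,
    refit_method: str = "tail",
) -> EnrichmentResult:
    """Run the per-condition enrichment analysis on replicate track pairs.

    The null is fitted in two passes by default: a contamination-
    resistant first fit (``null_method``, default median/MAD) seeds
    candidate regions, which are then excluded from a second fit
    (``refit_method``, default the upper-tail QQ fit) so that the
    p-values of the final pass come from a null calibrated on
    enrichment-free background. Set ``refit_excluding_regions=False``
    for a single-pass fit.
    """
    pooled_input = pool_replicates([inp for inp, _ in replicate_pairs])
    pooled_output = pool_replicates([out for _, out in replicate_pairs])
    ratio_profiles = compute_ratio_set(
        pooled_input, pooled_output, pseudocount=pseudocount, min_input=min_input
    )
    null = fit_null(ratio_profiles.values(), method=null_method)

    def call_all(null_model: NullModel) -> tuple[dict, list]:
        profs = {
            contig: pvalue_track(prof, null_model)
            for contig, prof in ratio_profiles.items()
        }
        regs: list[CandidateRegion] = []
        for contig in sorted(profs):
            regs.extend(
                call_regions(
                    profs[contig], config,
                    pooled_input=pooled_input, pooled_output=pooled_output,
                )
            )
        return profs, regs

    profiles, regions = call_all(null)
    if refit_excluding_regions:
        exclude: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            exclude.setdefault(r.contig, []).append((r.start, r.end))
        null = fit_null(ratio_profiles.values(), method=refit_method, exclude=exclude)
        profiles, regions = call_all(null)

    passing, verdicts = apply_filters(regions, replicate_pairs, config)
    return EnrichmentResult(
        null=null,
        profiles=profiles,
        regions=regions,
        passing=passing,
        verdicts=verdicts,
        pooled_input=pooled_input,
        pooled_output=pooled_output,
    )


def run_transcript_hits(
    result: EnrichmentResult,
    annotation: Annotation,
    hit_threshold: float = 0.8,
    pseudocount: float = 0.5,
) -> tuple[list[TranscriptHit], RegionAssignment]:
    """Aggregate a condition's passing regions into transcript hits."""
    assignment = assign_regions(result.passing, annotation)
    hits = aggregate_transcripts(
        assignment,
        result.pooled_input,
        result.pooled_output,
        annotation,
        hit_threshold=hit_threshold,
        pseudocount=pseudocount,
    )
    return hits, assignment
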