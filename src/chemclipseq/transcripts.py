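"""Transcript-level aggregation of enriched regions and condition comparison.

A transcript occasionally receives multiple regions of enrichment; in
that case the reads over all of its regions are summed, normalized to
total library reads (reads per million), and the transcript's log2
enrichment is computed on the normalized sums. Transcripts at or above
the hit threshold (default log2 0.8) form the reported hit set.

Region-to-transcript assignment is by transcript-span overlap of at
least one nucleotide; a region overlapping several transcripts counts
toward all of them and is flagged ambiguous, so no signal silently
drops (the double counting across transcripts is deliberate and
documented).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .coverage_io import Annotation, TrackSet, library_total
from .regions import CandidateRegion

__all__ = [
    "TranscriptHit",
    "RegionAssignment",
    "assign_regions",
    "aggregate_transcripts",
    "hits_table",
    "compare_conditions",
]


@dataclass
class TranscriptHit:
    transcript_id: str
    gene_id: str
    n_regions: int
    reads_input_norm: float  # reads per million
    reads_output_norm: float
    log2_enrichment: float
    passing: bool
    ambiguous: bool = False  # any contributing region overlaps another transcript


@dataclass
class RegionAssignment:
    by_transcript: dict[str, list[CandidateRegion]] = field(default_factory=dict)
    intergenic: list[CandidateRegion] = field(default_factory=list)
    ambiguous_regions: list[CandidateRegion] = field(default_factory=list)


def assign_regions(
    regions: Sequence[CandidateRegion], annotation: Annotation
) -> RegionAssignment:
    """Assign each region to every transcript whose span it overlaps.

    Overlap of >= 1 nt suffices. Regions overlapping no transcript are
    reported as intergenic; regions overlapping more than one transcript
    are assigned to all of them and flagged ambiguous.
    """
    trees: dict[str, IntervalTree] = {}
    for t in annotation:
        trees.setdefault(t.contig, IntervalTree())[t.start : t.end] = t
    assignment = RegionAssignment()
    for region in regions:
        tree = trees.get(region.contig)
        overlaps = sorted(tree[region.start : region.end]) if tree else []
        if not overlaps:
            assignment.intergenic.append(region)
            continue
        if len(overlaps) > 1:
            assignment.ambiguous_regions.append(region)
        for iv in overlaps:
            assignment.by_transcript.setdefault(iv.data.transcript_id, []).append(region)
    return assignment


def aggregate_transcripts(
    assignment: RegionAssignment,
    pooled_input: TrackSet,
    pooled_output: TrackSet,
    annotation: Annotation,
    hit_threshold: float = 0.8,
    pseudocount: float = 0.5,
) -> list[TranscriptHit]:
    """Sum region reads per transcript, normalize per million, score hits.

    Per transcript and library side, raw reads are summed over its
    assigned regions (regions on one contig are disjoint, so nothing is
    double-counted within a transcript) and divided by total library
    reads / 1e6. log2_enrichment = log2((output_rpm + pc) / (input_rpm
    + pc)) with a small pseudocount in per-million units; a transcript
    passes iff log2_enrichment >= hit_threshold.
    """
    n_in = library_total(pooled_input)
    n_out = library_total(pooled_output)
    if n_in <= 0 or n_out <= 0:
        raise ValueError("zero total library reads; cannot normalize")
    ambiguous = {id(r) for r in assignment.ambiguous_regions}
    by_id = {t.transcript_id: t for t in annotation}

    hits = []
    for tid, regs in sorted(assignment.by_transcript.items()):
        reads_in = reads_out = 0.0
        for region in regs:
            track_in = pooled_input[region.contig]
            track_out = pooled_output[region.contig]
            s = max(region.start - track_in.offset, 0)
            e = min(region.end - track_in.offset, len(track_in))
            reads_in += float(track_in.values[s:e].sum())
            reads_out += float(track_out.values[s:e].sum())
        in_rpm = reads_in / n_in * 1e6
        out_rpm = reads_out / n_out * 1e6
        log2_enr = float(np.log2((out_rpm + pseudocount) / (in_rpm + pseudocount)))
        hits.append(
            TranscriptHit(
                transcript_id=tid,
                gene_id=by_id[tid].gene_id if tid in by_id else tid,
                n_regions=len(regs),
                reads_input_norm=in_rpm,
                reads_output_norm=out_rpm,
                log2_enrichment=log2_enr,
                passing=log2_enr >= hit_threshold,
                ambiguous=any(id(r) in ambiguous for r in regs),
            )
        )
    return hits


def hits_table(hits: Sequence[TranscriptHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": h.transcript_id,
                "gene_id": h.gene_id,
                "n_regions": h.n_regions,
                "reads_input_rpm": h.reads_input_norm,
                "reads_output_rpm": h.reads_output_norm,
                "log2_enrichment": h.log2_enrichment,
                "passing": h.passing,
                "ambiguous": h.ambiguous,
            }
            for h in hits
        ],
        columns=[
            "transcript_id", "gene_id", "n_regions", "reads_input_rpm",
            "reads_output_rpm", "log2_enrichment", "passing", "ambiguous",
        ],
    )


def compare_conditions(
    hits_a: Sequence[TranscriptHit],
    hits_b: Sequence[TranscriptHit],
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Compare passing hit sets of two conditions.

    Returns one row per transcript that passes in either condition, with
    both conditions' log2 enrichments side by side and a ``membership``
    column (``{label_a}_only``, ``{label_b}_only``, ``shared``). A
    selective binder shows up as condition-exclusive: enriched in one
    background and not the other.
    """
    a = {h.transcript_id: h for h in hits_a}
    b = {h.transcript_id: h for h in hits_b}
    pass_a = {tid for tid, h in a.items() if h.passing}
    pass_b = {tid for tid, h in b.items() if h.passing}

    rows = []
    for tid in sorted(pass_a | pass_b):
        if tid in pass_a and tid in pass_b:
            membership = "shared"
        elif tid in pass_a:
            membership = f"{label_a}_only"
        else:
            membership = f"{label_b}_only"
        ha, hb = a.get(tid), b.get(tid)
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": (ha or hb).gene_id,
                "membership": membership,
                f"log2_{label_a}": ha.log2_enrichment if ha else np.nan,
                f"log2_{label_b}": hb.log2_enrichment if hb else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "membership",
                 f"log2_{label_a}", f"log2_{label_b}"],
    )
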