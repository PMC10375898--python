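"""Coverage data model and readers/writers for the plain-text formats the
pipeline touches (BedGraph, GTF transcript subsets, BED6, TSV).

Coordinates are 0-based, half-open everywhere in memory; GTF values are
converted at the file boundary (GTF is 1-based, closed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError

__all__ = [
    "CoverageTrack",
    "TrackSet",
    "Transcript",
    "Annotation",
    "library_total",
    "read_bedgraph",
    "write_bedgraph",
    "read_gtf_subset",
    "write_gtf",
    "write_bed",
    "write_results_tsv",
]


@dataclass
class CoverageTrack:
    """Dense per-nucleotide coverage on one contig.

    ``values[i]`` is the coverage at genomic position ``offset + i``.
    Raw read coverage is integer and non-negative; derived tracks
    (ratios, -log10 p) use float values.
    """

    contig: str
    values: np.ndarray
    offset: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be one-dimensional")
        if np.issubdtype(self.values.dtype, np.integer) and (self.values < 0).any():
            raise ValueError(f"negative coverage on contig {self.contig!r}")

    @property
    def span(self) -> tuple[int, int]:
        return self.offset, self.offset + len(self.values)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def __len__(self) -> int:
        return len(self.values)


#: One library (condition, replicate, side): per-contig coverage tracks.
TrackSet = Mapping[str, CoverageTrack]


def library_total(tracks: TrackSet) -> float:
    """Total read count of a library, summed over all contigs."""
    return float(sum(t.values.sum() for t in tracks.values()))


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    contig: str
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"transcript {self.transcript_id!r}: start must be < end"
            )


@dataclass
class Annotation:
    """Transcript annotation (span-level; exon structure is out of scope)."""

    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transcript_ids in annotation")

    def __iter__(self):
        return iter(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    def by_id(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


def read_bedgraph(path: str | os.PathLike, float_values: bool = False) -> dict[str, CoverageTrack]:
    """Read a 4-column BedGraph into dense per-nucleotide tracks.

    Gaps between records are filled with 0; overlapping records are an
    error (a coverage track assigns one value per nucleotide). Raw
    coverage must be integer and non-negative unless ``float_values`` is
    set (used for derived ratio / -log10 p tracks).
    """
    records: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            contig, s, e, v = fields
            try:
                start, end = int(s), int(e)
                value = float(v)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if start < 0 or end <= start:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative coverage value {value}")
            if not float_values and value != int(value):
                raise ParseError(
                    f"{path}:{lineno}: non-integer coverage {value} (raw coverage must be integer)"
                )
            records.setdefault(contig, []).append((start, end, value))

    tracks: dict[str, CoverageTrack] = {}
    dtype = float if float_values else np.int64
    for contig, recs in records.items():
        recs.sort(key=lambda r: r[0])
        for (s1, e1, _), (s2, _, _) in zip(recs, recs[1:]):
            if s2 < e1:
                raise ParseError(
                    f"{path}: overlapping BedGraph records on {contig!r} "
                    f"([..., {e1}) then [{s2}, ...))"
                )
        length = recs[-1][1]
        values = np.zeros(length, dtype=dtype)
        for s, e, v in recs:
            values[s:e] = v
        tracks[contig] = CoverageTrack(contig, values)
    return tracks


def write_bedgraph(tracks: TrackSet, path: str | os.PathLike) -> None:
    """Write dense tracks as run-length-encoded BedGraph.

    Zero runs are written explicitly so that write -> read is the
    identity on the dense arrays (trailing zeros included).
    """
    with open(path, "w") as fh:
        for contig in sorted(tracks):
            track = tracks[contig]
            vals = track.values
            if len(vals) == 0:
                continue
            change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vals)]))
            for s, e in zip(starts, ends):
                v = vals[s]
                v_str = str(int(v)) if float(v) == int(v) else repr(float(v))
                fh.write(f"{contig}\t{s + track.offset}\t{e + track.offset}\t{v_str}\n")


def read_gtf_subset(path: str | os.PathLike) -> Annotation:
    """Read transcript features from a GTF into an :class:`Annotation`.

    Only ``transcript`` features are used; ``transcript_id`` and
    ``gene_id`` attributes are mandatory. GTF 1-based closed coordinates
    are converted to 0-based half-open.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_transcripts=True,
            disable_infer_genes=True,
        )
    except Exception as exc:
        raise ParseError(f"{path}: failed to parse GTF ({exc})") from None

    transcripts = []
    for feat in db.features_of_type("transcript"):
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise ParseError(
                f"{path}: transcript feature at {feat.seqid}:{feat.start} "
                f"missing mandatory attribute {exc}"
            ) from None
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        transcripts.append(
            Transcript(tid, gid, feat.seqid, feat.start - 1, feat.end, strand)
        )
    return Annotation(transcripts)


def write_gtf(annotation: Annotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in annotation:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.contig}\tchemclipseq\ttranscript\t{t.start + 1}\t{t.end}"
                f"\t.\t{t.strand}\t.\t{attrs}\n"
            )


def write_bed(
    regions: Iterable[tuple[str, int, int] | tuple[str, int, int, str, float, str]],
    path: str | os.PathLike,
) -> None:
    """Write intervals as BED (0-based half-open); BED6 when name/score/strand given."""
    with open(path, "w") as fh:
        for reg in regions:
            if len(reg) == 3:
                contig, start, end = reg
                fh.write(f"{contig}\t{start}\t{end}\n")
            else:
                contig, start, end, name, score, strand = reg
                fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


def write_results_tsv(
    table: pd.DataFrame,
    path: str | os.PathLike,
    header_comments: Sequence[str] = (),
) -> None:
    """Write a results table as TSV with optional ``#``-prefixed provenance lines."""
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False, lineterminator="\n")
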