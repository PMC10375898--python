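"""Per-nucleotide enrichment ratios and the log-normal null model.

The enrichment statistic is the ratio of post-pull-down ("output") to
pre-pull-down ("input") coverage at each nucleotide, optionally
depth-normalized by total library counts. Under the null the log of the
ratio is modelled as Normal(mu, sigma^2); the upper-tail probability of
that distribution at ln(r_i) gives a per-nucleotide p-value, reported as
-log10(p) computed in log space so that extreme sites (p << 1e-300)
remain finite.

p-values are computed on replicate-pooled tracks; per-replicate fold
change is applied downstream as a separate consistency filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .coverage_io import CoverageTrack, TrackSet, library_total
from .exceptions import FitError

__all__ = [
    "EnrichmentProfile",
    "NullModel",
    "compute_ratio",
    "compute_ratio_set",
    "fit_null",
    "pvalue_track",
    "pool_replicates",
]

#: -log10(p) values are clipped here to keep downstream arithmetic finite.
NEGLOG10P_CAP = 350.0

_LN10 = np.log(10.0)


@dataclass
class EnrichmentProfile:
    """Per-nucleotide enrichment ratio and significance on one contig.

    ``neglog10p`` is NaN at masked nucleotides (input coverage below
    ``min_input``) and is ``None`` until :func:`pvalue_track` has run.
    """

    contig: str
    ratio: np.ndarray
    mask: np.ndarray  # True where the nucleotide is valid for testing
    neglog10p: np.ndarray | None = None
    offset: int = 0

    def __len__(self) -> int:
        return len(self.ratio)


@dataclass(frozen=True)
class NullModel:
    """Log-normal null: ln(ratio) ~ Normal(mu, sigma^2) at background sites."""

    mu: float
    sigma: float
    fit_n: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise FitError("null model sigma must be > 0")
        if self.fit_n <= 0:
            raise FitError("null model fit_n must be > 0")

    def to_dict(self) -> dict:
        return {"mu": float(self.mu), "sigma": float(self.sigma), "fit_n": int(self.fit_n)}


def compute_ratio(
    input_track: CoverageTrack,
    output_track: CoverageTrack,
    pseudocount: float = 1.0,
    depth_normalize: bool = True,
    min_input: int = 1,
    lib_input: float | None = None,
    lib_output: float | None = None,
) -> EnrichmentProfile:
    """Per-nucleotide output/input enrichment ratio on one contig.

    With depth normalization, r_i = ((O_i + pc) / N_O) / ((I_i + pc) / N_I)
    where N are total library counts (defaulting to this track's totals;
    pass ``lib_input`` / ``lib_output`` for multi-contig libraries).
    Nucleotides with input coverage below ``min_input`` are masked.
    """
    if input_track.contig != output_track.contig:
        raise ValueError(
            f"contig mismatch: {input_track.contig!r} vs {output_track.contig!r}"
        )
    if len(input_track) != len(output_track) or input_track.offset != output_track.offset:
        raise ValueError(f"span mismatch on contig {input_track.contig!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")

    inp = input_track.values.astype(float)
    out = output_track.values.astype(float)
    num = out + pseudocount
    den = inp + pseudocount
    if depth_normalize:
        n_in = float(lib_input) if lib_input is not None else input_track.total
        n_out = float(lib_output) if lib_output is not None else output_track.total
        if n_in <= 0 or n_out <= 0:
            raise ValueError("library totals must be > 0 for depth normalization")
        num = num / n_out
        den = den / n_in
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / den, np.inf)
    mask = input_track.values >= min_input
    return EnrichmentProfile(
        contig=input_track.contig, ratio=ratio, mask=mask, offset=input_track.offset
    )


def compute_ratio_set(
    input_tracks: TrackSet,
    output_tracks: TrackSet,
    pseudocount: float = 1.0,
    depth_normalize: bool = True,
    min_input: int = 1,
) -> dict[str, EnrichmentProfile]:
    """Ratio profiles for a whole library; totals are summed over contigs."""
    if set(input_tracks) != set(output_tracks):
        raise ValueError("input and output libraries cover different contigs")
    n_in = library_total(input_tracks)
    n_out = library_total(output_tracks)
    return {
        contig: compute_ratio(
            input_tracks[contig],
            output_tracks[contig],
            pseudocount=pseudocount,
            depth_normalize=depth_normalize,
            min_input=min_input,
            lib_input=n_in,
            lib_output=n_out,
        )
        for contig in input_tracks
    }


def _excluded_mask(
    profile: EnrichmentProfile,
    exclude: Mapping[str, Sequence[tuple[int, int]]] | None,
) -> np.ndarray:
    bad = np.zeros(len(profile), dtype=bool)
    if exclude:
        for start, end in exclude.get(profile.contig, ()):
            s = max(start - profile.offset, 0)
            e = min(end - profile.offset, len(profile))
            if e > s:
                bad[s:e] = True
    return bad


def fit_null(
    profiles: Iterable[EnrichmentProfile],
    method: str = "robust",
    exclude: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    min_fit_n: int = 100,
    tail_range: tuple[float, float] = (0.75, 0.999),
    n_quantiles: int = 60,
) -> NullModel:
    """Fit the log-normal null from unmasked, non-excluded nucleotides.

    Three estimators of (mu, sigma) from the observed ln(ratio):

    - ``"robust"`` (default): median and normal-consistent MAD
      (MAD x 1.4826). Resists contamination by truly enriched sites, so
      it is the safe first-pass choice, but its central scale estimate
      makes the extreme upper tail slightly conservative when counting
      noise rides on top of the log-normal background.
    - ``"tail"``: least-squares line through the normal QQ plot over the
      upper quantiles (``tail_range``). Calibrates exactly the tail the
      one-sided test uses; intended for background that is already free
      of enriched regions (e.g. after a first-pass exclusion).
    - ``"moments"``: plain mean / sd.

    ``exclude`` maps contig -> intervals (e.g. candidate regions from a
    first pass) to drop before refitting.
    """
    if method not in ("robust", "moments", "tail"):
        raise ValueError(f"unknown fit method {method!r}")
    chunks = []
    for profile in profiles:
        keep = profile.mask & ~_excluded_mask(profile, exclude) & (profile.ratio > 0)
        chunks.append(np.log(profile.ratio[keep]))
    if not chunks:
        raise FitError("no profiles supplied to fit_null")
    lnr = np.concatenate(chunks)
    n = len(lnr)
    if n < min_fit_n:
        raise FitError(f"too few nucleotides to fit null: {n} < {min_fit_n}")
    if method == "robust":
        mu = float(np.median(lnr))
        sigma = float(stats.median_abs_deviation(lnr, scale="normal"))
    elif method == "tail":
        lo, hi = tail_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError(f"invalid tail_range {tail_range!r}")
        probs = np.linspace(lo, hi, n_quantiles)
        sigma, mu = np.polyfit(stats.norm.ppf(probs), np.quantile(lnr, probs), 1)
        mu, sigma = float(mu), float(sigma)
    else:
        mu = float(lnr.mean())
        sigma = float(lnr.std(ddof=1))
    if sigma <= 0:
        raise FitError("zero dispersion in ln(ratio): cannot fit null")
    return NullModel(mu=mu, sigma=sigma, fit_n=n)


def pvalue_track(profile: EnrichmentProfile, null: NullModel) -> EnrichmentProfile:
    """Attach upper-tail -log10 p-values under the fitted null.

    Computed via the log survival function of the standard normal, so
    p-values far below the float underflow threshold stay accurate;
    capped at 350. Masked nucleotides get NaN.
    """
    with np.errstate(divide="ignore"):
        lnr = np.log(profile.ratio)
    z = (lnr - null.mu) / null.sigma
    neglog10p = np.full(len(profile), np.nan)
    valid = profile.mask
    neglog10p[valid] = np.minimum(-stats.norm.logsf(z[valid]) / _LN10, NEGLOG10P_CAP)
    return EnrichmentProfile(
        contig=profile.contig,
        ratio=profile.ratio,
        mask=profile.mask,
        neglog10p=neglog10p,
        offset=profile.offset,
    )


def pool_replicates(tracksets: Sequence[TrackSet]) -> dict[str, CoverageTrack]:
    """Element-wise sum of per-replicate tracks (one library side)."""
    if not tracksets:
        raise ValueError("need at least one replicate")
    contigs = set(tracksets[0])
    for ts in tracksets[1:]:
        if set(ts) != contigs:
            raise ValueError("replicates cover different contigs")
    pooled = {}
    for contig in contigs:
        base = tracksets[0][contig]
        for ts in tracksets[1:]:
            other = ts[contig]
            if len(other) != len(base) or other.offset != base.offset:
                raise ValueError(f"replicate span mismatch on contig {contig!r}")
        total = np.sum([ts[contig].values for ts in tracksets], axis=0)
        pooled[contig] = CoverageTrack(contig, total, offset=base.offset)
    return pooled
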