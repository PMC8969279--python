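"""Cleavage-region localization from exon-usage profiles.

A transcript cleaved once by IRE1 and read out through poly(A) selection
shows a step-shaped exon-usage profile: every bin 5' of the cut is depleted
in treated samples, every bin 3' of it is unchanged.  The cleavage region is
the boundary of that step, formalized here as the two-segment least-squares
change-point of the per-bin log2 usage fold changes (5'->3' order).  Ties are
broken toward the smallest k — the 5'-most optimal boundary — because the
depletion is anchored at the transcript start.

A gene is classified "XBP1-like" when the 5' segment is depleted by at least
``min_delta`` log2 units relative to the 3' segment, at least half of the 5'
bins are individually significant, and the 3' segment is near zero; the last
clause separates cleavage from whole-transcript downregulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import ExonBin, TranscriptModel, genomic_to_transcript

__all__ = [
    "DepletionProfile",
    "build_profile",
    "localize_changepoint",
    "classify_xbp1_like",
    "cleavage_window",
]


@dataclass
class DepletionProfile:
    """Per-gene exon-usage depletion profile in 5'->3' bin order."""

    gene_id: str
    values: np.ndarray  # log2 usage fold change per bin, rank 1 first
    significant: np.ndarray  # per-bin fdr < threshold flags
    bin_ids: list[str]
    changepoint: int | None = None  # cleavage between bin k and bin k+1
    depth_delta: float = np.nan  # mean(5' segment) - mean(3' segment), log2
    xbp1_like: bool = False


def signed_fc_to_log2(fc: float) -> float:
    """Map the signed fold change (|fc| >= 1) back to log2 ratio scale."""
    if np.isnan(fc):
        return np.nan
    return np.log2(fc) if fc > 0 else -np.log2(-fc)


def build_profile(
    gene_results: pd.DataFrame, gene_id: str, fdr_threshold: float = 0.05
) -> DepletionProfile:
    """Assemble a gene's profile from its DEU result rows (any row order).

    Profile values come from the per-bin count fold change (``count_fc``,
    treated over mock coverage) when present, falling back to the usage fold
    change: coverage is flat at 0 over the 3' segment of a cleaved
    transcript, which is what the step model and the classifier assume.
    Significance flags come from the per-bin usage test.
    """
    rows = gene_results[gene_results["gene_id"] == gene_id]
    rows = rows[rows["testable"]]
    if len(rows) == 0:
        return DepletionProfile(gene_id, np.array([]), np.array([], bool), [])
    rows = rows.sort_values("rank_5to3")
    fc_col = "count_fc" if "count_fc" in rows.columns else "fc"
    values = np.array([signed_fc_to_log2(fc) for fc in rows[fc_col]])
    sig = (rows["fdr"] < fdr_threshold).to_numpy()
    return DepletionProfile(gene_id, values, sig, rows["bin_id"].tolist())


def localize_changepoint(values: np.ndarray) -> tuple[int, float]:
    """Best two-segment split of a profile by residual sum of squares.

    Returns (k, depth_delta): cleavage lies between bin k and bin k+1
    (1 <= k < n); depth_delta = mean(values[:k]) - mean(values[k:]).  Ties
    are broken toward the smallest k.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 bins to localize a change-point")
    csum = np.cumsum(values)
    csq = np.cumsum(values**2)
    total_sum, total_sq = csum[-1], csq[-1]
    best_k, best_rss = 1, np.inf
    for k in range(1, n):
        left_rss = csq[k - 1] - csum[k - 1] ** 2 / k
        right_sum = total_sum - csum[k - 1]
        right_rss = (total_sq - csq[k - 1]) - right_sum**2 / (n - k)
        rss = left_rss + right_rss
        if rss < best_rss - 1e-12:
            best_rss, best_k = rss, k
    k = best_k
    delta = float(values[:k].mean() - values[k:].mean())
    return k, delta


def classify_xbp1_like(
    profile: DepletionProfile,
    min_delta: float = 1.0,
    min_5p_sig_fraction: float = 0.5,
    max_3p_depletion: float = 0.5,
) -> DepletionProfile:
    """Flag profiles with a significant 5'-anchored depletion step.

    Requires depth_delta <= -min_delta, at least *min_5p_sig_fraction* of the
    5'-segment bins individually significant, and |mean 3' segment| <=
    *max_3p_depletion* log2 units (rejecting uniform downregulation).
    """
    if profile.changepoint is None:
        if len(profile.values) < 2:
            profile.xbp1_like = False
            return profile
        profile.changepoint, profile.depth_delta = localize_changepoint(profile.values)
    k = profile.changepoint
    # the bin just 3' of the boundary may straddle the cut and be partially
    # depleted; judge 3' flatness on the clearly-3' bins when there are any
    vals3 = profile.values[k + 1:] if len(profile.values) - k >= 2 else profile.values[k:]
    mean3 = float(vals3.mean())
    sig_frac = float(profile.significant[:k].mean()) if k > 0 else 0.0
    profile.xbp1_like = (
        profile.depth_delta <= -min_delta
        and sig_frac >= min_5p_sig_fraction
        and abs(mean3) <= max_3p_depletion
    )
    return profile


def _bin_transcript_span(b: ExonBin, t: TranscriptModel) -> tuple[int, int]:
    a = genomic_to_transcript(t, b.start)
    c = genomic_to_transcript(t, b.end - 1)
    return (a, c) if a <= c else (c, a)


def refine_cut_position(
    profile: DepletionProfile,
    ordered_bins: list[ExonBin],
    transcript: TranscriptModel,
) -> int:
    """Sub-bin cleavage-position estimate by inverting the depletion model.

    The change-point has one-bin resolution; within the two bins flanking
    the boundary the depletion model is invertible: a bin whose 5' fraction
    f lies 5' of the cut retains coverage scale = f * r + (1 - f), where
    r = 2**(mean 5'-segment log2 fold change) estimates the retained
    fraction after cleavage.  Solving f = (1 - scale) / (1 - r) for the two
    boundary bins and accumulating f * length places the cut inside the
    straddling bin instead of at the bin junction.
    """
    if profile.changepoint is None:
        raise ValueError("profile has no change-point")
    k = profile.changepoint
    values = profile.values
    # estimate the retained fraction from clearly-5' bins (exclude the
    # boundary bin when the 5' segment has more than one)
    m5 = float(values[: max(1, k - 1)].mean())
    r = min(2.0**m5, 0.999)
    t5 = _bin_transcript_span(ordered_bins[k - 1], transcript)[0] - 1
    cut = float(t5)
    for b, v in ((ordered_bins[k - 1], values[k - 1]), (ordered_bins[k], values[k])):
        scale = 2.0**v
        f = np.clip((1.0 - scale) / (1.0 - r), 0.0, 1.0)
        cut += f * b.length
    lo = _bin_transcript_span(ordered_bins[k - 1], transcript)[0]
    hi = _bin_transcript_span(ordered_bins[k], transcript)[1]
    return int(np.clip(round(cut), lo, hi))


def cleavage_window(
    profile: DepletionProfile,
    ordered_bins: list[ExonBin],
    transcript: TranscriptModel,
    pad: int = 100,
    refine: bool = True,
) -> tuple[int, int]:
    """Transcript-coordinate search window around the change-point junction.

    The junction — by default refined to a sub-bin estimate via
    :func:`refine_cut_position`, otherwise the 3'-most base of the rank-k
    bin — is mapped to transcript coordinates and widened by +/- *pad*
    nucleotides, clipped to the transcript bounds.  Returned as a 1-based
    inclusive interval, handed to the stem-loop scanner.
    """
    if profile.changepoint is None:
        raise ValueError("profile has no change-point")
    k = profile.changepoint
    if refine:
        tpos = refine_cut_position(profile, ordered_bins, transcript)
    else:
        bin_k = ordered_bins[k - 1]
        # 3'-most genomic base of the rank-k bin depends on strand
        gpos = bin_k.end - 1 if transcript.strand == "+" else bin_k.start
        tpos = genomic_to_transcript(transcript, gpos)
    lo = max(1, tpos - pad)
    hi = min(transcript.length, tpos + pad)
    return lo, hi
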