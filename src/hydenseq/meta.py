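"""Origin-centered meta-profiles and lagging/leading strand-bias statistics.

Every origin is anchored at the 5' end of its ACS and oriented so that the
ACS reads 5'→3' from offset 0.  Counts in fixed-width bins (5 bp by default)
are summed over origins, separately for the strand the ACS lies on ("same")
and its complement ("opposite").  For an origin annotated on the reverse
strand the offset axis is reversed and the genomic strands are swapped so
"same" always means the ACS strand.

The lagging-over-leading bias r_b of a ribonucleotide map compares the
RER−/RER+ ratio profile between bins assigned to the nascent lagging and
nascent leading strand.  For an ACS on the forward strand, nascent-leading
ends map to the forward strand at positive offsets (rightward fork) and to
the reverse strand at negative offsets (leftward fork); nascent-lagging is
the complement.  r_b is the arithmetic mean of binned ratios over
lagging-assigned bins within the flank window, divided by the mean over
leading-assigned bins; a core around the anchor is excluded where the
assignment is ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .tracks import OriginSet, StrandedEndTrack

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 5
DEFAULT_WINDOW = (-10_000, 10_000)
DEFAULT_FLANK_WINDOW = (500, 10_000)
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class MetaProfile:
    """Origin-centered binned counts, strand-resolved.

    Bin ``i`` covers offsets ``[window[0] + i*bin_width, window[0] + (i+1)*bin_width)``
    relative to the ACS anchor; offset 0 is the first base of the ACS.
    """

    bin_width: int
    window: tuple[int, int]
    same: np.ndarray
    opposite: np.ndarray
    n_origins: int
    moving_average_k: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.window
        n_bins = (hi - lo) // self.bin_width
        if (hi - lo) % self.bin_width:
            raise ValueError("window width must be a multiple of bin_width")
        if len(self.same) != n_bins or len(self.opposite) != n_bins:
            raise ValueError("value arrays do not match the bin grid")

    @property
    def n_bins(self) -> int:
        return len(self.same)

    @property
    def bin_starts(self) -> np.ndarray:
        return self.window[0] + self.bin_width * np.arange(self.n_bins)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_starts + self.bin_width / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset_bp": self.bin_starts,
                "same_strand": self.same,
                "opposite_strand": self.opposite,
            }
        )


@dataclass
class RatioProfile:
    """Per-bin, per-strand RER−/RER+ ratios plus the r_b summary when computed."""

    bin_width: int
    window: tuple[int, int]
    same: np.ndarray
    opposite: np.ndarray
    pseudocount: float
    r_b: float | None = None
    window_used_for_rb: tuple[int, int] | None = None

    bin_starts = MetaProfile.bin_starts
    bin_centers = MetaProfile.bin_centers

    @property
    def n_bins(self) -> int:
        return len(self.same)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset_bp": self.bin_starts,
                "same_strand_ratio": self.same,
                "opposite_strand_ratio": self.opposite,
            }
        )


def build_meta_profile(
    track: StrandedEndTrack,
    origins: OriginSet,
    bin_width: int = DEFAULT_BIN_WIDTH,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> MetaProfile:
    """Sum a track's counts into origin-centered, orientation-aware bins.

    Origins whose window overruns a chromosome end contribute only their
    in-bounds bins (logged).  The track should already be normalized (and
    usually shifted to implied ribonucleotide positions), but any semantics
    is accepted so raw-profile diagnostics remain possible.
    """
    lo, hi = window
    n_bins = (hi - lo) // bin_width
    if (hi - lo) % bin_width:
        raise ValueError("window width must be a multiple of bin_width")
    same = np.zeros(n_bins)
    opposite = np.zeros(n_bins)
    n_clipped = 0
    for origin in origins:
        fwd, rev = track.counts[origin.chrom]
        n = len(fwd)
        # per-offset values in oriented coordinates [lo, hi)
        if origin.strand == "+":
            g_lo, g_hi = origin.anchor + lo, origin.anchor + hi
            c_lo, c_hi = max(0, g_lo), min(n, g_hi)
            if (c_lo, c_hi) != (g_lo, g_hi):
                n_clipped += 1
            if c_lo >= c_hi:
                continue
            same_vals = fwd[c_lo:c_hi]
            opp_vals = rev[c_lo:c_hi]
            off0 = c_lo - origin.anchor  # first oriented offset present
        else:
            # oriented offset o maps to genomic position anchor - o
            g_lo, g_hi = origin.anchor - hi + 1, origin.anchor - lo + 1
            c_lo, c_hi = max(0, g_lo), min(n, g_hi)
            if (c_lo, c_hi) != (g_lo, g_hi):
                n_clipped += 1
            if c_lo >= c_hi:
                continue
            same_vals = rev[c_lo:c_hi][::-1]
            opp_vals = fwd[c_lo:c_hi][::-1]
            off0 = origin.anchor - (c_hi - 1)
        offsets = off0 + np.arange(len(same_vals))
        bins = (offsets - lo) // bin_width
        valid = (bins >= 0) & (bins < n_bins)
        np.add.at(same, bins[valid], same_vals[valid])
        np.add.at(opposite, bins[valid], opp_vals[valid])
    if n_clipped:
        logger.info("build_meta_profile: %d origins clipped at chromosome ends", n_clipped)
    return MetaProfile(
        bin_width=bin_width, window=window, same=same, opposite=opposite,
        n_origins=len(origins),
    )


def _centered_moving_average(values: np.ndarray, k: int) -> np.ndarray:
    """Centered running mean over k bins, shrinking the window at the edges."""
    n = len(values)
    left = (k - 1) // 2
    right = k // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - left)
    hi = np.minimum(n, idx + right + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def moving_average(profile: MetaProfile, k: int) -> MetaProfile:
    """Smooth both strands with a centered k-bin running mean (k=1: identity)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return replace(
        profile,
        same=_centered_moving_average(profile.same, k),
        opposite=_centered_moving_average(profile.opposite, k),
        moving_average_k=k,
    )


def rer_ratio(
    meta_rer_minus: MetaProfile,
    meta_rer_plus: MetaProfile,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> RatioProfile:
    """Per-bin, per-strand ratio of RER-deficient over RER-proficient profiles."""
    if (meta_rer_minus.window != meta_rer_plus.window
            or meta_rer_minus.bin_width != meta_rer_plus.bin_width):
        raise ValueError("profiles are not on the same bin grid")
    return RatioProfile(
        bin_width=meta_rer_minus.bin_width,
        window=meta_rer_minus.window,
        same=(meta_rer_minus.same + pseudocount) / (meta_rer_plus.same + pseudocount),
        opposite=(meta_rer_minus.opposite + pseudocount) / (meta_rer_plus.opposite + pseudocount),
        pseudocount=pseudocount,
    )


def lagging_leading_masks(
    profile: MetaProfile | RatioProfile,
    flank_window: tuple[int, int] = DEFAULT_FLANK_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (lagging, leading) masks over the (bin, strand) plane.

    Returned arrays have shape (n_bins, 2) with column 0 = same strand,
    column 1 = opposite strand.  Assignment follows the fork-direction
    convention: same strand is nascent-leading at positive offsets and
    nascent-lagging at negative offsets; the opposite strand mirrors.  Only
    bins whose center magnitude lies inside [flank_min, flank_max] are set.
    """
    inner, outer = flank_window
    centers = profile.bin_centers
    in_flank = (np.abs(centers) >= inner) & (np.abs(centers) <= outer)
    downstream = centers > 0
    leading = np.zeros((len(centers), 2), dtype=bool)
    lagging = np.zeros((len(centers), 2), dtype=bool)
    leading[:, 0] = in_flank & downstream
    lagging[:, 0] = in_flank & ~downstream
    leading[:, 1] = in_flank & ~downstream
    lagging[:, 1] = in_flank & downstream
    return lagging, leading


def strand_bias(
    ratio_profile: RatioProfile,
    flank_window: tuple[int, int] = DEFAULT_FLANK_WINDOW,
) -> RatioProfile:
    """Average lagging-over-leading bias r_b of an RER−/RER+ ratio profile.

    r_b = mean(ratio over lagging-assigned flank bins) /
          mean(ratio over leading-assigned flank bins).
    Returns a copy of the profile with ``r_b`` and the window recorded.
    """
    lagging, leading = lagging_leading_masks(ratio_profile, flank_window)
    values = np.column_stack([ratio_profile.same, ratio_profile.opposite])
    if not lagging.any() or not leading.any():
        raise ValueError("flank window selects no bins on one strand class")
    r_b = float(values[lagging].mean() / values[leading].mean())
    return replace(ratio_profile, r_b=r_b, window_used_for_rb=flank_window)
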