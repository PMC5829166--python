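"""Per-polymerase synthesis-fraction deconvolution at replication origins.

Three strains, each carrying one ribonucleotide-promiscuous replicase variant
(Pol alpha, delta or epsilon), see the same replication program but report it
with different per-polymerase ribonucleotide incorporation propensities rho.
After subtracting the RER-proficient background and anchoring each strain's
scale on the distal flanks (where the canonical division of labor is known),
the three corrected end densities at each bin and strand form a linear system

    d_g = sum_p rho[p, allele_p(g)] * f_p,      sum_p f_p = 1,  f_p >= 0,

whose solution f = (f_alpha, f_delta, f_epsilon) is the fraction of nascent
DNA synthesized by each replicase in that bin.  The system is solved exactly
as a tiny non-negative least-squares problem with the sum-to-one constraint
eliminated (never penalized), bin by bin.

The two strands are then combined by reflecting the opposite strand around
the axis of strand symmetry (estimated, close to +45 bp in the source data)
and averaging.  Subtracting the distal-flank canonical lagging level from
the averaged Pol delta fraction exposes the origin-proximal Pol delta tract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .meta import MetaProfile, lagging_leading_masks

logger = logging.getLogger(__name__)

POLS = ("alpha", "delta", "epsilon")
DEFAULT_DISTAL_FLANK = (2_000, 9_500)


@dataclass
class PolymeraseRates:
    """Relative rNMP incorporation propensities per nucleotide synthesized.

    ``wild_type[p]`` is the propensity of the wild-type enzyme and
    ``variant_fold[p]`` the fold-elevation of the mapping variant
    (pol1-L868M, pol3-L612M, pol2-M644G).  The defaults are configuration
    values chosen for order-of-magnitude realism, not measured constants;
    every analysis that uses them is self-consistent as long as simulator
    and solver share the same table.
    """

    wild_type: dict[str, float] = field(
        default_factory=lambda: {"alpha": 4.0, "delta": 1.0, "epsilon": 2.0}
    )
    variant_fold: dict[str, float] = field(
        default_factory=lambda: {"alpha": 4.0, "delta": 5.0, "epsilon": 10.0}
    )

    def __post_init__(self) -> None:
        for p in POLS:
            if self.wild_type[p] <= 0:
                raise ValueError("wild-type propensities must be positive")
            if self.variant_fold[p] <= 1:
                raise ValueError("variant propensity must exceed wild type")

    def rho(self, pol: str, variant: bool) -> float:
        r = self.wild_type[pol]
        return r * self.variant_fold[pol] if variant else r

    def strain_vector(self, variant_pol: str) -> np.ndarray:
        """(rho_alpha, rho_delta, rho_epsilon) for a strain whose
        ``variant_pol`` replicase carries the promiscuous substitution."""
        return np.array([self.rho(p, p == variant_pol) for p in POLS])


@dataclass
class CorrectedDensity:
    """Background-subtracted, flank-rescaled end densities for one strain."""

    variant_pol: str
    profile: MetaProfile
    rescale_constant: float


@dataclass
class FractionProfile:
    """Per-bin fraction of nascent-strand synthesis by each replicase."""

    bin_width: int
    window: tuple[int, int]
    f_alpha: np.ndarray
    f_delta: np.ndarray
    f_epsilon: np.ndarray
    strand: str = "same"  # "same", "opposite" or "averaged"
    residual: np.ndarray | None = None
    symmetry_axis_bp: float | None = None

    bin_starts = MetaProfile.bin_starts
    bin_centers = MetaProfile.bin_centers

    def __post_init__(self) -> None:
        total = self.f_alpha + self.f_delta + self.f_epsilon
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("fractions do not sum to 1 per bin")

    @property
    def n_bins(self) -> int:
        return len(self.f_alpha)

    def stack(self) -> np.ndarray:
        return np.vstack([self.f_alpha, self.f_delta, self.f_epsilon])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "offset_bp": self.bin_starts,
                "f_alpha": self.f_alpha,
                "f_delta": self.f_delta,
                "f_epsilon": self.f_epsilon,
            }
        )
        if self.residual is not None:
            df["residual"] = self.residual
        return df


def canonical_fractions(primer_fraction: float) -> dict[str, np.ndarray]:
    """Asymptotic division of labor far from origins.

    Lagging strands are Okazaki fragments: a Pol alpha primer of ~15 nt in a
    ~165 nt fragment, the rest Pol delta.  Leading strands are Pol epsilon.
    """
    return {
        "lagging": np.array([primer_fraction, 1.0 - primer_fraction, 0.0]),
        "leading": np.array([0.0, 0.0, 1.0]),
    }


def subtract_background(
    meta_rer_minus: MetaProfile, meta_rer_plus: MetaProfile
) -> MetaProfile:
    """RER− minus RER+ profile, bin-wise.

    Both profiles must already be on a common per-cell scale — which is what
    the SbfI size-factor normalization provides, since restriction ends and
    free background ends are per-genome-copy constants independent of
    genotype.  The difference then isolates the repaired-away ribonucleotide
    signal directly.  (Scaling each profile to its own total instead would
    force the difference to be zero-sum over the window, subtracting the
    signal mean along with the background.)  Negative bins are clipped to
    zero and the clipped mass logged.
    """
    if (meta_rer_minus.window != meta_rer_plus.window
            or meta_rer_minus.bin_width != meta_rer_plus.bin_width):
        raise ValueError("profiles are not on the same bin grid")
    same = meta_rer_minus.same - meta_rer_plus.same
    opp = meta_rer_minus.opposite - meta_rer_plus.opposite
    clipped = -(same[same < 0].sum() + opp[opp < 0].sum())
    if clipped > 0:
        logger.info("subtract_background: clipped negative mass %.3g", clipped)
    return MetaProfile(
        bin_width=meta_rer_minus.bin_width,
        window=meta_rer_minus.window,
        same=np.clip(same, 0.0, None),
        opposite=np.clip(opp, 0.0, None),
        n_origins=meta_rer_minus.n_origins,
    )


def rescale_to_canonical(
    density: MetaProfile,
    variant_pol: str,
    rates: PolymeraseRates,
    primer_fraction: float,
    distal_flank: tuple[int, int] = DEFAULT_DISTAL_FLANK,
) -> CorrectedDensity:
    """Anchor a strain's density scale on the distal flanks.

    The rescale constant C_g makes the flank-averaged density equal the
    forward-model prediction under the canonical division of labor, so the
    per-bin system becomes identifiable in absolute rho units.
    """
    rho = rates.strain_vector(variant_pol)
    canon = canonical_fractions(primer_fraction)
    pred_lag = float(rho @ canon["lagging"])
    pred_lead = float(rho @ canon["leading"])
    lagging, leading = lagging_leading_masks(density, distal_flank)
    values = np.column_stack([density.same, density.opposite])
    d_mean = float(np.concatenate([values[lagging], values[leading]]).mean())
    pred_mean = (pred_lag * lagging.sum() + pred_lead * leading.sum()) / (
        lagging.sum() + leading.sum()
    )
    if d_mean <= 0:
        raise ValueError(f"strain {variant_pol}: zero flank density, cannot rescale")
    c_g = d_mean / pred_mean
    return CorrectedDensity(
        variant_pol=variant_pol,
        profile=replace(density, same=density.same / c_g, opposite=density.opposite / c_g),
        rescale_constant=c_g,
    )


def _solve_bin(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact solution of min ||B x - y|| s.t. x >= 0, x1 + x2 <= 1 (x in R^2).

    The unconstrained optimum is accepted when feasible; otherwise the
    optimum lies on one of the three constraint edges, each a clipped 1-D
    least squares with closed form.  Convexity makes this enumeration exact.
    """
    x_free, *_ = np.linalg.lstsq(B, y, rcond=None)
    if x_free[0] >= 0 and x_free[1] >= 0 and x_free.sum() <= 1.0:
        r = B @ x_free - y
        return x_free, float(r @ r)
    candidates = []

    def _edge(b_vec: np.ndarray, y_vec: np.ndarray, lo: float, hi: float):
        denom = float(b_vec @ b_vec)
        t = float(b_vec @ y_vec) / denom if denom > 0 else 0.0
        return min(max(t, lo), hi)

    # x1 = 0 edge
    t = _edge(B[:, 1], y, 0.0, 1.0)
    candidates.append(np.array([0.0, t]))
    # x2 = 0 edge
    t = _edge(B[:, 0], y, 0.0, 1.0)
    candidates.append(np.array([t, 0.0]))
    # x1 + x2 = 1 edge
    t = _edge(B[:, 0] - B[:, 1], y - B[:, 1], 0.0, 1.0)
    candidates.append(np.array([t, 1.0 - t]))
    best, best_sq = None, np.inf
    for x in candidates:
        r = B @ x - y
        sq = float(r @ r)
        if sq < best_sq:
            best, best_sq = x, sq
    return best, best_sq


def solve_fractions(
    corrected: dict[str, CorrectedDensity],
    rates: PolymeraseRates,
    condition_limit: float = 1e8,
) -> dict[str, FractionProfile]:
    """Solve the per-bin three-strain system on each strand.

    ``corrected`` maps variant polymerase name -> flank-rescaled density.
    Returns ``{"same": FractionProfile, "opposite": FractionProfile}`` with
    per-bin residual norms.  Fails with a condition-number diagnostic when
    the strain design is singular (e.g., two strains share a variant).
    """
    if set(corrected) != set(POLS):
        raise ValueError(f"need exactly one strain per variant replicase {POLS}")
    grids = {(c.profile.window, c.profile.bin_width) for c in corrected.values()}
    if len(grids) != 1:
        raise ValueError("corrected densities are not on a shared grid")
    R = np.vstack([rates.strain_vector(p) for p in POLS])  # strains x pols
    cond = np.linalg.cond(R)
    if cond > condition_limit:
        raise ValueError(
            f"strain design matrix is singular or near-singular (cond={cond:.3g})"
        )
    # eliminate f_epsilon = 1 - f_alpha - f_delta
    B = R[:, :2] - R[:, 2:3]
    ref = next(iter(corrected.values())).profile
    out: dict[str, FractionProfile] = {}
    for strand in ("same", "opposite"):
        D = np.vstack(
            [getattr(corrected[p].profile, strand) for p in POLS]
        )  # strains x bins
        Y = D - R[:, 2:3]  # subtract the epsilon column contribution
        n_bins = D.shape[1]
        f = np.empty((3, n_bins))
        resid = np.empty(n_bins)
        # vectorized unconstrained solve; per-bin repair where infeasible
        X_free = np.linalg.lstsq(B, Y, rcond=None)[0]
        feasible = (X_free[0] >= 0) & (X_free[1] >= 0) & (X_free.sum(axis=0) <= 1.0)
        for i in range(n_bins):
            if feasible[i]:
                x = X_free[:, i]
                r = B @ x - Y[:, i]
                sq = float(r @ r)
            else:
                x, sq = _solve_bin(B, Y[:, i])
            f[0, i], f[1, i] = x
            f[2, i] = 1.0 - x.sum()
            resid[i] = np.sqrt(sq)
        # numerical hygiene: clip and renormalize exactly
        f = np.clip(f, 0.0, 1.0)
        f /= f.sum(axis=0)
        out[strand] = FractionProfile(
            bin_width=ref.bin_width,
            window=ref.window,
            f_alpha=f[0],
            f_delta=f[1],
            f_epsilon=f[2],
            strand=strand,
            residual=resid,
        )
    return out


def _reflect_interp(values: np.ndarray, centers: np.ndarray, axis_bp: float) -> np.ndarray:
    """Values of a profile reflected around ``axis_bp``, interpolated back
    onto the original bin centers (edges extend the boundary value)."""
    return np.interp(2.0 * axis_bp - centers, centers, values)


def reflect_and_average(
    same: FractionProfile, opposite: FractionProfile, axis_bp: float
) -> FractionProfile:
    """Average the same-strand profile with the opposite strand reflected
    around the axis of strand symmetry."""
    if (same.window, same.bin_width) != (opposite.window, opposite.bin_width):
        raise ValueError("strand profiles are not on a shared grid")
    centers = same.bin_centers
    f = 0.5 * (
        same.stack()
        + np.vstack([_reflect_interp(v, centers, axis_bp) for v in opposite.stack()])
    )
    f = np.clip(f, 0.0, None)
    f /= f.sum(axis=0)
    return FractionProfile(
        bin_width=same.bin_width,
        window=same.window,
        f_alpha=f[0],
        f_delta=f[1],
        f_epsilon=f[2],
        strand="averaged",
        symmetry_axis_bp=axis_bp,
    )


def estimate_symmetry_axis(
    same: np.ndarray | FractionProfile,
    opposite: np.ndarray | FractionProfile | None = None,
    centers: np.ndarray | None = None,
    search: tuple[float, float] = (-100.0, 200.0),
    step: float = 0.5,
) -> float:
    """Axis maximizing same-strand vs reflected-opposite-strand agreement.

    Scans candidate axes on a ``step`` grid and returns the axis with the
    minimum sum of squared differences over the overlapping support
    (smallest axis on ties).  Accepts a FractionProfile pair or raw arrays
    (2-D arrays are treated as stacked component profiles).
    """
    if isinstance(same, FractionProfile):
        opposite_fp = opposite
        centers = same.bin_centers
        same_arr = same.stack()
        opp_arr = opposite_fp.stack()
    else:
        if opposite is None or centers is None:
            raise ValueError("array input needs opposite and centers")
        same_arr = np.atleast_2d(np.asarray(same, dtype=float))
        opp_arr = np.atleast_2d(np.asarray(opposite, dtype=float))
    candidates = np.arange(search[0], search[1] + step / 2, step)
    best_axis, best_ssd = None, np.inf
    lo, hi = centers[0], centers[-1]
    for a in candidates:
        reflected_x = 2.0 * a - centers
        mask = (reflected_x >= lo) & (reflected_x <= hi)
        if mask.sum() < max(10, len(centers) // 10):
            continue
        ssd = 0.0
        for s_row, o_row in zip(same_arr, opp_arr):
            refl = np.interp(reflected_x[mask], centers, o_row)
            ssd += float(((s_row[mask] - refl) ** 2).sum())
        ssd /= mask.sum()
        if ssd < best_ssd - 1e-15:
            best_axis, best_ssd = float(a), ssd
    if best_axis is None:
        raise ValueError("no candidate axis had sufficient overlap")
    return best_axis


@dataclass
class DeltaExcess:
    """Origin-proximal Pol delta synthesis above the canonical lagging level."""

    bin_width: int
    window: tuple[int, int]
    excess: np.ndarray
    canonical_level: float
    peak_bp: float | None
    fwhm_bp: float | None

    bin_starts = MetaProfile.bin_starts
    bin_centers = MetaProfile.bin_centers

    @property
    def n_bins(self) -> int:
        return len(self.excess)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset_bp": self.bin_starts, "f_delta_excess": self.excess})


def subtract_canonical_lagging(
    averaged: FractionProfile,
    flank_window: tuple[int, int] = DEFAULT_DISTAL_FLANK,
    peak_window: tuple[int, int] = (-1_000, 1_000),
) -> DeltaExcess:
    """Expose the origin-proximal Pol delta tract.

    The canonical lagging component is estimated as the mean strand-averaged
    f_delta over the upstream distal flank (offsets in [-outer, -inner]),
    where division of labor is asymptotic, and subtracted bin-wise; negatives
    are clipped.  The peak apex is searched inside ``peak_window`` (the tract
    is origin-proximal by construction) and reported as the midpoint of the
    contiguous full-width-at-half-maximum interval, which is stable on
    plateau-shaped excesses where an argmax with tie-breaking is not.
    """
    inner, outer = flank_window
    centers = averaged.bin_centers
    upstream = (centers <= -inner) & (centers >= -outer)
    if not upstream.any():
        raise ValueError("flank window selects no upstream bins")
    canonical = float(averaged.f_delta[upstream].mean())
    excess = np.clip(averaged.f_delta - canonical, 0.0, None)
    peak_bp = fwhm_bp = None
    core = (centers >= peak_window[0]) & (centers <= peak_window[1])
    if core.any() and excess[core].max() > 0:
        core_idx = np.flatnonzero(core)
        apex = core_idx[int(np.argmax(excess[core]))]
        half = excess[apex] / 2.0
        # contiguous above-half region around the apex, ignoring distal noise
        lo = apex
        while lo > 0 and excess[lo - 1] >= half:
            lo -= 1
        hi = apex
        while hi < len(excess) - 1 and excess[hi + 1] >= half:
            hi += 1
        peak_bp = float((centers[lo] + centers[hi]) / 2.0)
        fwhm_bp = float(centers[hi] - centers[lo] + averaged.bin_width)
    return DeltaExcess(
        bin_width=averaged.bin_width,
        window=averaged.window,
        excess=excess,
        canonical_level=canonical,
        peak_bp=peak_bp,
        fwhm_bp=fwhm_bp,
    )
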