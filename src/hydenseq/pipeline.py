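"""End-to-end orchestration: raw stranded end tracks to transfer-model fit.

``analyze_panel`` chains the stages on an in-memory sample panel:

1. size factors from SbfI-site 5'-end counts (median of ratios),
2. implied-ribonucleotide shift and normalization per sample,
3. origin-centered meta-profiles, RER−/RER+ ratios and r_b per genotype,
4. background subtraction, flank rescaling and per-bin synthesis-fraction
   deconvolution across the three variant strains,
5. strand-symmetry axis estimation, reflect-and-average, canonical-lagging
   subtraction, and the transfer-tract regression.

Replicate libraries of a genotype are averaged at the normalized-profile
level.  Stages degrade gracefully: genotypes lacking an RER+ partner skip
the ratio stage and panels lacking a full three-variant design skip the
deconvolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fractions as fr
from . import meta as mt
from . import normalization as nm
from . import tracks as tk
from .transfer import TransferModel, TransferResults, summarize_transfers

logger = logging.getLogger(__name__)


@dataclass
class PanelParams:
    """Stage parameters of one analysis run."""

    bin_width: int = mt.DEFAULT_BIN_WIDTH
    window: tuple[int, int] = mt.DEFAULT_WINDOW
    flank_window: tuple[int, int] = mt.DEFAULT_FLANK_WINDOW
    distal_flank: tuple[int, int] = fr.DEFAULT_DISTAL_FLANK
    pseudocount: float = mt.DEFAULT_PSEUDOCOUNT
    moving_average_k: int = 10
    # odd width: an even centered boxcar is half-a-bin asymmetric, which
    # would bias the strand-symmetry axis by ~bin_width/2
    density_smooth_k: int = 9
    site_window_bp: int = 0
    rates: fr.PolymeraseRates = field(default_factory=fr.PolymeraseRates)
    primer_length: int = 15
    okazaki_mean: float = 165.0
    fit_window: tuple[int, int] = (-1_000, 1_000)
    priming: str = "gaussian_start"
    symmetry_axis_override: float | None = None

    @property
    def primer_fraction(self) -> float:
        return self.primer_length / self.okazaki_mean


@dataclass
class GenotypeResult:
    """Meta/ratio stage output for one variant-polymerase genotype."""

    variant_polymerase: str
    meta_rer_minus: mt.MetaProfile
    meta_rer_plus: mt.MetaProfile | None = None
    ratio: mt.RatioProfile | None = None

    @property
    def r_b(self) -> float | None:
        return self.ratio.r_b if self.ratio is not None else None


@dataclass
class PanelResults:
    """Everything one panel run computes."""

    size_factors: nm.SizeFactors
    meta_by_sample: dict[str, mt.MetaProfile]
    genotypes: dict[str, GenotypeResult]
    corrected: dict[str, fr.CorrectedDensity] | None = None
    fractions_by_strand: dict[str, fr.FractionProfile] | None = None
    symmetry_axis_bp: float | None = None
    fractions_averaged: fr.FractionProfile | None = None
    delta_excess: fr.DeltaExcess | None = None
    transfer: TransferResults | None = None

    def transfer_summary(self) -> dict | None:
        return summarize_transfers(self.transfer) if self.transfer else None


def _mean_profiles(profiles: list[mt.MetaProfile]) -> mt.MetaProfile:
    ref = profiles[0]
    return mt.MetaProfile(
        bin_width=ref.bin_width,
        window=ref.window,
        same=np.mean([p.same for p in profiles], axis=0),
        opposite=np.mean([p.opposite for p in profiles], axis=0),
        n_origins=ref.n_origins,
    )


def compute_size_factors(
    sample_tracks: dict[str, tk.StrandedEndTrack],
    genome: tk.Genome,
    site_window_bp: int = 0,
) -> tuple[nm.SizeFactors, nm.RestrictionSiteSet]:
    """Median-of-ratios factors from SbfI-site end counts of raw tracks."""
    sites = nm.find_sbfi_sites(genome)
    ids = list(sample_tracks)
    matrix = np.vstack(
        [nm.site_end_counts(sample_tracks[sid], sites, window_bp=site_window_bp) for sid in ids]
    )
    return nm.median_of_ratios(matrix, sample_ids=ids), sites


def analyze_panel(
    sample_tracks: dict[str, tk.StrandedEndTrack],
    sheet: pd.DataFrame,
    genome: tk.Genome,
    origins: tk.OriginSet,
    params: PanelParams | None = None,
) -> PanelResults:
    """Run the full analysis over a panel of raw stranded end tracks."""
    params = params or PanelParams()
    missing = set(sheet["sample_id"]) - set(sample_tracks)
    if missing:
        raise ValueError(f"sample sheet lists tracks not supplied: {sorted(missing)}")
    size_factors, _sites = compute_size_factors(
        sample_tracks, genome, site_window_bp=params.site_window_bp
    )
    meta_by_sample: dict[str, mt.MetaProfile] = {}
    for sid, raw in sample_tracks.items():
        shifted = tk.implied_rnmp_positions(raw)
        normalized = nm.apply_size_factor(shifted, size_factors[sid])
        meta_by_sample[sid] = mt.build_meta_profile(
            normalized, origins, bin_width=params.bin_width, window=params.window
        )
    # genotype grouping: replicates averaged at the normalized-profile level
    genotypes: dict[str, GenotypeResult] = {}
    for variant, sub in sheet.groupby("variant_polymerase"):
        if variant == "none":
            continue
        minus_ids = sub.loc[sub["rer"] == "RER-", "sample_id"].tolist()
        plus_ids = sub.loc[sub["rer"] == "RER+", "sample_id"].tolist()
        if not minus_ids:
            logger.warning("genotype %s has no RER- library; skipped", variant)
            continue
        g = GenotypeResult(
            variant_polymerase=variant,
            meta_rer_minus=_mean_profiles([meta_by_sample[s] for s in minus_ids]),
        )
        if plus_ids:
            g.meta_rer_plus = _mean_profiles([meta_by_sample[s] for s in plus_ids])
            ratio = mt.rer_ratio(g.meta_rer_minus, g.meta_rer_plus, params.pseudocount)
            g.ratio = mt.strand_bias(ratio, params.flank_window)
        genotypes[variant] = g
    results = PanelResults(
        size_factors=size_factors,
        meta_by_sample=meta_by_sample,
        genotypes=genotypes,
    )
    # deconvolution needs one complete RER-/RER+ pair per variant replicase
    wanted = {v: p for v, p in tk.VARIANT_TO_POL.items()}
    if not all(
        v in genotypes and genotypes[v].meta_rer_plus is not None for v in wanted
    ):
        return results
    corrected: dict[str, fr.CorrectedDensity] = {}
    for variant, pol in wanted.items():
        g = genotypes[variant]
        density = fr.subtract_background(g.meta_rer_minus, g.meta_rer_plus)
        if params.density_smooth_k > 1:
            # variance reduction before the per-bin simplex solve; the
            # transfer fit applies the same kernel to its model curves
            density = mt.moving_average(density, params.density_smooth_k)
        corrected[pol] = fr.rescale_to_canonical(
            density, pol, params.rates, params.primer_fraction, params.distal_flank
        )
    results.corrected = corrected
    by_strand = fr.solve_fractions(corrected, params.rates)
    results.fractions_by_strand = by_strand
    if params.symmetry_axis_override is not None:
        axis = float(params.symmetry_axis_override)
    else:
        # estimate on the central window: distal flanks are symmetric on
        # average and would contribute only noise to the criterion
        centers_all = by_strand["same"].bin_centers
        core = (centers_all >= params.fit_window[0]) & (centers_all <= params.fit_window[1])
        axis = fr.estimate_symmetry_axis(
            by_strand["same"].stack()[:, core],
            by_strand["opposite"].stack()[:, core],
            centers=centers_all[core],
        )
    results.symmetry_axis_bp = axis
    averaged = fr.reflect_and_average(by_strand["same"], by_strand["opposite"], axis)
    results.fractions_averaged = averaged
    results.delta_excess = fr.subtract_canonical_lagging(averaged, params.distal_flank)
    # transfer-model fit on the fit window, weighted by total corrected density
    centers = averaged.bin_centers
    lo, hi = params.fit_window
    sel = (centers >= lo) & (centers <= hi)
    weight_total = sum(
        c.profile.same + c.profile.opposite for c in corrected.values()
    )
    model = TransferModel(
        offsets=centers[sel],
        f_alpha=averaged.f_alpha[sel],
        f_delta=averaged.f_delta[sel],
        f_epsilon=averaged.f_epsilon[sel],
        weights=weight_total[sel],
        ell_alpha=params.primer_length,
        lagging_alpha_fraction=params.primer_fraction,
        priming=params.priming,
        smooth_k=params.density_smooth_k,
    )
    results.transfer = model.fit()
    return results
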