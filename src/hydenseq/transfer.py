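"""Regression model of polymerase hand-offs at replication origins.

The strand-averaged fraction-of-synthesis profiles are described by a
generative model of one oriented fork family.  A Pol alpha primer of fixed
length ``ell_alpha`` starts leading-strand synthesis at a random offset X;
Pol delta extends it for a random tract length L; Pol epsilon synthesizes
the rest.  Offsets upstream of X belong to the mirrored fork's lagging
strand, where the canonical Okazaki division of labor holds (a fixed Pol
alpha fraction, the rest Pol delta).  With X ~ Normal(mu_alpha, sigma_alpha)
(or, in the geometric-priming variant, X measured back from an ssDNA
exposure point with a per-bp priming probability p_prime) and
L ~ Normal(mu_delta, sigma_delta) truncated at zero, the expected fractions
at offset x are

    f_alpha(x)   = P(X > x) * c_alpha + P(X <= x < X + ell)
    f_delta(x)   = P(X > x) * (1 - c_alpha) + P(X + ell <= x < X + ell + L)
    f_epsilon(x) = P(x >= X + ell + L)

computed by 1-bp quadrature over the priming-position distribution.  The
densities of X + ell and X + ell + L are the alpha->delta and delta->epsilon
transfer-event densities; their modes are the most frequent hand-off
positions, and mu_delta is the most frequent origin Pol delta tract length.

The model is fitted to measured fractions by weighted least squares with
box bounds and a fixed multi-start schedule, statsmodels-style:
``TransferModel(...).fit()`` returns a :class:`TransferResults` with the
estimates, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_PRIMER_LENGTH = 15
DEFAULT_LAGGING_ALPHA_FRACTION = 15.0 / 165.0


@dataclass
class TransferFit:
    """Parameters of the hand-off model (the fit's estimand)."""

    mu_alpha: float
    sigma_alpha: float
    mu_delta: float
    sigma_delta: float
    ell_alpha: int = DEFAULT_PRIMER_LENGTH
    p_prime: float | None = None  # set in the geometric-priming variant
    priming: str = "gaussian_start"
    rss: float | None = None
    mode_alpha_delta: float | None = None
    mode_delta_epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_alpha < 0 or self.sigma_delta < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.mu_delta < 0:
            raise ValueError("mean tract length must be non-negative")
        if self.p_prime is not None and not (0.0 < self.p_prime < 1.0):
            raise ValueError("p_prime must be in (0, 1)")


@dataclass
class ModelCurves:
    """Predicted fractions on the data grid and transfer densities (1-bp axis)."""

    grid: np.ndarray
    f_alpha: np.ndarray
    f_delta: np.ndarray
    f_epsilon: np.ndarray
    transfer_axis: np.ndarray
    density_alpha_delta: np.ndarray
    density_delta_epsilon: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset_bp": self.grid,
                "f_alpha": self.f_alpha,
                "f_delta": self.f_delta,
                "f_epsilon": self.f_epsilon,
            }
        )


def _priming_pmf(fit: TransferFit, axis: np.ndarray) -> np.ndarray:
    """P(u <= X < u+1) on the integer axis for either priming variant."""
    if fit.priming == "gaussian_start":
        if fit.sigma_alpha < 1e-6:
            pmf = np.zeros(len(axis))
            idx = np.searchsorted(axis, round(fit.mu_alpha))
            pmf[min(idx, len(axis) - 1)] = 1.0
            return pmf
        upper = stats.norm.cdf(axis + 1, fit.mu_alpha, fit.sigma_alpha)
        lower = stats.norm.cdf(axis, fit.mu_alpha, fit.sigma_alpha)
        return upper - lower
    if fit.priming == "geometric":
        if fit.p_prime is None:
            raise ValueError("geometric priming requires p_prime")
        # X = x0 - G with G ~ Geometric(p) on {0,1,...}: the priming density
        # decays by p per bp moving upstream of the exposure point x0.
        x0 = round(fit.mu_alpha)
        g = x0 - axis
        pmf = np.where(g >= 0, fit.p_prime * (1 - fit.p_prime) ** np.maximum(g, 0), 0.0)
        return pmf
    raise ValueError(f"unknown priming mode {fit.priming!r}")


def _tract_pmf_survival(fit: TransferFit, tmax: int) -> tuple[np.ndarray, np.ndarray]:
    """(pmf, survival) of the truncated-at-zero tract length on t = 0..tmax."""
    t = np.arange(tmax + 1)
    if fit.sigma_delta < 1e-6:
        pmf = np.zeros(tmax + 1)
        pmf[min(int(round(fit.mu_delta)), tmax)] = 1.0
    else:
        z0 = stats.norm.cdf(0, fit.mu_delta, fit.sigma_delta)
        norm = 1.0 - z0
        upper = stats.norm.cdf(t + 1, fit.mu_delta, fit.sigma_delta)
        lower = stats.norm.cdf(t, fit.mu_delta, fit.sigma_delta)
        pmf = (upper - lower) / norm
        pmf[-1] += max(0.0, 1.0 - pmf.sum())  # fold far tail into the last cell
    survival = 1.0 - np.cumsum(pmf) + pmf  # P(L >= t)
    return pmf, survival


def predict_curves(
    fit: TransferFit,
    grid: np.ndarray,
    lagging_alpha_fraction: float = DEFAULT_LAGGING_ALPHA_FRACTION,
) -> ModelCurves:
    """Expected fraction curves and transfer densities for one parameter set.

    Quadrature is on a 1-bp integer axis padded well beyond the data grid on
    both sides; values are interpolated back onto ``grid``.
    """
    grid = np.asarray(grid, dtype=float)
    if fit.priming == "geometric":
        # cover enough upstream tail of the geometric priming distribution
        pad = int(min(12.0 / max(fit.p_prime or 1e-3, 1e-5), 30_000))
    else:
        pad = int(6 * max(fit.sigma_alpha, 1.0))
    lo = int(np.floor(min(grid[0], fit.mu_alpha - pad))) - 2
    hi = int(np.ceil(max(grid[-1], fit.mu_alpha + fit.ell_alpha + fit.mu_delta
                         + 6 * max(fit.sigma_delta, 1.0)))) + 2
    axis = np.arange(lo, hi + 1)
    w = _priming_pmf(fit, axis)
    total = w.sum()
    if total <= 0:
        raise ValueError("priming distribution has no mass on the quadrature axis")
    w = w / total
    cdf = np.cumsum(w)  # P(X <= u) at integer u
    p_lag = 1.0 - cdf
    ell = fit.ell_alpha
    # alpha coverage: P(x - ell < X <= x)
    cdf_shift = np.concatenate([np.zeros(ell), cdf[:-ell]]) if ell > 0 else cdf
    a_cov = cdf - cdf_shift
    tmax = int(fit.mu_delta + 8 * max(fit.sigma_delta, 1.0)) + 2
    tract_pmf, tract_surv = _tract_pmf_survival(fit, tmax)
    # delta coverage: sum_u w(u) P(L > x - u - ell) for u <= x - ell
    strict_surv = tract_surv - tract_pmf  # P(L > t)
    conv = np.convolve(w, strict_surv)
    d_cov = np.zeros(len(axis))
    # conv index i corresponds to offset axis[0] + ell + i on the x axis
    for_i = np.arange(len(conv))
    target = for_i + ell
    valid = target < len(axis)
    d_cov[target[valid]] = conv[valid]
    # clip float roundoff before forming the partition
    p_lag, a_cov, d_cov = (np.clip(v, 0.0, 1.0) for v in (p_lag, a_cov, d_cov))
    f_eps = np.clip(1.0 - p_lag - a_cov - d_cov, 0.0, 1.0)
    f_alpha = p_lag * lagging_alpha_fraction + a_cov
    f_delta = p_lag * (1.0 - lagging_alpha_fraction) + d_cov
    # exact partition of unity on the quadrature axis
    total_f = f_alpha + f_delta + f_eps
    f_alpha, f_delta, f_eps = f_alpha / total_f, f_delta / total_f, f_eps / total_f
    # transfer densities on the 1-bp axis
    dens_ad = np.zeros(len(axis))
    if ell > 0:
        dens_ad[ell:] = w[:-ell]
    else:
        dens_ad = w.copy()
    conv_de = np.convolve(w, tract_pmf)
    dens_de = np.zeros(len(axis))
    dens_de[target[valid]] = conv_de[valid]
    return ModelCurves(
        grid=grid,
        f_alpha=np.interp(grid, axis, f_alpha),
        f_delta=np.interp(grid, axis, f_delta),
        f_epsilon=np.interp(grid, axis, f_eps),
        transfer_axis=axis,
        density_alpha_delta=dens_ad,
        density_delta_epsilon=dens_de,
    )


def _density_mode(axis: np.ndarray, density: np.ndarray) -> float:
    """Grid argmax; ties resolved toward the smallest offset."""
    return float(axis[int(np.argmax(density))])


class TransferModel:
    """Hand-off regression model over measured synthesis fractions.

    Parameters
    ----------
    offsets : bin-center offsets (bp) of the measured profile.
    f_alpha, f_delta, f_epsilon : measured strand-averaged fractions.
    weights : per-bin weights, typically the total corrected end density
        (a heteroskedasticity proxy); uniform when omitted.
    priming : "gaussian_start" or "geometric".
    delta_is_excess : set when the supplied f_delta already has the canonical
        lagging component removed; the model then predicts the excess.
    smooth_k : when the measured fractions were boxcar-smoothed over k bins,
        pass the same k so model curves are smoothed identically before the
        residual is formed.
    """

    def __init__(
        self,
        offsets: np.ndarray,
        f_alpha: np.ndarray,
        f_delta: np.ndarray,
        f_epsilon: np.ndarray,
        weights: np.ndarray | None = None,
        ell_alpha: int = DEFAULT_PRIMER_LENGTH,
        lagging_alpha_fraction: float = DEFAULT_LAGGING_ALPHA_FRACTION,
        priming: str = "gaussian_start",
        delta_is_excess: bool = False,
        smooth_k: int = 1,
    ):
        self.offsets = np.asarray(offsets, dtype=float)
        self.data = np.vstack([f_alpha, f_delta, f_epsilon]).astype(float)
        if weights is None:
            weights = np.ones_like(self.offsets)
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        self.weights = w / w.mean()
        self.ell_alpha = int(ell_alpha)
        self.lagging_alpha_fraction = float(lagging_alpha_fraction)
        self.priming = priming
        self.delta_is_excess = bool(delta_is_excess)
        self.smooth_k = int(smooth_k)

    @classmethod
    def from_fraction_profile(cls, profile, weights=None, **kwargs) -> "TransferModel":
        return cls(
            offsets=profile.bin_centers,
            f_alpha=profile.f_alpha,
            f_delta=profile.f_delta,
            f_epsilon=profile.f_epsilon,
            weights=weights,
            **kwargs,
        )

    # -- parameter vector <-> TransferFit ---------------------------------
    def _make_fit(self, theta: np.ndarray) -> TransferFit:
        if self.priming == "gaussian_start":
            mu_a, sig_a, mu_d, sig_d = theta
            return TransferFit(mu_a, sig_a, mu_d, sig_d, self.ell_alpha,
                               priming=self.priming)
        x0, log10_p, mu_d, sig_d = theta
        return TransferFit(x0, 0.0, mu_d, sig_d, self.ell_alpha,
                           p_prime=10.0 ** log10_p, priming=self.priming)

    def _default_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo_x, hi_x = self.offsets[0], self.offsets[-1]
        if self.priming == "gaussian_start":
            return (np.array([lo_x, 1.0, 0.0, 0.1]),
                    np.array([hi_x, 200.0, 500.0, 100.0]))
        return (np.array([lo_x, -4.5, 0.0, 0.1]),
                np.array([hi_x, -0.5, 500.0, 100.0]))

    def _model_curves(self, fit: TransferFit) -> np.ndarray:
        curves = predict_curves(fit, self.offsets, self.lagging_alpha_fraction)
        stack = np.vstack([curves.f_alpha, curves.f_delta, curves.f_epsilon])
        if self.delta_is_excess:
            base = 1.0 - (curves.f_alpha + curves.f_epsilon)
            canonical = 1.0 - self.lagging_alpha_fraction
            stack[1] = np.clip(base - canonical, 0.0, None)
        if self.smooth_k > 1:
            from .meta import _centered_moving_average

            stack = np.vstack(
                [_centered_moving_average(row, self.smooth_k) for row in stack]
            )
        return stack

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        model = self._model_curves(self._make_fit(theta))
        return (np.sqrt(self.weights) * (model - self.data)).ravel()

    def fit(
        self,
        starts: Sequence[np.ndarray] | None = None,
        bounds: tuple[np.ndarray, np.ndarray] | None = None,
        n_starts: int = 5,
        seed: int = 1234,
    ) -> "TransferResults":
        """Weighted least squares across the three curves jointly.

        Multi-start with a fixed seeded schedule inside the box bounds;
        the best converged start wins.  Raises on all-start failure.
        """
        lo, hi = bounds if bounds is not None else self._default_bounds()
        if starts is None:
            rng = np.random.default_rng(seed)
            center = self._heuristic_start(lo, hi)
            starts = [center]
            for _ in range(n_starts - 1):
                starts.append(lo + (hi - lo) * rng.uniform(0.15, 0.85, size=len(lo)))
        attempts = []
        for x0 in starts:
            x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
            try:
                res = optimize.least_squares(
                    self._residuals, x0, bounds=(lo, hi), method="trf",
                    xtol=1e-9, ftol=1e-10, max_nfev=800,
                )
                attempts.append(res)
            except Exception as exc:  # pragma: no cover - optimizer edge cases
                attempts.append(exc)
        # accept budget-limited runs too (status 0): with a numerical
        # jacobian they are routinely parameter-converged at the bound
        ok = [
            r for r in attempts
            if isinstance(r, optimize.OptimizeResult) and np.isfinite(r.cost)
            and (r.success or r.status == 0)
        ]
        if not ok:
            trace = "; ".join(str(a) for a in attempts)
            raise RuntimeError(f"transfer-model fit failed on all starts: {trace}")
        best = min(ok, key=lambda r: r.cost)
        fit = self._make_fit(best.x)
        fit.rss = float(2 * best.cost)
        curves = predict_curves(fit, self.offsets, self.lagging_alpha_fraction)
        fit.mode_alpha_delta = _density_mode(curves.transfer_axis, curves.density_alpha_delta)
        fit.mode_delta_epsilon = _density_mode(curves.transfer_axis, curves.density_delta_epsilon)
        degenerate = bool(fit.mu_delta <= lo[2] + 0.5)
        return TransferResults(
            model=self, fit=fit, curves=curves,
            starts_tried=len(starts),
            start_costs=[float(2 * r.cost) if isinstance(r, optimize.OptimizeResult) else np.inf
                         for r in attempts],
            degenerate_delta_tract=degenerate,
        )

    def _heuristic_start(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """Data-driven first start: alpha peak position and epsilon rise."""
        alpha_peak = self.offsets[int(np.argmax(self.data[0]))]
        eps = self.data[2]
        half = (eps.min() + eps.max()) / 2.0
        above = np.flatnonzero(eps >= half)
        eps_rise = self.offsets[above[0]] if above.size else self.offsets[len(self.offsets) // 2]
        mu_d0 = max(10.0, eps_rise - alpha_peak - self.ell_alpha)
        if self.priming == "gaussian_start":
            theta = np.array([alpha_peak - self.ell_alpha / 2.0, 25.0, mu_d0, 10.0])
        else:
            theta = np.array([alpha_peak, -3.0, mu_d0, 10.0])
        return np.clip(theta, lo, hi)


@dataclass
class TransferResults:
    """Fitted hand-off model: estimates, curves and diagnostics."""

    model: TransferModel
    fit: TransferFit
    curves: ModelCurves
    starts_tried: int
    start_costs: list[float]
    degenerate_delta_tract: bool = False

    @property
    def params(self) -> dict[str, float]:
        out = {
            "mu_alpha": self.fit.mu_alpha,
            "sigma_alpha": self.fit.sigma_alpha,
            "mu_delta": self.fit.mu_delta,
            "sigma_delta": self.fit.sigma_delta,
            "ell_alpha": float(self.fit.ell_alpha),
        }
        if self.fit.p_prime is not None:
            out["p_prime"] = self.fit.p_prime
        return out

    @property
    def rss(self) -> float:
        return self.fit.rss

    def predict(self, grid: np.ndarray | None = None) -> ModelCurves:
        grid = self.model.offsets if grid is None else np.asarray(grid, dtype=float)
        return predict_curves(self.fit, grid, self.model.lagging_alpha_fraction)

    def summary(self) -> str:
        rows = [
            ("priming model", self.fit.priming),
            ("mu_alpha (bp)", f"{self.fit.mu_alpha:.1f}"),
            ("sigma_alpha (bp)", f"{self.fit.sigma_alpha:.1f}"),
            ("ell_alpha (bp, fixed)", f"{self.fit.ell_alpha}"),
            ("mu_delta (bp)", f"{self.fit.mu_delta:.1f}"),
            ("sigma_delta (bp)", f"{self.fit.sigma_delta:.1f}"),
            ("alpha->delta mode (bp)", f"{self.fit.mode_alpha_delta:.1f}"),
            ("delta->epsilon mode (bp)", f"{self.fit.mode_delta_epsilon:.1f}"),
            ("rss", f"{self.fit.rss:.4g}"),
            ("starts tried", f"{self.starts_tried}"),
            ("degenerate delta tract", str(self.degenerate_delta_tract)),
        ]
        if self.fit.p_prime is not None:
            rows.insert(4, ("p_prime (%/bp)", f"{100 * self.fit.p_prime:.3f}"))
        width = max(len(k) for k, _ in rows)
        lines = ["Transfer-tract model fit", "=" * 40]
        lines += [f"{k.ljust(width)}  {v}" for k, v in rows]
        return "\n".join(lines)


def summarize_transfers(results: TransferResults) -> dict[str, float | None]:
    """Modal hand-off positions and most-frequent tract lengths."""
    fit = results.fit
    out = {
        "mode_alpha_delta_bp": fit.mode_alpha_delta,
        "mode_delta_epsilon_bp": fit.mode_delta_epsilon,
        "most_frequent_alpha_tract_bp": float(fit.ell_alpha),
        "most_frequent_delta_tract_bp": float(
            fit.mode_delta_epsilon - fit.mode_alpha_delta
        ),
        "p_prime_percent_per_bp": 100.0 * fit.p_prime if fit.p_prime is not None else None,
    }
    return out
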