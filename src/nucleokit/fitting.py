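"""Fitting the nucleation free-energy form to empirical curves.

The model ``dG(n) = a*n^(2/3) - b*n + c`` is linear in the basis
``{n^(2/3), n, 1}``; the free intercept absorbs the histogram
normalization and bin-width constant, leaving ``a`` and ``b`` (and hence
the critical radius and barrier) invariant to those conventions.

Also provides the two diagnostics used before the full fit: the low-n
log-log asymptote (slope 2/3 indicating a surface-dominated regime) and
the surface-subtracted residual (linear in n with a sign that separates
sub- from super-saturation), plus the self-consistent choice of the upper
fitting limit at 80% of the fitted critical size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial.legendre import leggauss

from .distribution import FreeEnergyCurve, SizeDistribution, empirical_free_energy
from .errors import ConvergenceError, FitError, ParameterError, RangeCollapseError
from .thermo import critical_point

__all__ = [
    "FreeEnergyFit",
    "fit_free_energy",
    "fit_distribution",
    "fit_surface_asymptote",
    "subtract_surface",
    "self_consistent_fit",
    "ASYMPTOTE_N_MAX",
    "ASYMPTOTE_BIN_WIDTH",
]

logger = logging.getLogger(__name__)

ASYMPTOTE_N_MAX = 2e5
ASYMPTOTE_BIN_WIDTH = 5e3


@dataclass(frozen=True)
class FreeEnergyFit:
    """Result of the linear fit of dG on {n^(2/3), n, 1}.

    ``b`` is reported in the ``dG = a*n^(2/3) - b*n`` sign convention:
    positive for a super-saturated (condensing) system, negative for a
    sub-saturated one.
    """

    a: float
    b: float
    intercept: float
    sem_a: float
    sem_b: float
    cov_ab: float  # covariance of (a, b) in the reported sign convention
    n_lo: float
    n_hi: float
    n_bins: int
    iterations: int = 1
    history: tuple = ()

    @property
    def saturation_class(self) -> str:
        return "super" if self.b > 0 else "sub"

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "intercept": self.intercept,
            "sem_a": self.sem_a, "sem_b": self.sem_b, "cov_ab": self.cov_ab,
            "n_lo": self.n_lo, "n_hi": self.n_hi, "n_bins": self.n_bins,
            "iterations": self.iterations,
            "saturation_class": self.saturation_class,
        }


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares with coefficient covariance sigma^2 (X'X)^-1."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("rank-deficient design matrix (fitting range too narrow)")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, cov


def fit_free_energy(curve: FreeEnergyCurve, n_lo: float | None = None,
                    n_hi: float | None = None) -> FreeEnergyFit:
    """OLS fit of the curve to ``a*n^(2/3) - b*n + c`` on [n_lo, n_hi]."""
    n_lo = float(curve.n.min()) if n_lo is None else n_lo
    n_hi = float(curve.n.max()) if n_hi is None else n_hi
    if n_lo >= n_hi:
        raise ParameterError(f"empty fit range [{n_lo:g}, {n_hi:g}]")
    mask = (curve.n >= n_lo) & (curve.n <= n_hi)
    n = curve.n[mask]
    y = curve.dG[mask]
    if len(n) < 6:
        raise FitError(f"need >= 6 occupied bins in range, got {len(n)}")
    X = np.column_stack([n ** (2.0 / 3.0), n, np.ones_like(n)])
    beta, cov = _ols(X, y)
    # model coefficient of n is -b in the reported convention
    return FreeEnergyFit(
        a=float(beta[0]), b=float(-beta[1]), intercept=float(beta[2]),
        sem_a=float(np.sqrt(max(cov[0, 0], 0.0))),
        sem_b=float(np.sqrt(max(cov[1, 1], 0.0))),
        cov_ab=float(-cov[0, 1]),
        n_lo=n_lo, n_hi=n_hi, n_bins=len(n),
    )


_GL_NODES, _GL_WEIGHTS = leggauss(16)


def _bin_log_ratio(edges_lo, edges_hi, a, b):
    """log of (bin integral of e^-dG) / (midpoint density * bin width)."""
    c = 0.5 * (edges_lo + edges_hi)
    h = 0.5 * (edges_hi - edges_lo)
    nodes = c[:, None] + h[:, None] * _GL_NODES[None, :]
    dg_c = a * c ** (2.0 / 3.0) - b * c
    rel = np.exp(-((a * nodes ** (2.0 / 3.0) - b * nodes) - dg_c[:, None]))
    integral_over_midpoint = (rel * _GL_WEIGHTS[None, :]).sum(axis=1) / 2.0
    return np.log(integral_over_midpoint)


def fit_distribution(dist: SizeDistribution, n_lo: float | None = None,
                     n_hi: float | None = None, method: str = "poisson") -> FreeEnergyFit:
    """Fit the free-energy model directly to a binned size distribution.

    ``method="poisson"`` (default): maximum-likelihood Poisson regression
    of the per-bin counts on ``{n^(2/3), n, 1}`` — empty bins carry
    information, which removes the low-count bias that masking them
    induces in the -ln P curve, and makes the fitted parameters nearly
    independent of the bin width.  The midpoint density is refined to the
    exact bin integral by an iterated offset.

    ``method="ols"`` / ``"wls"``: least squares on the empirical -ln P
    curve over occupied bins, unweighted or weighted by counts.
    """
    if method not in ("poisson", "ols", "wls"):
        raise ParameterError("method must be 'poisson', 'ols' or 'wls'")
    centers = dist.bin_centers
    n_lo = float(centers[dist.occupied].min()) if n_lo is None else n_lo
    n_hi = float(centers[dist.occupied].max()) if n_hi is None else n_hi
    if n_lo >= n_hi:
        raise ParameterError(f"empty fit range [{n_lo:g}, {n_hi:g}]")
    mask = (centers >= n_lo) & (centers <= n_hi)
    n_occ = int((dist.counts[mask] > 0).sum())
    if n_occ < 6:
        raise FitError(f"need >= 6 occupied bins in range, got {n_occ}")

    if method in ("ols", "wls"):
        occ = mask & dist.occupied
        n = centers[occ]
        y = -np.log(dist.P[occ])
        X = np.column_stack([n ** (2.0 / 3.0), n, np.ones_like(n)])
        if method == "wls":
            w = np.sqrt(dist.counts[occ].astype(float))
            beta, cov = _ols(X * w[:, None], y * w)
        else:
            beta, cov = _ols(X, y)
        return FreeEnergyFit(
            a=float(beta[0]), b=float(-beta[1]), intercept=float(beta[2]),
            sem_a=float(np.sqrt(max(cov[0, 0], 0.0))),
            sem_b=float(np.sqrt(max(cov[1, 1], 0.0))),
            cov_ab=float(-cov[0, 1]),
            n_lo=n_lo, n_hi=n_hi, n_bins=n_occ)

    import statsmodels.api as sm

    counts = dist.counts[mask]
    n = centers[mask]
    lo, hi = dist.bin_edges[:-1][mask], dist.bin_edges[1:][mask]
    # log mu = intercept - a*n^(2/3) + b*n (+ bin-shape offset)
    X = np.column_stack([-(n ** (2.0 / 3.0)), n, np.ones_like(n)])
    offset = np.zeros(len(n))
    a_prev = None
    res = None
    for _ in range(8):
        try:
            res = sm.GLM(counts, X, family=sm.families.Poisson(),
                         offset=offset).fit()
        except Exception as exc:  # perfect separation, singularities
            raise FitError(f"Poisson regression failed: {exc}") from exc
        a_hat, b_hat = float(res.params[0]), float(res.params[1])
        if a_prev is not None and abs(a_hat - a_prev) < 1e-12 * max(abs(a_hat), 1e-300):
            break
        a_prev = a_hat
        offset = _bin_log_ratio(lo, hi, a_hat, b_hat)
    cov = np.asarray(res.cov_params())
    return FreeEnergyFit(
        a=a_hat, b=b_hat, intercept=float(res.params[2]),
        sem_a=float(np.sqrt(max(cov[0, 0], 0.0))),
        sem_b=float(np.sqrt(max(cov[1, 1], 0.0))),
        cov_ab=float(cov[0, 1]),
        n_lo=n_lo, n_hi=n_hi, n_bins=n_occ)


def fit_surface_asymptote(curve: FreeEnergyCurve,
                          n_max: float = ASYMPTOTE_N_MAX):
    """Low-n diagnostics: log-log slope gamma1 and surface coefficient.

    ``gamma1`` is the OLS slope of ln(dG) vs ln(n) over occupied bins with
    ``n < n_max`` (a pure ``a*n^(2/3)`` regime gives exactly 2/3);
    ``a_est`` is the no-intercept OLS coefficient of ``dG ~ a * n^(2/3)``
    on the same range.  Non-positive dG values (offset not applied, or
    noise) are excluded with a warning.

    Returns ``(a_est, gamma1, sem_gamma1)``.
    """
    mask = curve.n < n_max
    n = curve.n[mask]
    y = curve.dG[mask]
    pos = y > 0
    if np.any(~pos):
        logger.warning("fit_surface_asymptote: excluding %d non-positive dG values",
                       int((~pos).sum()))
        n, y = n[pos], y[pos]
    if len(n) < 5:
        raise FitError(f"need >= 5 usable bins below n_max={n_max:g}, got {len(n)}")
    X = np.column_stack([np.log(n), np.ones(len(n))])
    beta, cov = _ols(X, np.log(y))
    gamma1 = float(beta[0])
    sem_gamma1 = float(np.sqrt(max(cov[0, 0], 0.0)))
    x23 = n ** (2.0 / 3.0)
    a_est = float((x23 @ y) / (x23 @ x23))
    return a_est, gamma1, sem_gamma1


def subtract_surface(curve: FreeEnergyCurve, a: float):
    """Residual after removing the surface term: r(n) = dG(n) - a*n^(2/3).

    Returns ``(residual, gamma2, slope, sem_slope)`` where ``gamma2`` is
    the log-log slope of |r| vs n (1 for a purely volumetric residual) and
    ``slope`` is the signed OLS slope of r vs n (negative for the
    super-saturated ``-b*n`` branch, positive for sub-saturated).
    """
    if a <= 0:
        raise ParameterError(f"surface coefficient must be positive, got {a}")
    r = curve.dG - a * curve.n ** (2.0 / 3.0)
    floor = 1e-12 * max(1.0, float(np.abs(curve.dG).max()))
    usable = np.abs(r) > floor
    if usable.sum() < 2:
        raise FitError("residuals are all within the noise floor; gamma2 undefined")
    Xg = np.column_stack([np.log(curve.n[usable]), np.ones(int(usable.sum()))])
    beta_g, _ = _ols(Xg, np.log(np.abs(r[usable])))
    gamma2 = float(beta_g[0])
    Xs = np.column_stack([curve.n, np.ones(len(curve.n))])
    beta_s, cov_s = _ols(Xs, r)
    return r, gamma2, float(beta_s[0]), float(np.sqrt(max(cov_s[0, 0], 0.0)))


def self_consistent_fit(source: SizeDistribution | FreeEnergyCurve,
                        fit_fraction: float = 0.8,
                        cut_variable: str = "n",
                        tol: float = 0.01,
                        max_iter: int = 50,
                        method: str = "poisson") -> FreeEnergyFit:
    """Fit with the upper range chosen self-consistently from the fit.

    Iterates: fit on ``[n_lo, n_hi]``; compute ``n_c`` from the fit; set
    ``n_hi`` to 80% of the critical size (``fit_fraction * n_c`` when
    cutting in ``n``; ``(fit_fraction * R_c)**3 = fit_fraction**3 * n_c``
    when cutting in ``R``) — until the relative change in ``n_c`` drops
    below ``tol``.  A fit landing on the sub-saturated branch (no critical
    size) returns the full-range fit unchanged.

    A :class:`SizeDistribution` source is fit with
    :func:`fit_distribution` (``method`` as given); a bare curve with the
    OLS :func:`fit_free_energy`.
    """
    if cut_variable not in ("n", "R"):
        raise ParameterError("cut_variable must be 'n' or 'R'")
    frac = fit_fraction if cut_variable == "n" else fit_fraction**3
    if isinstance(source, SizeDistribution):
        occ_n = source.bin_centers[source.occupied]

        def fitter(lo, hi):
            return fit_distribution(source, lo, hi, method=method)
    else:
        occ_n = source.n

        def fitter(lo, hi):
            return fit_free_energy(source, lo, hi)

    n_lo = float(occ_n.min())
    n_hi = float(occ_n.max())
    if n_hi < 4.0 * n_lo:
        raise ParameterError("distribution must span at least a 4-fold range in n")
    history = []
    hi_seen: list[float] = []
    n_c_prev = None
    averaged_cycle = False
    for it in range(1, max_iter + 1):
        fit = fitter(n_lo, n_hi)
        if fit.a <= 0:
            raise FitError(f"fit produced non-positive surface coefficient a={fit.a:g}")
        cp = critical_point(fit.a, fit.b) if fit.b > 0 else None
        if cp is None:
            # sub-saturated branch: no critical size, keep the full range
            return replace(fit, iterations=it, history=tuple(history))
        n_c = cp[0]
        history.append((n_hi, fit.a, fit.b, n_c))
        converged = n_c_prev is not None and abs(n_c - n_c_prev) / n_c_prev < tol
        if converged or averaged_cycle:
            return replace(fit, iterations=it, history=tuple(history))
        n_c_prev = n_c
        new_hi = min(frac * n_c, float(occ_n.max()))
        if new_hi <= n_lo:
            raise RangeCollapseError(
                f"self-consistent upper limit {new_hi:g} fell below n_lo={n_lo:g}")
        # the map n_hi -> 0.8*n_c(n_hi) is piecewise constant in the bin
        # structure and can fall into a short cycle; resolve by averaging
        # the cycle's limits and doing one final fit
        for k, prev in enumerate(hi_seen):
            if abs(prev - new_hi) < 1e-9 * max(prev, new_hi):
                cycle = hi_seen[k:] + [new_hi]
                new_hi = float(np.mean(cycle))
                averaged_cycle = True
                logger.info("self_consistent_fit: limit cycle of length %d "
                            "detected; averaging n_hi to %.4g",
                            len(cycle) - 1, new_hi)
                break
        hi_seen.append(n_hi)
        n_hi = new_hi
    raise ConvergenceError(
        f"self-consistent fit did not converge in {max_iter} iterations",
        history=history)
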