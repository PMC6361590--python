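"""Size histograms and the empirical free-energy curve.

The cluster sizes are histogrammed with fixed-width bins starting at
``n_start``; per-bin probabilities ``P = counts/total`` give the empirical
free energy ``dG = -ln P`` (kBT units) on occupied bins.  Empty bins are
masked, never zero-logged.  The per-bin convention means the curve carries
an additive ``ln(bin width)`` term that the fit intercept absorbs; the
normalization offset utility restores the ``A = 1`` convention so the
barrier can be read directly off the curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad

from .errors import ParameterError
from .thermo import critical_point, free_energy

__all__ = [
    "SizeDistribution",
    "FreeEnergyCurve",
    "histogram_sizes",
    "empirical_free_energy",
    "normalization_constant",
    "apply_normalization_offset",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_N_START",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 3e4
DEFAULT_N_START = 1.5e4


@dataclass(frozen=True)
class SizeDistribution:
    """Fixed-width binned, normalized histogram of cluster sizes."""

    bin_edges: np.ndarray
    counts: np.ndarray
    P: np.ndarray
    total_clusters: int

    def __post_init__(self):
        occ = self.P[self.counts > 0]
        if len(occ) and abs(occ.sum() - 1.0) > 1e-12:
            raise ParameterError("per-bin probabilities must sum to 1 over occupied bins")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


@dataclass(frozen=True)
class FreeEnergyCurve:
    """Empirical dG(n) = -ln P(n) on occupied bins, in kBT units."""

    n: np.ndarray
    dG: np.ndarray
    bin_width: float
    offset: float = 0.0
    offset_applied: bool = False


def histogram_sizes(values, bin_width: float = DEFAULT_BIN_WIDTH,
                    n_start: float = DEFAULT_N_START) -> SizeDistribution:
    """Bin sizes into fixed-width bins from ``n_start``; P = counts/total."""
    values = np.asarray(values, dtype=float)
    if bin_width <= 0:
        raise ParameterError(f"bin_width must be positive, got {bin_width}")
    if len(values) == 0:
        raise ParameterError("cannot histogram an empty sample")
    if values.min() < n_start:
        raise ParameterError(
            f"values below n_start={n_start:g} present; filter upstream")
    if len(values) < 100:
        logger.warning("histogram_sizes: only %d values; bins may undersample "
                       "the distribution", len(values))
    n_bins = int(math.ceil((values.max() - n_start) / bin_width))
    n_bins = max(n_bins, 1)
    edges = n_start + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return SizeDistribution(bin_edges=edges, counts=counts,
                            P=counts / counts.sum(), total_clusters=len(values))


def empirical_free_energy(dist: SizeDistribution) -> FreeEnergyCurve:
    """dG = -ln P per occupied bin; empty bins are dropped (masked)."""
    occ = dist.occupied
    return FreeEnergyCurve(n=dist.bin_centers[occ],
                           dG=-np.log(dist.P[occ]),
                           bin_width=dist.bin_width)


def normalization_constant(a: float, b: float) -> float:
    """A = 1 / integral_0^{n_c} exp(-dG(n)) dn for the fitted (a, b).

    On the sub-saturated branch (``b <= 0``) there is no critical size;
    raises in that case (no self-consistent A=1 convention applies).
    """
    cp = critical_point(a, b)
    if cp is None:
        raise ParameterError("normalization offset requires a super-saturated fit")
    n_c = cp[0]
    val, err = quad(lambda n: math.exp(-free_energy(n, a, b)), 0.0, n_c, limit=200)
    if not np.isfinite(val) or val <= 0 or err > 1e-6 * val:
        raise ParameterError("quadrature for the normalization constant did not converge")
    return 1.0 / val


def apply_normalization_offset(curve: FreeEnergyCurve, a: float, b: float) -> FreeEnergyCurve:
    """Shift the empirical curve to the self-consistent ``A = 1`` convention.

    The per-bin probability of an occupied bin is approximately
    ``A * exp(-dG(n)) * bin_width``, so the raw curve reads
    ``dG - ln A - ln(bin_width)``.  Adding ``ln(A * bin_width)`` puts the
    empirical curve on the same footing as the fitted model with ``A = 1``,
    letting the barrier be read directly as the curve maximum.

    Applying the offset twice is a bookkeeping error and raises.
    """
    if curve.offset_applied:
        raise ParameterError("normalization offset already applied to this curve")
    A = normalization_constant(a, b)
    offset = math.log(A * curve.bin_width)
    return replace(curve, dG=curve.dG + offset, offset=offset, offset_applied=True)
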