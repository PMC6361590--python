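"""Free-energy model and derived thermodynamic quantities.

The working free energy of a cluster of size ``n`` (in units of kBT) is

    dG(n) = a * n**(2/3) - b * n

with ``a > 0`` the dimensionless surface coefficient and ``b`` the signed
bulk coefficient: ``b > 0`` describes a super-saturated system (the bulk
term lowers the free energy, producing a barrier and a critical size),
``b <= 0`` a sub-saturated one (monotonically increasing free energy, no
critical size).

The size statistic ``n`` is defined as ``(R / 1 nm)**3`` so the critical
radius in nm is simply ``n_c**(1/3)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants

from .errors import ParameterError

__all__ = [
    "free_energy",
    "critical_point",
    "barrier_height",
    "scale_transform",
    "NucleationParameters",
    "nucleation_parameters",
    "propagate_uncertainty",
    "SurfaceTensionEstimate",
    "surface_tension_bounds",
]

BOLTZMANN_J_PER_K = constants.k  # J/K


def free_energy(n, a: float, b: float):
    """dG(n) = a*n^(2/3) - b*n in kBT units; vectorized over ``n``."""
    n = np.asarray(n, dtype=float)
    return a * n ** (2.0 / 3.0) - b * n


def critical_point(a: float, b: float):
    """Critical size and radius ``(n_c, R_c_nm)``.

    ``n_c = (2a / 3b)**3`` is where dG is maximal; ``R_c = n_c**(1/3)``
    in nm under the ``n = (R/1 nm)**3`` convention.  Returns ``None`` when
    ``b <= 0`` (sub-saturated branch: no critical point exists).
    """
    if a <= 0:
        raise ParameterError(f"surface coefficient a must be positive, got {a}")
    if b <= 0:
        return None
    r_c = 2.0 * a / (3.0 * b)
    return r_c**3, r_c


def barrier_height(a: float, b: float):
    """Nucleation barrier dG(n_c) = 4 a^3 / (27 b^2) in kBT.

    Returns ``None`` when ``b <= 0`` (no barrier on the sub-saturated
    branch).
    """
    if a <= 0:
        raise ParameterError(f"surface coefficient a must be positive, got {a}")
    if b <= 0:
        return None
    return 4.0 * a**3 / (27.0 * b**2)


def scale_transform(a: float, b: float, k: float):
    """Re-express (a, b) after rescaling the size variable by a factor k.

    If the size statistic is misrepresented as n' = k * n the fitted
    coefficients become (a * k^(2/3), b * k); the barrier and the critical
    radius are invariant under this transformation.
    """
    if k <= 0:
        raise ParameterError(f"scale factor k must be positive, got {k}")
    return a * k ** (2.0 / 3.0), b * k


@dataclass(frozen=True)
class NucleationParameters:
    """Derived quantities of a super-saturated fit."""

    a: float
    b: float
    n_c: float
    R_c_nm: float
    barrier_kBT: float
    sem_Rc_nm: float = float("nan")
    sem_barrier_kBT: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "n_c": self.n_c,
            "R_c_nm": self.R_c_nm,
            "barrier_kBT": self.barrier_kBT,
            "sem_Rc_nm": self.sem_Rc_nm,
            "sem_barrier_kBT": self.sem_barrier_kBT,
        }


def nucleation_parameters(a: float, b: float) -> NucleationParameters | None:
    """Bundle n_c, R_c and the barrier; ``None`` on the sub-saturated branch."""
    cp = critical_point(a, b)
    if cp is None:
        return None
    n_c, r_c = cp
    return NucleationParameters(a=a, b=b, n_c=n_c, R_c_nm=r_c, barrier_kBT=barrier_height(a, b))


def propagate_uncertainty(a, b, sem_a, sem_b, cov_ab=0.0, monte_carlo=False,
                          n_draws=10_000, seed=0):
    """First-order (delta-method) standard errors of R_c and the barrier.

    Parameters are the fitted (a, b) with their standard errors and
    covariance.  With ``monte_carlo=True`` the errors are instead estimated
    from ``n_draws`` bivariate-normal parameter draws (draws falling on the
    sub-saturated branch are discarded).
    """
    if a <= 0 or b <= 0:
        raise ParameterError("uncertainty propagation requires a > 0 and b > 0")
    cov = np.array([[sem_a**2, cov_ab], [cov_ab, sem_b**2]], dtype=float)
    if np.any(np.linalg.eigvalsh(cov) < -1e-30 * max(sem_a, sem_b, 1.0) ** 2):
        raise ParameterError("covariance matrix is not positive semi-definite")
    if monte_carlo:
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal([a, b], cov, size=n_draws)
        ok = (draws[:, 0] > 0) & (draws[:, 1] > 0)
        da, db = draws[ok, 0], draws[ok, 1]
        r_c = 2.0 * da / (3.0 * db)
        barrier = 4.0 * da**3 / (27.0 * db**2)
        return float(np.std(r_c, ddof=1)), float(np.std(barrier, ddof=1))
    grad_rc = np.array([2.0 / (3.0 * b), -2.0 * a / (3.0 * b**2)])
    grad_barrier = np.array([12.0 * a**2 / (27.0 * b**2), -8.0 * a**3 / (27.0 * b**3)])
    var_rc = float(grad_rc @ cov @ grad_rc)
    var_barrier = float(grad_barrier @ cov @ grad_barrier)
    return math.sqrt(max(var_rc, 0.0)), math.sqrt(max(var_barrier, 0.0))


@dataclass(frozen=True)
class SurfaceTensionEstimate:
    """Bounds on the interfacial tension and labeled-molecule geometry.

    The fitted coefficient only equals the true surface coefficient
    ``a* = r1^2 sigma / (kB T)`` up to the unknown density (fixed-cell) or
    labeling fraction (live-cell) scale factor, so only bounds follow.
    """

    rho_min_per_nm3: float
    sigma_lower_N_per_m: float
    sigma_upper_live_N_per_m: float
    sigma_upper_fixed_N_per_m: float
    spacing_nm: float
    label_volume_fraction: float
    T_K: float
    r1_nm: float

    def to_dict(self) -> dict:
        return {
            "rho_min_per_nm3": self.rho_min_per_nm3,
            "sigma_lower_N_per_m": self.sigma_lower_N_per_m,
            "sigma_upper_live_N_per_m": self.sigma_upper_live_N_per_m,
            "sigma_upper_fixed_N_per_m": self.sigma_upper_fixed_N_per_m,
            "spacing_nm": self.spacing_nm,
            "label_volume_fraction": self.label_volume_fraction,
            "T_K": self.T_K,
            "r1_nm": self.r1_nm,
        }


def _sigma_from_a(a_star: float, T: float, r1_nm: float) -> float:
    """sigma = a* kB T / r1^2 in N/m, r1 converted to metres."""
    r1_m = r1_nm * 1e-9
    return a_star * BOLTZMANN_J_PER_K * T / r1_m**2


def surface_tension_bounds(a_fixed: float, a_live: float, N_c: float, R_c_nm: float,
                           T: float = 310.0, r1_nm: float = 1.0,
                           r_label_nm: float = 1.5) -> SurfaceTensionEstimate:
    """Bracket the condensate interfacial tension from both assays.

    * ``rho_min`` — labeled molecules per nm^3 at the critical size,
      ``N_c / R_c^3``; a lower bound on the total molecular density.
    * ``sigma_lower`` — assumes the maximal density of 1 molecule/nm^3 so
      ``a* >= a_fixed``.
    * ``sigma_upper_live`` — the live-cell coefficient over-counts per
      molecule, ``a* <= a_live``.
    * ``sigma_upper_fixed`` — fixed-cell coefficient de-scaled by
      ``rho_min^(2/3)``.

    Also reports the mean label spacing ``R_c / N_c^(1/3)`` and the volume
    fraction occupied by labels of radius ``r_label_nm``.
    """
    for name, v in (("a_fixed", a_fixed), ("a_live", a_live), ("N_c", N_c),
                    ("R_c_nm", R_c_nm), ("T", T), ("r1_nm", r1_nm)):
        if v <= 0:
            raise ParameterError(f"{name} must be positive, got {v}")
    rho_min = N_c / R_c_nm**3
    return SurfaceTensionEstimate(
        rho_min_per_nm3=rho_min,
        sigma_lower_N_per_m=_sigma_from_a(a_fixed, T, r1_nm),
        sigma_upper_live_N_per_m=_sigma_from_a(a_live, T, r1_nm),
        sigma_upper_fixed_N_per_m=_sigma_from_a(a_fixed / rho_min ** (2.0 / 3.0), T, r1_nm),
        spacing_nm=R_c_nm / N_c ** (1.0 / 3.0),
        label_volume_fraction=N_c * r_label_nm**3 / R_c_nm**3,
        T_K=T,
        r1_nm=r1_nm,
    )
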