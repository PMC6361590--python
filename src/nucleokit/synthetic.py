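"""Synthetic data with the statistical structure the analysis assumes.

Generates (i) cluster-size samples from the truncated Boltzmann density
``P(n) ~ exp(-dG(n))``, (ii) 2D localization maps rendering each cluster as
a uniformly labeled disc with fluorophore blinking and Gaussian
localization error, (iii) live-cell intensity tables, and (iv) intensity
traces with photobleaching and scripted merger events.

Every generator takes an explicit seed and is deterministic under it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GeometryError, InvalidRangeError, ParameterError
from .thermo import critical_point, free_energy

__all__ = [
    "GeneratorConfig",
    "LocalizationMap",
    "GroundTruthCluster",
    "IntensityTrace",
    "sample_cluster_sizes",
    "generate_localization_map",
    "generate_livecell_intensities",
    "generate_intensity_traces",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic fixed-cell experiment.

    ``a`` and ``b`` follow the sign convention of :mod:`nucleokit.thermo`:
    ``b > 0`` super-saturated (sizes sampled on ``[n_min, n_c]``),
    ``b <= 0`` sub-saturated (sizes sampled on ``[n_min, n_max]``).
    """

    a: float
    b: float
    seed: int
    n_clusters: int = 1000
    n_min: float = 1.5e4
    n_max: float | None = None  # only used on the sub-saturated branch
    field_size: float = 25_000.0  # nm
    n_background_molecules: int = 0
    blink_mean: float = 5.0  # mean localizations per molecule (geometric)
    loc_sigma: float = 20.0  # nm localization error (isotropic Gaussian)
    rho_label: float = 1e-3  # labeled molecules per unit n
    n_frames: int = 10_000

    def __post_init__(self):
        if self.a <= 0:
            raise ParameterError(f"a must be positive, got {self.a}")
        if self.n_min < 1:
            raise ParameterError(f"n_min must be >= 1, got {self.n_min}")
        if self.loc_sigma < 0:
            raise ParameterError(f"loc_sigma must be >= 0, got {self.loc_sigma}")
        if self.blink_mean < 1:
            raise ParameterError(f"blink_mean must be >= 1, got {self.blink_mean}")


@dataclass(frozen=True)
class LocalizationMap:
    """Single-cell point set: (x, y) in nm plus acquisition frame index."""

    x_nm: np.ndarray
    y_nm: np.ndarray
    frame: np.ndarray
    field_size: float
    cell_id: str = "cell_0"

    def __post_init__(self):
        if len(self.x_nm):
            if (self.x_nm.min() < 0 or self.y_nm.min() < 0
                    or self.x_nm.max() > self.field_size or self.y_nm.max() > self.field_size):
                raise GeometryError("localizations outside the field of view")

    def __len__(self) -> int:
        return len(self.x_nm)

    @property
    def points(self) -> np.ndarray:
        """(N, 2) coordinate array in nm."""
        return np.column_stack([self.x_nm, self.y_nm])


@dataclass(frozen=True)
class GroundTruthCluster:
    cluster_id: int
    x_nm: float
    y_nm: float
    R_nm: float
    n_true: float
    n_molecules: int
    n_localizations: int


@dataclass
class IntensityTrace:
    """Time series of one tracked cluster's integrated intensity."""

    trace_id: str
    t_s: np.ndarray
    intensity: np.ndarray
    corrected: np.ndarray | None = None
    label: str | None = None
    clipped: bool = False

    def __len__(self) -> int:
        return len(self.t_s)


# ---------------------------------------------------------------------------
# cluster-size sampling


def _support(cfg_a: float, cfg_b: float, n_min: float, n_max: float | None):
    """Sampling interval for the truncated Boltzmann density."""
    if cfg_b > 0:
        cp = critical_point(cfg_a, cfg_b)
        n_hi = cp[0]
        if n_min >= n_hi:
            raise InvalidRangeError(
                f"n_min={n_min:g} must lie below the critical size n_c={n_hi:g}")
        return n_min, n_hi
    if n_max is not None:
        if n_max <= n_min:
            raise InvalidRangeError(f"n_max={n_max:g} must exceed n_min={n_min:g}")
        return n_min, n_max
    # default truncation: where the density falls 30 kBT below its value
    # at n_min (unbounded support is limited in practice by observation)
    target = free_energy(n_min, cfg_a, cfg_b) + 30.0
    lo, hi = n_min, max(4.0 * n_min, 10.0)
    while free_energy(hi, cfg_a, cfg_b) < target:
        hi *= 2.0
        if hi > 1e30:  # pragma: no cover - pathological parameters
            raise InvalidRangeError("could not bracket the sub-saturated truncation")
    from scipy.optimize import brentq

    n_max_auto = brentq(lambda n: free_energy(n, cfg_a, cfg_b) - target, lo, hi)
    return n_min, n_max_auto


def _inverse_cdf_grid(a: float, b: float, n_lo: float, n_hi: float, m: int = 60_001):
    """Dense grid and normalized CDF of exp(-dG) on [n_lo, n_hi]."""
    grid = np.linspace(n_lo, n_hi, m)
    log_w = -free_energy(grid, a, b)
    log_w -= log_w.max()
    w = np.exp(log_w)
    dx = grid[1] - grid[0]
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) * 0.5 * dx)])
    cdf /= cdf[-1]
    return grid, cdf


def sample_cluster_sizes(cfg: GeneratorConfig,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw i.i.d. cluster sizes from the truncated density exp(-dG(n)).

    Super-saturated (``b > 0``): support is ``[n_min, n_c]`` — the
    sub-critical range where the Boltzmann form holds.  Sub-saturated
    (``b <= 0``): support is ``[n_min, n_max]``.

    Uses inverse-CDF sampling on a dense trapezoid-integrated grid.
    """
    if cfg.n_clusters < 0:
        raise ParameterError("n_clusters must be non-negative")
    if cfg.n_clusters == 0:
        return np.empty(0)
    n_lo, n_hi = _support(cfg.a, cfg.b, cfg.n_min, cfg.n_max)
    grid, cdf = _inverse_cdf_grid(cfg.a, cfg.b, n_lo, n_hi)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    u = rng.random(cfg.n_clusters)
    return np.interp(u, cdf, grid)


# ---------------------------------------------------------------------------
# localization-map rendering


def _blink_counts(rng: np.random.Generator, n_molecules: int, blink_mean: float) -> np.ndarray:
    # geometric on {1, 2, ...} with mean blink_mean
    if blink_mean == 1.0:
        return np.ones(n_molecules, dtype=int)
    return rng.geometric(1.0 / blink_mean, size=n_molecules)


def _render_molecules(rng, centers, blink_mean, loc_sigma):
    """Expand molecule positions into blinking localizations with error."""
    counts = _blink_counts(rng, len(centers), blink_mean)
    pts = np.repeat(centers, counts, axis=0)
    if loc_sigma > 0:
        pts = pts + rng.normal(0.0, loc_sigma, size=pts.shape)
    return pts, counts


def generate_localization_map(sizes: Sequence[float], cfg: GeneratorConfig,
                              cell_id: str = "cell_0",
                              rng: np.random.Generator | None = None):
    """Render cluster sizes into a blinking-fluorophore localization map.

    Each cluster of size ``n`` becomes ``round(rho_label * n)`` molecules
    (at least 1) placed uniformly in a disc of radius ``R = n**(1/3)`` nm
    (the cube-law count/radius relation is imposed directly); every
    molecule emits a geometric number of localizations (mean
    ``blink_mean``), each jittered by an isotropic Gaussian of sd
    ``loc_sigma``.  Background molecules are uniform over the field with
    the same blink model.

    Returns ``(LocalizationMap, list[GroundTruthCluster])``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sizes = np.asarray(sizes, dtype=float)
    if np.any(sizes < 0):
        raise ParameterError("cluster sizes must be non-negative")
    radii = sizes ** (1.0 / 3.0)
    if len(radii) and 2.0 * radii.max() > cfg.field_size:
        raise GeometryError(
            f"cluster radius {radii.max():.1f} nm does not fit in field {cfg.field_size:.0f} nm")

    xs, ys, truth = [], [], []
    for i, (n, r) in enumerate(zip(sizes, radii)):
        cx = rng.uniform(r, cfg.field_size - r)
        cy = rng.uniform(r, cfg.field_size - r)
        n_mol = max(1, int(round(cfg.rho_label * n)))
        # uniform in disc
        rr = r * np.sqrt(rng.random(n_mol))
        th = rng.uniform(0.0, 2.0 * math.pi, n_mol)
        centers = np.column_stack([cx + rr * np.cos(th), cy + rr * np.sin(th)])
        pts, _ = _render_molecules(rng, centers, cfg.blink_mean, cfg.loc_sigma)
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
        truth.append(GroundTruthCluster(
            cluster_id=i, x_nm=cx, y_nm=cy, R_nm=float(r), n_true=float(n),
            n_molecules=n_mol, n_localizations=len(pts)))

    if cfg.n_background_molecules > 0:
        centers = rng.uniform(0.0, cfg.field_size, size=(cfg.n_background_molecules, 2))
        pts, _ = _render_molecules(rng, centers, cfg.blink_mean, cfg.loc_sigma)
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])

    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
    else:
        x = np.empty(0)
        y = np.empty(0)
    x = np.clip(x, 0.0, cfg.field_size)
    y = np.clip(y, 0.0, cfg.field_size)
    frame = np.sort(rng.integers(0, cfg.n_frames, size=len(x)))
    return LocalizationMap(x_nm=x, y_nm=y, frame=frame, field_size=cfg.field_size,
                           cell_id=cell_id), truth


# ---------------------------------------------------------------------------
# live-cell generators


def generate_livecell_intensities(a: float, b: float, n_samples: int,
                                  I_single: float = 24.0, noise_cv: float = 0.0,
                                  seed: int = 0, n_min: float = 1.0,
                                  n_max: float | None = None):
    """Cluster intensity table: I = N * I_single * (1 + Gaussian(0, noise_cv)).

    ``N`` (molecules per cluster) is drawn from the same truncated
    Boltzmann density as the fixed-cell sizes, with live-cell (a, b).
    Returns ``(N, I)`` arrays.
    """
    if I_single <= 0:
        raise ParameterError(f"I_single must be positive, got {I_single}")
    if noise_cv < 0:
        raise ParameterError(f"noise_cv must be >= 0, got {noise_cv}")
    cfg = GeneratorConfig(a=a, b=b, seed=seed, n_clusters=n_samples,
                          n_min=n_min, n_max=n_max)
    rng = np.random.default_rng(seed)
    N = sample_cluster_sizes(cfg, rng=rng)
    I = N * I_single
    if noise_cv > 0:
        I = I * (1.0 + rng.normal(0.0, noise_cv, size=len(I)))
        I = np.clip(I, 0.0, None)
    return N, I


def generate_intensity_traces(trace_specs: Sequence[tuple[float, float]],
                              bleach_rate: float = 0.0, dt: float = 15.0,
                              duration: float = 360.0, noise_cv: float = 0.0,
                              I_single: float = 1.0, seed: int = 0,
                              mergers: Sequence[tuple[float, int, int]] = ()):
    """Linear-growth intensity traces with photobleaching and mergers.

    ``trace_specs`` is a sequence of ``(N0, g)`` pairs: the pre-noise
    molecule count follows ``N(t) = N0 + g*t``, observed as
    ``I = N * I_single * exp(-bleach_rate*t)`` times multiplicative noise.
    Scripted ``mergers`` are ``(t_merge, i, j)`` events: traces ``i`` and
    ``j`` end at the last time point before ``t_merge`` and a new trace
    carrying the sum of their pre-noise sizes (and summed growth rates)
    continues from ``t_merge``.

    Negative post-noise intensities are clipped at 0 and the trace flagged.
    Returns a list of :class:`IntensityTrace`.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    n_steps = duration / dt
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ParameterError("duration must be an integer multiple of dt")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 0.5 * dt, dt)

    # pre-noise molecule-count tracks, with merger bookkeeping
    tracks = [{"id": f"trace_{k}", "t0": 0.0, "N0": float(N0), "g": float(g),
               "t_end": duration}
              for k, (N0, g) in enumerate(trace_specs)]
    merged_id = len(tracks)
    for t_merge, i, j in sorted(mergers):
        ti, tj = tracks[i], tracks[j]
        if ti["t_end"] < t_merge or tj["t_end"] < t_merge:
            raise ParameterError("merger refers to a trace that already ended")
        n_i = ti["N0"] + ti["g"] * (t_merge - ti["t0"])
        n_j = tj["N0"] + tj["g"] * (t_merge - tj["t0"])
        ti["t_end"] = tj["t_end"] = t_merge - dt
        tracks.append({"id": f"trace_{merged_id}", "t0": t_merge,
                       "N0": n_i + n_j, "g": ti["g"] + tj["g"], "t_end": duration})
        merged_id += 1

    traces = []
    for tr in tracks:
        mask = (t >= tr["t0"] - 1e-9) & (t <= tr["t_end"] + 1e-9)
        tt = t[mask]
        if not len(tt):
            continue
        N = tr["N0"] + tr["g"] * (tt - tr["t0"])
        I = N * I_single * np.exp(-bleach_rate * tt)
        clipped = False
        if noise_cv > 0:
            I = I * (1.0 + rng.normal(0.0, noise_cv, size=len(I)))
            if np.any(I < 0):
                I = np.clip(I, 0.0, None)
                clipped = True
        traces.append(IntensityTrace(trace_id=tr["id"], t_s=tt, intensity=I,
                                     clipped=clipped))
    return traces
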