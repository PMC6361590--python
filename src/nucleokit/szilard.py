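"""Szilard non-equilibrium steady state: production, condensation, clearance.

A birth-death cluster population driven by the free energy
``dG(n) = a*n^(2/3) - b*n``:

* monomers are produced at rate ``J``,
* dimers nucleate from the pool at rate ``k_nuc * pool * (pool - 1) / 2``,
* clusters attach pool monomers at a surface-limited rate
  ``k_on(n) = k_att0 * n^(2/3)`` (a constant-rate alternative is
  available),
* detachment obeys detailed balance exactly,
  ``k_off(n) = k_on(n-1) * exp(dG(n) - dG(n-1))``,
* clusters at or above ``n_clear`` are eliminated at rate ``kappa`` —
  either removed from the system ("remove") or returned to the monomer
  pool ("recycle").

With clearance on, the sub-critical population keeps the Boltzmann shape
``exp(-dG)`` while super-critical clusters are suppressed: a steady-state
super-saturation.  A dense master-equation solver for the truncated chain
serves as the independent oracle for the stochastic simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError, RateModelError
from .thermo import critical_point, free_energy

__all__ = [
    "SzilardModel",
    "SzilardTrajectory",
    "build_rate_model",
    "kmc_simulate",
    "master_equation_solve",
    "washout_experiment",
]

_MAX_LOG_RATE = 500.0  # cap on |dG(n) - dG(n-1)| inside exp()


@dataclass(frozen=True)
class SzilardModel:
    a: float
    b: float
    k_att0: float = 1.0
    J: float = 0.0
    kappa: float = 0.0
    n_clear: int | None = None  # default: ceil(n_c)
    n_max: int = 100
    clearance_mode: str = "remove"
    k_nuc: float = 0.0
    attachment_mode: str = "surface"  # or "constant"

    def k_on(self, n):
        """Attachment rate of a size-n cluster (per pool-available monomer)."""
        n = np.asarray(n, dtype=float)
        if self.attachment_mode == "surface":
            return self.k_att0 * n ** (2.0 / 3.0)
        return self.k_att0 * np.ones_like(n)

    def k_off(self, n):
        """Detachment rate from detailed balance against k_on(n-1)."""
        n = np.asarray(n, dtype=float)
        ddg = free_energy(n, self.a, self.b) - free_energy(n - 1, self.a, self.b)
        return self.k_on(n - 1) * np.exp(ddg)

    @property
    def clear_threshold(self) -> int:
        if self.n_clear is not None:
            return self.n_clear
        cp = critical_point(self.a, self.b)
        if cp is None:
            return self.n_max + 1  # sub-saturated: nothing to clear
        return min(int(math.ceil(cp[0])), self.n_max)


@dataclass
class SzilardTrajectory:
    """Time-stamped population states of one simulation run.

    ``counts_t[k, n]`` is the number of clusters of size ``n`` at
    ``times[k]``; ``occupancy[n]`` is the time-integrated cluster count at
    size ``n`` (divide by ``times[-1] - times[0]`` for the mean census).
    """

    times: np.ndarray
    counts_t: np.ndarray
    pool_t: np.ndarray
    cleared_t: np.ndarray
    occupancy: np.ndarray
    produced: int
    initial_mass: int
    n_events: int

    @property
    def final_counts(self) -> np.ndarray:
        return self.counts_t[-1]

    @property
    def final_pool(self) -> int:
        return int(self.pool_t[-1])

    @property
    def final_cleared(self) -> int:
        return int(self.cleared_t[-1])

    def mass_balance(self) -> tuple[int, int]:
        """(produced + initial, in clusters + pool + cleared) — equal exactly."""
        sizes = np.arange(self.counts_t.shape[1])
        in_clusters = int(self.final_counts @ sizes)
        return self.produced + self.initial_mass, in_clusters + self.final_pool + self.final_cleared

    def supercritical_count(self, n_clear: int) -> int:
        return int(self.final_counts[n_clear:].sum())


def build_rate_model(a: float, b: float, k_att0: float = 1.0, J: float = 0.0,
                     kappa: float = 0.0, clearance_mode: str = "remove",
                     n_clear: int | None = None, n_max: int = 100,
                     k_nuc: float = 0.0,
                     attachment_mode: str = "surface") -> SzilardModel:
    """Validate parameters and rates up to ``n_max`` and build the model."""
    if a < 0:
        raise ParameterError(f"a must be non-negative, got {a}")
    for name, v in (("k_att0", k_att0), ("J", J), ("kappa", kappa), ("k_nuc", k_nuc)):
        if v < 0:
            raise ParameterError(f"{name} must be non-negative, got {v}")
    if clearance_mode not in ("remove", "recycle"):
        raise ParameterError("clearance_mode must be 'remove' or 'recycle'")
    if attachment_mode not in ("surface", "constant"):
        raise ParameterError("attachment_mode must be 'surface' or 'constant'")
    if n_max < 2:
        raise ParameterError("n_max must be >= 2")
    model = SzilardModel(a=a, b=b, k_att0=k_att0, J=J, kappa=kappa,
                         n_clear=n_clear, n_max=n_max,
                         clearance_mode=clearance_mode, k_nuc=k_nuc,
                         attachment_mode=attachment_mode)
    sizes = np.arange(2, n_max + 1)
    ddg = free_energy(sizes, a, b) - free_energy(sizes - 1, a, b)
    if np.any(np.abs(ddg) > _MAX_LOG_RATE):
        worst = sizes[int(np.argmax(np.abs(ddg)))]
        raise RateModelError(
            f"free-energy step at n={worst} overflows exp(); rescale parameters")
    if not np.all(np.isfinite(model.k_off(sizes))):
        raise RateModelError("non-finite detachment rate in state space")
    return model


def kmc_simulate(model: SzilardModel, t_max: float, seed: int = 0,
                 initial_pool: int = 0,
                 initial_counts: np.ndarray | None = None,
                 max_events: int = 5_000_000,
                 n_snapshots: int = 200,
                 t_burn: float = 0.0) -> SzilardTrajectory:
    """Exact event-driven (Gillespie) simulation of the cluster population.

    The state is the monomer pool plus per-size cluster counts for sizes
    ``2..n_max`` (attachment at ``n_max`` is suppressed: reflecting
    truncation).  A size-2 detachment dissolves the cluster back into two
    pool monomers.  ``occupancy`` accumulates time-weighted counts only
    after ``t_burn``, so the stationary census can be read without the
    transient.
    """
    rng = np.random.default_rng(seed)
    nm = model.n_max
    sizes = np.arange(nm + 1)  # index = cluster size; 0,1 unused
    counts = np.zeros(nm + 1, dtype=np.int64)
    if initial_counts is not None:
        initial_counts = np.asarray(initial_counts, dtype=np.int64)
        counts[: len(initial_counts)] = initial_counts
        counts[:2] = 0
    pool = int(initial_pool)
    initial_mass = pool + int(counts @ sizes)

    kon = model.k_on(sizes)
    kon[:2] = 0.0
    kon[nm] = 0.0  # reflecting at the truncation boundary
    koff = np.zeros(nm + 1)
    koff[2:] = model.k_off(sizes[2:])
    clear_mask = np.zeros(nm + 1)
    clear_mask[model.clear_threshold:] = model.kappa

    t = 0.0
    produced = 0
    cleared = 0
    n_events = 0
    occupancy = np.zeros(nm + 1)

    snap_every = t_max / max(n_snapshots, 1)
    next_snap = 0.0
    times, counts_t, pool_t, cleared_t = [], [], [], []

    def snapshot(at):
        times.append(at)
        counts_t.append(counts.copy())
        pool_t.append(pool)
        cleared_t.append(cleared)

    while True:
        r_attach = kon * counts if pool >= 1 else np.zeros(nm + 1)
        r_detach = koff * counts
        r_clear = clear_mask * counts
        r_prod = model.J
        r_nuc = model.k_nuc * pool * (pool - 1) / 2.0 if pool >= 2 else 0.0
        total = r_attach.sum() + r_detach.sum() + r_clear.sum() + r_prod + r_nuc
        t_next = t_max if total <= 0.0 else t + rng.exponential(1.0 / total)

        # the state is constant on [t, t_next): flush snapshots, accumulate
        while next_snap < min(t_next, t_max) - 1e-12:
            snapshot(next_snap)
            next_snap += snap_every
        horizon = min(t_next, t_max)
        if horizon > t_burn:
            occupancy += counts * (horizon - max(t, t_burn))
        if total <= 0.0 or t_next >= t_max:
            t = t_max
            break
        t = t_next

        u = rng.random() * total
        if u < r_prod:
            pool += 1
            produced += 1
        elif u < r_prod + r_nuc:
            pool -= 2
            counts[2] += 1
        else:
            u -= r_prod + r_nuc
            for rates, kind in ((r_attach, "attach"), (r_detach, "detach"),
                                (r_clear, "clear")):
                s = rates.sum()
                if u < s:
                    n = int(np.searchsorted(np.cumsum(rates), u, side="right"))
                    if kind == "attach":
                        counts[n] -= 1
                        counts[n + 1] += 1
                        pool -= 1
                    elif kind == "detach":
                        counts[n] -= 1
                        if n == 2:
                            pool += 2
                        else:
                            counts[n - 1] += 1
                            pool += 1
                    else:
                        counts[n] -= 1
                        if model.clearance_mode == "recycle":
                            pool += n
                        else:
                            cleared += n
                    break
                u -= s
        n_events += 1
        if n_events >= max_events:
            raise RateModelError(
                f"event budget {max_events} exhausted at t={t:.3g} "
                f"(pool={pool}, clusters={int(counts.sum())})")

    snapshot(t_max)
    return SzilardTrajectory(
        times=np.array(times), counts_t=np.array(counts_t),
        pool_t=np.array(pool_t), cleared_t=np.array(cleared_t),
        occupancy=occupancy, produced=produced, initial_mass=initial_mass,
        n_events=n_events)


def master_equation_solve(model: SzilardModel, closed: bool = False) -> np.ndarray:
    """Stationary size distribution of the truncated chain by linear algebra.

    ``closed=True``: a single conserved cluster random-walking on sizes
    ``2..n_max`` with reflecting ends and no clearance — the stationary law
    is exactly Boltzmann, ``pi(n) ~ exp(-dG(n))``.

    ``closed=False`` (default): the open population census.  Clusters are
    born at size 2 (unit source), shrink/grow by detailed-balance rates,
    dissolve via size-2 detachment, and are removed by clearance.  The
    expected stationary counts ``c`` solve the linear system ``M c = -s``;
    the normalized ``c`` is what the KMC time-averaged census converges to
    (the source intensity cancels in the normalization).

    Returns an array over sizes ``0..n_max`` (entries below 2 are zero).
    """
    nm = model.n_max
    if nm > 200:
        raise ParameterError("dense master-equation solve limited to n_max <= 200")
    sizes = np.arange(nm + 1, dtype=float)
    kon = model.k_on(sizes)
    kon[:2] = 0.0
    kon[nm] = 0.0
    koff = np.zeros(nm + 1)
    koff[2:] = model.k_off(np.arange(2, nm + 1))
    kappa = np.zeros(nm + 1)
    kappa[model.clear_threshold:] = model.kappa

    idx = np.arange(2, nm + 1)
    m = len(idx)
    M = np.zeros((m, m))
    for k, n in enumerate(idx):
        out = kon[n] + kappa[n]
        if closed:
            out += koff[n] if n > 2 else 0.0  # reflecting: no dissolution at 2
        else:
            out += koff[n]  # dissolution sink at n=2
        M[k, k] = -out
        if n + 1 <= nm:
            M[k, k + 1] = koff[n + 1]
        if n - 1 >= 2:
            M[k, k - 1] = kon[n - 1]
    if closed:
        if model.kappa > 0:
            # clearance recycles the walker to size 2 (renewal chain)
            M[0, :] += kappa[idx]
        # stationary distribution of the conservative generator
        A = np.vstack([M, np.ones(m)])
        rhs = np.zeros(m + 1)
        rhs[-1] = 1.0
        c, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    else:
        s = np.zeros(m)
        s[0] = 1.0  # unit nucleation source at size 2
        try:
            c = np.linalg.solve(M, -s)
        except np.linalg.LinAlgError as exc:
            raise RateModelError(f"singular stationary system: {exc}") from exc
    if np.any(c < -1e-9 * max(abs(c).max(), 1.0)):
        raise RateModelError("stationary solution has negative components")
    c = np.clip(c, 0.0, None)
    out = np.zeros(nm + 1)
    out[2:] = c / c.sum()
    return out


def washout_experiment(model: SzilardModel, schedule, seed: int = 0,
                       initial_pool: int = 0, **kmc_kwargs):
    """Run contiguous phases with per-phase parameter overrides.

    ``schedule`` is a list of ``(duration, overrides)`` where ``overrides``
    is a dict of :class:`SzilardModel` field replacements (e.g. a raised
    ``b`` during drug treatment, ``kappa=0`` for a clearance knockdown).
    State (pool and cluster counts) carries across phase boundaries.
    Returns the list of per-phase :class:`SzilardTrajectory`.
    """
    trajectories = []
    counts = None
    pool = initial_pool
    for k, (duration, overrides) in enumerate(schedule):
        phase_model = replace(model, **overrides)
        traj = kmc_simulate(phase_model, duration, seed=seed + k,
                            initial_pool=pool, initial_counts=counts,
                            **kmc_kwargs)
        trajectories.append(traj)
        counts = traj.final_counts
        pool = traj.final_pool
    return trajectories
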