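"""Live-cell intensity analysis: bleach correction, distribution fit in N,
trace classification, growth law, merger additivity.

Cluster brightness stands in for cluster size: the integrated intensity
divided by the single-molecule unit intensity (24 counts by default)
estimates the number of fluorescent molecules N, and the same free-energy
fitting machinery used for fixed-cell sizes applies with N in place of n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .distribution import empirical_free_energy, histogram_sizes
from .errors import FitError, ParameterError
from .fitting import FreeEnergyFit, self_consistent_fit
from .synthetic import IntensityTrace
from .thermo import NucleationParameters, nucleation_parameters

__all__ = [
    "DEFAULT_I_SINGLE",
    "bleach_correct",
    "intensity_to_count",
    "fit_livecell_distribution",
    "classify_traces",
    "growth_law_fit",
    "check_merger_additivity",
]

logger = logging.getLogger(__name__)

DEFAULT_I_SINGLE = 24.0  # counts per fluorescent molecule


def bleach_correct(traces: list[IntensityTrace],
                   reference_t: np.ndarray | None = None,
                   reference_I: np.ndarray | None = None) -> float:
    """Fit and divide out a single-exponential photobleaching decay.

    The decay is fit as ``I0 * exp(-lam * t)`` by least squares on the log
    of a reference series — ideally the mean intensity of the whole
    imaging plane (``reference_t``/``reference_I``), which bleaches
    exponentially even while individual clusters grow or shrink.  Without
    a reference the mean across the traces themselves is used (adequate
    when their net growth averages out).  Every trace is then divided by
    ``exp(-lam * t)`` (stored in ``trace.corrected``).  A non-decaying
    reference (``lam <= 0``) leaves traces unchanged with a warning.
    Returns the fitted decay rate ``lam`` (1/s).
    """
    if not traces:
        raise ParameterError("no traces to correct")
    t_ref = traces[0].t_s
    if len(t_ref) < 5:
        raise ParameterError("need >= 5 time points for the bleach fit")
    if reference_I is not None:
        all_t = np.asarray(reference_t, dtype=float)
        mean_I = np.asarray(reference_I, dtype=float)
        if len(all_t) != len(mean_I) or len(all_t) < 5:
            raise ParameterError("reference series needs >= 5 matching points")
    else:
        # mean over traces; traces may cover different windows (mergers),
        # so average whatever is present at each global time point
        all_t = np.unique(np.concatenate([tr.t_s for tr in traces]))
        mean_I = np.array([
            np.mean([tr.intensity[np.argmin(np.abs(tr.t_s - t))]
                     for tr in traces if np.any(np.abs(tr.t_s - t) < 1e-9)])
            for t in all_t])
    pos = mean_I > 0
    if pos.sum() < 5:
        raise ParameterError("fewer than 5 positive mean intensities")
    slope, _ = np.polyfit(all_t[pos], np.log(mean_I[pos]), 1)
    lam = -float(slope)
    if lam <= 1e-12:  # flat to numerical precision, or genuinely rising
        if lam < -1e-12:
            logger.warning("bleach_correct: mean intensity not decaying "
                           "(lambda=%.3g); applying identity correction", lam)
        lam = 0.0
    for tr in traces:
        tr.corrected = tr.intensity * np.exp(lam * tr.t_s)
    return lam


def intensity_to_count(I, I_single: float = DEFAULT_I_SINGLE):
    """Estimated molecule number N = I / I_single (real-valued, unrounded)."""
    if I_single <= 0:
        raise ParameterError(f"I_single must be positive, got {I_single}")
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ParameterError("negative intensities cannot be converted")
    return I / I_single


def fit_livecell_distribution(N_values, bin_width: float = 10.0,
                              n_start: float = 5.0,
                              **fit_kwargs) -> tuple[FreeEnergyFit, NucleationParameters | None]:
    """Fit dG(N) = a*N^(2/3) - b*N to the molecule-count distribution.

    Histograms ``N`` in fixed bins (default width 10) and runs the same
    self-consistent fit as the fixed-cell path.  Returns the fit and the
    derived critical point/barrier (``None`` if the fit lands on the
    sub-saturated branch).
    """
    N_values = np.asarray(N_values, dtype=float)
    if len(N_values) < 500:
        raise FitError(f"need >= 500 values for the distribution fit, got {len(N_values)}")
    N_values = N_values[N_values >= n_start]
    dist = histogram_sizes(N_values, bin_width=bin_width, n_start=n_start)
    fit = self_consistent_fit(dist, **fit_kwargs)
    params = nucleation_parameters(fit.a, fit.b) if fit.saturation_class == "super" else None
    return fit, params


def classify_traces(traces: list[IntensityTrace], threshold: float = 0.10) -> list[str]:
    """Label each trace growing/shrinking/stable by its end/start change.

    Uses bleach-corrected values; relative change above ``+threshold`` is
    "growing", below ``-threshold`` "shrinking", otherwise "stable".  A
    zero start value is unclassifiable and labeled "unclassifiable".
    """
    labels = []
    for tr in traces:
        values = tr.corrected if tr.corrected is not None else tr.intensity
        if tr.corrected is None:
            logger.warning("classify_traces: trace %s not bleach-corrected; "
                           "using raw intensities", tr.trace_id)
        start, end = values[0], values[-1]
        if start == 0:
            labels.append("unclassifiable")
            tr.label = "unclassifiable"
            continue
        change = (end - start) / start
        label = ("growing" if change > threshold
                 else "shrinking" if change < -threshold else "stable")
        labels.append(label)
        tr.label = label
    return labels


def growth_law_fit(trace: IntensityTrace):
    """Linear growth-law diagnostics for one bleach-corrected trace.

    Returns ``(slope, exponent)``: the OLS slope of N(t) vs t and the
    log-log slope of ``|N - N0|`` vs t (``N0`` the fitted intercept), the
    latter ``None`` when ``N - N0`` changes sign.  A linear trace gives
    exponent 1; a cube-root-transformed linear trace gives 1/3.
    """
    values = trace.corrected if trace.corrected is not None else trace.intensity
    if len(values) < 10:
        raise ParameterError("need >= 10 points for the growth-law fit")
    if np.any(values <= 0):
        raise ParameterError("growth-law fit requires strictly positive values")
    t = trace.t_s
    slope, n0 = np.polyfit(t, values, 1)
    dev = values - n0
    pos = t > 0
    exponent = None
    if np.all(dev[pos] > 0) or np.all(dev[pos] < 0):
        exponent = float(np.polyfit(np.log(t[pos]), np.log(np.abs(dev[pos])), 1)[0])
    return float(slope), exponent


def check_merger_additivity(pre1: IntensityTrace, pre2: IntensityTrace,
                            post: IntensityTrace, tolerance: float = 0.15):
    """Test intensity additivity at a merger: I_post ~ I_pre1 + I_pre2.

    The precursor intensities are taken at their final time points and the
    product at its first; the two precursors must end at the same time and
    the product must start at the following time point (same cadence).
    Returns ``(passed, residual)`` with
    ``residual = |I_post - (I1 + I2)| / (I1 + I2)``.
    """
    if abs(pre1.t_s[-1] - pre2.t_s[-1]) > 1e-9:
        raise ParameterError("precursor traces end at different times")
    if post.t_s[0] <= pre1.t_s[-1]:
        raise ParameterError("product trace must start after the precursors end")

    def val(tr, idx):
        return (tr.corrected if tr.corrected is not None else tr.intensity)[idx]

    total_pre = val(pre1, -1) + val(pre2, -1)
    if total_pre <= 0:
        raise ParameterError("precursor intensities sum to zero")
    residual = abs(val(post, 0) - total_pre) / total_pre
    return residual <= tolerance, float(residual)
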