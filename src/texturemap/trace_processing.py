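"""Raw fluorescence to dF/F and response summaries.

Implements the trace-level chain used for line-scan calcium recordings:
baseline from the dimmest 10% of samples, linear detrend fitted on the 1-s
pre-stimulus window, trial averaging, 10-sample windowed peak and
trapezoidal area over the whisking train, responsiveness ANOVA against the
pre-stimulus baseline, single-exponential decay fit with a 650-ms
exclusion threshold, a two-block stability check, and spike-train binning
for single-unit data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic_data import TrialSet

PEAK_WINDOW = 10  # samples averaged around the maximum of the mean trace


def window_bounds(n: int, i: int, width: int = PEAK_WINDOW) -> tuple[int, int]:
    """[lo, hi) bounds of a ``width``-sample window centered on index ``i``,
    clipped at the trace edges (whole trace if shorter than ``width``)."""
    if n <= width:
        return 0, n
    lo = i - (width // 2 - 1)
    lo = max(0, min(lo, n - width))
    return lo, lo + width


@dataclass
class DffTrace:
    """Relative fluorescence change of one trial after detrending."""

    r: np.ndarray
    t: np.ndarray
    baseline: float
    detrend_slope: float
    detrend_intercept: float
    stim_onset: float
    stim_offset: float


def compute_dff(
    f: np.ndarray,
    t: np.ndarray,
    stim_onset: float,
    stim_offset: float,
    baseline_fraction: float = 0.10,
) -> DffTrace:
    """dF/F with baseline from the dimmest samples plus linear detrend.

    The baseline B is the mean of the lowest ``baseline_fraction`` of the
    trace's own samples and R = (F - B)/B.  A straight line fitted to R
    over the 1-s window preceding stimulus onset is then subtracted from
    the whole trace (extrapolated), removing slow drift.

    Raises
    ------
    ValueError
        If the baseline is non-positive or fewer than two samples fall in
        the lowest fraction.
    """
    f = np.asarray(f, dtype=float)
    t = np.asarray(t, dtype=float)
    if not 0.0 < baseline_fraction < 1.0:
        raise ValueError("baseline_fraction must lie in (0, 1)")
    k = int(np.ceil(baseline_fraction * f.size))
    if k < 2:
        raise ValueError("fewer than 2 samples in the baseline fraction")
    b = float(np.mean(np.sort(f)[:k]))
    if b <= 0:
        raise ValueError("non-positive baseline fluorescence")
    r = (f - b) / b
    pre = (t >= stim_onset - 1.0) & (t < stim_onset)
    if pre.sum() < 2:
        raise ValueError("need >= 1 s of pre-stimulus samples")
    slope, intercept = np.polyfit(t[pre], r[pre], 1)
    r = r - (slope * t + intercept)
    return DffTrace(
        r=r,
        t=t,
        baseline=b,
        detrend_slope=float(slope),
        detrend_intercept=float(intercept),
        stim_onset=stim_onset,
        stim_offset=stim_offset,
    )


@dataclass
class ResponseSummary:
    """Trial-averaged response of one neuron to one condition."""

    condition: str
    mean_trace: np.ndarray
    t: np.ndarray
    peak: float
    area: float
    trial_peaks: np.ndarray
    trial_areas: np.ndarray
    trial_baselines: np.ndarray
    peak_index: int
    stim_onset: float
    stim_offset: float
    block_of_trial: np.ndarray | None = None
    decay_tau: float = np.nan
    responsive: bool = False
    peak_window_samples: np.ndarray | None = None  # all trials x window samples
    pre_window_samples: np.ndarray | None = None


def average_and_summarize(
    traces: Sequence[DffTrace],
    condition: str = "",
    block_of_trial: np.ndarray | None = None,
    peak_mode: Literal["average_argmax", "own_argmax"] = "average_argmax",
) -> ResponseSummary:
    """Average trials of one neuron x condition and extract peak and area.

    Unequal trial lengths are truncated to the shortest.  Peak = mean of a
    10-sample window centered on the argmax of the trial-averaged trace
    (earliest index wins ties; window clipped at edges).  Per-trial peaks
    use the same window placed at the average's argmax by default
    (``peak_mode="own_argmax"`` instead re-centers on each trial's own
    maximum).  Area = trapezoidal integral over the stimulation window.
    """
    if len(traces) == 0:
        raise ValueError("no trials for this condition")
    n = min(tr.r.size for tr in traces)
    r = np.stack([tr.r[:n] for tr in traces])
    t = traces[0].t[:n]
    stim_onset, stim_offset = traces[0].stim_onset, traces[0].stim_offset
    mean_trace = r.mean(axis=0)
    i_peak = int(np.argmax(mean_trace))
    lo, hi = window_bounds(n, i_peak)
    peak = float(mean_trace[lo:hi].mean())
    if peak_mode == "average_argmax":
        trial_peaks = r[:, lo:hi].mean(axis=1)
    else:
        trial_peaks = np.array(
            [tr[slice(*window_bounds(n, int(np.argmax(tr))))].mean() for tr in r]
        )
    stim = (t >= stim_onset) & (t <= stim_offset)
    area = float(np.trapezoid(mean_trace[stim], t[stim]))
    trial_areas = np.trapezoid(r[:, stim], t[stim], axis=1)
    pre = (t >= stim_onset - 1.0) & (t < stim_onset)
    trial_baselines = r[:, pre].mean(axis=1)
    return ResponseSummary(
        condition=condition,
        mean_trace=mean_trace,
        t=t,
        peak=peak,
        area=area,
        trial_peaks=np.asarray(trial_peaks),
        trial_areas=np.asarray(trial_areas),
        trial_baselines=trial_baselines,
        peak_index=i_peak,
        stim_onset=stim_onset,
        stim_offset=stim_offset,
        block_of_trial=None if block_of_trial is None else np.asarray(block_of_trial),
        peak_window_samples=r[:, lo:hi].ravel(),
        pre_window_samples=r[:, pre].ravel(),
    )


def responsiveness_test(
    summary: ResponseSummary,
    alpha: float = 0.01,
    method: Literal["per_trial_peaks", "all_samples"] = "per_trial_peaks",
) -> tuple[bool, float]:
    """Is the evoked peak significantly above the pre-stimulus baseline?

    One-way ANOVA between per-trial peak values and per-trial pre-stimulus
    means (one value per trial in each group); responsive requires p <
    alpha AND mean peak above mean baseline.  ``all_samples`` compares the
    pooled peak-window samples against pooled pre-stimulus samples
    instead.  Zero variance in both groups counts as non-responsive.
    """
    if method == "all_samples":
        peaks, base = summary.peak_window_samples, summary.pre_window_samples
        if peaks is None or base is None:
            raise ValueError("summary lacks pooled window samples")
    else:
        peaks, base = summary.trial_peaks, summary.trial_baselines
    if peaks.size < 2 or base.size < 2:
        return False, np.nan
    if np.ptp(peaks) == 0 and np.ptp(base) == 0:
        return False, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fstat, p = stats.f_oneway(peaks, base)
    responsive = bool(p < alpha and peaks.mean() > base.mean())
    return responsive, float(p)


def fit_decay_tau(summary: ResponseSummary) -> float:
    """Single-exponential fit to the post-stimulus decay of the mean trace.

    Fits A*exp(-(t-t0)/tau) + c from the maximum of the post-stimulus
    segment onward.  Returns NaN when the fit does not converge.
    """
    t, y = summary.t, summary.mean_trace
    post = t >= summary.stim_offset
    if post.sum() < 3:
        return np.nan
    tp, yp = t[post], y[post]
    i0 = int(np.argmax(yp))
    tp, yp = tp[i0:], yp[i0:]
    if tp.size < 3:
        return np.nan
    a0 = max(yp[0] - yp[-1], 1e-9)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                lambda x, a, tau, c: a * np.exp(-(x - tp[0]) / tau) + c,
                tp,
                yp,
                p0=(a0, 0.5, float(yp[-1])),
                bounds=([0, 1e-3, -np.inf], [np.inf, 30.0, np.inf]),
                maxfev=2000,
            )
    except (RuntimeError, ValueError):
        return np.nan
    return float(popt[1])


def decay_filter(tau: float, tau_min: float = 0.650) -> bool:
    """Keep a neuron unless its fitted decay constant is below ``tau_min``
    seconds (fast decays indicate dominant neuropil contamination).
    Non-convergent fits (NaN) are kept and flagged upstream."""
    if np.isnan(tau):
        return True
    return tau >= tau_min


def stability_test(
    summaries: Sequence[ResponseSummary],
    alpha: float = 0.01,
) -> tuple[bool, dict[str, float]]:
    """Two-block response stability of one experiment.

    For every condition, per-trial peaks of block 1 vs block 2 are
    compared with a Welch t-test; the experiment passes only if no
    condition differs at ``alpha`` (unstable recordings are excluded from
    further analysis).
    """
    pvals: dict[str, float] = {}
    for s in summaries:
        if s.block_of_trial is None:
            raise ValueError(f"condition {s.condition!r} has no block assignment")
        blocks = np.unique(s.block_of_trial)
        if blocks.size < 2:
            raise ValueError(f"condition {s.condition!r} is missing a block")
        g1 = s.trial_peaks[s.block_of_trial == blocks[0]]
        g2 = s.trial_peaks[s.block_of_trial == blocks[1]]
        if np.ptp(g1) == 0 and np.ptp(g2) == 0 and g1.mean() == g2.mean():
            pvals[s.condition] = 1.0
            continue
        _, p = stats.ttest_ind(g1, g2, equal_var=False)
        pvals[s.condition] = float(p)
    ok = all(p >= alpha for p in pvals.values())
    return ok, pvals


def psth(
    spike_times: np.ndarray,
    bin_s: float = 0.010,
    window: tuple[float, float] = (0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Peri-stimulus time histogram of spike counts.

    Returns (counts, bin_edges).  10-ms bins display the dynamics;
    selectivity on unit data uses 100-ms bins over the stimulation period.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = window
    if hi <= lo:
        raise ValueError("invalid window")
    edges = np.arange(lo, hi + 0.5 * bin_s, bin_s)
    counts, _ = np.histogram(np.asarray(spike_times), bins=edges)
    return counts, edges


# ---------------------------------------------------------------------------
# experiment-level driver


def summarize_trial_set(
    trials: TrialSet,
    baseline_fraction: float = 0.10,
    alpha: float = 0.01,
    tau_min: float = 0.650,
    peak_mode: Literal["average_argmax", "own_argmax"] = "average_argmax",
) -> pd.DataFrame:
    """Run the full trace chain over a simulated experiment.

    Returns one row per neuron x condition with columns neuron_id,
    condition, peak, area, p_responsive, responsive, tau, tau_kept,
    stable, p_stability_min, plus per-trial peaks retained in the
    companion :func:`trial_peak_table` for selectivity testing.
    """
    rows = []
    peak_rows = []
    n, c, _, _ = trials.f.shape
    blocks = trials.block_of_trial
    for j in range(n):
        summaries = []
        for ci, cond in enumerate(trials.conditions):
            dffs = [
                compute_dff(
                    trials.f[j, ci, ri],
                    trials.t,
                    trials.stim_onset,
                    trials.stim_offset,
                    baseline_fraction,
                )
                for ri in range(trials.f.shape[2])
            ]
            s = average_and_summarize(dffs, cond, block_of_trial=blocks, peak_mode=peak_mode)
            s.responsive, p_resp = responsiveness_test(s, alpha=alpha)
            s.decay_tau = fit_decay_tau(s) if s.responsive else np.nan
            summaries.append((s, p_resp))
        stable, pvals = stability_test([s for s, _ in summaries], alpha=alpha)
        for s, p_resp in summaries:
            rows.append(
                {
                    "neuron_id": j,
                    "condition": s.condition,
                    "peak": s.peak,
                    "area": s.area,
                    "p_responsive": p_resp,
                    "responsive": s.responsive,
                    "tau": s.decay_tau,
                    "tau_kept": decay_filter(s.decay_tau, tau_min),
                    "stable": stable,
                    "p_stability_min": min(pvals.values()),
                }
            )
            for ri, (pk, ar) in enumerate(zip(s.trial_peaks, s.trial_areas)):
                peak_rows.append(
                    {
                        "neuron_id": j,
                        "condition": s.condition,
                        "trial": ri,
                        "block": int(blocks[ri]),
                        "trial_peak": pk,
                        "trial_area": ar,
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["trial_peaks"] = pd.DataFrame(peak_rows)
    return df


def trial_peak_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-trial peak/area table attached by :func:`summarize_trial_set`."""
    tp = summaries.attrs.get("trial_peaks")
    if tp is None:
        raise ValueError("summaries carry no per-trial peak table")
    return tp
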