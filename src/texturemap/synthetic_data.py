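"""Synthetic-data generators for the texture-coding pipeline.

Every input the analysis consumes can be produced here with known ground
truth: neuron populations with planted preference clusters inside a barrel
outline, whisk-locked calcium transients with noise and slow drift,
whisker shapes with analytic angle/curvature, and band-limited vibration
signals with a known spectral centroid.

The generators emulate the study conditions of the experiments they stand
in for: 10 whisk cycles at 5.5 Hz over a 2-s train, four sandpaper
conditions (P120, P320, P600, P1000, optionally free whisk), typically 30
repetitions per condition split into two time-segregated blocks, ~50
neurons per field of view, and line-scan sampling intervals of 10-17 ms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

DEFAULT_CONDITIONS = ("P120", "P320", "P600", "P1000")

#: labels for neurons without a planted texture preference
NON_PREFERRING = "NP"
NON_RESPONSIVE = "NR"


def default_barrel_polygon(
    center: tuple[float, float] = (150.0, 150.0),
    radii: tuple[float, float] = (130.0, 100.0),
    angle_deg: float = 45.0,
    n_vertices: int = 48,
) -> Polygon:
    """Elliptical stand-in for a barrel outline, in map pixels.

    The long axis is tilted to mimic the medial-caudal to lateral-rostral
    (MC-LR) diagonal of a real barrel.
    """
    th = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    x = radii[0] * np.cos(th)
    y = radii[1] * np.sin(th)
    a = np.deg2rad(angle_deg)
    xr = x * np.cos(a) - y * np.sin(a) + center[0]
    yr = x * np.sin(a) + y * np.cos(a) + center[1]
    return Polygon(np.column_stack([xr, yr]))


@dataclass(frozen=True)
class PopulationSpec:
    """Blueprint for one imaged field of view.

    Parameters
    ----------
    n_neurons
        Cells in the field (the study imaged 50.3 +/- 3.4 per experiment).
    conditions
        Ordered texture labels; free whisk may be appended as ``"FW"``.
    frac_selective, frac_nonresponsive
        Fractions of planted texture-preferring and non-responsive cells;
        the remainder are responsive but untuned ("non-preferring").
    cluster_count, cluster_radius
        Number of planted spatial clusters of same-preference cells and
        their radius in map pixels.  ``cluster_count=0`` scatters the
        selective cells uniformly instead.
    planted_si
        Ground-truth selectivity index of selective cells: non-preferred
        conditions get amplitude ``(1 - planted_si)`` relative to the
        preferred one.
    barrel_polygon
        Closed outline (map pixels) that every cell must fall inside.
    """

    n_neurons: int = 50
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    frac_selective: float = 0.55
    frac_nonresponsive: float = 0.20
    cluster_count: int = 4
    cluster_radius: float = 25.0
    planted_si: float = 0.6
    barrel_polygon: Polygon = field(default_factory=default_barrel_polygon)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be positive")
        if not (0.0 <= self.frac_selective <= 1.0):
            raise ValueError("frac_selective must lie in [0, 1]")
        if not (0.0 <= self.frac_nonresponsive <= 1.0):
            raise ValueError("frac_nonresponsive must lie in [0, 1]")
        if self.frac_selective + self.frac_nonresponsive > 1.0 + 1e-12:
            raise ValueError("frac_selective + frac_nonresponsive must be <= 1")
        if self.cluster_radius <= 0:
            raise ValueError("cluster_radius must be positive")
        if not (0.0 < self.planted_si <= 1.0):
            raise ValueError("planted_si must lie in (0, 1]")
        if not self.barrel_polygon.is_valid or self.barrel_polygon.area <= 0:
            raise ValueError("barrel_polygon must be a simple polygon")


@dataclass(frozen=True)
class TransientSpec:
    """Shape of the stimulus-locked calcium transients and trial layout.

    Amplitudes are peak dF/F of the preferred condition (population mean
    in the study was a few percent; default 0.08 gives robust but
    realistic signals).  ``noise_sd`` is additive Gaussian noise in dF/F
    units; ``drift_slope`` a slow multiplicative baseline drift per
    second.  Thirty repetitions split 15/15 into two time-segregated
    blocks mirror the stability design of the recordings.
    """

    sample_interval: float = 0.012
    pre_stim: float = 1.0
    stim_duration: float = 2.0
    post_stim: float = 2.0
    n_whisks: int = 10
    whisk_rate: float = 5.5
    amp_dff: float = 0.08
    decay_tau: float = 0.8
    noise_sd: float = 0.01
    drift_slope: float = 0.0
    baseline_f: float = 1000.0
    n_trials_per_block: int = 15
    n_blocks: int = 2
    block_gain: tuple[float, ...] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.amp_dff < 0:
            raise ValueError("amp_dff must be non-negative")
        if self.pre_stim < 1.0:
            raise ValueError("at least 1 s of pre-stimulus window is required")
        if len(self.block_gain) != self.n_blocks:
            raise ValueError("block_gain needs one entry per block")


@dataclass
class Population:
    """Generated field of view with ground truth.

    ``table`` columns: neuron_id, x_px, y_px, truth_label, truth_SI,
    cluster_id.  ``amplitudes`` holds each neuron's relative per-condition
    amplitude (preferred = 1).
    """

    table: pd.DataFrame
    amplitudes: pd.DataFrame
    spec: PopulationSpec

    @property
    def conditions(self) -> tuple[str, ...]:
        return self.spec.conditions

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "population.csv", index=False)
        self.amplitudes.to_csv(out / "amplitudes.csv", index=False)
        meta = {
            "barrel_polygon": list(map(list, self.spec.barrel_polygon.exterior.coords)),
            "conditions": list(self.spec.conditions),
            "n_neurons": self.spec.n_neurons,
            "frac_selective": self.spec.frac_selective,
            "frac_nonresponsive": self.spec.frac_nonresponsive,
            "cluster_count": self.spec.cluster_count,
            "cluster_radius": self.spec.cluster_radius,
            "planted_si": self.spec.planted_si,
            "seed": self.spec.seed,
        }
        (out / "population.json").write_text(json.dumps(meta, indent=2))


def _largest_remainder_counts(n: int, fracs: Sequence[float], rng: np.random.Generator) -> list[int]:
    """Apportion n items to categories: floor, then remainders by size with
    seeded shuffle breaking ties."""
    raw = np.asarray(fracs, dtype=float) * n
    base = np.floor(raw + 1e-9).astype(int)
    leftover = n - int(base.sum())
    if leftover > 0:
        rem = raw - base
        order = rng.permutation(len(fracs))  # tie-break
        ranked = sorted(order, key=lambda i: -rem[i])
        for i in ranked[:leftover]:
            base[i] += 1
    return base.tolist()


def _uniform_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(4 * (n - got), 16)
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        ok = shapely.contains_xy(poly, x, y)
        take = min(int(ok.sum()), n - got)
        pts[got : got + take] = np.column_stack([x[ok], y[ok]])[:take]
        got += take
    return pts


def _cluster_centers(poly: Polygon, k: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample k centers inside the (eroded) polygon with pairwise
    separation >= 2*radius so planted clusters are disjoint."""
    region = poly.buffer(-radius)
    if region.is_empty:
        region = poly
    centers: list[np.ndarray] = []
    for _ in range(20000):
        c = _uniform_in_polygon(region, 1, rng)[0]
        if all(np.hypot(*(c - p)) >= 2.0 * radius for p in centers):
            centers.append(c)
            if len(centers) == k:
                return np.array(centers)
    raise RuntimeError(
        f"could not place {k} cluster centers with separation {2 * radius} "
        "inside the barrel polygon; reduce cluster_count or cluster_radius"
    )


def _points_near(center: np.ndarray, radius: float, n: int, poly: Polygon, rng: np.random.Generator) -> np.ndarray:
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(4 * (n - got), 16)
        r = radius * np.sqrt(rng.uniform(0, 1, m))
        th = rng.uniform(0, 2 * np.pi, m)
        x = center[0] + r * np.cos(th)
        y = center[1] + r * np.sin(th)
        ok = shapely.contains_xy(poly, x, y)
        take = min(int(ok.sum()), n - got)
        pts[got : got + take] = np.column_stack([x[ok], y[ok]])[:take]
        got += take
    return pts


def generate_population(spec: PopulationSpec) -> Population:
    """Place neurons in the barrel outline and assign ground-truth labels.

    Selective neurons form ``cluster_count`` disjoint spatial clusters
    (one preferred condition each, conditions cycled); non-preferring and
    non-responsive neurons are scattered uniformly.  Reproducible given
    ``spec.seed``.

    Raises
    ------
    ValueError
        If the spec demands more clusters than selective neurons.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_neurons
    n_sel, n_nr, n_np = _largest_remainder_counts(
        n,
        [spec.frac_selective, spec.frac_nonresponsive, 1.0 - spec.frac_selective - spec.frac_nonresponsive],
        rng,
    )
    if spec.cluster_count > 0 and n_sel < spec.cluster_count:
        raise ValueError(
            f"infeasible spec: {spec.cluster_count} clusters but only {n_sel} selective neurons"
        )

    labels = np.empty(n, dtype=object)
    cluster_id = np.full(n, -1)
    pos = np.empty((n, 2))

    # selective neurons first, then non-preferring, then non-responsive
    if n_sel > 0:
        if spec.cluster_count > 0:
            centers = _cluster_centers(spec.barrel_polygon, spec.cluster_count, spec.cluster_radius, rng)
            sizes = np.full(spec.cluster_count, n_sel // spec.cluster_count)
            sizes[: n_sel % spec.cluster_count] += 1
            i = 0
            for ci, (c, sz) in enumerate(zip(centers, sizes)):
                cond = spec.conditions[ci % len(spec.conditions)]
                pos[i : i + sz] = _points_near(c, spec.cluster_radius, sz, spec.barrel_polygon, rng)
                labels[i : i + sz] = cond
                cluster_id[i : i + sz] = ci
                i += sz
        else:
            pos[:n_sel] = _uniform_in_polygon(spec.barrel_polygon, n_sel, rng)
            conds = [spec.conditions[i % len(spec.conditions)] for i in range(n_sel)]
            rng.shuffle(conds)
            labels[:n_sel] = conds
    rest = n - n_sel
    if rest > 0:
        pos[n_sel:] = _uniform_in_polygon(spec.barrel_polygon, rest, rng)
        labels[n_sel : n_sel + n_np] = NON_PREFERRING
        labels[n_sel + n_np :] = NON_RESPONSIVE

    amp = np.zeros((n, len(spec.conditions)))
    truth_si = np.zeros(n)
    for j in range(n):
        if labels[j] == NON_RESPONSIVE:
            amp[j] = 0.0
            truth_si[j] = np.nan
        elif labels[j] == NON_PREFERRING:
            amp[j] = 1.0
            truth_si[j] = 0.0
        else:
            amp[j] = 1.0 - spec.planted_si
            amp[j, spec.conditions.index(labels[j])] = 1.0
            truth_si[j] = spec.planted_si

    table = pd.DataFrame(
        {
            "neuron_id": np.arange(n),
            "x_px": pos[:, 0],
            "y_px": pos[:, 1],
            "truth_label": labels,
            "truth_SI": truth_si,
            "cluster_id": cluster_id,
        }
    )
    amplitudes = pd.DataFrame(amp, columns=list(spec.conditions))
    amplitudes.insert(0, "neuron_id", np.arange(n))
    return Population(table=table, amplitudes=amplitudes, spec=spec)


@dataclass
class TrialSet:
    """All raw traces of one experiment.

    ``f`` has shape (neurons, conditions, trials, time) where trials are
    ordered block-major (block 1 first).  ``t`` is the shared time base in
    seconds; stimulation runs over ``[stim_onset, stim_offset]``.
    """

    f: np.ndarray
    t: np.ndarray
    conditions: tuple[str, ...]
    n_blocks: int
    n_trials_per_block: int
    stim_onset: float
    stim_offset: float
    sample_interval: float
    spec: TransientSpec

    @property
    def block_of_trial(self) -> np.ndarray:
        custom = getattr(self, "_block_of_trial", None)
        if custom is not None:
            return custom
        return np.repeat(np.arange(1, self.n_blocks + 1), self.n_trials_per_block)

    def to_frame(self) -> pd.DataFrame:
        """Long CSV schema: neuron_id, condition, block, trial, t_s, F."""
        n, c, r, m = self.f.shape
        idx = pd.MultiIndex.from_product(
            [np.arange(n), list(self.conditions), np.arange(r), np.arange(m)],
            names=["neuron_id", "condition", "trial", "sample"],
        )
        df = pd.DataFrame({"F": self.f.reshape(-1)}, index=idx).reset_index()
        df["block"] = self.block_of_trial[df["trial"].to_numpy()]
        df["t_s"] = self.t[df["sample"].to_numpy()]
        return df[["neuron_id", "condition", "block", "trial", "t_s", "F"]]

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        stim_onset: float = 1.0,
        stim_offset: float = 3.0,
    ) -> "TrialSet":
        """Rebuild a TrialSet from the long CSV schema
        (neuron_id, condition, block, trial, t_s, F)."""
        neurons = np.sort(df["neuron_id"].unique())
        conditions = tuple(df["condition"].unique())
        trials = np.sort(df["trial"].unique())
        t = np.sort(df["t_s"].unique())
        blocks = df.groupby("trial")["block"].first().sort_index().to_numpy()
        n_blocks = int(df["block"].nunique())
        pivot = (
            df.sort_values(["neuron_id", "condition", "trial", "t_s"])["F"]
            .to_numpy()
            .reshape(len(neurons), len(conditions), len(trials), len(t))
        )
        # condition axis order must follow the sort order used above
        conditions = tuple(sorted(conditions))
        ts = float(np.median(np.diff(t)))
        spec = TransientSpec(
            sample_interval=ts,
            n_trials_per_block=len(trials) // n_blocks,
            n_blocks=n_blocks,
            block_gain=tuple([1.0] * n_blocks),
        )
        out = cls(
            f=pivot,
            t=t,
            conditions=conditions,
            n_blocks=n_blocks,
            n_trials_per_block=len(trials) // n_blocks,
            stim_onset=stim_onset,
            stim_offset=stim_offset,
            sample_interval=ts,
            spec=spec,
        )
        # trials may not split evenly into blocks; keep the true mapping
        out._block_of_trial = blocks
        return out


def transient_kernel(t: np.ndarray, tspec: TransientSpec) -> np.ndarray:
    """Noise-free unit dF/F waveform on the time base ``t``.

    Sum of one instant-rise / single-exponential-decay transient per whisk
    cycle, normalized so that the 10-sample windowed peak (the measure the
    pipeline extracts) equals exactly 1.
    """
    onsets = tspec.pre_stim + np.arange(tspec.n_whisks) / tspec.whisk_rate
    u = np.zeros_like(t)
    for on in onsets:
        m = t >= on
        u[m] += np.exp(-(t[m] - on) / tspec.decay_tau)
    peak = _windowed_peak(u)
    if peak > 0:
        u /= peak
    return u


def _windowed_peak(x: np.ndarray) -> float:
    from .trace_processing import window_bounds  # shared peak-window rule

    lo, hi = window_bounds(len(x), int(np.argmax(x)))
    return float(np.mean(x[lo:hi]))


def generate_trials(population: Population, tspec: TransientSpec) -> TrialSet:
    """Simulate raw fluorescence for every neuron / condition / trial.

    Each trace is ``baseline * (1 + drift) * (1 + dF/F signal) + noise``
    with the signal a whisk-locked transient train scaled by the neuron's
    ground-truth relative amplitude times ``tspec.amp_dff``.  Trials are
    split into ``n_blocks`` time-segregated blocks (conditions interleaved
    within each block, as in the stability design).
    """
    rng = np.random.default_rng(tspec.seed)
    n_time = int(round((tspec.pre_stim + tspec.stim_duration + tspec.post_stim) / tspec.sample_interval))
    t = np.arange(n_time) * tspec.sample_interval
    unit = transient_kernel(t, tspec)

    amp_rel = population.amplitudes[list(population.conditions)].to_numpy()  # (n, c)
    n, c = amp_rel.shape
    r = tspec.n_blocks * tspec.n_trials_per_block
    gain = np.repeat(np.asarray(tspec.block_gain, dtype=float), tspec.n_trials_per_block)  # (r,)

    dff = (
        amp_rel[:, :, None, None]
        * tspec.amp_dff
        * gain[None, None, :, None]
        * unit[None, None, None, :]
    )
    drift = 1.0 + tspec.drift_slope * t
    f = tspec.baseline_f * drift[None, None, None, :] * (1.0 + dff)
    if tspec.noise_sd > 0:
        f = f + tspec.baseline_f * tspec.noise_sd * rng.standard_normal(f.shape)
    return TrialSet(
        f=f,
        t=t,
        conditions=population.conditions,
        n_blocks=tspec.n_blocks,
        n_trials_per_block=tspec.n_trials_per_block,
        stim_onset=tspec.pre_stim,
        stim_offset=tspec.pre_stim + tspec.stim_duration,
        sample_interval=tspec.sample_interval,
        spec=tspec,
    )


# ---------------------------------------------------------------------------
# whisker-shape and vibration fixtures


@dataclass
class WhiskerTrack:
    """Ordered base-to-tip point chain for one video frame plus the
    analytic ground truth of the generating curve."""

    points: np.ndarray  # (N, 2), pixels
    frame_rate: float = 1000.0
    truth: Mapping[str, float] = field(default_factory=dict)


def generate_whisker_track(shape: str, params: Mapping[str, float], n_points: int) -> WhiskerTrack:
    """Sample a named analytic curve as a tracked whisker.

    Shapes: ``line`` (x0, y0, slope, length), ``circle`` (radius, cx, cy,
    theta0, theta1), ``parabola`` (a, x0, x1).  Ground-truth base angle
    and curvature are recorded in ``truth``.
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4 (second differences undefined)")
    p = dict(params)
    if shape == "line":
        slope = p.get("slope", 1.0)
        length = p.get("length", 100.0)
        s = np.linspace(0.0, length, n_points)
        d = np.array([1.0, slope]) / np.hypot(1.0, slope)
        pts = np.array([p.get("x0", 0.0), p.get("y0", 0.0)]) + s[:, None] * d
        truth = {"theta_base": float(np.arctan(slope)), "curvature": 0.0}
    elif shape == "circle":
        radius = p["radius"]
        th = np.linspace(p.get("theta0", 0.0), p.get("theta1", np.pi / 2), n_points)
        pts = np.column_stack(
            [p.get("cx", 0.0) + radius * np.cos(th), p.get("cy", 0.0) + radius * np.sin(th)]
        )
        truth = {
            "theta_base": float(np.arctan2(np.cos(th[0]), -np.sin(th[0]))),
            "curvature": 1.0 / radius,
        }
    elif shape == "parabola":
        a = p["a"]
        x = np.linspace(p.get("x0", -1.0), p.get("x1", 1.0), n_points)
        pts = np.column_stack([x, a * x * x])
        truth = {
            "theta_base": float(np.arctan(2 * a * x[0])),
            "curvature": float(abs(2 * a)),  # at the apex
        }
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return WhiskerTrack(points=pts, truth=truth)


@dataclass
class VibrationSignal:
    """Voltage trace of whisker micro-vibrations at a fixed sampling rate."""

    v: np.ndarray
    rate: float
    truth_centroid: float = np.nan


def generate_vibration(
    components: Sequence[tuple[float, float]],
    rate: float = 10_000.0,
    duration: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> VibrationSignal:
    """Sum of sinusoids plus white noise.

    ``components`` is a list of (frequency Hz, amplitude) pairs; the
    recorded ground-truth centroid is the power-weighted (amplitude
    squared) mean frequency of the sinusoids.
    """
    for f0, _ in components:
        if f0 >= rate / 2:
            raise ValueError(f"component at {f0} Hz aliases at rate {rate} Hz")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(rate * duration))) / rate
    v = np.zeros_like(t)
    for f0, a in components:
        v += a * np.sin(2 * np.pi * f0 * t)
    if noise_sd > 0:
        v = v + noise_sd * rng.standard_normal(t.shape)
    power = np.array([a * a for _, a in components])
    freqs = np.array([f0 for f0, _ in components])
    centroid = float(np.sum(power * freqs) / np.sum(power)) if power.sum() > 0 else np.nan
    return VibrationSignal(v=v, rate=rate, truth_centroid=centroid)


def with_seed(spec: PopulationSpec | TransientSpec, seed: int):
    """Copy of a spec with a different seed."""
    return replace(spec, seed=seed)
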