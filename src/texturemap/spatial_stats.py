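"""Spatial clustering statistics for texture-preference maps.

Two complementary statistics quantify whether neurons sharing a preferred
texture sit closer together than chance:

* k-nearest-neighbor probabilities — the fraction of labeled neurons whose
  k closest labeled neighbors all share their preferred texture, against
  the closed-form chance level P = sum_k (N_k / sum N) * (N_k / Ntotal).
* a Monte-Carlo null on mean intra-group distance — positions are redrawn
  uniformly over the recorded region many times; a label clusters
  significantly when its observed mean same-label distance falls below
  the 5th percentile of the pooled null histogram.

Columnar (depth) consistency for multi-contact electrode recordings uses
the same label-frequency logic across contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial.distance import cdist
from shapely.geometry import MultiPoint, Polygon


def distance_matrix(positions: np.ndarray) -> np.ndarray:
    """Euclidean N x N distance matrix of 2-D neuron positions (pixels)."""
    p = np.asarray(positions, dtype=float)
    return cdist(p, p)


def measured_neighbor_probability(
    positions: np.ndarray,
    labels: Sequence[str],
    k: int = 1,
    si: np.ndarray | None = None,
    si_min: float | None = None,
    mode: Literal["all", "any"] = "all",
) -> float:
    """Fraction of labeled neurons whose k nearest labeled neighbors share
    their preferred texture.

    ``mode="all"`` requires all k neighbors to agree (k=1 reduces to the
    closest-neighbor probability); ``mode="any"`` requires at least one.
    When ``si_min`` is given, only neurons with SI >= si_min enter
    (thresholded maps).  Distance ties are broken by neuron index;
    neurons with fewer than k neighbors are skipped.
    """
    pos = np.asarray(positions, dtype=float)
    lab = np.asarray(labels, dtype=object)
    if si_min is not None:
        if si is None:
            raise ValueError("si values required for thresholded mode")
        keep = np.asarray(si, dtype=float) >= si_min
        pos, lab = pos[keep], lab[keep]
    n = len(lab)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} labeled neurons")
    d = distance_matrix(pos)
    np.fill_diagonal(d, np.inf)
    hits = []
    idx = np.arange(n)
    for j in range(n):
        order = np.lexsort((idx, d[j]))  # distance, then index
        nbrs = order[:k]
        same = lab[nbrs] == lab[j]
        hits.append(same.all() if mode == "all" else same.any())
    return float(np.mean(hits))


def expected_neighbor_probability(counts: Mapping[str, int] | Sequence[int], n_total: int) -> float:
    """Chance closest-neighbor probability from label counts.

    P = sum_k (N_k / sum_t N_t) * (N_k / Ntotal), where N_k counts the
    selective neurons preferring texture k and Ntotal all neurons in the
    map (selective plus unselective).
    """
    nk = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts, dtype=float
    )
    s = nk.sum()
    if s <= 0:
        raise ValueError("no selective neurons: expected probability undefined")
    if n_total < s:
        raise ValueError("n_total must be at least the number of selective neurons")
    return float(np.sum((nk / s) * (nk / n_total)))


def expected_neighbor_probability_empirical(
    positions: np.ndarray,
    labels: Sequence[str],
    k: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
    mode: Literal["all", "any"] = "all",
) -> float:
    """Chance level for k neighbors by label permutation.

    The closed form above covers k=1 only; for k >= 2 the chance level is
    estimated by shuffling labels over the fixed positions.
    """
    rng = np.random.default_rng(seed)
    lab = np.asarray(labels, dtype=object)
    vals = []
    for _ in range(n_perm):
        vals.append(
            measured_neighbor_probability(positions, rng.permutation(lab), k=k, mode=mode)
        )
    return float(np.mean(vals))


def intra_group_distance(d: np.ndarray, members: np.ndarray) -> float:
    """Mean distance over ordered same-label pairs:
    D_AA = sum_{j,k in A} d_jk / (|A| (|A|-1))."""
    m = np.asarray(members)
    a = m.size
    if a < 2:
        return np.nan
    sub = d[np.ix_(m, m)]
    return float(sub.sum() / (a * (a - 1)))


def inter_group_distance(d: np.ndarray, members_a: np.ndarray, members_b: np.ndarray) -> float:
    """Mean distance between two label groups:
    D_AB = sum_{j in A, k in B} d_jk / (|A| |B|)."""
    a, b = np.asarray(members_a), np.asarray(members_b)
    if a.size == 0 or b.size == 0:
        return np.nan
    return float(d[np.ix_(a, b)].sum() / (a.size * b.size))


@dataclass
class ClusterNull:
    """Result of the Monte-Carlo intra-group-distance test."""

    runs: int
    percentile: float
    threshold: float
    null_distances: np.ndarray
    observed: dict[str, float]
    inter_group: dict[tuple[str, str], float] = field(default_factory=dict)
    significant: dict[str, bool] = field(default_factory=dict)
    seed: int = 0


def _uniform_in_region(region: Polygon, shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    n = int(np.prod(shape))
    minx, miny, maxx, maxy = region.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(2 * (n - got), 256)
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        ok = shapely.contains_xy(region, x, y)
        take = min(int(ok.sum()), n - got)
        out[got : got + take] = np.column_stack([x[ok], y[ok]])[:take]
        got += take
    return out.reshape(*shape, 2)


def monte_carlo_cluster_test(
    positions: np.ndarray,
    labels: Sequence[str],
    runs: int = 1000,
    percentile: float = 5.0,
    seed: int = 0,
    region: Polygon | Literal["hull", "bbox"] = "hull",
) -> ClusterNull:
    """Monte-Carlo significance of same-preference spatial clustering.

    Neuron positions are redrawn uniformly over the recording region
    (default: convex hull of the observed positions) ``runs`` times with
    the observed per-label counts; the mean intra-group distances of all
    labels are pooled into a null histogram whose ``percentile``-th
    percentile is the significance threshold.  A label clusters
    significantly when its observed intra-group distance lies below it.
    """
    pos = np.asarray(positions, dtype=float)
    lab = np.asarray(labels, dtype=object)
    groups = {
        l: np.flatnonzero(lab == l)
        for l in pd.unique(lab)
        if np.count_nonzero(lab == l) >= 2
    }
    if len(groups) < 1:
        raise ValueError("need at least one label with >= 2 members")
    if region == "hull":
        reg = MultiPoint(pos).convex_hull
    elif region == "bbox":
        minx, miny = pos.min(0)
        maxx, maxy = pos.max(0)
        reg = shapely.box(minx, miny, maxx, maxy)
    else:
        reg = region
    if not isinstance(reg, Polygon) or reg.area <= 0:
        raise ValueError("degenerate region: zero area")

    d_obs = distance_matrix(pos)
    observed = {l: intra_group_distance(d_obs, m) for l, m in groups.items()}
    inter = {}
    keys = list(groups)
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            inter[(a, b)] = inter_group_distance(d_obs, groups[a], groups[b])

    rng = np.random.default_rng(seed)
    n = pos.shape[0]
    null_vals = []
    batch = max(1, min(runs, int(2e7 / (n * n) ) or 1))
    done = 0
    while done < runs:
        b = min(batch, runs - done)
        pts = _uniform_in_region(reg, (b, n), rng)
        diff = pts[:, :, None, :] - pts[:, None, :, :]
        d = np.sqrt((diff * diff).sum(-1))
        for l, m in groups.items():
            a = m.size
            sub = d[:, m][:, :, m]
            null_vals.append(sub.sum(axis=(1, 2)) / (a * (a - 1)))
        done += b
    null = np.concatenate(null_vals)
    threshold = float(np.percentile(null, percentile))
    significant = {l: bool(v < threshold) for l, v in observed.items()}
    return ClusterNull(
        runs=runs,
        percentile=percentile,
        threshold=threshold,
        null_distances=null,
        observed=observed,
        inter_group=inter,
        significant=significant,
        seed=seed,
    )


@dataclass
class ColumnarResult:
    measured_all_agree: float
    expected_all_agree: float
    retention: pd.DataFrame
    n_electrodes: int


def columnar_consistency(
    units: pd.DataFrame,
    dominant_min: float = 2.0 / 3.0,
) -> ColumnarResult:
    """Depth consistency of texture preference along electrode penetrations.

    ``units`` needs columns electrode, contact (ordered superficial ->
    deep) and label (one row per sorted unit).  Measured probability: the
    fraction of electrodes whose units all share one label.  Expected:
    mean over electrodes of sum_k f_k^m, with f_k the global label
    frequencies and m the electrode's unit count.  The retention curve
    gives, per contact rank, the probability of matching the dominant
    label of the most superficial contact, restricted to electrodes where
    that contact has a dominant label at >= ``dominant_min``.
    """
    req = {"electrode", "contact", "label"}
    if not req.issubset(units.columns):
        raise ValueError(f"units table needs columns {sorted(req)}")
    freqs = units["label"].value_counts(normalize=True)
    agree, expect = [], []
    retention_rows = []
    n_used = 0
    for _, g in units.groupby("electrode"):
        if g["contact"].nunique() < 2:
            continue
        first = g[g["contact"] == g["contact"].min()]
        if len(first) == 0:
            continue
        n_used += 1
        agree.append(float(g["label"].nunique() == 1))
        m = len(g)
        expect.append(float(np.sum(freqs.to_numpy() ** m)))
        # retention relative to the superficial contact's dominant label
        counts = first["label"].value_counts()
        if counts.iloc[0] / len(first) >= dominant_min:
            dom = counts.index[0]
            for rank, (_, gc) in enumerate(g.groupby("contact")):
                retention_rows.append(
                    {"contact_rank": rank, "match": float((gc["label"] == dom).mean())}
                )
    if n_used == 0:
        raise ValueError("no electrode with >= 2 non-empty contacts")
    retention = (
        pd.DataFrame(retention_rows).groupby("contact_rank", as_index=False)["match"].mean()
        if retention_rows
        else pd.DataFrame(columns=["contact_rank", "match"])
    )
    return ColumnarResult(
        measured_all_agree=float(np.mean(agree)),
        expected_all_agree=float(np.mean(expect)),
        retention=retention,
        n_electrodes=n_used,
    )


def label_counts(labels: Sequence[str], condition_labels: Sequence[str]) -> dict[str, int]:
    """Per-condition selective counts N_k from a label vector."""
    lab = np.asarray(labels, dtype=object)
    return {c: int(np.count_nonzero(lab == c)) for c in condition_labels}
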