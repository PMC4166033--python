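"""Normalized-barrel projection and smoothed texture-preference maps.

Experiments from different animals are co-registered by projecting each
field of view onto a canonical "normalized" barrel: a unit circle whose
medial-caudal to lateral-rostral (MC-LR) diagonal runs at 45 degrees.
Per-texture density maps are Gaussian sums over neuron positions
(sigma = 15 px on a 300 x 300 px raster), normalized per pixel so the
per-texture maps behave like preference probabilities, and mixed into a
single color map.  Position statistics use the signed distance to the
MC-LR diagonal and the radial distance to the barrel center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import stats
from shapely.geometry import Polygon

RASTER_SHAPE = (300, 300)
#: half-width of the canonical raster in normalized units (barrel radius 1)
RASTER_EXTENT = 1.25

DEFAULT_COLORS: dict[str, tuple[float, float, float]] = {
    "P120": (0.0, 0.0, 1.0),   # blue, coarsest
    "P320": (1.0, 0.0, 0.0),   # red
    "P600": (0.0, 0.8, 0.0),   # green
    "P1000": (1.0, 1.0, 0.0),  # yellow, finest
    "FW": (0.0, 1.0, 1.0),     # cyan, free whisk
}

COARSE_GROUP = ("P120", "P320")
FINE_GROUP = ("P600", "P1000")


@dataclass
class NormalizedBarrel:
    """Neuron coordinates expressed in the canonical barrel frame."""

    coords: np.ndarray          # (n, 2) normalized units
    diagonal_distance: np.ndarray  # signed distance to the MC-LR diagonal
    radial_distance: np.ndarray    # distance to the barrel center
    outline: np.ndarray            # transformed barrel outline
    rotation: float
    scale: tuple[float, float]
    center: tuple[float, float]

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Apply the fitted barrel-normalizing transform to new points."""
        return _apply(points, self.center, self.rotation, self.scale)


def _apply(points: np.ndarray, center, rotation, scale) -> np.ndarray:
    p = np.asarray(points, dtype=float) - np.asarray(center)
    c, s = np.cos(-rotation), np.sin(-rotation)
    u = p[:, 0] * c - p[:, 1] * s
    v = p[:, 0] * s + p[:, 1] * c
    u, v = u / scale[0], v / scale[1]
    a = np.pi / 4  # canonical MC-LR diagonal at 45 degrees
    ca, sa = np.cos(a), np.sin(a)
    return np.column_stack([u * ca - v * sa, u * sa + v * ca])


def normalize_to_barrel(
    positions: np.ndarray,
    barrel_polygon: Polygon | np.ndarray,
    anchors: tuple[Sequence[float], Sequence[float]],
) -> NormalizedBarrel:
    """Map one experiment's barrel onto the canonical unit barrel.

    ``anchors`` are the rostro-medial and caudo-lateral anatomical points;
    their midpoint becomes the barrel center and their axis the MC-LR
    diagonal (placed at 45 degrees).  The polygon's half-extents along and
    across that axis are scaled to 1 (similarity plus anisotropic scale),
    so the outline's bounding ellipse maps onto the unit circle.
    """
    poly = barrel_polygon if isinstance(barrel_polygon, Polygon) else Polygon(np.asarray(barrel_polygon))
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("degenerate barrel polygon")
    a0, a1 = np.asarray(anchors[0], float), np.asarray(anchors[1], float)
    center = (a0 + a1) / 2.0
    axis = a1 - a0
    if np.hypot(*axis) == 0:
        raise ValueError("anchor points coincide")
    rotation = float(np.arctan2(axis[1], axis[0]))

    ring = np.asarray(poly.exterior.coords, dtype=float)
    rel = ring - center
    c, s = np.cos(-rotation), np.sin(-rotation)
    u = rel[:, 0] * c - rel[:, 1] * s
    v = rel[:, 0] * s + rel[:, 1] * c
    scale = (float(np.abs(u).max()), float(np.abs(v).max()))
    if min(scale) <= 0:
        raise ValueError("degenerate barrel polygon")

    coords = _apply(np.asarray(positions, float), tuple(center), rotation, scale)
    outline = _apply(ring, tuple(center), rotation, scale)
    diag = (coords[:, 1] - coords[:, 0]) / np.sqrt(2.0)  # signed offset from 45-deg line
    radial = np.hypot(coords[:, 0], coords[:, 1])
    return NormalizedBarrel(
        coords=coords,
        diagonal_distance=diag,
        radial_distance=radial,
        outline=outline,
        rotation=rotation,
        scale=scale,
        center=(float(center[0]), float(center[1])),
    )


@dataclass
class TextureMapStack:
    """Raw, normalized and mixed-color preference maps on one raster."""

    labels: tuple[str, ...]
    raw: dict[str, np.ndarray]
    norm: dict[str, np.ndarray]
    color: np.ndarray  # (H, W, 3) RGB in [0, 1]
    sigma: float
    eps: float
    extent: float = RASTER_EXTENT
    colors: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)

    def write_tiff(self, path: str | Path) -> None:
        """Stack of per-label normalized channels followed by the RGB mix."""
        chans = [self.norm[l].astype(np.float32) for l in self.labels]
        tifffile.imwrite(Path(path), np.stack(chans), photometric="minisblack",
                         metadata={"labels": list(self.labels)})
        rgb_path = Path(path).with_name(Path(path).stem + "_rgb.tif")
        tifffile.imwrite(rgb_path, (self.color * 255).astype(np.uint8), photometric="rgb")


def normalized_to_pixels(
    coords: np.ndarray,
    shape: tuple[int, int] = RASTER_SHAPE,
    extent: float = RASTER_EXTENT,
) -> np.ndarray:
    """Canonical-barrel coordinates -> raster pixel coordinates (x, y)."""
    c = np.asarray(coords, dtype=float)
    h, w = shape
    px = (c[:, 0] + extent) / (2 * extent) * (w - 1)
    py = (c[:, 1] + extent) / (2 * extent) * (h - 1)
    return np.column_stack([px, py])


def build_texture_maps(
    coords: np.ndarray,
    labels: Sequence[str],
    sigma: float = 15.0,
    shape: tuple[int, int] = RASTER_SHAPE,
    extent: float = RASTER_EXTENT,
    eps: float | None = None,
    colors: Mapping[str, tuple[float, float, float]] | None = None,
    white_below: float = 0.05,
    label_order: Sequence[str] | None = None,
) -> TextureMapStack:
    """Gaussian-sum texture maps with per-pixel normalization.

    For each texture k, M_k(x, y) = sum_i exp(-((x-x_i)^2+(y-y_i)^2) /
    (2 sigma^2)) over the neurons preferring k, evaluated analytically at
    every raster pixel (no kernel truncation).  Normalized maps divide by
    (eps + sum_t M_t); pixels where the normalized maps sum below
    ``white_below`` are rendered white in the mixed color map.

    ``coords`` are canonical-barrel coordinates; ``sigma`` is in raster
    pixels.  ``eps`` defaults to 1e-6 times the peak of the summed raw
    maps.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    lab = np.asarray(labels, dtype=object)
    if lab.size == 0:
        raise ValueError("no labeled neurons")
    order = tuple(label_order) if label_order is not None else tuple(pd.unique(lab))
    pix = normalized_to_pixels(coords, shape, extent)
    h, w = shape
    gx = np.arange(w, dtype=float)
    gy = np.arange(h, dtype=float)
    raw: dict[str, np.ndarray] = {}
    for l in order:
        pts = pix[lab == l]
        m = np.zeros(shape)
        for x0, y0 in pts:
            ex = np.exp(-((gx - x0) ** 2) / (2 * sigma**2))
            ey = np.exp(-((gy - y0) ** 2) / (2 * sigma**2))
            m += np.outer(ey, ex)  # separable 2-D Gaussian, exact
        raw[l] = m
    total = np.sum(list(raw.values()), axis=0)
    if eps is None:
        eps = 1e-6 * float(total.max()) if total.max() > 0 else 1e-12
    norm = {l: m / (eps + total) for l, m in raw.items()}

    cmap = dict(DEFAULT_COLORS)
    if colors:
        cmap.update(colors)
    color = np.zeros((h, w, 3))
    for l in order:
        c = np.asarray(cmap.get(l, (0.5, 0.5, 0.5)))
        color += norm[l][:, :, None] * c[None, None, :]
    weak = np.sum(list(norm.values()), axis=0) < white_below
    color[weak] = 1.0
    color = np.clip(color, 0.0, 1.0)
    return TextureMapStack(
        labels=order, raw=raw, norm=norm, color=color,
        sigma=sigma, eps=float(eps), extent=extent, colors=cmap,
    )


@dataclass
class DiagonalRadialStats:
    per_label: pd.DataFrame
    p_anova_diagonal: float
    p_anova_radial: float
    p_coarse_fine_radial: float
    p_coarse_fine_diagonal: float
    coarse_mean_radial: float
    fine_mean_radial: float
    excluded_labels: tuple[str, ...]


def diagonal_radial_stats(
    barrel: NormalizedBarrel | None,
    labels: Sequence[str],
    diagonal_distance: np.ndarray | None = None,
    radial_distance: np.ndarray | None = None,
    coarse: Sequence[str] = COARSE_GROUP,
    fine: Sequence[str] = FINE_GROUP,
) -> DiagonalRadialStats:
    """Position statistics of preferred textures in the normalized barrel.

    Reports per-label distributions of the signed MC-LR-diagonal distance
    and the radial distance, a 4-group ANOVA on each, and a Welch t-test
    comparing the combined coarser (P120, P320) against finer (P600,
    P1000) textures on both measures.  Labels with fewer than 2 members
    are excluded from the tests but still tabulated.
    """
    lab = np.asarray(labels, dtype=object)
    diag = np.asarray(barrel.diagonal_distance if barrel is not None else diagonal_distance, float)
    rad = np.asarray(barrel.radial_distance if barrel is not None else radial_distance, float)
    uniq = list(pd.unique(lab))
    rows = []
    groups_d, groups_r, excluded = [], [], []
    for l in uniq:
        m = lab == l
        rows.append(
            {
                "label": l,
                "n": int(m.sum()),
                "diag_mean": float(diag[m].mean()),
                "diag_sd": float(diag[m].std(ddof=1)) if m.sum() > 1 else np.nan,
                "radial_mean": float(rad[m].mean()),
                "radial_sd": float(rad[m].std(ddof=1)) if m.sum() > 1 else np.nan,
            }
        )
        if m.sum() >= 2:
            groups_d.append(diag[m])
            groups_r.append(rad[m])
        else:
            excluded.append(l)
    if len(groups_d) >= 2:
        p_ad = float(stats.f_oneway(*groups_d).pvalue)
        p_ar = float(stats.f_oneway(*groups_r).pvalue)
    else:
        p_ad = p_ar = np.nan
    cm = np.isin(lab, list(coarse))
    fm = np.isin(lab, list(fine))
    if cm.sum() >= 2 and fm.sum() >= 2:
        p_cf_r = float(stats.ttest_ind(rad[cm], rad[fm], equal_var=False).pvalue)
        p_cf_d = float(stats.ttest_ind(diag[cm], diag[fm], equal_var=False).pvalue)
    else:
        p_cf_r = p_cf_d = np.nan
    return DiagonalRadialStats(
        per_label=pd.DataFrame(rows),
        p_anova_diagonal=p_ad,
        p_anova_radial=p_ar,
        p_coarse_fine_radial=p_cf_r,
        p_coarse_fine_diagonal=p_cf_d,
        coarse_mean_radial=float(rad[cm].mean()) if cm.any() else np.nan,
        fine_mean_radial=float(rad[fm].mean()) if fm.any() else np.nan,
        excluded_labels=tuple(excluded),
    )


def dominant_texture(counts: pd.DataFrame) -> pd.DataFrame:
    """Dominant preferred texture per barrel.

    ``counts`` is long form with columns barrel, label, count and
    optionally row, arc (barrel-field position).  Returns one row per
    barrel with the strict-argmax label (ties -> None) and the total
    preferring count; row/arc columns are carried through for the
    barrel-field table.
    """
    req = {"barrel", "label", "count"}
    if not req.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(req)}")
    rows = []
    keep = [c for c in ("row", "arc") if c in counts.columns]
    for b, g in counts.groupby("barrel"):
        totals = g.groupby("label")["count"].sum().sort_values(ascending=False)
        if totals.sum() == 0:
            dom = None
        elif len(totals) > 1 and totals.iloc[0] == totals.iloc[1]:
            dom = None  # tie
        else:
            dom = totals.index[0]
        row = {"barrel": b, "dominant": dom, "n_preferring": int(totals.sum())}
        for c in keep:
            row[c] = g[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
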