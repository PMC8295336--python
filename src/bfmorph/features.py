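"""Fixed 296-feature texture profile for bright-field cell crops.

The profile is organized around a multi-threshold "clump" procedure: for
each threshold tau (a fraction of the crop's min-max intensity range),
darker pixels are selected, 8-connected components above a minimum area
become clumps, and per-threshold measurements (count, size, perimeter,
noncircularity, ...) are recorded together with their across-threshold
sample means and SDs. The vector is completed by whole-mask binarized
shape measures, pixel-intensity distribution statistics, and
gradient-magnitude statistics.

Schema (exactly 296 values, fixed order):

- 8 thresholds x 24 per-threshold measurements      = 192
- across-threshold mean + SD of the 24 measurements =  48
- intensity block: 16 statistics + 12-bin histogram =  28
- gradient-magnitude block: same 28                 =  28

Perimeter is the count of exposed pixel edges (city-block boundary), so
every shape number is exactly reproducible; noncircularity is
``1 - 4*pi*area/perimeter**2`` clamped at 0, and thinness is its
complement ``4*pi*area/perimeter**2``.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label

__all__ = [
    "FeatureConfig",
    "Clump",
    "FeatureVector",
    "binarize_dark",
    "label_clumps",
    "noncircularity",
    "clump_measurements",
    "intensity_statistics",
    "binarized_shape_measures",
    "extract_features",
    "apply_filter",
    "N_FEATURES",
]

N_FEATURES = 296

_CLUMP_STATS = [
    "clump_count",
    "clump_total_area",
    "clump_mean_area",
    "clump_sd_area",
    "clump_min_area",
    "clump_max_area",
    "clump_median_area",
    "clump_mean_perimeter",
    "clump_sd_perimeter",
    "clump_min_perimeter",
    "clump_max_perimeter",
    "clump_mean_noncircularity",
    "clump_sd_noncircularity",
    "clump_min_noncircularity",
    "clump_max_noncircularity",
    "clump_mean_eqdiameter",
    "clump_max_eqdiameter",
    "clump_area_fraction",
    "clump_count_per_kpx",
    "clump_mean_center_dist",
    "clump_max_center_dist",
]

_SHAPE_STATS = ["mask_area", "mask_perimeter", "mask_thinness"]

_PER_TAU = _CLUMP_STATS + _SHAPE_STATS  # 24 measurements per threshold

_DIST_STATS = (
    ["mean", "sd", "skewness", "kurtosis", "min", "max"]
    + [f"d{k}0" for k in range(1, 10)]
    + ["idr"]
)  # 16 statistics

_N_HIST = 12


def _build_schema(tau_ladder) -> list[str]:
    names: list[str] = []
    for k in range(len(tau_ladder)):
        names += [f"tau{k + 1}_{s}" for s in _PER_TAU]
    names += [f"taumean_{s}" for s in _PER_TAU]
    names += [f"tausd_{s}" for s in _PER_TAU]
    for prefix in ("int", "grad"):
        names += [f"{prefix}_{s}" for s in _DIST_STATS]
        names += [f"{prefix}_hist{b + 1:02d}" for b in range(_N_HIST)]
    return names


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds, connectivity, and the fixed 296-name feature schema."""

    tau_ladder: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    connectivity: int = 8
    min_clump_area: int = 5
    feature_schema: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        taus = self.tau_ladder
        if any(not 0 < t < 1 for t in taus) or any(
            b <= a for a, b in zip(taus, taus[1:])
        ):
            raise ValueError("tau ladder must be strictly increasing within (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.feature_schema is None:
            object.__setattr__(self, "feature_schema", tuple(_build_schema(taus)))
        schema = self.feature_schema
        if len(schema) != N_FEATURES or len(set(schema)) != N_FEATURES:
            raise ValueError(f"schema must hold {N_FEATURES} unique names")

    @property
    def schema_hash(self) -> str:
        h = hashlib.sha256("\n".join(self.feature_schema).encode())
        return h.hexdigest()[:16]

    def schema_records(self) -> list[dict]:
        """Schema as JSON-serializable records (name, family, tau)."""
        records = []
        for name in self.feature_schema:
            head = name.split("_", 1)[0]
            if head.startswith("tau") and head[3:].isdigit():
                tau = self.tau_ladder[int(head[3:]) - 1]
                family = "per_threshold"
            elif head in ("taumean", "tausd"):
                tau, family = None, "threshold_summary"
            else:
                tau = None
                family = "intensity" if head == "int" else "gradient"
            records.append({"name": name, "family": family, "tau": tau})
        return records


@dataclass
class Clump:
    """One connected dark region within a crop."""

    pixels: np.ndarray  # (n, 2) row/col coordinates
    area: int
    perimeter: int
    centroid: tuple[float, float]


@dataclass
class FeatureVector:
    values: np.ndarray
    schema: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.schema),):
            raise ValueError("values must match schema length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.schema.index(name)])


def _as_array(crop) -> np.ndarray:
    img = getattr(crop, "image", crop)
    return np.asarray(img, dtype=float)


def binarize_dark(crop, tau: float) -> np.ndarray:
    """Mask of pixels strictly below ``min + tau * (max - min)`` of the crop."""
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    img = _as_array(crop)
    lo, hi = img.min(), img.max()
    if hi == lo:
        warnings.warn("constant crop: empty dark mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    return img < lo + tau * (hi - lo)


def _component_arrays(mask: np.ndarray, connectivity: int, min_area: int):
    """Labeled components with per-component area/perimeter/centroid arrays.

    Perimeter counts exposed pixel edges (4-neighborhood boundary),
    independent of the labeling connectivity.
    """
    lab = sk_label(mask, connectivity=2 if connectivity == 8 else 1)
    nlab = int(lab.max())
    if nlab == 0:
        z = np.zeros(0)
        return lab, z, z, z, z
    areas = np.bincount(lab.ravel(), minlength=nlab + 1)[1:]
    padded = np.pad(lab, 1)
    core = padded[1:-1, 1:-1]
    perims = np.zeros(nlab + 1, dtype=np.int64)
    H = padded.shape[0]
    W = padded.shape[1]
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = padded[1 + dr : H - 1 + dr, 1 + dc : W - 1 + dc]
        exposed = (core > 0) & (nb != core)
        perims += np.bincount(core[exposed], minlength=nlab + 1)
    perims = perims[1:]
    rr, cc = np.nonzero(lab)
    vals = lab[rr, cc]
    cent_r = np.bincount(vals, weights=rr, minlength=nlab + 1)[1:] / areas
    cent_c = np.bincount(vals, weights=cc, minlength=nlab + 1)[1:] / areas
    keep = areas >= min_area
    # relabel kept components 1..k for downstream pixel lookups
    remap = np.zeros(nlab + 1, dtype=lab.dtype)
    remap[1:][keep] = np.arange(1, keep.sum() + 1)
    return remap[lab], areas[keep], perims[keep], cent_r[keep], cent_c[keep]


def label_clumps(mask: np.ndarray, config: FeatureConfig | None = None) -> list[Clump]:
    """Connected dark components above the minimum area, as Clump objects."""
    config = config or FeatureConfig()
    lab, areas, perims, cr, cc = _component_arrays(
        np.asarray(mask, dtype=bool), config.connectivity, config.min_clump_area
    )
    clumps = []
    for k in range(len(areas)):
        pix = np.argwhere(lab == k + 1)
        clumps.append(
            Clump(
                pixels=pix,
                area=int(areas[k]),
                perimeter=int(perims[k]),
                centroid=(float(cr[k]), float(cc[k])),
            )
        )
    return clumps


def noncircularity(area: float, perimeter: float) -> float:
    """Deviation from a circle: ``1 - 4*pi*area/perimeter**2``, clamped at 0."""
    if area < 1 or perimeter <= 0:
        raise ValueError("area must be >= 1 and perimeter > 0")
    return max(0.0, 1.0 - 4.0 * math.pi * area / perimeter**2)


def clump_measurements(clumps: list[Clump]) -> tuple[int, float, float]:
    """(count, mean area, mean noncircularity); (0, 0, 0) for no clumps."""
    if not clumps:
        return 0, 0.0, 0.0
    areas = [c.area for c in clumps]
    ncs = [noncircularity(c.area, c.perimeter) for c in clumps]
    return len(clumps), float(np.mean(areas)), float(np.mean(ncs))


def _nc_vec(areas, perims):
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = 1.0 - 4.0 * math.pi * areas / perims**2
    return np.clip(nc, 0.0, None)


def _clump_stat_block(areas, perims, cent_r, cent_c, shape) -> np.ndarray:
    out = np.zeros(len(_CLUMP_STATS))
    n = len(areas)
    if n == 0:
        return out
    nc = _nc_vec(areas, perims)
    eqd = np.sqrt(4.0 * areas / math.pi)
    ctr = ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
    half_diag = math.hypot(shape[0], shape[1]) / 2
    dist = np.hypot(cent_r - ctr[0], cent_c - ctr[1]) / half_diag
    npx = shape[0] * shape[1]
    out[:] = [
        n,
        areas.sum(),
        areas.mean(),
        areas.std(),
        areas.min(),
        areas.max(),
        np.median(areas),
        perims.mean(),
        perims.std(),
        perims.min(),
        perims.max(),
        nc.mean(),
        nc.std(),
        nc.min(),
        nc.max(),
        eqd.mean(),
        eqd.max(),
        areas.sum() / npx,
        1000.0 * n / npx,
        dist.mean(),
        dist.max(),
    ]
    return out


def intensity_statistics(crop) -> dict[str, float]:
    """Distribution statistics of the crop's pixel values.

    Skewness and excess kurtosis are defined as 0 for a constant crop.
    """
    img = _as_array(crop)
    if img.size == 0:
        raise ValueError("empty crop")
    return dict(zip(_DIST_STATS, _dist_stat_values(img.ravel())))


def _dist_stat_values(v: np.ndarray) -> np.ndarray:
    mean = v.mean()
    sd = v.std()
    if sd > 0:
        z = (v - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    else:
        skew = kurt = 0.0
    deciles = np.percentile(v, np.arange(10, 100, 10))
    idr = deciles[8] - deciles[0]
    return np.concatenate([[mean, sd, skew, kurt, v.min(), v.max()], deciles, [idr]])


def _hist_block(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        out = np.zeros(_N_HIST)
        out[0] = 1.0
        return out
    counts, _ = np.histogram(v, bins=_N_HIST, range=(lo, hi))
    return counts / v.size


def binarized_shape_measures(mask: np.ndarray) -> tuple[int, int, float]:
    """(area, exposed-edge perimeter, thinness) of the whole foreground."""
    m = np.asarray(mask, dtype=bool)
    area = int(m.sum())
    if area == 0:
        return 0, 0, 0.0
    padded = np.pad(m, 1)
    per = 0
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = np.roll(padded, (dr, dc), axis=(0, 1))
        per += int(np.sum(padded & ~nb))
    thinness = 4.0 * math.pi * area / per**2
    return area, per, thinness


def extract_features(crop, config: FeatureConfig | None = None) -> FeatureVector:
    """Assemble the fixed-order 296-value texture profile of one crop."""
    config = config or FeatureConfig()
    img = _as_array(crop)
    lo, hi = img.min(), img.max()
    per_tau = np.zeros((len(config.tau_ladder), len(_PER_TAU)))
    if hi == lo:
        warnings.warn("constant crop: clump and shape features set to 0", stacklevel=2)
    else:
        for k, tau in enumerate(config.tau_ladder):
            mask = img < lo + tau * (hi - lo)
            _, areas, perims, cr, cc = _component_arrays(
                mask, config.connectivity, config.min_clump_area
            )
            block = _clump_stat_block(areas, perims, cr, cc, img.shape)
            shape_block = binarized_shape_measures(mask)
            per_tau[k] = np.concatenate([block, shape_block])
    tau_mean = per_tau.mean(axis=0)
    tau_sd = per_tau.std(axis=0, ddof=1)
    flat = img.ravel()
    gr = np.gradient(img)
    gmag = np.hypot(gr[0], gr[1]).ravel()
    values = np.concatenate(
        [
            per_tau.ravel(),
            tau_mean,
            tau_sd,
            _dist_stat_values(flat),
            _hist_block(flat),
            _dist_stat_values(gmag),
            _hist_block(gmag),
        ]
    )
    return FeatureVector(values, config.feature_schema)


# Fixed convolution kernels of the classic PIL image filters, normalized.
_FILTER_KERNELS = {
    "blur": (
        np.array(
            [
                [1, 1, 1, 1, 1],
                [1, 0, 0, 0, 1],
                [1, 0, 0, 0, 1],
                [1, 0, 0, 0, 1],
                [1, 1, 1, 1, 1],
            ],
            dtype=float,
        ),
        16.0,
    ),
    "edge_enhance": (
        np.array([[-1, -1, -1], [-1, 10, -1], [-1, -1, -1]], dtype=float),
        2.0,
    ),
    "sharpen": (
        np.array([[-2, -2, -2], [-2, 32, -2], [-2, -2, -2]], dtype=float),
        16.0,
    ),
}


def apply_filter(crop, kind: str) -> np.ndarray:
    """Apply a fixed preprocessing convolution (blur / edge_enhance / sharpen)."""
    key = kind.lower()
    if key == "none":
        return _as_array(crop)
    if key not in _FILTER_KERNELS:
        raise ValueError(f"unknown filter kind: {kind!r}")
    kernel, scale = _FILTER_KERNELS[key]
    return ndimage.correlate(_as_array(crop), kernel / scale, mode="reflect")
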