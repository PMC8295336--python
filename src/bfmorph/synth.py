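"""Synthetic bright-field / nuclear-stain image pairs and feature tables.

The generator emulates the statistical structure the downstream analysis
relies on: each cell is a region of an otherwise flat bright-field image
containing a Poisson number of darker elliptical "clumps" (stand-ins for
organelles and other intracellular structures), while the paired nuclear
channel carries one bright Gaussian blob per cell for localization.
Genotypes differ only through the clump process (count rate, lognormal
area, ellipse axis ratio, darkness), so every planted effect is known
exactly and can be checked against the extracted features.

A faster, image-free shortcut (`generate_feature_table`) draws feature
vectors directly from an equicorrelated Gaussian with mean shifts on a
chosen index set; it is used to exercise the modeling stack at scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GenotypeParams",
    "FieldGeometry",
    "TruthRecord",
    "FieldImagePair",
    "EffectSpec",
    "generate_cell_image",
    "generate_population",
    "generate_feature_table",
    "default_genotype_panel",
    "write_population",
    "feature_columns",
]

N_FEATURES = 296


def feature_columns(n: int = N_FEATURES) -> list[str]:
    """Canonical feature column names ``f001 .. f296``."""
    return [f"f{i + 1:03d}" for i in range(n)]


@dataclass(frozen=True)
class GenotypeParams:
    """Clump-process parameters for one genotype.

    clump_rate
        Expected clumps per cell (Poisson mean).
    clump_area_mu, clump_area_sigma
        Log-scale location/scale of the lognormal clump pixel area.
    clump_axis_ratio
        Major/minor axis ratio of the clump ellipses (>= 1); drives
        noncircularity.
    clump_darkness
        Typical intensity offset of clump pixels below background, in gray
        levels. Individual clumps vary in depth (see clump_depth_spread),
        so successive thresholds of the ladder reveal successively more
        clumps, as in real bright-field texture.
    clump_depth_spread
        Half-width of the per-clump relative depth factor: each clump's
        depth is ``clump_darkness * U(1 - s, 1 + s)``.
    background_mean, background_noise_sd
        Background gray level and i.i.d. Gaussian noise SD.
    clone_offsets
        Additive shifts on ``clump_rate`` for the two independently
        screened clones.
    """

    name: str
    clump_rate: float = 3.0
    clump_area_mu: float = math.log(45.0)
    clump_area_sigma: float = 0.35
    clump_axis_ratio: float = 1.3
    clump_darkness: float = 60.0
    clump_depth_spread: float = 0.4
    background_mean: float = 1000.0
    background_noise_sd: float = 6.0
    clone_offsets: tuple[float, float] = (-0.15, 0.15)

    def __post_init__(self) -> None:
        if self.clump_rate < 0:
            raise ValueError("clump_rate must be >= 0")
        if self.clump_axis_ratio < 1:
            raise ValueError("clump_axis_ratio must be >= 1")
        if not 0 <= self.clump_depth_spread < 1:
            raise ValueError("clump_depth_spread must lie in [0, 1)")
        if self.background_mean - self.clump_darkness * (1 + self.clump_depth_spread) < 0:
            raise ValueError("clump_darkness may not exceed background_mean")
        if len(self.clone_offsets) != 2:
            raise ValueError("exactly two clone offsets are required")


@dataclass(frozen=True)
class FieldGeometry:
    """Pixel geometry of a synthetic field.

    Defaults target a 1024x1024 field holding >= 25 cells as disks of
    radius ~40 px; the nuclear blob (Gaussian, sigma 8 px, amplitude far
    above background) is deliberately easy for a classical detector.
    """

    field_shape: tuple[int, int] = (1024, 1024)
    cell_radius: int = 40
    nucleus_sigma: float = 8.0
    nucleus_amplitude: float = 20000.0
    nucleus_background: float = 100.0
    nucleus_noise_sd: float = 5.0

    def scaled(self, factor: float) -> "FieldGeometry":
        """Proportionally smaller geometry for fast runs."""
        return FieldGeometry(
            field_shape=(
                max(64, int(self.field_shape[0] * factor)),
                max(64, int(self.field_shape[1] * factor)),
            ),
            cell_radius=max(8, int(self.cell_radius * factor)),
            nucleus_sigma=max(2.0, self.nucleus_sigma * factor),
            nucleus_amplitude=self.nucleus_amplitude,
            nucleus_background=self.nucleus_background,
            nucleus_noise_sd=self.nucleus_noise_sd,
        )


@dataclass
class TruthRecord:
    """Ground truth for one planted cell (test plumbing)."""

    cell_center: tuple[int, int]
    nucleus_box: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    planted_clumps: list[tuple[tuple[float, float], int, float]]
    genotype: str
    clone: int


@dataclass
class FieldImagePair:
    """One imaging field: bright-field + nuclear channel + ground truth."""

    bf: np.ndarray
    nuclear: np.ndarray
    truth: list[TruthRecord]
    field_id: str = "field_000"

    def __post_init__(self) -> None:
        if self.bf.shape != self.nuclear.shape:
            raise ValueError("bf and nuclear images must share a shape")


@dataclass(frozen=True)
class EffectSpec:
    """Model-level effect description for the image-free table generator."""

    n_features: int = N_FEATURES
    shifted_indices: tuple[int, ...] = ()
    delta: tuple[float, ...] = ()
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")
        if len(self.shifted_indices) != len(self.delta):
            raise ValueError("delta must match shifted_indices in length")
        if any(not 0 <= i < self.n_features for i in self.shifted_indices):
            raise ValueError("shifted index out of range")


def _rasterize_ellipse(center, area, axis_ratio, theta, shape):
    """Pixel coordinates of a filled ellipse of given continuous area."""
    a = math.sqrt(area * axis_ratio / math.pi)  # major semi-axis
    b = math.sqrt(area / (axis_ratio * math.pi))
    r0 = max(0, int(center[0] - a - 1))
    r1 = min(shape[0], int(center[0] + a + 2))
    c0 = max(0, int(center[1] - a - 1))
    c1 = min(shape[1], int(center[1] + a + 2))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc[inside], a


def _sample_clumps(rng, params, rate, center, cell_radius, shape,
                   min_area=5, min_gap=3.0, max_attempts=60):
    """Place k ~ Poisson(rate) non-overlapping dark ellipses inside the cell disk.

    Degenerate draws (too large for the cell, too small to survive the
    extractor's area filter, or overlapping a previous clump) are
    resampled; the number of resamples is returned for logging.
    """
    k = int(rng.poisson(rate))
    placed = []  # (center, coords_r, coords_c, bounding_radius, area, axis_ratio)
    resamples = 0
    for _ in range(k):
        for attempt in range(max_attempts):
            area = float(rng.lognormal(params.clump_area_mu, params.clump_area_sigma))
            area = max(area, float(min_area) + 1.0)
            a = math.sqrt(area * params.clump_axis_ratio / math.pi)
            if a + 2 >= cell_radius:
                resamples += 1
                continue
            rad = float(rng.uniform(0, cell_radius - a - 2))
            ang = float(rng.uniform(0, 2 * math.pi))
            cr = center[0] + rad * math.sin(ang)
            cc = center[1] + rad * math.cos(ang)
            theta = float(rng.uniform(0, math.pi))
            ok = all(
                math.hypot(cr - p[0][0], cc - p[0][1]) > a + p[3] + min_gap
                for p in placed
            )
            if not ok:
                resamples += 1
                continue
            rr, cols, a_out = _rasterize_ellipse((cr, cc), area, params.clump_axis_ratio, theta, shape)
            if rr.size < min_area:
                resamples += 1
                continue
            placed.append(((cr, cc), rr, cols, a_out, int(rr.size), params.clump_axis_ratio))
            break
        # else: clump dropped after max_attempts (counted via resamples)
    return placed, resamples


def _paint_cell(bf, nuclear, rng, params, rate, center, geometry):
    placed, resamples = _sample_clumps(
        rng, params, rate, center, geometry.cell_radius, bf.shape
    )
    s = params.clump_depth_spread
    for (ctr, rr, cc, _a, _area, _q) in placed:
        depth = params.clump_darkness * rng.uniform(1 - s, 1 + s)
        bf[rr, cc] -= depth
    # nuclear blob
    sig = geometry.nucleus_sigma
    half = int(math.ceil(3 * sig))
    r0 = max(0, center[0] - half)
    r1 = min(bf.shape[0], center[0] + half + 1)
    c0 = max(0, center[1] - half)
    c1 = min(bf.shape[1], center[1] + half + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    nuclear[r0:r1, c0:c1] += geometry.nucleus_amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sig**2)
    )
    box_half = int(math.ceil(2 * sig))
    box = (center[0] - box_half, center[1] - box_half,
           center[0] + box_half + 1, center[1] + box_half + 1)
    clumps = [(p[0], p[4], p[5]) for p in placed]
    return clumps, box, resamples


def _finalize(img):
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def generate_cell_image(
    params: GenotypeParams,
    clone: int = 0,
    seed: int | np.random.SeedSequence = 0,
    geometry: FieldGeometry | None = None,
) -> FieldImagePair:
    """Synthesize a single-cell field (one cell centered in a small image)."""
    if clone not in (0, 1):
        raise ValueError("clone must be 0 or 1")
    geometry = geometry or FieldGeometry()
    rng = np.random.default_rng(seed)
    side = 4 * geometry.cell_radius
    shape = (side, side)
    bf = rng.normal(params.background_mean, params.background_noise_sd, shape)
    nuclear = rng.normal(geometry.nucleus_background, geometry.nucleus_noise_sd, shape)
    center = (side // 2, side // 2)
    rate = max(0.0, params.clump_rate + params.clone_offsets[clone])
    clumps, box, _ = _paint_cell(bf, nuclear, rng, params, rate, center, geometry)
    truth = TruthRecord(center, box, clumps, params.name, clone)
    return FieldImagePair(_finalize(bf), _finalize(nuclear), [truth], "cell_000")


def generate_population(
    params: GenotypeParams,
    n_cells: int,
    cells_per_field: int = 27,
    seed: int | np.random.SeedSequence = 0,
    geometry: FieldGeometry | None = None,
) -> list[FieldImagePair]:
    """Generate fields holding ``n_cells`` cells on a jittered grid.

    Cells alternate between the two clones; nucleus boxes never overlap
    (cells sit on a grid whose pitch exceeds four cell radii, which also
    keeps each cell's clumps out of its neighbours' crops).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    geometry = geometry or FieldGeometry()
    H, W = geometry.field_shape
    ncols = max(1, int(math.floor(math.sqrt(cells_per_field))))
    nrows = int(math.ceil(cells_per_field / ncols))
    pitch_r = H / nrows
    pitch_c = W / ncols
    min_pitch = 4 * geometry.cell_radius
    if pitch_r < min_pitch or pitch_c < min_pitch:
        raise ValueError(
            f"field {H}x{W} too small for {cells_per_field} cells of radius "
            f"{geometry.cell_radius}: grid pitch ({pitch_r:.0f}, {pitch_c:.0f}) px "
            f"is below the {min_pitch} px needed for non-overlapping crops"
        )
    n_fields = int(math.ceil(n_cells / cells_per_field))
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = ss.spawn(n_fields)
    fields = []
    cell_index = 0
    for fi in range(n_fields):
        rng = np.random.default_rng(children[fi])
        bf = rng.normal(params.background_mean, params.background_noise_sd, (H, W))
        nuclear = rng.normal(geometry.nucleus_background, geometry.nucleus_noise_sd, (H, W))
        truth = []
        n_here = min(cells_per_field, n_cells - cell_index)
        jitter = max(0.0, min(pitch_r, pitch_c) / 2 - 2 * geometry.cell_radius - 1)
        for k in range(n_here):
            gr, gc = divmod(k, ncols)
            center = (
                int(round((gr + 0.5) * pitch_r + rng.uniform(-jitter, jitter))),
                int(round((gc + 0.5) * pitch_c + rng.uniform(-jitter, jitter))),
            )
            clone = cell_index % 2
            rate = max(0.0, params.clump_rate + params.clone_offsets[clone])
            clumps, box, _ = _paint_cell(bf, nuclear, rng, params, rate, center, geometry)
            truth.append(TruthRecord(center, box, clumps, params.name, clone))
            cell_index += 1
        fields.append(FieldImagePair(_finalize(bf), _finalize(nuclear), truth, f"field_{fi:03d}"))
    return fields


def generate_feature_table(
    spec: EffectSpec,
    n_per_class: int,
    seed: int | np.random.SeedSequence = 0,
    mutant_name: str = "MUT",
) -> pd.DataFrame:
    """Draw a wild-type + one-mutant feature table directly at model level.

    Wild-type rows are equicorrelated standard normal; mutant rows add the
    specified mean shifts. Columns: cell_id, genotype, clone, f001..f296.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = np.random.default_rng(seed)
    p = spec.n_features
    rho = spec.correlation

    def draw(n):
        z = rng.standard_normal((n, p))
        if rho > 0:
            common = rng.standard_normal((n, 1))
            z = math.sqrt(rho) * common + math.sqrt(1 - rho) * z
        return z

    wt = draw(n_per_class)
    mut = draw(n_per_class)
    for idx, d in zip(spec.shifted_indices, spec.delta):
        mut[:, idx] += d
    X = np.vstack([wt, mut])
    df = pd.DataFrame(X, columns=feature_columns(p))
    df.insert(0, "clone", np.arange(2 * n_per_class) % 2)
    df.insert(0, "genotype", ["WT"] * n_per_class + [mutant_name] * n_per_class)
    df.insert(0, "cell_id", [f"c{i:05d}" for i in range(2 * n_per_class)])
    return df


#: Paralog pairs of the knockout panel (ubiquitin-proteasome system).
PARALOG_PAIRS = (
    ("PSMA2", "PSMA7"),
    ("PSMB5", "PSMB6"),
    ("PSME1", "PSME2"),
    ("UBQLN1", "UBQLN2"),
)

WILD_TYPE = "WT"


def default_genotype_panel(seed: int | None = None) -> list[GenotypeParams]:
    """Reference wild type + eight mutants, paralog pairs sharing effect direction.

    Each paralog pair perturbs one clump property in a common direction
    (with slightly different magnitudes within the pair), so that
    coefficient-profile clustering can recover the pairs:

    - PSMA2/PSMA7: more clumps
    - PSMB5/PSMB6: larger but fewer clumps (total clump area roughly
      conserved, so the pair is separable from PSMA2/PSMA7 in profile
      space, not only in magnitude)
    - PSME1/PSME2: more elongated (noncircular) clumps
    - UBQLN1/UBQLN2: darker clumps

    Effect sizes are calibrated to the subtle regime the analysis is
    meant for (per-mutant nested-CV AUC roughly 0.6-0.85, not ceiling).
    ``seed`` is accepted for interface symmetry; the panel is fixed.
    """
    wt = GenotypeParams(WILD_TYPE)
    return [
        wt,
        GenotypeParams("PSMA2", clump_rate=4.7),
        GenotypeParams("PSMA7", clump_rate=5.0),
        GenotypeParams("PSMB5", clump_area_mu=wt.clump_area_mu + 0.22, clump_rate=2.4),
        GenotypeParams("PSMB6", clump_area_mu=wt.clump_area_mu + 0.30, clump_rate=2.2),
        GenotypeParams("PSME1", clump_axis_ratio=1.60),
        GenotypeParams("PSME2", clump_axis_ratio=1.70),
        GenotypeParams("UBQLN1", clump_darkness=68.0),
        GenotypeParams("UBQLN2", clump_darkness=72.0),
    ]


def matched_clump_count(pair: FieldImagePair, params: GenotypeParams, config=None) -> int:
    """Clump count at the threshold matched to the planted contrast.

    The matched threshold sits halfway into the shallowest planted
    darkness, ``background_mean - clump_darkness * (1 - spread) / 2``,
    expressed as the fraction tau of the crop's min-max range and fed
    through the extractor's own binarize + label machinery. In a crop
    with no planted clump the matched cut falls below the crop minimum
    (there is no planted contrast), so the matched count is zero.
    """
    from . import features as feat

    config = config or feat.FeatureConfig()
    img = pair.bf.astype(float)
    lo, hi = img.min(), img.max()
    cut = params.background_mean - params.clump_darkness * (
        1 - params.clump_depth_spread
    ) / 2
    if hi == lo or cut <= lo:
        return 0
    tau = (cut - lo) / (hi - lo)
    mask = feat.binarize_dark(img, min(tau, 1.0 - 1e-9))
    return len(feat.label_clumps(mask, config))


def write_population(fields: Sequence[FieldImagePair], outdir: str | Path) -> None:
    """Write 16-bit TIFF pairs plus one JSON truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_blob = {}
    for f in fields:
        tifffile.imwrite(outdir / f"{f.field_id}_bf.tif", f.bf)
        tifffile.imwrite(outdir / f"{f.field_id}_nuc.tif", f.nuclear)
        truth_blob[f.field_id] = [
            {
                "cell_center": list(t.cell_center),
                "nucleus_box": list(t.nucleus_box),
                "planted_clumps": [
                    {"center": list(c[0]), "area": c[1], "axis_ratio": c[2]}
                    for c in t.planted_clumps
                ],
                "genotype": t.genotype,
                "clone": t.clone,
            }
            for t in f.truth
        ]
    (outdir / "truth.json").write_text(json.dumps(truth_blob, indent=1))
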