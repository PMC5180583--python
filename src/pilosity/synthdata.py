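"""Synthetic specimens and trait tables with known ground truth.

Real inputs are focus-stacked photographs of pinned insects; these
generators emulate the features the pipeline responds to — a matte cuticle
base, anti-aliased hair strokes 3.5-4.5 px wide (the width range observed
across species at the original imaging scale), bright near-circular pollen
contaminants, and sensor noise — so every stage can be tested against a
recorded ground truth without photographs.

Trait tables are drawn from a linear model with a known true predictor
subset, emulating the statistical structure behind the species-level
regression analysis (n ~ 7-10 species, top-model R^2 ~ 0.95).

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .roi import CANONICAL_LABELS, PolygonRoI, RoISet, save_roiset

__all__ = [
    "TextureParams",
    "SyntheticSpecimen",
    "SyntheticTraitConfig",
    "make_hairy_patch",
    "add_pollen_artifacts",
    "make_specimen",
    "make_trait_table",
    "write_fixture_bundle",
]

#: Dark matte cuticle with dim hairs; bright-yellow pollen must out-shine
#: the surface ~7x in luminance for the local-mean segmentation to isolate
#: grains behind a sub-threshold moat (see methods note).
DEFAULT_BASE_COLOR = (18, 15, 12)
DEFAULT_HAIR_COLOR = (34, 30, 22)
DEFAULT_POLLEN_COLOR = (250, 240, 80)

#: Default pollen grain radius range, px. Large grains at the original
#: imaging scale; small digital disks (radius < ~5 px) fall outside the 5%
#: circularity band under the center-to-center boundary perimeter.
DEFAULT_POLLEN_RADIUS = (6.0, 9.0)


@dataclass
class TextureParams:
    """Hair texture parameters.

    ``hair_density`` is the target areal hair coverage (0 = bare cuticle,
    ~0.8 = dense fur); the stroke count is Poisson with mean
    ``density * patch_area / mean_stroke_area``, so overlap makes realized
    coverage somewhat lower. Stroke width is drawn uniformly from
    ``hair_width`` (px), length from ``hair_length`` (px). ``noise_sd`` is
    additive Gaussian sensor noise in gray levels.
    """

    hair_density: float = 0.5
    hair_width: tuple[float, float] = (3.5, 4.5)
    hair_length: tuple[float, float] = (15.0, 30.0)
    base_color: tuple[int, int, int] = DEFAULT_BASE_COLOR
    hair_color: tuple[int, int, int] = DEFAULT_HAIR_COLOR
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hair_density < 0:
            raise ValueError("hair_density must be >= 0")
        if self.hair_width[0] <= 0:
            raise ValueError("hair_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticSpecimen:
    """A generated image with its RoI set and recorded ground truth."""

    rgb: np.ndarray
    roiset: RoISet
    densities: dict[str, float]
    contaminants: list[tuple[float, float, float]] = field(default_factory=list)
    # contaminants: (center_x, center_y, radius) in image coordinates


@dataclass
class SyntheticTraitConfig:
    """Ground truth for a synthetic species-level trait table.

    Predictors (eight region entropies + body length) are multivariate
    normal; the response is ``intercept + sum(coef * predictor) + noise``
    with the residual SD calibrated so the true model's expected R^2 equals
    ``target_r2``.
    """

    n_species: int = 10
    response: str = "svd"
    true_effects: dict[str, float] = field(
        default_factory=lambda: {"face": 1.2, "thorax_dorsal": 0.9}
    )
    intercept: float = 5.0
    target_r2: float = 0.95
    predictor_mean: float = 50.0
    predictor_sd: float = 15.0
    predictor_corr: float = 0.3
    residual_sd: float | None = None  # overrides target_r2 calibration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < len(self.true_effects) + 3:
            raise ValueError("n_species must be >= true subset size + 3")
        if not 0 < self.target_r2 < 1:
            raise ValueError("target_r2 must be in (0, 1)")


def _draw_capsule(img: np.ndarray, p0, p1, width: float, color: np.ndarray) -> None:
    """Alpha-blend an anti-aliased thick segment (capsule) onto float img."""
    h, w = img.shape[:2]
    half = width / 2.0
    x0 = int(max(0, np.floor(min(p0[0], p1[0]) - half - 1)))
    x1 = int(min(w, np.ceil(max(p0[0], p1[0]) + half + 2)))
    y0 = int(max(0, np.floor(min(p0[1], p1[1]) - half - 1)))
    y1 = int(min(h, np.ceil(max(p0[1], p1[1]) + half + 2)))
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) + 0.5
    ys = np.arange(y0, y1) + 0.5
    px, py = np.meshgrid(xs, ys)
    ex, ey = p1[0] - p0[0], p1[1] - p0[1]
    seg2 = ex * ex + ey * ey
    if seg2 == 0:
        dist = np.hypot(px - p0[0], py - p0[1])
    else:
        t = np.clip(((px - p0[0]) * ex + (py - p0[1]) * ey) / seg2, 0.0, 1.0)
        dist = np.hypot(px - (p0[0] + t * ex), py - (p0[1] + t * ey))
    alpha = np.clip(half + 0.5 - dist, 0.0, 1.0)[..., None]
    img[y0:y1, x0:x1] = img[y0:y1, x0:x1] * (1 - alpha) + color * alpha


def _draw_disk(img: np.ndarray, cx: float, cy: float, radius: float,
               color: np.ndarray) -> None:
    """Alpha-blend an anti-aliased filled disk onto float img."""
    _draw_capsule(img, (cx, cy), (cx, cy), 2.0 * radius, color)


def make_hairy_patch(width: int, height: int, params: TextureParams) -> np.ndarray:
    """Render one hairy surface patch as an 8-bit RGB image.

    Strokes are straight anti-aliased capsules with uniform random position,
    orientation, width and length, slight per-stroke brightness jitter, on a
    flat base color, plus clipped Gaussian noise. Deterministic in ``seed``.
    """
    rng = np.random.default_rng(params.seed)
    img = np.empty((height, width, 3), dtype=np.float64)
    img[:] = np.asarray(params.base_color, dtype=np.float64)
    mean_stroke_area = (
        0.5 * (params.hair_length[0] + params.hair_length[1])
        * 0.5 * (params.hair_width[0] + params.hair_width[1])
    )
    n_strokes = rng.poisson(
        params.hair_density * width * height / mean_stroke_area
    )
    hair = np.asarray(params.hair_color, dtype=np.float64)
    for _ in range(n_strokes):
        cx = rng.uniform(0, width)
        cy = rng.uniform(0, height)
        theta = rng.uniform(0, np.pi)
        length = rng.uniform(*params.hair_length)
        w_px = rng.uniform(*params.hair_width)
        shade = rng.uniform(0.8, 1.2)
        dx, dy = 0.5 * length * np.cos(theta), 0.5 * length * np.sin(theta)
        _draw_capsule(img, (cx - dx, cy - dy), (cx + dx, cy + dy), w_px,
                      np.clip(hair * shade, 0, 255))
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def add_pollen_artifacts(
    image: np.ndarray,
    n: int,
    radius_range: tuple[float, float] = DEFAULT_POLLEN_RADIUS,
    color: tuple[int, int, int] = DEFAULT_POLLEN_COLOR,
    seed: int = 0,
    region_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, list[tuple[float, float, float]]]:
    """Stamp ``n`` bright pollen-like disks onto a copy of ``image``.

    Centers are uniform over the allowed area (``region_mask`` if given,
    else the whole image with a margin) and kept at least one diameter
    apart so grains stay individually detectable. Returns the new image and
    the ground-truth circle list ``(cx, cy, radius)``.
    """
    if radius_range[0] < 2:
        raise ValueError("pollen radii must be >= 2 px")
    img = image.astype(np.float64).copy()
    h, w = img.shape[:2]
    circles: list[tuple[float, float, float]] = []
    if n == 0:
        return image.copy(), circles
    rng = np.random.default_rng(seed)
    col = np.asarray(color, dtype=np.float64)
    r_max = radius_range[1]
    min_sep = 2.0 * r_max + 2.0
    attempts = 0
    while len(circles) < n and attempts < 1000 * n:
        attempts += 1
        cx = rng.uniform(r_max + 2, w - r_max - 2)
        cy = rng.uniform(r_max + 2, h - r_max - 2)
        if region_mask is not None:
            ix, iy = int(cx), int(cy)
            if not region_mask[iy, ix]:
                continue
        if any(np.hypot(cx - x, cy - y) < min_sep for x, y, _ in circles):
            continue
        radius = rng.uniform(*radius_range)
        _draw_disk(img, cx, cy, radius, col)
        circles.append((cx, cy, radius))
    if len(circles) < n:
        raise ValueError(f"could not place {n} non-overlapping pollen disks")
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), circles


def make_specimen(
    regions_spec: list[tuple[str, float]],
    seed: int = 0,
    region_size: tuple[int, int] = (160, 160),
    margin: int = 16,
    params: TextureParams | None = None,
    n_pollen: int = 0,
    image_id: str = "synthetic",
) -> SyntheticSpecimen:
    """Compose hairy patches into one specimen image with an RoI set.

    Each (label, density) pair becomes one axis-aligned rectangular region;
    regions are laid out on a grid, separated and set back from the image
    border by ``margin`` px, on a white background (pinned specimens are
    photographed on white). Pollen contaminants, if requested, are stamped
    into every region and recorded as ground truth.
    """
    if not regions_spec:
        raise ValueError("at least one region required")
    labels = [lbl for lbl, _ in regions_spec]
    if len(set(labels)) != len(labels):
        raise ValueError("region labels overlap (duplicate labels)")
    base = params or TextureParams()
    rw, rh = region_size
    ncols = int(np.ceil(np.sqrt(len(regions_spec))))
    nrows = int(np.ceil(len(regions_spec) / ncols))
    width = margin + ncols * (rw + margin)
    height = margin + nrows * (rh + margin)
    img = np.full((height, width, 3), 235, dtype=np.uint8)  # white card
    rois: list[PolygonRoI] = []
    densities: dict[str, float] = {}
    contaminants: list[tuple[float, float, float]] = []
    rng = np.random.default_rng(seed)
    for idx, (label, density) in enumerate(regions_spec):
        gx = idx % ncols
        gy = idx // ncols
        x0 = margin + gx * (rw + margin)
        y0 = margin + gy * (rh + margin)
        p = TextureParams(
            hair_density=density,
            hair_width=base.hair_width,
            hair_length=base.hair_length,
            base_color=base.base_color,
            hair_color=base.hair_color,
            noise_sd=base.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        patch = make_hairy_patch(rw, rh, p)
        if n_pollen > 0:
            patch, circles = add_pollen_artifacts(
                patch, n_pollen, seed=int(rng.integers(0, 2**31 - 1))
            )
            contaminants.extend((cx + x0, cy + y0, r) for cx, cy, r in circles)
        img[y0 : y0 + rh, x0 : x0 + rw] = patch
        rois.append(
            PolygonRoI(
                label,
                np.array(
                    [[x0, y0], [x0 + rw, y0], [x0 + rw, y0 + rh], [x0, y0 + rh]],
                    dtype=float,
                ),
            )
        )
        densities[label] = density
    roiset = RoISet(image_id, width, height, rois)
    return SyntheticSpecimen(img, roiset, densities, contaminants)


def make_trait_table(cfg: SyntheticTraitConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a species-level trait table from a known linear model.

    Predictor rows (eight region entropies + body length) come from an
    equicorrelated multivariate normal; the response adds Gaussian noise
    whose SD is set from the true coefficients and predictor covariance so
    the true model's population R^2 equals ``cfg.target_r2``. Returns the
    table and a truth record (coefficients, residual SD, true subset).
    """
    rng = np.random.default_rng(cfg.seed)
    preds = list(CANONICAL_LABELS) + ["body_length"]
    for t in cfg.true_effects:
        if t not in preds:
            raise ValueError(f"unknown true predictor {t!r}")
    p = len(preds)
    corr = np.full((p, p), cfg.predictor_corr)
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("predictor correlation is not positive definite") from exc
    z = rng.standard_normal((cfg.n_species, p))
    X = cfg.predictor_mean + cfg.predictor_sd * (z @ chol.T)
    # body length on its own scale (mm)
    bl = X[:, -1]
    X[:, -1] = 10.0 + 3.0 * (bl - cfg.predictor_mean) / cfg.predictor_sd
    df = pd.DataFrame(X, columns=preds)
    beta = np.array([cfg.true_effects.get(t, 0.0) for t in preds])
    # population covariance of the predictors on their final scales
    scales = np.full(p, cfg.predictor_sd)
    scales[-1] = 3.0
    cov = corr * np.outer(scales, scales)
    signal_var = float(beta @ cov @ beta)
    if cfg.residual_sd is not None:
        resid_sd = float(cfg.residual_sd)
    else:
        resid_sd = float(
            np.sqrt(signal_var * (1.0 - cfg.target_r2) / cfg.target_r2)
        )
    y = cfg.intercept + df.to_numpy() @ beta
    if resid_sd > 0:
        y = y + rng.normal(0.0, resid_sd, cfg.n_species)
    df.insert(0, "species", [f"species_{i+1:02d}" for i in range(cfg.n_species)])
    df[cfg.response] = y
    truth = {
        "response": cfg.response,
        "true_subset": tuple(sorted(cfg.true_effects)),
        "coefficients": dict(cfg.true_effects),
        "intercept": cfg.intercept,
        "residual_sd": resid_sd,
        "target_r2": cfg.target_r2,
    }
    return df, truth


def write_fixture_bundle(out_dir, preset: str, seed: int = 0) -> dict:
    """Write a named fixture bundle (PNG + RoI JSON + truth JSON + CSV).

    Presets: ``two-region`` (smooth vs hairy patch), ``eight-region`` (all
    canonical regions, graded densities), ``pollen`` (two regions with five
    injected grains each), ``trait-recovery`` (trait CSV with known truth).
    Returns a manifest of written paths.
    """
    import imageio.v3 as iio
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"preset": preset, "seed": seed, "files": []}

    def _write_specimen(spec: SyntheticSpecimen) -> None:
        img_path = out / f"{spec.roiset.image_id}.png"
        iio.imwrite(img_path, spec.rgb)
        roi_path = out / f"{spec.roiset.image_id}.rois.json"
        save_roiset(spec.roiset, roi_path)
        truth_path = out / f"{spec.roiset.image_id}.truth.json"
        with open(truth_path, "w") as fh:
            json.dump(
                {
                    "densities": spec.densities,
                    "contaminants": spec.contaminants,
                },
                fh,
                indent=1,
            )
        manifest["files"] += [img_path.name, roi_path.name, truth_path.name]

    if preset == "two-region":
        _write_specimen(
            make_specimen(
                [("thorax_dorsal", 0.0), ("face", 0.8)], seed=seed,
                image_id=f"two_region_{seed}",
            )
        )
    elif preset == "eight-region":
        densities = np.linspace(0.1, 0.8, len(CANONICAL_LABELS))
        _write_specimen(
            make_specimen(
                list(zip(CANONICAL_LABELS, densities)), seed=seed,
                image_id=f"eight_region_{seed}",
            )
        )
    elif preset == "pollen":
        _write_specimen(
            make_specimen(
                [("face", 0.5), ("thorax_dorsal", 0.5)], seed=seed,
                n_pollen=5, image_id=f"pollen_{seed}",
            )
        )
    elif preset == "trait-recovery":
        df, truth = make_trait_table(SyntheticTraitConfig(seed=seed))
        csv_path = out / "traits.csv"
        df.to_csv(csv_path, index=False)
        truth_path = out / "traits.truth.json"
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)
        manifest["files"] += [csv_path.name, truth_path.name]
    else:
        raise ValueError(f"unknown preset {preset!r}")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
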