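"""Pigmentation classification and planar-area measurement of colony photographs.

Each scene carries an embedded color chart and a scale marker.  The chart
drives a per-channel affine color correction for water-column tint; the
scale marker converts pixel counts to cm².  After correction, colony
pixels are classified in CIELAB space:

* **DEAD** — turf/skeleton signature (strongly green, a* below a cutoff),
* **BLEACHED** — nearly completely white: high lightness, low chroma,
* **PARTIAL** — residual pigmentation: an intermediate lightness band,
* **PIGMENTED** — everything else inside the colony mask.

Measurement reports live planar area (pigmented + partial + bleached),
dead area, and bleached / partially bleached fractions of the live area.
Dead patches fully enclosed by live tissue are reported separately as
interior dead area (they are never part of the live area); dead regions
touching the colony margin count toward the dead total as colony margin
mortality.

The thresholds are conventions standing in for a visual judgement; they
are carried in :class:`ClassifierConfig` and echoed into output metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as _ndi
from skimage import color as _skcolor
from skimage import measure as _skmeasure

from .synth import (
    BACKGROUND,
    BLEACHED,
    DEAD,
    PARTIAL,
    PIGMENTED,
    ChartPatch,
    SceneImage,
)

__all__ = [
    "CalibrationError",
    "EmptyColonyError",
    "ColorTransform",
    "ClassifierConfig",
    "PigmentationMap",
    "ColonyObservation",
    "calibrate_color",
    "classify_tissue",
    "measure",
    "quantify_scene",
    "scene_from_files",
]


class CalibrationError(ValueError):
    """Too few usable chart patches to fit a color transform."""


class EmptyColonyError(ValueError):
    """A provided colony mask contains no pixels."""


@dataclass(frozen=True)
class ColorTransform:
    """Per-channel affine map ``true = gain * observed + offset``."""

    gains: tuple[float, float, float]
    offsets: tuple[float, float, float]
    residual_rms: float
    n_patches: int

    def apply(self, image: np.ndarray) -> np.ndarray:
        g = np.asarray(self.gains)[None, None, :]
        o = np.asarray(self.offsets)[None, None, :]
        return np.clip(image * g + o, 0.0, 1.0)

    @classmethod
    def identity(cls) -> "ColorTransform":
        return cls((1.0, 1.0, 1.0), (0.0, 0.0, 0.0), 0.0, 0)


@dataclass(frozen=True)
class ClassifierConfig:
    """CIELAB decision thresholds for the pigmentation classes."""

    bleached_L_min: float = 80.0
    bleached_chroma_max: float = 14.0
    partial_L_min: float = 55.0
    dead_a_max: float = -10.0
    patch_std_max: float = 0.05  # a chart patch above this is considered occluded
    background_dist_min: float = 0.12  # RGB distance for mask derivation


@dataclass
class PigmentationMap:
    """Per-pixel pigmentation labels with the physical pixel scale."""

    labels: np.ndarray  # uint8, codes BACKGROUND..DEAD
    cm_per_pixel: float
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    def __post_init__(self):
        if self.cm_per_pixel <= 0:
            raise ValueError("cm_per_pixel must be positive")


@dataclass(frozen=True)
class ColonyObservation:
    """Planar-area and pigmentation summary of one colony at one time point."""

    colony_id: str
    month: int
    live_area_cm2: float
    frac_bleached: float
    frac_partial: float
    dead_area_cm2: float
    interior_dead_area_cm2: float
    status: str  # alive | dead | lost
    subsampled: bool = False

    def __post_init__(self):
        if self.frac_bleached + self.frac_partial > 1.0 + 1e-9:
            raise ValueError("bleached + partial fractions exceed the live area")
        if self.status == "dead" and self.live_area_cm2 != 0:
            raise ValueError("a dead colony has zero live area")


def calibrate_color(scene: SceneImage) -> ColorTransform:
    """Fit the per-channel affine tint correction from the chart patches.

    A patch is usable when it lies inside the image and its pixel spread is
    small (occluded or overgrown patches fail that check).  At least three
    usable patches are required; the least-squares fit minimizes the
    squared error between observed and true patch colors per channel.
    """
    H, W = scene.image.shape[:2]
    observed, true = [], []
    for p in scene.chart:
        y0, y1, x0, x1 = p.rect
        if y0 < 0 or x0 < 0 or y1 > H or x1 > W or y1 <= y0 or x1 <= x0:
            continue
        region = scene.image[y0:y1, x0:x1].reshape(-1, 3)
        if region.std(axis=0).max() > ClassifierConfig.patch_std_max:
            continue
        observed.append(region.mean(axis=0))
        true.append(p.true_rgb)
    if len(observed) < 3:
        raise CalibrationError(
            f"only {len(observed)} usable chart patches found (need >= 3)"
        )
    obs = np.asarray(observed)
    tru = np.asarray(true)
    gains, offsets, resid = [], [], []
    for ch in range(3):
        A = np.column_stack([obs[:, ch], np.ones(len(obs))])
        (g, o), res, *_ = np.linalg.lstsq(A, tru[:, ch], rcond=None)
        gains.append(float(g))
        offsets.append(float(o))
        resid.append(float(res[0]) if len(res) else 0.0)
    rms = math.sqrt(sum(resid) / (3 * len(obs)))
    return ColorTransform(tuple(gains), tuple(offsets), rms, len(obs))


def _derive_mask(scene: SceneImage, corrected: np.ndarray, config: ClassifierConfig) -> np.ndarray:
    """Colony mask from background-color distance, excluding the references."""
    border = np.concatenate(
        [
            corrected[0:4].reshape(-1, 3),
            corrected[-4:].reshape(-1, 3),
            corrected[:, 0:4].reshape(-1, 3),
            corrected[:, -4:].reshape(-1, 3),
        ]
    )
    bg = np.median(border, axis=0)
    dist = np.linalg.norm(corrected - bg[None, None, :], axis=-1)
    mask = dist > config.background_dist_min
    for p in scene.chart:
        y0, y1, x0, x1 = p.rect
        mask[max(y0 - 3, 0) : y1 + 3, max(x0 - 3, 0) : x1 + 3] = False
    # scale bar: very dark pixels
    mask &= corrected.sum(axis=-1) > 0.3
    return mask


def classify_tissue(
    scene: SceneImage,
    transform: ColorTransform | None = None,
    colony_mask: np.ndarray | None = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> PigmentationMap:
    """Label every pixel of a (calibrated) scene with a pigmentation class.

    ``colony_mask`` delimits the colony; when omitted it is derived from
    the background color.  A provided empty mask raises
    :class:`EmptyColonyError`; a scene with no colony at all simply yields
    an all-background map.
    """
    corrected = transform.apply(scene.image) if transform is not None else scene.image
    if colony_mask is None:
        mask = _derive_mask(scene, corrected, config)
    else:
        mask = np.asarray(colony_mask, dtype=bool)
        if not mask.any():
            raise EmptyColonyError("provided colony mask is empty")
    lab = _skcolor.rgb2lab(corrected)
    L = lab[..., 0]
    chroma = np.hypot(lab[..., 1], lab[..., 2])
    labels = np.full(mask.shape, BACKGROUND, dtype=np.uint8)
    dead = mask & (lab[..., 1] < config.dead_a_max)
    bleached = mask & ~dead & (L >= config.bleached_L_min) & (chroma <= config.bleached_chroma_max)
    partial = mask & ~dead & ~bleached & (L >= config.partial_L_min)
    pigmented = mask & ~dead & ~bleached & ~partial
    labels[dead] = DEAD
    labels[bleached] = BLEACHED
    labels[partial] = PARTIAL
    labels[pigmented] = PIGMENTED
    return PigmentationMap(labels, scene.cm_per_pixel, config)


def measure(
    pigmap: PigmentationMap,
    colony_id: str = "colony",
    month: int = 0,
    subsampled: bool = False,
) -> ColonyObservation:
    """Planar areas and pigment fractions from a pigmentation map.

    Live area is pigmented + partial + bleached pixels times the pixel
    area; all dead pixels are excluded from it.  Dead components entirely
    enclosed by live tissue are additionally reported as interior dead
    area.  Zero live pixels with dead pixels present yields a whole-colony
    mortality observation (status ``dead``), not an error.
    """
    labels = pigmap.labels
    px_area = pigmap.cm_per_pixel**2
    n_pig = int((labels == PIGMENTED).sum())
    n_par = int((labels == PARTIAL).sum())
    n_bl = int((labels == BLEACHED).sum())
    n_live = n_pig + n_par + n_bl
    dead_mask = labels == DEAD
    n_dead = int(dead_mask.sum())

    interior_px = 0
    if n_dead:
        live_mask = (labels == PIGMENTED) | (labels == PARTIAL) | (labels == BLEACHED)
        comps = _skmeasure.label(dead_mask, connectivity=1)
        for region in _skmeasure.regionprops(comps):
            y0, x0, y1, x1 = region.bbox
            if y0 == 0 or x0 == 0 or y1 == labels.shape[0] or x1 == labels.shape[1]:
                continue  # touches the image border: margin mortality
            comp = comps == region.label
            ring = _ndi.binary_dilation(comp) & ~comp
            if np.all(live_mask[ring]):
                interior_px += int(region.area)

    live_area = n_live * px_area
    status = "dead" if (n_live == 0 and n_dead > 0) else "alive"
    return ColonyObservation(
        colony_id=colony_id,
        month=month,
        live_area_cm2=live_area,
        frac_bleached=n_bl / n_live if n_live else 0.0,
        frac_partial=n_par / n_live if n_live else 0.0,
        dead_area_cm2=n_dead * px_area,
        interior_dead_area_cm2=interior_px * px_area,
        status=status,
        subsampled=subsampled,
    )


def quantify_scene(
    scene: SceneImage,
    colony_mask: np.ndarray | None = None,
    colony_id: str = "colony",
    month: int = 0,
    config: ClassifierConfig = ClassifierConfig(),
    calibrate: bool = True,
) -> tuple[ColonyObservation, ColorTransform]:
    """Calibrate, classify and measure a scene in one call.

    A failed calibration falls back to the identity transform with a
    warning embedded in the returned transform (``n_patches == 0``).
    """
    if calibrate:
        try:
            transform = calibrate_color(scene)
        except CalibrationError:
            import warnings

            warnings.warn("color chart not found; proceeding uncalibrated", stacklevel=2)
            transform = ColorTransform.identity()
    else:
        transform = ColorTransform.identity()
    mask = colony_mask if colony_mask is not None else scene.colony_mask
    pigmap = classify_tissue(scene, transform, mask, config)
    return measure(pigmap, colony_id, month), transform


def scene_from_files(image_path, sidecar_path) -> SceneImage:
    """Load a scene from a PNG/TIFF image and its JSON sidecar.

    The sidecar holds the chart layout (true colors + rectangles), the
    scale marker (cm and pixels), and optionally a colony-mask polygon
    (list of [y, x] vertices).
    """
    import imageio.v3 as iio
    from skimage.draw import polygon as _sk_polygon

    img = iio.imread(image_path)
    if img.dtype != np.float64:
        img = img.astype(np.float64) / 255.0
    img = img[..., :3]
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    chart = [
        ChartPatch(tuple(p["true_rgb"]), tuple(p["rect"])) for p in meta["chart"]
    ]
    mask = None
    if "colony_polygon" in meta:
        poly = np.asarray(meta["colony_polygon"], dtype=float)
        rr, cc = _sk_polygon(poly[:, 0], poly[:, 1], shape=img.shape[:2])
        mask = np.zeros(img.shape[:2], dtype=bool)
        mask[rr, cc] = True
    return SceneImage(
        image=img,
        chart=chart,
        scale_cm=float(meta["scale_cm"]),
        scale_px=float(meta["scale_px"]),
        colony_mask=mask,
    )
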