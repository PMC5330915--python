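"""Synthetic data with the statistical structure the analysis assumes.

Three generators make every stage of the pipeline testable without any
field data:

* :func:`simulate_temperature` — a multi-year, depth-stratified logger
  series: sinusoidal seasonality around a long-term mean of 28.68 °C with
  triangular-ramp anomaly events (by default peaking in the 2005 and 2010
  warm seasons) plus Gaussian reading noise.
* :func:`simulate_colonies` — tagged-colony observation tables: lognormal
  initial planar areas, period-specific exponential growth or decline with
  colony-to-colony rate dispersion, whole-colony mortality in the response
  period, loss to follow-up, and multiplicative (lognormal) measurement
  noise.
* :func:`render_scene` — colony photographs with an embedded color chart
  and scale bar, a known water-column tint, and a pixel-exact ground-truth
  pigmentation map.

``PRESETS`` ships one :class:`TrajectoryParams` per species × 2005-bleaching
group, calibrated to the study's printed sample sizes, mortality counts,
per-period annualized rates, and group-mean standard errors (rate
dispersions are back-solved from SE·sqrt(n); unprinted rates are
back-solved from the group live-area tables — see docs/methods.md).

Everything is driven by a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .demography import OBSERVATION_MONTHS

__all__ = [
    "AnomalySpec",
    "TrajectoryParams",
    "ImageSceneParams",
    "ChartPatch",
    "SceneImage",
    "LayoutError",
    "PRESETS",
    "default_anomalies",
    "simulate_temperature",
    "simulate_colonies",
    "simulate_study",
    "render_scene",
    "BACKGROUND",
    "PIGMENTED",
    "PARTIAL",
    "BLEACHED",
    "DEAD",
    "CLASS_COLORS",
    "BACKGROUND_RGB",
]

# pigmentation-map label codes (shared with coraldemog.imagequant)
BACKGROUND, PIGMENTED, PARTIAL, BLEACHED, DEAD = 0, 1, 2, 3, 4

#: rendering colors per class: pigmented brown, partially bleached pale tan,
#: bleached near-white, dead turf green
CLASS_COLORS = {
    PIGMENTED: (0.45, 0.28, 0.12),
    PARTIAL: (0.74, 0.64, 0.52),
    BLEACHED: (0.96, 0.96, 0.93),
    DEAD: (0.24, 0.40, 0.20),
}
BACKGROUND_RGB = (0.16, 0.28, 0.40)


class LayoutError(ValueError):
    """Scene geometry does not fit on the canvas."""


# ---------------------------------------------------------------------------
# temperature


@dataclass(frozen=True)
class AnomalySpec:
    """A triangular-ramp warm anomaly added to the seasonal curve."""

    start_date: _dt.date
    duration_days: int
    amplitude_C: float

    def __post_init__(self):
        if self.duration_days <= 0:
            raise ValueError("anomaly duration must be positive")
        if self.amplitude_C < 0:
            raise ValueError("anomaly amplitude must be >= 0")

    @property
    def end_date(self) -> _dt.date:
        return self.start_date + _dt.timedelta(days=self.duration_days)


def default_anomalies() -> list[AnomalySpec]:
    """Two warm-season anomaly events, peaking in 2005 and 2010."""
    return [
        AnomalySpec(_dt.date(2005, 8, 1), 100, 2.2),
        AnomalySpec(_dt.date(2010, 8, 11), 90, 1.9),
    ]


def _merge_anomalies(anomalies: Sequence[AnomalySpec]) -> list[AnomalySpec]:
    merged: list[AnomalySpec] = []
    for an in sorted(anomalies, key=lambda a: a.start_date):
        if merged and an.start_date < merged[-1].end_date:
            prev = merged.pop()
            warnings.warn("overlapping anomalies merged", stacklevel=3)
            end = max(prev.end_date, an.end_date)
            merged.append(
                AnomalySpec(
                    prev.start_date,
                    (end - prev.start_date).days,
                    max(prev.amplitude_C, an.amplitude_C),
                )
            )
        else:
            merged.append(an)
    return merged


def simulate_temperature(
    start: str | _dt.date = "1999-01-01",
    years: int = 16,
    depths: Sequence[float] = (4.0, 10.0, 20.0),
    mean_C: float = 28.68,
    seasonal_amplitude_C: float = 1.5,
    peak_doy: int = 258,
    anomalies: Sequence[AnomalySpec] | None = None,
    noise_sd_C: float = 0.15,
    readings_per_day: int = 4,
    diurnal_amplitude_C: float = 0.0,
    depth_mean_offset_C_per_m: float = -0.01,
    depth_anomaly_damping_per_m: float = 0.003,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a depth-stratified sub-daily logger series.

    The seasonal component is evaluated at day resolution (so daily means
    are exact in the noise-free case), a diurnal sinusoid averages to zero
    over evenly spaced readings, and anomalies are triangular ramps damped
    slightly with depth.  Returns a DataFrame with columns ``timestamp``,
    ``depth_m``, ``temp_C``.
    """
    if anomalies is None:
        anomalies = default_anomalies()
    anomalies = _merge_anomalies(anomalies)
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(start)
    dates = pd.date_range(start, start + pd.DateOffset(years=years), freq="D", inclusive="left")
    doy = dates.dayofyear.to_numpy()
    seasonal = mean_C + seasonal_amplitude_C * np.cos(
        2.0 * math.pi * (doy - peak_doy) / 365.25
    )
    anomaly = np.zeros(len(dates))
    day_index = dates.normalize()
    for an in anomalies:
        center = pd.Timestamp(an.start_date) + pd.Timedelta(days=an.duration_days / 2.0)
        offset_days = (day_index - center).days.to_numpy().astype(float)
        tri = an.amplitude_C * (1.0 - np.abs(offset_days) / (an.duration_days / 2.0))
        anomaly += np.maximum(0.0, tri)
    hours = np.arange(readings_per_day) * (24.0 / readings_per_day)
    diurnal = diurnal_amplitude_C * np.cos(2.0 * math.pi * (hours - 14.0) / 24.0)
    frames = []
    for depth in depths:
        base = (
            seasonal
            + depth_mean_offset_C_per_m * (depth - depths[0])
            + anomaly * max(0.0, 1.0 - depth_anomaly_damping_per_m * (depth - depths[0]))
        )
        day_part = np.repeat(base, readings_per_day)
        hour_part = np.tile(diurnal, len(dates))
        noise = rng.normal(0.0, noise_sd_C, len(day_part)) if noise_sd_C > 0 else 0.0
        ts = np.repeat(dates.values, readings_per_day) + np.tile(
            (hours * 3.6e12).astype("timedelta64[ns]"), len(dates)
        )
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": ts,
                    "depth_m": depth,
                    "temp_C": day_part + hour_part + noise,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# colony trajectories


@dataclass(frozen=True)
class TrajectoryParams:
    """Generating parameters for one species × 2005-bleaching-group cell.

    Rates are annualized % change of live planar area; ``rate_sigma_log``
    is the colony-to-colony standard deviation of the *annual log* growth
    factor per period.  Initial sizes are lognormal with the given
    arithmetic mean and log-scale dispersion.  Mortality removes whole
    colonies (area 0 from the death month onward) during the response
    period; ``lost_n`` colonies silently leave the record from a random
    later observation onward.
    """

    species: str
    group2005: str
    n_colonies: int
    initial_mean_cm2: float
    initial_sigma_log: float
    period_rates: Mapping[str, float]  # response / recovery / second_event_response
    rate_sigma_log: Mapping[str, float] = field(
        default_factory=lambda: {
            "response": 0.2,
            "recovery": 0.15,
            "second_event_response": 0.2,
        }
    )
    response_mortality_prob: float = 0.0
    response_mortality_n: int | None = None
    lost_n: int = 0
    lost_months: tuple[int, ...] = (22, 34, 46, 58)
    observation_months: tuple[int, ...] = OBSERVATION_MONTHS
    measurement_noise_cv: float = 0.05
    bleach0_mean_pct: float = 10.0
    bleach0_sd_pct: float = 5.0
    partial0_mean_pct: float = 10.0
    partial0_sd_pct: float = 5.0
    # optional size-conditional initial bleaching: {"large": (mean, sd), "small": ...}
    bleach0_by_size: Mapping[str, tuple[float, float]] | None = None
    partial0_by_size: Mapping[str, tuple[float, float]] | None = None
    species_mean_cm2: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.response_mortality_prob <= 1.0:
            raise ValueError("mortality probability must be in [0, 1]")
        for name, r in dict(self.period_rates).items():
            if r <= -100:
                raise ValueError(f"rate for {name} must exceed -100 %/yr")


def _period_of(month: float) -> str:
    if month <= 9:
        return "response"
    if month <= 58:
        return "recovery"
    return "second_event_response"


def simulate_colonies(params: TrajectoryParams, seed: int = 0) -> pd.DataFrame:
    """Simulate one group cell into a colony-observation table.

    Per colony, the monthly log-area slope within each period is
    ``[ln(1 + rate/100) + N(0, sigma_period)] / 12`` — the specified rate
    in expectation of the log slope — integrated piecewise across the
    observation schedule, with multiplicative lognormal measurement noise
    on every emitted area.  Bleached/partial pigment fractions start at the
    drawn 2005 extents and decay exponentially (time constants 2 and 9
    months).
    """
    rng = np.random.default_rng(seed)
    n = params.n_colonies
    mu0 = math.log(params.initial_mean_cm2) - params.initial_sigma_log**2 / 2.0
    log_a0 = rng.normal(mu0, params.initial_sigma_log, n)

    period_names = ("response", "recovery", "second_event_response")
    slopes = {}
    for name in period_names:
        rate = params.period_rates.get(name, 0.0)
        sigma = params.rate_sigma_log.get(name, 0.0)
        annual_log = math.log1p(rate / 100.0) + (
            rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
        )
        slopes[name] = annual_log / 12.0

    # whole-colony mortality during the response period
    n_dead = (
        params.response_mortality_n
        if params.response_mortality_n is not None
        else int(rng.binomial(n, params.response_mortality_prob))
    )
    n_dead = min(n_dead, n)
    dead_ids = rng.choice(n, size=n_dead, replace=False) if n_dead else np.array([], int)
    death_month = dict(zip(dead_ids, rng.choice((6, 9), size=n_dead)))

    # loss to follow-up among survivors, from a later observation onward
    alive = np.setdiff1d(np.arange(n), dead_ids)
    n_lost = min(params.lost_n, len(alive))
    lost_ids = rng.choice(alive, size=n_lost, replace=False) if n_lost else np.array([], int)
    lost_from = dict(zip(lost_ids, rng.choice(params.lost_months, size=n_lost)))

    # 2005 pigmentation extents, optionally conditional on colony size
    def _draw_pct(spec_by_size, mean, sd, sizes):
        if spec_by_size is not None:
            if params.species_mean_cm2 is None:
                raise ValueError("size-conditional fractions need species_mean_cm2")
            means = np.where(
                sizes > params.species_mean_cm2,
                spec_by_size["large"][0],
                spec_by_size["small"][0],
            )
            sds = np.where(
                sizes > params.species_mean_cm2,
                spec_by_size["large"][1],
                spec_by_size["small"][1],
            )
        else:
            means, sds = np.full(n, mean), np.full(n, sd)
        return np.clip(rng.normal(means, sds), 0.0, 100.0) / 100.0

    sizes0 = np.exp(log_a0)
    f_bl0 = _draw_pct(params.bleach0_by_size, params.bleach0_mean_pct, params.bleach0_sd_pct, sizes0)
    f_pb0 = _draw_pct(params.partial0_by_size, params.partial0_mean_pct, params.partial0_sd_pct, sizes0)
    f_pb0 = np.minimum(f_pb0, 1.0 - f_bl0)

    bounds = [(0.0, 9.0, "response"), (9.0, 58.0, "recovery"), (58.0, math.inf, "second_event_response")]

    rows = []
    noise_sd = params.measurement_noise_cv
    for i in range(n):
        cid = f"{params.species}_{params.group2005}_{i:03d}"
        for month in params.observation_months:
            if i in lost_from and month >= lost_from[i]:
                break
            if i in death_month and month >= death_month[i]:
                rows.append(
                    dict(
                        colony_id=cid,
                        species=params.species,
                        group2005=params.group2005,
                        month=month,
                        live_area_cm2=0.0,
                        frac_bleached=0.0,
                        frac_partial=0.0,
                        dead_area_cm2=float(np.exp(log_a0[i])),
                        status="dead",
                    )
                )
                continue
            log_a = log_a0[i]
            for lo, hi, name in bounds:
                if month > lo:
                    log_a += slopes[name][i] * (min(month, hi) - lo)
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            f_bl = f_bl0[i] * math.exp(-month / 2.0)
            f_pb = f_pb0[i] * math.exp(-month / 9.0)
            rows.append(
                dict(
                    colony_id=cid,
                    species=params.species,
                    group2005=params.group2005,
                    month=month,
                    live_area_cm2=float(np.exp(log_a + noise)),
                    frac_bleached=float(f_bl),
                    frac_partial=float(min(f_pb, 1.0 - f_bl)),
                    dead_area_cm2=0.0,
                    status="alive",
                )
            )
    return pd.DataFrame(rows)


def simulate_study(seed: int = 0, presets: Mapping[str, TrajectoryParams] | None = None) -> pd.DataFrame:
    """Simulate all preset group cells into one colony table."""
    presets = PRESETS if presets is None else presets
    frames = []
    for k, name in enumerate(sorted(presets)):
        frames.append(simulate_colonies(presets[name], seed=(seed * 1009 + k) % 2**31))
    return pd.concat(frames, ignore_index=True)


def _preset(**kw) -> TrajectoryParams:
    return TrajectoryParams(**kw)


#: six species × 2005-bleaching-group cells at the study's sample sizes.
#: Rates in %/yr; response-period dispersions back-solved from the printed
#: group-mean SEs (SE·sqrt(n) on the loss scale mapped to a log-scale SD).
PRESETS: dict[str, TrajectoryParams] = {
    "of_bleached": _preset(
        species="O_franksi",
        group2005="bleached",
        n_colonies=37,
        initial_mean_cm2=591.8,
        initial_sigma_log=0.8,
        period_rates={"response": -40.3, "recovery": 2.23, "second_event_response": -9.1},
        rate_sigma_log={"response": 0.56, "recovery": 0.15, "second_event_response": 0.2},
        response_mortality_n=3,
        bleach0_mean_pct=14.4,
        bleach0_sd_pct=14.6,
        partial0_mean_pct=18.8,
        partial0_sd_pct=10.9,
    ),
    "of_unbleached": _preset(
        species="O_franksi",
        group2005="unbleached",
        n_colonies=15,
        initial_mean_cm2=386.8,
        initial_sigma_log=0.8,
        period_rates={"response": -0.53, "recovery": 1.9, "second_event_response": -12.7},
        bleach0_mean_pct=0.7,
        bleach0_sd_pct=0.8,
        partial0_mean_pct=1.6,
        partial0_sd_pct=2.3,
    ),
    "sm_bleached": _preset(
        species="S_michelini",
        group2005="bleached",
        n_colonies=62,
        initial_mean_cm2=243.1,
        initial_sigma_log=0.5,
        period_rates={"response": -56.6, "recovery": 0.05, "second_event_response": -20.6},
        rate_sigma_log={"response": 0.73, "recovery": 0.15, "second_event_response": 0.2},
        response_mortality_n=15,
        bleach0_mean_pct=38.3,
        bleach0_sd_pct=38.6,
        partial0_mean_pct=19.4,
        partial0_sd_pct=21.3,
    ),
    "sm_unbleached": _preset(
        species="S_michelini",
        group2005="unbleached",
        n_colonies=6,
        initial_mean_cm2=207.4,
        initial_sigma_log=0.5,
        period_rates={"response": -12.2, "recovery": -5.3, "second_event_response": -26.4},
        response_mortality_n=1,
        bleach0_mean_pct=0.1,
        bleach0_sd_pct=0.12,
        partial0_mean_pct=5.2,
        partial0_sd_pct=3.4,
    ),
    "ss_bleached": _preset(
        species="S_siderea",
        group2005="bleached",
        n_colonies=25,
        initial_mean_cm2=308.3,
        initial_sigma_log=0.7,
        period_rates={"response": -17.3, "recovery": -1.66, "second_event_response": -3.4},
        rate_sigma_log={"response": 0.29, "recovery": 0.15, "second_event_response": 0.2},
        lost_n=2,
        bleach0_by_size={"large": (1.6, 1.6), "small": (11.2, 11.1)},
        partial0_by_size={"large": (2.6, 2.5), "small": (10.3, 11.1)},
        species_mean_cm2=383.9,
    ),
    "ss_unbleached": _preset(
        species="S_siderea",
        group2005="unbleached",
        n_colonies=33,
        initial_mean_cm2=441.3,
        initial_sigma_log=0.7,
        period_rates={"response": -2.0, "recovery": -3.33, "second_event_response": -3.7},
        lost_n=3,
        bleach0_by_size={"large": (1.6, 1.6), "small": (11.2, 11.1)},
        partial0_by_size={"large": (2.6, 2.5), "small": (10.3, 11.1)},
        species_mean_cm2=383.9,
    ),
}


# ---------------------------------------------------------------------------
# scene rendering


@dataclass(frozen=True)
class ChartPatch:
    true_rgb: tuple[float, float, float]
    rect: tuple[int, int, int, int]  # y0, y1, x0, x1 (half-open)


@dataclass
class SceneImage:
    """A rendered colony photograph with embedded references.

    ``image`` is an (H, W, 3) float array in [0, 1]; ``chart`` lists the
    reference patches with their true colors; the physical scale is
    ``scale_cm`` over ``scale_px`` pixels.  ``colony_mask`` delimits the
    colony (including dead patches) when known.
    """

    image: np.ndarray
    chart: list[ChartPatch]
    scale_cm: float
    scale_px: float
    background_rgb: tuple[float, float, float] = BACKGROUND_RGB
    colony_mask: np.ndarray | None = None

    @property
    def cm_per_pixel(self) -> float:
        return self.scale_cm / self.scale_px


def _default_chart(margin: int = 10, size: int = 28) -> list[ChartPatch]:
    colors = [
        (0.18, 0.18, 0.18),
        (0.45, 0.45, 0.45),
        (0.80, 0.80, 0.80),
        (0.75, 0.20, 0.18),
        (0.18, 0.65, 0.25),
        (0.20, 0.30, 0.80),
    ]
    patches = []
    for i, c in enumerate(colors):
        x0 = margin + i * (size + 6)
        patches.append(ChartPatch(c, (margin, margin + size, x0, x0 + size)))
    return patches


@dataclass(frozen=True)
class ImageSceneParams:
    """Geometry, class fractions and optics of a rendered colony scene."""

    canvas_hw: tuple[int, int] = (360, 480)
    center_yx: tuple[float, float] | None = None
    radii_xy: tuple[float, float] = (130.0, 100.0)
    boundary_noise_amp: float = 0.06
    fractions: tuple[float, float, float, float] = (0.6, 0.25, 0.15, 0.0)
    # pigmented, partial, bleached, dead
    cm_per_pixel: float = 0.1
    scale_cm: float = 10.0
    tint_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.01
    occlude_chart: bool = False

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("class fractions must be non-negative")


def render_scene(
    params: ImageSceneParams = ImageSceneParams(), seed: int = 0
) -> tuple[SceneImage, np.ndarray]:
    """Render a colony scene and its pixel-exact ground-truth label map.

    The colony is a boundary-perturbed ellipse.  Dead tissue (if any) is
    placed as an interior hole (the most central pixels), the live classes
    as contiguous angular sectors whose pixel counts match the requested
    fractions exactly up to rounding.  The water-column tint multiplies
    each channel of the finished image.
    """
    rng = np.random.default_rng(seed)
    H, W = params.canvas_hw
    cy, cx = params.center_yx if params.center_yx is not None else (H * 0.58, W * 0.5)
    a, b = params.radii_xy
    chart = _default_chart()
    chart_bottom = max(p.rect[1] for p in chart)
    margin = 1.0 + params.boundary_noise_amp
    if (
        cx - a * margin < 0
        or cx + a * margin >= W
        or cy - b * margin <= chart_bottom
        or cy + b * margin >= H - 30
    ):
        raise LayoutError("colony does not fit on the canvas clear of the references")

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    theta = np.arctan2(yy - cy, xx - cx)
    wobble = np.ones_like(theta)
    for k in (2, 3, 5):
        amp = rng.uniform(0.0, params.boundary_noise_amp / 2.0)
        wobble += amp * np.cos(k * theta + rng.uniform(0, 2 * math.pi))
    rr = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)
    mask = rr <= wobble

    labels = np.zeros((H, W), dtype=np.uint8)
    idx = np.flatnonzero(mask)
    n_px = idx.size
    f_pig, f_par, f_bl, f_dead = params.fractions
    n_dead = int(round(f_dead * n_px))
    order_r = idx[np.argsort(rr.ravel()[idx], kind="stable")]
    dead_idx = order_r[:n_dead]
    labels.ravel()[dead_idx] = DEAD
    live_idx = order_r[n_dead:]
    live_n = live_idx.size
    live_frac = np.array([f_pig, f_par, f_bl])
    live_frac = live_frac / live_frac.sum() if live_frac.sum() > 0 else live_frac
    order_t = live_idx[np.argsort(theta.ravel()[live_idx], kind="stable")]
    n_pig = int(round(live_frac[0] * live_n))
    n_par = int(round(live_frac[1] * live_n))
    labels.ravel()[order_t[:n_pig]] = PIGMENTED
    labels.ravel()[order_t[n_pig : n_pig + n_par]] = PARTIAL
    labels.ravel()[order_t[n_pig + n_par :]] = BLEACHED

    img = np.empty((H, W, 3))
    img[:] = BACKGROUND_RGB
    for cls, color in CLASS_COLORS.items():
        img[labels == cls] = color
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, img.shape)

    for p in chart:
        y0, y1, x0, x1 = p.rect
        if params.occlude_chart:
            img[y0:y1, x0:x1] = rng.uniform(0.0, 1.0, (y1 - y0, x1 - x0, 3))
        else:
            img[y0:y1, x0:x1] = p.true_rgb
            if params.noise_sd > 0:
                img[y0:y1, x0:x1] += rng.normal(
                    0.0, params.noise_sd, (y1 - y0, x1 - x0, 3)
                )

    scale_px = int(round(params.scale_cm / params.cm_per_pixel))
    bar_y0, bar_x0 = H - 22, 12
    if bar_x0 + scale_px >= W:
        raise LayoutError("scale bar does not fit on the canvas")
    img[bar_y0 : bar_y0 + 8, bar_x0 : bar_x0 + scale_px] = 0.02

    img = np.clip(img * np.asarray(params.tint_gains)[None, None, :], 0.0, 1.0)
    scene = SceneImage(
        image=img,
        chart=chart,
        scale_cm=params.scale_cm,
        scale_px=float(scale_px),
        colony_mask=mask,
    )
    return scene, labels
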