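"""Parametric lobed-leaf outlines, specimen metadata, and daily weather.

Real shepherd's-purse rosette leaves vary from entire (unlobed) blades to
deeply dissected ones with many lobes of irregular depth.  The generator
emulates that variability with an analytically controllable lamina model:
the blade half-width at proximal-distal position ``t`` (0 = tip, 1 = base)
is

    h(t) = W * sin(pi * t) * (1 - lobe_depth * sin^2(lobe_count * pi * t))

mirrored about the midrib, perturbed by per-vertex Gaussian asymmetry
noise, and finished with a rectangular petiole stub — so lobing depth and
count, elongation, and asymmetry are each a single dial.  Specimens are
placed inside per-region bounding boxes of the packaged NOAA climate-region
lookup; daily site weather follows a latitude-dependent sinusoidal annual
cycle with Gaussian temperature noise and Bernoulli-Gamma precipitation;
and a planted linear effect of growing-season mean temperature on lobe
depth links the two so the downstream shape ~ climate models have a known
ground truth to recover.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import climate
from .archetypes import IANNETTA_NAMES, SHULL_NAMES, ArchetypeSet
from .errors import CoverageError, GeometryError, ParameterError
from .landmarking import LandmarkConfiguration, landmark_outline
from .outline_io import LeafOutline
from .regions import REGION_BBOX, REGION_STATES, REGIONS, validate_regions

__all__ = [
    "LeafParams",
    "EffectSpec",
    "LeafPriors",
    "WeatherConfig",
    "SyntheticLeafOutline",
    "generate_leaf",
    "generate_specimens",
    "generate_weather",
    "generate_archetypes",
    "link_shape_to_climate",
]

BLADE_LENGTH = 100.0  # px; all other scales derive from it
MAX_LOBE_DEPTH = 0.95


@dataclass(frozen=True)
class LeafParams:
    """Parameters of one generated leaf.

    ``lobe_depth`` < 0.95 keeps the lamina half-width positive everywhere;
    ``elongation`` is the blade length / maximum blade width ratio;
    ``petiole_frac`` is the petiole length as a fraction of blade length;
    ``asymmetry_sd`` scales per-vertex Gaussian half-width noise (relative
    to the half-width scale W).
    """

    lobe_count: int = 4
    lobe_depth: float = 0.4
    elongation: float = 2.5
    petiole_frac: float = 0.2
    asymmetry_sd: float = 0.01
    n_points: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.lobe_count, (int, np.integer)) and self.lobe_count >= 0):
            raise ParameterError(f"lobe_count must be an integer >= 0, got {self.lobe_count!r}")
        if not (0.0 <= self.lobe_depth <= MAX_LOBE_DEPTH):
            raise ParameterError(f"lobe_depth must be in [0, {MAX_LOBE_DEPTH}], got {self.lobe_depth}")
        if self.elongation <= 0:
            raise ParameterError(f"elongation must be positive, got {self.elongation}")
        if not (0.0 <= self.petiole_frac <= 0.5):
            raise ParameterError(f"petiole_frac must be in [0, 0.5], got {self.petiole_frac}")
        if self.asymmetry_sd < 0:
            raise ParameterError(f"asymmetry_sd must be >= 0, got {self.asymmetry_sd}")
        if self.n_points < 100:
            raise ParameterError(f"n_points must be >= 100, got {self.n_points}")


@dataclass(frozen=True)
class EffectSpec:
    """Planted linear effect of GS mean temperature on lobe depth."""

    intercept_d: float = 0.75
    slope_d_per_degC: float = -0.02
    noise_sd: float = 0.05


@dataclass(frozen=True)
class LeafPriors:
    """Priors for the non-planted leaf parameters in linked datasets."""

    lobe_count_range: tuple[int, int] = (0, 7)  # inclusive
    elongation_range: tuple[float, float] = (1.4, 4.0)
    petiole_frac_range: tuple[float, float] = (0.15, 0.30)
    asymmetry_sd: float = 0.01
    n_points: int = 300


@dataclass(frozen=True)
class SyntheticLeafOutline(LeafOutline):
    """A generated outline carrying its ground-truth tip and base.

    ``true_tip_index`` indexes the blade apex vertex; ``true_base_point``
    is the midpoint of the cut petiole end (the first/last trace points).
    """

    true_tip_index: int = 0
    true_base_point: tuple[float, float] = (0.0, 0.0)


def _half_width(t: np.ndarray, W: float, depth: float, count: int) -> np.ndarray:
    return W * np.sin(np.pi * t) * (1.0 - depth * np.sin(count * np.pi * t) ** 2)


def generate_leaf(params: LeafParams, id: str | None = None) -> SyntheticLeafOutline:
    """Generate one lobed-leaf outline from parameters.

    The trace runs from one corner of the petiole end, up one side of the
    blade from base to tip, down the other side, and back to the opposite
    petiole corner — the same traversal a hand-traced specimen follows.
    If the asymmetry noise produces a self-intersecting polygon the noise
    is halved and the leaf regenerated, up to 10 attempts.
    """
    leaf_id = id if id is not None else f"leaf_{params.seed}"
    L = BLADE_LENGTH
    W = L / (2.0 * params.elongation)
    pl = params.petiole_frac * L
    pw = 0.16 * W  # petiole stub width
    nb = max((params.n_points - 5 + 1) // 2, 48)  # blade vertices per side
    rng = np.random.default_rng(params.seed)
    sd = params.asymmetry_sd * W
    for attempt in range(10):
        # interior blade positions, t in (0, 1), excluding tip and base
        t = np.linspace(0.0, 1.0, nb + 2)[1:-1]
        h = _half_width(t, W, params.lobe_depth, params.lobe_count)
        noise_l = rng.normal(0.0, sd, size=nb) if sd > 0 else np.zeros(nb)
        noise_r = rng.normal(0.0, sd, size=nb) if sd > 0 else np.zeros(nb)
        floor = 0.01 * W  # keep the lamina on its own side of the midrib
        h_left = np.maximum(h + noise_l, floor * np.sin(np.pi * t))
        h_right = np.maximum(h + noise_r, floor * np.sin(np.pi * t))
        y = L * (1.0 - t)
        left = np.column_stack([-h_left, y])[::-1]  # base -> tip
        right = np.column_stack([h_right, y])  # tip -> base
        tip = np.array([[0.0, L]])
        if pl > 0:
            head = np.array([[-pw / 2.0, -pl], [-pw / 2.0, 0.0]])
            tail = np.array([[pw / 2.0, 0.0], [pw / 2.0, -pl]])
        else:
            head = np.array([[-pw / 2.0, 0.0]])
            tail = np.array([[pw / 2.0, 0.0]])
        pts = np.vstack([head, left, tip, right, tail])
        outline = SyntheticLeafOutline(
            id=leaf_id,
            points=pts,
            true_tip_index=len(head) + nb,
            true_base_point=(0.0, -pl),
        )
        if sd == 0 or outline.is_simple():
            return outline
        sd *= 0.5  # dampen and retry
    raise GeometryError(
        f"leaf {leaf_id!r}: self-intersecting outline after 10 noise-dampened attempts"
    )


def generate_specimens(
    n: int,
    date_range: tuple[str, str] = ("1990-01-01", "1995-12-31"),
    regions: tuple[str, ...] | list[str] = REGIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate specimen metadata: id, location, state, region, date.

    Each record draws a region uniformly from ``regions``, a member state
    uniformly within the region, a lat/lon uniformly inside the region's
    bounding box, and a collection date uniformly inside ``date_range``.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    regions = validate_regions(list(regions))
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(date_range[0])
    end = pd.Timestamp(date_range[1])
    if end < start:
        raise ParameterError(f"empty date range {date_range}")
    span = (end - start).days
    region_idx = rng.integers(0, len(regions), size=n)
    rows = []
    for i in range(n):
        region = regions[region_idx[i]]
        lat_lo, lat_hi, lon_lo, lon_hi = REGION_BBOX[region]
        state = REGION_STATES[region][rng.integers(0, len(REGION_STATES[region]))]
        date = start + pd.Timedelta(days=int(rng.integers(0, span + 1)))
        rows.append(
            {
                "id": f"spec_{i:04d}",
                "latitude": float(rng.uniform(lat_lo, lat_hi)),
                "longitude": float(rng.uniform(lon_lo, lon_hi)),
                "state": state,
                "climate_region": region,
                "collection_date": date,
                "year": int(date.year),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WeatherConfig:
    """Daily weather model: seasonal sinusoid plus noise.

    TAVG on day-of-year d at latitude phi is
    ``intercept + lat_slope * phi + amplitude * cos(2*pi*(d - peak_doy)/365)``
    plus N(0, sigma); TMAX/TMIN sit a half-normal offset above/below TAVG;
    precipitation is a Bernoulli wet day times a Gamma amount (inches).
    """

    intercept: float = 38.0  # deg C at latitude 0
    lat_slope: float = -0.7  # deg C per degree latitude
    amplitude: float = 12.0
    peak_doy: int = 200
    sigma: float = 3.0
    diurnal_range: tuple[float, float] = (3.0, 8.0)  # per-site mean TMAX-TAVG offset
    offset_sd: float = 1.5
    wet_prob: float = 0.3
    gamma_shape: float = 0.7
    gamma_scale: float = 0.4
    missing_rate: float = 0.0
    pad_days: int = 370  # series starts this many days before the earliest collection


def deterministic_tavg(latitude: float, doy: np.ndarray | int, config: WeatherConfig) -> np.ndarray:
    """Closed-form noise-free TAVG for a latitude and day(s) of year."""
    doy = np.asarray(doy, dtype=float)
    seasonal = config.amplitude * np.cos(2.0 * np.pi * (doy - config.peak_doy) / 365.0)
    return config.intercept + config.lat_slope * latitude + seasonal


def generate_weather(
    specimens: pd.DataFrame,
    seed: int = 0,
    config: WeatherConfig = WeatherConfig(),
) -> pd.DataFrame:
    """Generate a daily weather series for every specimen site.

    The series spans from ``pad_days`` before the earliest collection date
    to just after the latest, so every GS and YL window is covered.
    Ordering TMIN <= TAVG <= TMAX holds on every generated day.
    """
    if specimens.empty:
        raise ParameterError("generate_weather: no specimens")
    if not (0.0 <= config.missing_rate < 1.0):
        raise ParameterError(f"missing_rate must be in [0, 1), got {config.missing_rate}")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(
        pd.Timestamp(specimens["collection_date"].min()) - pd.Timedelta(days=config.pad_days),
        pd.Timestamp(specimens["collection_date"].max()) + pd.Timedelta(days=1),
        freq="D",
    )
    doy = dates.dayofyear.values.astype(float)
    nd = len(dates)
    frames = []
    for rec in specimens.itertuples(index=False):
        tavg = deterministic_tavg(rec.latitude, doy, config)
        if config.sigma > 0:
            tavg = tavg + rng.normal(0.0, config.sigma, size=nd)
        # per-site diurnal ranges (continentality varies between sites)
        up_base = rng.uniform(*config.diurnal_range)
        dn_base = rng.uniform(*config.diurnal_range)
        up = up_base + np.abs(rng.normal(0.0, config.offset_sd, size=nd))
        dn = dn_base + np.abs(rng.normal(0.0, config.offset_sd, size=nd))
        tmax = tavg + up
        tmin = tavg - dn
        wet = rng.random(nd) < config.wet_prob
        prcp = np.where(
            wet, rng.gamma(config.gamma_shape, config.gamma_scale, size=nd), 0.0
        )
        frame = pd.DataFrame(
            {
                "site": rec.id,
                "date": dates,
                "TAVG": tavg,
                "TMAX": tmax,
                "TMIN": tmin,
                "PRCP": prcp,
            }
        )
        if config.missing_rate > 0:
            for col in ("TAVG", "TMAX", "TMIN", "PRCP"):
                frame.loc[rng.random(nd) < config.missing_rate, col] = np.nan
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# Archetype presets: documented LeafParams stand-ins for the historical
# type silhouettes (zero noise, fixed seed).  They span lobe_count 0-7 and
# lobe_depth 0-0.85.
SHULL_PRESETS: dict[str, LeafParams] = {
    "Simplex": LeafParams(lobe_count=0, lobe_depth=0.0, elongation=2.2, asymmetry_sd=0.0),
    "Rhomboidea": LeafParams(lobe_count=4, lobe_depth=0.35, elongation=2.4, asymmetry_sd=0.0),
    "Tenius": LeafParams(lobe_count=3, lobe_depth=0.60, elongation=3.0, asymmetry_sd=0.0),
    "Heteris": LeafParams(lobe_count=5, lobe_depth=0.85, elongation=2.6, asymmetry_sd=0.0),
}
IANNETTA_PRESETS: dict[str, LeafParams] = {
    "1a": LeafParams(lobe_count=0, lobe_depth=0.0, elongation=2.0, asymmetry_sd=0.0),
    "1b": LeafParams(lobe_count=3, lobe_depth=0.15, elongation=2.2, asymmetry_sd=0.0),
    "1c": LeafParams(lobe_count=4, lobe_depth=0.25, elongation=2.2, asymmetry_sd=0.0),
    "1d": LeafParams(lobe_count=4, lobe_depth=0.40, elongation=2.3, asymmetry_sd=0.0),
    "2a": LeafParams(lobe_count=5, lobe_depth=0.45, elongation=2.4, asymmetry_sd=0.0),
    "2b": LeafParams(lobe_count=5, lobe_depth=0.55, elongation=2.6, asymmetry_sd=0.0),
    "3/4": LeafParams(lobe_count=6, lobe_depth=0.65, elongation=2.8, asymmetry_sd=0.0),
    "5": LeafParams(lobe_count=6, lobe_depth=0.75, elongation=3.0, asymmetry_sd=0.0),
    "6": LeafParams(lobe_count=7, lobe_depth=0.80, elongation=3.2, asymmetry_sd=0.0),
    "7a": LeafParams(lobe_count=7, lobe_depth=0.85, elongation=2.8, asymmetry_sd=0.0),
    "7b": LeafParams(lobe_count=7, lobe_depth=0.85, elongation=3.6, asymmetry_sd=0.0),
}


def generate_archetypes(S: int = 100) -> dict[str, ArchetypeSet]:
    """Build the Shull and Iannetta archetype sets from the presets.

    Each preset leaf is generated noise-free and pushed through the full
    landmarking pipeline, so archetypes live in the same 2S-point
    representation as the leaves they classify.
    """
    def build(scheme: str, names: tuple[str, ...], presets: dict[str, LeafParams]) -> ArchetypeSet:
        configs: list[LandmarkConfiguration] = []
        for name in names:
            leaf = generate_leaf(presets[name], id=f"{scheme}:{name}")
            configs.append(landmark_outline(leaf, S=S))
        return ArchetypeSet(scheme=scheme, names=names, configurations=configs)

    return {
        "shull": build("shull", SHULL_NAMES, SHULL_PRESETS),
        "iannetta": build("iannetta", IANNETTA_NAMES, IANNETTA_PRESETS),
    }


def link_shape_to_climate(
    specimens: pd.DataFrame,
    weather: pd.DataFrame,
    effect: EffectSpec = EffectSpec(),
    seed: int = 0,
    priors: LeafPriors = LeafPriors(),
) -> tuple[dict[str, LeafParams], pd.DataFrame]:
    """Plant a linear GS-temperature effect on lobe depth.

    For specimen i with growing-season mean temperature ``AT_GS,i``:

        lobe_depth_i = clip(intercept_d + slope * AT_GS,i + N(0, noise_sd),
                            0, 0.95)

    Other leaf parameters are drawn from ``priors``.  Returns a mapping of
    specimen id to LeafParams and a ground-truth table (id, AT_GS,
    lobe_depth) for recovery tests.
    """
    rng = np.random.default_rng(seed)
    by_site = dict(tuple(weather.groupby("site")))
    lo, hi = priors.lobe_count_range
    params: dict[str, LeafParams] = {}
    truth_rows = []
    for rec in specimens.itertuples(index=False):
        if rec.id not in by_site:
            raise CoverageError(f"specimen {rec.id!r}: no weather series for its site")
        ws = climate.summarize_window(
            by_site[rec.id], rec.collection_date, "GS", specimen_id=rec.id
        )
        if not np.isfinite(ws.AT):
            raise CoverageError(
                f"specimen {rec.id!r}: GS window not covered (coverage {ws.coverage:.2f})"
            )
        noise = rng.normal(0.0, effect.noise_sd) if effect.noise_sd > 0 else 0.0
        depth = float(
            np.clip(effect.intercept_d + effect.slope_d_per_degC * ws.AT + noise,
                    0.0, MAX_LOBE_DEPTH)
        )
        params[rec.id] = LeafParams(
            lobe_count=int(rng.integers(lo, hi + 1)),
            lobe_depth=depth,
            elongation=float(rng.uniform(*priors.elongation_range)),
            petiole_frac=float(rng.uniform(*priors.petiole_frac_range)),
            asymmetry_sd=priors.asymmetry_sd,
            n_points=priors.n_points,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        truth_rows.append({"id": rec.id, "AT_GS": ws.AT, "lobe_depth": depth})
    return params, pd.DataFrame(truth_rows)
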