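"""Synthetic fine-resolution world: land mask, climate predictors, species.

The world stands in for gridded climate rasters, a land-cover layer and
expert range polygons.  It is built on a regular long-lat grid (default
0.1 degree) restricted to a northern study band, where the area distortion
of the long-lat projection is largest.

Everything is driven by a single integer seed; identical specs produce
bit-identical worlds.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter, zoom
from scipy.special import expit

from .projection import longlat_cell_area

PREDICTOR_NAMES = (
    "temperature",
    "diurnal_range",
    "precipitation",
    "precip_seasonality",
)


class InvalidSpecError(ValueError):
    pass


class InvalidNicheError(ValueError):
    pass


@dataclass(frozen=True)
class PredictorParams:
    """Shape of one synthetic climate surface.

    gradient: change per degree of latitude (log scale for precipitation).
    noise_amplitude: standard deviation of the smooth noise component.
    correlation_length: Gaussian smoothing length of the noise, in degrees.
    shared_fraction: fraction of noise variance drawn from a field shared
        across predictors, inducing mild, controllable collinearity.
    """

    gradient: float
    noise_amplitude: float
    correlation_length: float = 5.0
    shared_fraction: float = 0.3
    baseline: float = 0.0


def _default_predictor_params():
    # Gradient and noise variances are balanced so the latitude signal does
    # not dominate: that keeps the max VIF over the four predictors near 2.
    return {
        "temperature": PredictorParams(gradient=-0.6, noise_amplitude=6.5, baseline=30.0),
        "diurnal_range": PredictorParams(gradient=0.08, noise_amplitude=2.5, baseline=8.0),
        "precipitation": PredictorParams(
            gradient=-0.012, noise_amplitude=0.35, baseline=7.0
        ),
        "precip_seasonality": PredictorParams(
            gradient=0.35, noise_amplitude=11.0, baseline=20.0
        ),
    }


@dataclass(frozen=True)
class WorldSpec:
    """Geometry and stochastic parameters of the synthetic world."""

    seed: int
    fine_resolution: float = 0.1
    lat_extent: tuple[float, float] = (20.0, 90.0)
    lon_extent: tuple[float, float] = (-180.0, 180.0)
    land_fraction_target: float = 0.5
    predictor_params: dict = field(default_factory=_default_predictor_params)
    earth_radius: float = 6371.0

    def __post_init__(self):
        if self.fine_resolution <= 0:
            raise InvalidSpecError("fine_resolution must be > 0")
        for lo, hi, name in (
            (*self.lat_extent, "lat_extent"),
            (*self.lon_extent, "lon_extent"),
        ):
            if hi <= lo:
                raise InvalidSpecError(f"{name} is empty or inverted")
            n = (hi - lo) / self.fine_resolution
            if abs(n - round(n)) > 1e-9:
                raise InvalidSpecError(
                    f"fine_resolution does not divide {name} into whole cells"
                )
        if not (0.0 < self.land_fraction_target <= 1.0):
            raise InvalidSpecError("land_fraction_target must lie in (0, 1]")
        if set(self.predictor_params) != set(PREDICTOR_NAMES):
            raise InvalidSpecError(f"predictor_params must have keys {PREDICTOR_NAMES}")
        if self.n_lat * self.n_lon == 0:
            raise InvalidSpecError("degenerate extent: zero cells")

    @property
    def n_lat(self) -> int:
        return round((self.lat_extent[1] - self.lat_extent[0]) / self.fine_resolution)

    @property
    def n_lon(self) -> int:
        return round((self.lon_extent[1] - self.lon_extent[0]) / self.fine_resolution)

    @property
    def shape(self) -> tuple[int, int]:
        """(n_lat, n_lon); row 0 is the southern edge of the band."""
        return (self.n_lat, self.n_lon)

    @property
    def lat_centers(self) -> np.ndarray:
        lo = self.lat_extent[0]
        return lo + (np.arange(self.n_lat) + 0.5) * self.fine_resolution

    @property
    def lon_centers(self) -> np.ndarray:
        lo = self.lon_extent[0]
        return lo + (np.arange(self.n_lon) + 0.5) * self.fine_resolution

    def cell_areas(self) -> np.ndarray:
        """Spherical fine-cell areas (km^2), one value per latitude row,
        broadcast to the full grid shape."""
        south = self.lat_centers - self.fine_resolution / 2
        north = self.lat_centers + self.fine_resolution / 2
        band = longlat_cell_area(south, north, self.fine_resolution, self.earth_radius)
        return np.broadcast_to(band[:, None], self.shape)


@dataclass(frozen=True)
class TrueNiche:
    """Known species-climate relationship on standardized predictors.

    The linear predictor is
        intercept + sum_i (linear_i * x_i + quadratic_i * x_i**2)
    where x_i are the four predictors standardized to zero mean / unit
    variance over land cells.
    """

    intercept: float
    linear_coefs: tuple[float, ...]
    quadratic_coefs: tuple[float, ...]
    presence_rule: str = "threshold"
    threshold: float = 0.5
    #: standard deviation (logit scale) of a smooth unobserved component of
    #: the range, representing non-climatic drivers; 0 makes the range an
    #: exact function of the four predictors, which is degenerate for model
    #: fitting (the fitted design then separates the response perfectly).
    nuisance_amplitude: float = 0.0
    nuisance_correlation_length: float = 10.0
    #: penalty (logit scale) applied near coasts, fading out
    #: ``interior_scale`` degrees inland; > 0 builds a continental species
    #: whose range avoids the coastline, 0 leaves the range free to reach
    #: the sea.
    interior_affinity: float = 0.0
    interior_scale: float = 5.0

    def __post_init__(self):
        object.__setattr__(self, "linear_coefs", tuple(float(c) for c in self.linear_coefs))
        object.__setattr__(
            self, "quadratic_coefs", tuple(float(c) for c in self.quadratic_coefs)
        )
        if len(self.linear_coefs) != 4 or len(self.quadratic_coefs) != 4:
            raise InvalidNicheError("niche requires exactly 4 linear and 4 quadratic coefficients")
        if self.presence_rule not in ("bernoulli", "threshold"):
            raise InvalidNicheError(f"unknown presence_rule {self.presence_rule!r}")

    def raw_coefficients(self, means, sds) -> np.ndarray:
        """Translate the niche into coefficients on *unstandardized*
        predictors: [intercept, lin_1..lin_4, quad_1..quad_4].

        With x = (r - mu) / sigma the quadratic term q*x^2 expands into
        raw-scale terms, so the truth is expressible in the same basis a
        model fitted on raw predictor values uses.
        """
        mu = np.asarray(means, dtype=float)
        sd = np.asarray(sds, dtype=float)
        lin = np.asarray(self.linear_coefs)
        quad = np.asarray(self.quadratic_coefs)
        raw_quad = quad / sd**2
        raw_lin = lin / sd - 2.0 * quad * mu / sd**2
        raw_intercept = self.intercept + np.sum(-lin * mu / sd + quad * mu**2 / sd**2)
        return np.concatenate([[raw_intercept], raw_lin, raw_quad])

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "linear_coefs": list(self.linear_coefs),
            "quadratic_coefs": list(self.quadratic_coefs),
            "presence_rule": self.presence_rule,
            "threshold": self.threshold,
            "nuisance_amplitude": self.nuisance_amplitude,
            "nuisance_correlation_length": self.nuisance_correlation_length,
            "interior_affinity": self.interior_affinity,
            "interior_scale": self.interior_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueNiche":
        return cls(**d)


@dataclass
class FineWorld:
    """The synthetic planet: rasters share ``spec.shape``; sea cells carry
    NaN predictors, zero probability and no presences."""

    spec: WorldSpec
    land_mask: np.ndarray
    predictors: dict[str, np.ndarray]
    true_probability: Optional[np.ndarray] = None
    presence: Optional[np.ndarray] = None
    niche: Optional[TrueNiche] = None
    predictor_means: Optional[np.ndarray] = None
    predictor_sds: Optional[np.ndarray] = None

    def validate(self):
        shape = self.spec.shape
        rasters = [self.land_mask, *self.predictors.values()]
        if self.true_probability is not None:
            rasters += [self.true_probability, self.presence]
        for r in rasters:
            if r.shape != shape:
                raise InvalidSpecError("raster shape mismatch")
        if self.true_probability is not None:
            if np.any((self.true_probability < 0) | (self.true_probability > 1)):
                raise InvalidSpecError("true_probability outside [0, 1]")
            if np.any(self.presence & ~self.land_mask):
                raise InvalidSpecError("presence on sea cells")

    def standardized_predictors(self) -> np.ndarray:
        """Stack of the four predictors standardized over land, shape (4, nlat, nlon)."""
        x = np.stack([self.predictors[n] for n in PREDICTOR_NAMES])
        mu = self.predictor_means[:, None, None]
        sd = self.predictor_sds[:, None, None]
        return (x - mu) / sd


def _rng(spec: WorldSpec, stream: str) -> np.random.Generator:
    # zlib.crc32 is stable across processes (str hash is salted per run)
    tag = zlib.crc32(stream.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence((spec.seed, tag)))


def _harmonic_field(spec: WorldSpec, rng: np.random.Generator, n_modes: int = 12) -> np.ndarray:
    """Sum of seeded low-frequency harmonics, periodic in longitude."""
    lat = spec.lat_centers
    lon = spec.lon_centers
    lat_span = spec.lat_extent[1] - spec.lat_extent[0]
    u = (lat - spec.lat_extent[0]) / lat_span  # 0..1
    v = lon / 360.0
    field = np.zeros(spec.shape)
    for _ in range(n_modes):
        k_lon = rng.integers(0, 4)
        k_lat = rng.integers(0, 4)
        if k_lon == 0 and k_lat == 0:
            k_lat = 1
        amp = rng.normal() / (1.0 + k_lon**2 + k_lat**2) ** 0.5
        ph_lon = rng.uniform(0, 2 * np.pi)
        ph_lat = rng.uniform(0, 2 * np.pi)
        field += amp * np.outer(
            np.cos(2 * np.pi * k_lat * u + ph_lat), np.cos(2 * np.pi * k_lon * v + ph_lon)
        )
    return field


def generate_land_mask(spec: WorldSpec) -> np.ndarray:
    """Boolean land raster with the requested global land fraction.

    A smooth seeded harmonic field is thresholded at the quantile that
    yields ``land_fraction_target``, producing blobby continents with
    coasts, interior (landlocked) regions and enclosed seas.
    """
    if spec.land_fraction_target >= 1.0:
        return np.ones(spec.shape, dtype=bool)
    field = _harmonic_field(spec, _rng(spec, "land"))
    # small rough component so the threshold quantile is sharp
    field = field + 0.05 * gaussian_filter(
        _rng(spec, "land-rough").standard_normal(spec.shape), sigma=3.0, mode=("nearest", "wrap")
    )
    thr = np.quantile(field, 1.0 - spec.land_fraction_target)
    return field > thr


def _smooth_noise(spec: WorldSpec, rng: np.random.Generator, correlation_length: float) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation
    length (degrees).

    The field is generated and smoothed on a lattice ~4 cells per
    correlation length and bilinearly upsampled to the fine grid: for
    correlation lengths well above the fine resolution this is
    indistinguishable from smoothing at full resolution and far cheaper.
    """
    factor = max(1, int(correlation_length / (4.0 * spec.fine_resolution)))
    c_lat = min(max(4, -(-spec.n_lat // factor)), spec.n_lat)
    c_lon = min(max(4, -(-spec.n_lon // factor)), spec.n_lon)
    coarse_res = spec.fine_resolution * (spec.n_lat / c_lat)
    sigma = max(correlation_length / coarse_res, 0.5)
    raw = rng.standard_normal((c_lat, c_lon))
    smooth = gaussian_filter(raw, sigma=sigma, mode=("nearest", "wrap"))
    if (c_lat, c_lon) != spec.shape:
        smooth = zoom(smooth, (spec.n_lat / c_lat, spec.n_lon / c_lon), order=1, mode="nearest")
        smooth = smooth[: spec.n_lat, : spec.n_lon]
        if smooth.shape != spec.shape:  # zoom can undershoot by one row/col
            pad = ((0, spec.n_lat - smooth.shape[0]), (0, spec.n_lon - smooth.shape[1]))
            smooth = np.pad(smooth, pad, mode="edge")
    sd = smooth.std()
    if sd == 0:
        return smooth
    return smooth / sd


def generate_predictors(spec: WorldSpec, land: np.ndarray) -> dict[str, np.ndarray]:
    """Four latitudinally structured climate surfaces, NaN on sea.

    Temperature decreases with latitude; precipitation is built on a log
    scale and is therefore strictly positive.  A shared noise component
    induces mild collinearity, calibrated to keep the max VIF below 3.
    """
    lat2d = np.broadcast_to(spec.lat_centers[:, None], spec.shape)
    shared = _smooth_noise(spec, _rng(spec, "noise-shared"), 5.0)
    out = {}
    for name in PREDICTOR_NAMES:
        p = spec.predictor_params[name]
        own = _smooth_noise(spec, _rng(spec, f"noise-{name}"), p.correlation_length)
        rho = np.sqrt(np.clip(p.shared_fraction, 0.0, 1.0))
        noise = rho * shared + np.sqrt(1.0 - rho**2) * own
        surface = p.baseline + p.gradient * lat2d + p.noise_amplitude * noise
        if name == "precipitation":
            surface = np.exp(surface * 0.15) * 10.0  # mm-ish scale, > 0 everywhere
        surface = np.where(land, surface, np.nan)
        out[name] = surface
    return out


def generate_species(
    niche: TrueNiche, world: FineWorld
) -> tuple[np.ndarray, np.ndarray]:
    """Occurrence probability and presence rasters for a niche on a world.

    Predictors are standardized to zero mean / unit variance over land
    before the niche coefficients are applied; the standardization moments
    are stored on the world for translating the niche to raw scale.
    """
    land = world.land_mask
    has_land = bool(land.any())
    mu = np.empty(4)
    sd = np.empty(4)
    eta = np.full(world.spec.shape, niche.intercept, dtype=float)
    for i, name in enumerate(PREDICTOR_NAMES):
        surface = world.predictors[name]
        mu[i] = np.nanmean(surface[land]) if has_land else 0.0
        s = np.nanstd(surface[land]) if has_land else 1.0
        sd[i] = s if s > 0 else 1.0
        x = (surface - mu[i]) / sd[i]
        eta += niche.linear_coefs[i] * x
        eta += niche.quadratic_coefs[i] * x * x
    world.predictor_means = mu
    world.predictor_sds = sd

    if niche.nuisance_amplitude > 0:
        eta += niche.nuisance_amplitude * _smooth_noise(
            world.spec, _rng(world.spec, "species-nuisance"), niche.nuisance_correlation_length
        )
    if niche.interior_affinity != 0:
        d = coast_distance(world.spec, land)
        eta += niche.interior_affinity * (
            np.minimum(d, niche.interior_scale) / niche.interior_scale - 1.0
        )
    prob = np.where(land, expit(eta), 0.0)
    prob = np.nan_to_num(prob, nan=0.0)

    if niche.presence_rule == "threshold":
        presence = prob > niche.threshold
    else:
        rng = _rng(world.spec, "species-bernoulli")
        presence = rng.random(world.spec.shape) < prob
    presence = presence & land
    return prob, presence


def make_world(spec: WorldSpec, niche: Optional[TrueNiche] = None) -> FineWorld:
    """Assemble a full world: land, predictors and (optionally) a species."""
    land = generate_land_mask(spec)
    predictors = generate_predictors(spec, land)
    world = FineWorld(spec=spec, land_mask=land, predictors=predictors)
    if niche is not None:
        prob, presence = generate_species(niche, world)
        world.true_probability = prob
        world.presence = presence
        world.niche = niche
    world.validate()
    return world


def species_metadata(world: FineWorld, coastal_share_threshold: float = 0.005) -> dict:
    """Truth-derived annotations: range size (km^2), max latitude of the
    range, and whether the range reaches the coast.

    A species counts as coastal when more than ``coastal_share_threshold``
    of its presence cells lie on the coast; the tolerance keeps a handful
    of stray boundary cells from flipping an essentially continental range.
    """
    if world.presence is None:
        raise ValueError("world has no species")
    areas = world.spec.cell_areas()
    pres = world.presence
    range_km2 = float(np.sum(areas[pres]))
    lat2d = np.broadcast_to(world.spec.lat_centers[:, None], world.spec.shape)
    # area-weighted 99th percentile rather than max: stray suitable cells
    # near the pole (where fine cells are area-tiny but numerous) should
    # not define the species' northern limit
    if pres.any():
        lats = lat2d[pres]
        wts = areas[pres]
        order = np.argsort(lats)
        cum = np.cumsum(wts[order])
        max_lat = float(lats[order][np.searchsorted(cum, 0.99 * cum[-1])])
    else:
        max_lat = float("nan")
    n_pres = int(pres.sum())
    coast_share = float((pres & _coast_mask(world.land_mask)).sum() / n_pres) if n_pres else 0.0
    return {
        "range_km2": range_km2,
        "max_latitude": max_lat,
        "coast_share": coast_share,
        "coastal": bool(coast_share > coastal_share_threshold),
    }


def coast_distance(spec: WorldSpec, land: np.ndarray) -> np.ndarray:
    """Approximate distance (degrees) from each land cell to the nearest
    sea cell; 0 on sea.  Euclidean in grid coordinates, so the shrinking
    of longitude degrees with latitude is ignored — adequate for shaping
    species ranges, not for measurement."""
    if land.all():
        return np.full(spec.shape, np.inf)
    d = distance_transform_edt(land, sampling=spec.fine_resolution)
    return np.asarray(d, dtype=float)


def _coast_mask(land: np.ndarray) -> np.ndarray:
    """Land cells with at least one sea neighbour (4-neighbourhood,
    longitude wraps, band edges are not coasts)."""
    sea = ~land
    nb = np.zeros_like(land)
    nb[1:, :] |= sea[:-1, :]
    nb[:-1, :] |= sea[1:, :]
    nb |= np.roll(sea, 1, axis=1)
    nb |= np.roll(sea, -1, axis=1)
    return land & nb


# ---------------------------------------------------------------------------
# plain-text persistence (ESRI ASCII grid + JSON sidecar)

def write_ascii_grid(path, array: np.ndarray, spec: WorldSpec, nodata: float = -9999.0):
    """Write a raster as an ESRI ASCII grid (text; row 0 of the file is north)."""
    a = np.asarray(array, dtype=float)
    a = np.where(np.isnan(a), nodata, a)
    header = (
        f"ncols {spec.n_lon}\n"
        f"nrows {spec.n_lat}\n"
        f"xllcorner {spec.lon_extent[0]}\n"
        f"yllcorner {spec.lat_extent[0]}\n"
        f"cellsize {spec.fine_resolution}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, a[::-1], fmt="%.8g")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]
    data = np.where(data == header["nodata_value"], np.nan, data)
    return data, header


def save_world(world: FineWorld, directory) -> Path:
    """Persist a world to a directory of ASCII grids plus a JSON manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(d / "land_mask.asc", world.land_mask.astype(float), world.spec)
    for name in PREDICTOR_NAMES:
        write_ascii_grid(d / f"{name}.asc", world.predictors[name], world.spec)
    manifest = {
        "spec": {
            "seed": world.spec.seed,
            "fine_resolution": world.spec.fine_resolution,
            "lat_extent": list(world.spec.lat_extent),
            "lon_extent": list(world.spec.lon_extent),
            "land_fraction_target": world.spec.land_fraction_target,
            "earth_radius": world.spec.earth_radius,
        },
        "predictors": list(PREDICTOR_NAMES),
    }
    if world.true_probability is not None:
        write_ascii_grid(d / "true_probability.asc", world.true_probability, world.spec)
        write_ascii_grid(d / "presence.asc", world.presence.astype(float), world.spec)
        manifest["niche"] = world.niche.to_dict()
        manifest["predictor_means"] = world.predictor_means.tolist()
        manifest["predictor_sds"] = world.predictor_sds.tolist()
    (d / "world.json").write_text(json.dumps(manifest, indent=2))
    return d


def load_world(directory) -> FineWorld:
    d = Path(directory)
    manifest = json.loads((d / "world.json").read_text())
    s = manifest["spec"]
    spec = WorldSpec(
        seed=s["seed"],
        fine_resolution=s["fine_resolution"],
        lat_extent=tuple(s["lat_extent"]),
        lon_extent=tuple(s["lon_extent"]),
        land_fraction_target=s["land_fraction_target"],
        earth_radius=s["earth_radius"],
    )
    land, _ = read_ascii_grid(d / "land_mask.asc")
    world = FineWorld(
        spec=spec,
        land_mask=land.astype(bool),
        predictors={n: read_ascii_grid(d / f"{n}.asc")[0] for n in PREDICTOR_NAMES},
    )
    if (d / "true_probability.asc").exists():
        world.true_probability, _ = read_ascii_grid(d / "true_probability.asc")
        pres, _ = read_ascii_grid(d / "presence.asc")
        world.presence = np.nan_to_num(pres, nan=0.0).astype(bool)
        world.niche = TrueNiche.from_dict(manifest["niche"])
        world.predictor_means = np.array(manifest["predictor_means"])
        world.predictor_sds = np.array(manifest["predictor_sds"])
    world.validate()
    return world
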