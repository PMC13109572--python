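"""Synthetic plantation scenes with known geometry, reflectance and fPAR.

The simulator emulates a gridded conifer seed orchard: trees on a 6 x 8 m
lattice (randomized family blocks, 20 half-sib families), cone-shaped crowns,
LiDAR returns from crown surfaces/interiors and the ground, a soil/foliage
reflectance model coupled to the canopy's light absorption, and Beer-Lambert
PAR extinction that yields the six quantum-sensor components measured in the
field (incident/reflected at canopy top, mid-canopy and base).

Every random draw flows from an explicit seed; no global random state is
touched. The generated ground truth (crown geometry, per-tree extinction,
noiseless per-stratum absorbed fractions) is what the downstream modules are
tested against.

Model sketch
------------
A tree of height ``h`` carries a right circular cone crown (apex at ``h``,
base at ``0.2 h``) with total leaf area index ``lai`` distributed uniformly
over the crown's vertical extent. The downward PAR flux at height ``z`` is

    PAR(z) = PAR0 * exp(-k_eff * L(z)),   L(z) = leaf area above z,

with ``k_eff`` the tree's effective extinction coefficient. When the
chlorophyll coupling is on, ``k_eff = k * (0.75 + 0.5 * chl)`` so that trees
with higher chlorophyll absorb more light *and* show a stronger red-edge
signature in the orthomosaic — the mechanism that makes red-edge indices
(RECI in particular) informative for fPAR inversion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .cloud import GROUND_CLASS, VEGETATION_CLASS, PointCloud
from .errors import ConfigurationError
from .raster import MultiBandRaster

#: sensor mounting heights (m) mirroring the 20 / 10 / 4 m field setup
DEFAULT_SENSOR_HEIGHTS = (20.0, 10.0, 4.0)
STRATA = ("upper", "middle", "lower")
CARDINAL_DIRECTIONS = (0, 90, 180, 270)

#: fixed background spectrum at 450/560/650/730/840 nm: a regularly mown,
#: largely senescent understory rather than bare mineral soil. It is
#: photosynthetically inactive but structurally vegetated, so it matches the
#: live canopy in the structural bands (green/red/NIR) and contrasts with it
#: only in the red edge (no chlorophyll absorption edge: 730 nm reflectance
#: flattened toward the NIR plateau). The canopy-background contrast
#: that encodes crown geometry is thereby confined to the chlorophyll-
#: sensitive band, the regime in which red-edge indices dominate retrieval.
SOIL_SPECTRUM = np.array([0.06, 0.08, 0.06, 0.50, 0.52])


def foliage_spectrum(chlorophyll, green_jitter=0.0, red_jitter=0.0):
    """Five-band foliage reflectance as a function of chlorophyll level.

    Only the red-edge band responds to chlorophyll (linearly decreasing), so
    red-edge ratios (NIR/RE) are strictly increasing in chlorophyll while
    broadband greenness indices are not. ``green_jitter``/``red_jitter`` are
    small per-tree relative brightness perturbations (fine-scale BRDF and
    shadowing variation) uncorrelated with any canopy property.
    ``chlorophyll`` may be an array.
    """
    c = np.asarray(chlorophyll, dtype=float)
    out = np.empty(np.shape(c) + (5,))
    out[..., 0] = 0.04
    out[..., 1] = 0.08 * (1.0 + green_jitter)
    out[..., 2] = 0.06 * (1.0 + red_jitter)
    out[..., 3] = 0.42 - 0.16 * c
    out[..., 4] = 0.52
    return out


@dataclass(frozen=True)
class StandConfig:
    """Layout and biophysical parameters of a synthetic stand.

    Defaults mirror a slash-pine seed orchard: 6 x 8 m spacing, 20 half-sib
    families in randomized blocks, ~18 m trees. ``lai`` scales with height
    (constant nominal leaf-area density) so that vertical extinction per
    metre is comparable across trees.
    """

    n_rows: int = 4
    n_cols: int = 5
    spacing_x: float = 6.0
    spacing_y: float = 8.0
    n_families: int = 20
    height_mean: float = 18.0
    height_sd: float = 0.4
    crown_radius_ratio: float = 0.12
    crown_base_ratio: float = 0.2
    lai_mean: float = 3.0
    lai_rel_sd: float = 0.03
    extinction_k: float = 0.9
    chlorophyll_coupling: bool = True
    family_chl_sd: float = 0.10
    tree_chl_sd: float = 0.05
    albedo: float = 0.05
    par_noise_sd: float = 0.05
    jitter_frac: float = 0.1
    ground_plane: tuple = (50.0, 0.002, -0.001)
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 0 or self.n_cols < 0:
            raise ConfigurationError("grid dimensions must be non-negative")
        if self.spacing_x <= 0 or self.spacing_y <= 0:
            raise ConfigurationError("spacing must be positive")
        if self.height_sd < 0:
            raise ConfigurationError("height_sd must be >= 0")
        if self.extinction_k <= 0:
            raise ConfigurationError("extinction_k must be > 0")
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")
        if not 0 <= self.albedo < 1:
            raise ConfigurationError("albedo must be in [0, 1)")


@dataclass
class StandScene:
    """Ground truth for one synthetic stand.

    ``trees`` columns: tree_id, family_id, x, y, height, crown_radius,
    crown_base, lai, chlorophyll, k_eff. ``true_stratum_fpar`` columns:
    tree_id, stratum, fpar (noiseless absorbed fraction per layer for the
    default sensor heights; refreshed by :func:`simulate_par`).
    """

    config: StandConfig
    trees: pd.DataFrame
    ground_plane: tuple
    true_stratum_fpar: pd.DataFrame

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def ground_elevation(self, x, y):
        a, b, c = self.ground_plane
        return a + b * np.asarray(x, dtype=float) + c * np.asarray(y, dtype=float)

    def bounds(self, margin: float = 2.0):
        """(xmin, xmax, ymin, ymax) covering the lattice plus every crown."""
        cfg = self.config
        x1 = max(cfg.n_cols - 1, 0) * cfg.spacing_x
        y1 = max(cfg.n_rows - 1, 0) * cfg.spacing_y
        if self.n_trees:
            r = self.trees["crown_radius"]
            return (min(0.0, float((self.trees["x"] - r).min())) - margin,
                    max(x1, float((self.trees["x"] + r).max())) + margin,
                    min(0.0, float((self.trees["y"] - r).min())) - margin,
                    max(y1, float((self.trees["y"] + r).max())) + margin)
        return (-margin, x1 + margin, -margin, y1 + margin)


def _clipped_normal(rng, mean, sd, n, n_sigma=3.0, lo=None):
    v = rng.normal(mean, sd, n) if sd > 0 else np.full(n, float(mean))
    v = np.clip(v, mean - n_sigma * sd, mean + n_sigma * sd)
    if lo is not None:
        v = np.maximum(v, lo)
    return v


def generate_stand(config: StandConfig) -> StandScene:
    """Lay out the grid, draw tree attributes, and compute true fPAR."""
    rng = np.random.default_rng(config.seed)
    n = config.n_rows * config.n_cols
    rows, cols = np.divmod(np.arange(n), config.n_cols)
    x = cols * config.spacing_x + rng.uniform(
        -config.jitter_frac, config.jitter_frac, n) * config.spacing_x
    y = rows * config.spacing_y + rng.uniform(
        -config.jitter_frac, config.jitter_frac, n) * config.spacing_y

    # randomized blocks: consecutive groups of n_families trees each receive
    # a random permutation of the family labels
    family = np.empty(n, dtype=int)
    for start in range(0, n, config.n_families):
        perm = rng.permutation(config.n_families) + 1
        family[start:start + config.n_families] = perm[: n - start]

    height = _clipped_normal(rng, config.height_mean, config.height_sd, n, lo=1.0)
    lai_eps = np.clip(rng.normal(0.0, config.lai_rel_sd, n),
                      -2 * config.lai_rel_sd, 2 * config.lai_rel_sd)
    lai = config.lai_mean * (height / config.height_mean) * (1.0 + lai_eps)
    fam_mean = np.clip(rng.normal(0.5, config.family_chl_sd, config.n_families),
                       0.05, 0.95)
    chl = np.clip(fam_mean[family - 1] + rng.normal(0.0, config.tree_chl_sd, n),
                  0.05, 0.95)
    if config.chlorophyll_coupling:
        k_eff = config.extinction_k * (0.75 + 0.5 * chl)
    else:
        k_eff = np.full(n, config.extinction_k)

    trees = pd.DataFrame({
        "tree_id": np.arange(1, n + 1),
        "family_id": family,
        "x": x, "y": y,
        "height": height,
        "crown_radius": config.crown_radius_ratio * height,
        "crown_base": config.crown_base_ratio * height,
        "lai": lai,
        "chlorophyll": chl,
        "k_eff": k_eff,
        "green_jitter": np.clip(rng.normal(0.0, 0.06, n), -0.15, 0.15),
        "red_jitter": np.clip(rng.normal(0.0, 0.06, n), -0.15, 0.15),
    })
    scene = StandScene(config=config, trees=trees,
                       ground_plane=config.ground_plane,
                       true_stratum_fpar=pd.DataFrame(
                           columns=["tree_id", "stratum", "fpar"]))
    scene.true_stratum_fpar = true_layer_fpar(scene, DEFAULT_SENSOR_HEIGHTS,
                                              albedo=0.0)
    return scene


def cumulative_leaf_area(trees: pd.DataFrame, z: float) -> np.ndarray:
    """Leaf area above height ``z`` for every tree (uniform crown density)."""
    h = trees["height"].to_numpy()
    b = trees["crown_base"].to_numpy()
    frac = np.clip((h - z) / (h - b), 0.0, 1.0)
    return trees["lai"].to_numpy() * frac


def transmittance(scene: StandScene, z: float) -> np.ndarray:
    """Fraction of incident PAR transmitted to height ``z`` per tree."""
    return np.exp(-scene.trees["k_eff"].to_numpy()
                  * cumulative_leaf_area(scene.trees, z))


def true_layer_fpar(scene: StandScene,
                    sensor_heights: Sequence[float] = DEFAULT_SENSOR_HEIGHTS,
                    albedo: float = 0.0,
                    tau_floor: float = 0.0) -> pd.DataFrame:
    """Noiseless per-stratum absorbed fraction, referenced to the top sensor.

    upper  = (1-a) (T_u - T_m) / T_u
    middle = (1-a) (T_m - T_l) / T_u
    lower  = (1-a) T_l (1 - tau_floor) / T_u

    where T_z is the transmittance at sensor height z and ``a`` the albedo.
    With ``tau_floor = 0`` the lower stratum is credited with all flux
    passing the base sensor (the same convention the ground-measurement
    module uses by default).
    """
    hu, hm, hl = sensor_heights
    tu, tm, tl = (transmittance(scene, h) for h in (hu, hm, hl))
    one_a = 1.0 - albedo
    vals = {
        "upper": one_a * (tu - tm) / tu,
        "middle": one_a * (tm - tl) / tu,
        "lower": one_a * tl * (1.0 - tau_floor) / tu,
    }
    frames = [pd.DataFrame({"tree_id": scene.trees["tree_id"],
                            "stratum": s, "fpar": vals[s]}) for s in STRATA]
    return pd.concat(frames, ignore_index=True)


def sample_point_cloud(scene: StandScene, point_density: float = 40.0,
                       noise_sd: float = 0.05, seed: int = 0,
                       surface_fraction: float = 0.6) -> PointCloud:
    """Emulate a LiDAR acquisition over the stand.

    Points are drawn on each cone's lateral surface (density-weighted toward
    the wide base) and uniformly in its interior volume, plus ground returns
    over the full scene footprint at ``point_density`` pts/m^2. Each tree's
    exact apex is always included so crown tops are well sampled. Gaussian
    vertical noise with sd ``noise_sd`` is added; ground points carry the
    ASPRS ground class as a simulator oracle.
    """
    if point_density <= 0:
        raise ConfigurationError("point_density must be > 0")
    rng = np.random.default_rng(seed)
    x0, x1, y0, y1 = scene.bounds()
    xs, ys, zs, cls = [], [], [], []

    n_ground = rng.poisson(point_density * (x1 - x0) * (y1 - y0))
    gx = rng.uniform(x0, x1, n_ground)
    gy = rng.uniform(y0, y1, n_ground)
    gz = scene.ground_elevation(gx, gy) + rng.normal(0, noise_sd, n_ground)
    xs.append(gx); ys.append(gy); zs.append(gz)
    cls.append(np.full(n_ground, GROUND_CLASS, dtype=np.uint8))

    for t in scene.trees.itertuples():
        span = t.height - t.crown_base
        n_crown = rng.poisson(point_density * np.pi * t.crown_radius ** 2)
        n_surf = int(round(surface_fraction * n_crown))
        n_int = n_crown - n_surf
        # lateral surface: pdf(z) proportional to local radius
        zu = t.height - span * np.sqrt(rng.random(n_surf))
        ru = t.crown_radius * (t.height - zu) / span
        # interior: uniform in cone volume
        zi = t.height - span * rng.random(n_int) ** (1.0 / 3.0)
        ri = (t.crown_radius * (t.height - zi) / span
              * np.sqrt(rng.random(n_int)))
        zc = np.concatenate([zu, zi, [t.height]])
        rc = np.concatenate([ru, ri, [0.0]])
        az = rng.uniform(0, 2 * np.pi, zc.size)
        px = t.x + rc * np.cos(az)
        py = t.y + rc * np.sin(az)
        pz = (scene.ground_elevation(px, py) + zc
              + rng.normal(0, noise_sd, zc.size))
        xs.append(px); ys.append(py); zs.append(pz)
        cls.append(np.full(zc.size, VEGETATION_CLASS, dtype=np.uint8))

    return PointCloud(np.concatenate(xs), np.concatenate(ys),
                      np.concatenate(zs), np.concatenate(cls))


def render_orthomosaic(scene: StandScene, gsd: float = 0.10,
                       chlorophyll_scale: float = 1.0,
                       bounds: Optional[tuple] = None) -> MultiBandRaster:
    """Render the five-band top-of-canopy reflectance mosaic.

    Pixels inside a crown footprint mix the tree's foliage spectrum with the
    soil spectrum by the local cover fraction f = 1 - d/r (1 at the stem,
    0 at the crown edge), so crown-edge columns look progressively more
    soil-like — the nadir-view mixing that makes stratum membership visible
    in column-propagated reflectance. Background pixels are pure soil.
    ``chlorophyll_scale`` is a per-date multiplier emulating seasonal
    chlorophyll change. Deterministic (no noise).
    """
    if gsd <= 0:
        raise ConfigurationError("gsd must be > 0")
    if bounds is None:
        bounds = scene.bounds()
    x0, x1, y0, y1 = bounds
    nx = int(round((x1 - x0) / gsd))
    ny = int(round((y1 - y0) / gsd))
    surf = np.zeros((ny, nx))
    cover = np.zeros((ny, nx))
    chl = np.zeros((ny, nx))
    gjit = np.zeros((ny, nx))
    rjit = np.zeros((ny, nx))

    for t in scene.trees.itertuples():
        i0 = max(int(np.floor((t.x - t.crown_radius - x0) / gsd)), 0)
        i1 = min(int(np.ceil((t.x + t.crown_radius - x0) / gsd)) + 1, nx)
        j0 = max(int(np.floor((t.y - t.crown_radius - y0) / gsd)), 0)
        j1 = min(int(np.ceil((t.y + t.crown_radius - y0) / gsd)) + 1, ny)
        if i0 >= i1 or j0 >= j1:
            continue
        px = x0 + (np.arange(i0, i1) + 0.5) * gsd
        py = y0 + (np.arange(j0, j1) + 0.5) * gsd
        d = np.hypot(px[None, :] - t.x, py[:, None] - t.y)
        inside = d < t.crown_radius
        local_surf = t.height - (t.height - t.crown_base) * d / t.crown_radius
        win = (slice(j0, j1), slice(i0, i1))
        take = inside & (local_surf > surf[win])
        surf[win][take] = local_surf[take]
        cover[win][take] = (1.0 - d / t.crown_radius)[take]
        chl[win][take] = t.chlorophyll
        gjit[win][take] = getattr(t, "green_jitter", 0.0)
        rjit[win][take] = getattr(t, "red_jitter", 0.0)

    leaf = foliage_spectrum(np.clip(chl * chlorophyll_scale, 0.0, 1.0),
                            green_jitter=gjit, red_jitter=rjit)
    mix = (cover[..., None] * leaf
           + (1.0 - cover[..., None]) * SOIL_SPECTRUM[None, None, :])
    data = np.clip(np.moveaxis(mix, -1, 0), 0.0, 1.0)
    return MultiBandRaster(origin_x=x0, origin_y=y0, gsd=gsd, data=data)


def simulate_par(scene: StandScene, incident_par: float = 1800.0,
                 sensor_heights: Sequence[float] = DEFAULT_SENSOR_HEIGHTS,
                 seed: int = 0, albedo: Optional[float] = None,
                 noise_sd: Optional[float] = None,
                 date: str = "2023-07-15") -> pd.DataFrame:
    """Generate the six-component quantum-sensor readings for every tree.

    Incident components follow Beer-Lambert transmission through the leaf
    area above each sensor; reflected components are ``albedo`` times the
    local incident component. Four cardinal-direction replicates receive
    independent multiplicative Gaussian noise. As a side effect the scene's
    ``true_stratum_fpar`` is refreshed with the noiseless absorbed fractions
    for these sensor heights and albedo.

    Returns a tidy table: tree_id, date, direction_deg, level
    (top/middle/base), orientation (incident/reflected), par_value.
    """
    if incident_par <= 0:
        raise ConfigurationError("incident_par must be > 0")
    hu, hm, hl = sensor_heights
    if not hu > hm > hl:
        raise ConfigurationError("sensor heights must be strictly decreasing")
    if albedo is None:
        albedo = scene.config.albedo
    if noise_sd is None:
        noise_sd = scene.config.par_noise_sd
    rng = np.random.default_rng(seed)

    levels = {"top": hu, "middle": hm, "base": hl}
    frames = []
    for level, h in levels.items():
        inc = incident_par * transmittance(scene, h)
        for orientation, component in (("incident", inc),
                                       ("reflected", albedo * inc)):
            for direction in CARDINAL_DIRECTIONS:
                noise = rng.normal(0.0, noise_sd, scene.n_trees) if noise_sd > 0 \
                    else np.zeros(scene.n_trees)
                frames.append(pd.DataFrame({
                    "tree_id": scene.trees["tree_id"],
                    "date": date,
                    "direction_deg": direction,
                    "level": level,
                    "orientation": orientation,
                    "par_value": component * (1.0 + noise),
                }))
    scene.true_stratum_fpar = true_layer_fpar(scene, sensor_heights,
                                              albedo=albedo)
    return pd.concat(frames, ignore_index=True).sort_values(
        ["tree_id", "date", "direction_deg", "level", "orientation"],
        ignore_index=True)


def extinction_for_gradient(config: StandConfig, target_percent: float,
                            sensor_heights: Sequence[float] = DEFAULT_SENSOR_HEIGHTS,
                            ) -> StandConfig:
    """Return a config whose nominal tree shows the requested lower-to-upper
    relative fPAR increase, 100 * (upper - lower) / lower.

    Solved in closed form on the configuration's mean tree (height_mean,
    lai_mean, chlorophyll 0.5); tree-to-tree variation then scatters the
    realized stand-level gradient around the target.
    """
    hu, hm, hl = sensor_heights
    h, lai = config.height_mean, config.lai_mean
    base = config.crown_base_ratio * h

    def leaf_above(z):
        return lai * np.clip((h - z) / (h - base), 0.0, 1.0)

    lu, lm, ll = leaf_above(hu), leaf_above(hm), leaf_above(hl)

    def gradient(k):
        tu, tm, tl = np.exp(-k * lu), np.exp(-k * lm), np.exp(-k * ll)
        return 100.0 * ((tu - tm) - tl) / tl

    lo, hi = 1e-4, 8.0
    if gradient(lo) > target_percent or gradient(hi) < target_percent:
        raise ConfigurationError("target gradient outside attainable range")
    k = brentq(lambda k: gradient(k) - target_percent, lo, hi, xtol=1e-10)
    return dataclasses.replace(config, extinction_k=float(k))


# ---------------------------------------------------------------------------
# scene manifest (ground truth) serialization

def scene_to_manifest(scene: StandScene) -> dict:
    return {
        "config": dataclasses.asdict(scene.config),
        "ground_plane": list(scene.ground_plane),
        "trees": scene.trees.to_dict(orient="records"),
        "true_stratum_fpar": scene.true_stratum_fpar.to_dict(orient="records"),
    }


def save_scene(scene: StandScene, path) -> None:
    manifest = scene_to_manifest(scene)
    # plain python types for readable YAML
    manifest = yaml.safe_load(yaml.safe_dump(_to_plain(manifest)))
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


TREE_COLUMNS = ["tree_id", "family_id", "x", "y", "height", "crown_radius",
                "crown_base", "lai", "chlorophyll", "k_eff",
                "green_jitter", "red_jitter"]


def load_scene(path) -> StandScene:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    cfg_dict = dict(manifest["config"])
    cfg_dict["ground_plane"] = tuple(cfg_dict["ground_plane"])
    config = StandConfig(**cfg_dict)
    trees = pd.DataFrame(manifest["trees"], columns=TREE_COLUMNS)
    fpar = pd.DataFrame(manifest["true_stratum_fpar"],
                        columns=["tree_id", "stratum", "fpar"])
    return StandScene(config=config, trees=trees,
                      ground_plane=tuple(manifest["ground_plane"]),
                      true_stratum_fpar=fpar)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
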