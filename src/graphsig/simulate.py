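"""Seeded generators for the localization toy problems and test images.

Three sphere-localization scenarios emulate the study conditions:

* ``sim1`` -- 800 objects in four spherical-cap regions (200 each) measured
  by 5 sensors; sensor j reports d i.i.d. zero-mean Gaussians whose
  standard deviation 20 exp(-||x_i - s_j||^2) encodes only the
  object-sensor distance.  Region centers form a seeded-rotated regular
  tetrahedron; four sensors sit on the opposite face axes (each sensor is
  equidistant from three regions and singles out the fourth) and the fifth
  sits at their centroid, so no single sensor can resolve all regions
  while the joint profile can.
* ``sim2`` -- 400 objects from two mirrored regions measured by 12 sensors
  whose positions hug a seeded great-circle plane; mirroring the regions
  through that plane makes every per-sensor marginal (the variances)
  indistinguishable across regions, while region-specific cross-sensor
  covariances (|N(0, 0.5)| entries drawn once per scenario) remain
  detectable by the SSD.
* ``sim3`` -- as sim2 but only sensors 1 and 7 lie exactly in the mirror
  plane; the rest are pushed off-plane, so only those two sensors have
  matched marginals.

Also provides the two-hypothesis Gaussian bundle sampler and a synthetic
multiplexed-image generator for exercising the ROI-extraction pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signatures import ObservationBundle
from .imc_io import MultiplexImage
from .theory import BimodalGaussianSpec

__all__ = [
    "SphereScene",
    "SimulationConfig",
    "SyntheticMultiplexConfig",
    "make_scene",
    "observe_sim1",
    "observe_sim23",
    "sample_bimodal",
    "make_synthetic_multiplex",
]


@dataclass
class SphereScene:
    """Objects on the unit sphere, their regions, and sensor positions."""

    points: np.ndarray
    region_labels: np.ndarray
    sensors: np.ndarray
    region_centers: np.ndarray
    region_radius: float

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.points, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("scene points must lie on the unit sphere")


@dataclass
class SimulationConfig:
    """Scenario parameters; defaults follow the study conditions."""

    scenario: str = "sim1"
    n_regions: int = 4
    points_per_region: int = 200
    n_sensors: int = 5
    d: int = 100
    noise_scale: float = 20.0
    cov_halfnormal_scale: float = 0.5
    seed: int = 0
    sensor_radius: float = 1.5
    region_angular_radius: float = 0.3
    sensor_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.scenario not in ("sim1", "sim2", "sim3"):
            raise ValueError("scenario must be one of sim1, sim2, sim3")
        if self.scenario in ("sim2", "sim3"):
            # two mirrored regions measured by a 12-sensor arc
            if self.n_regions == 4 and self.n_sensors == 5:
                self.n_regions, self.n_sensors = 2, 12
            if self.sensor_radius == 1.5:
                self.sensor_radius = 1.2
        if min(self.n_regions, self.points_per_region, self.n_sensors, self.d) < 1:
            raise ValueError("counts must be positive")

    @property
    def n_points(self) -> int:
        return self.n_regions * self.points_per_region


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _cap_samples(center: np.ndarray, radius: float, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Uniform samples in the spherical cap of angular ``radius`` at ``center``."""
    z = rng.uniform(np.cos(radius), 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - z**2)
    local = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), z])
    # rotate the pole onto the center direction
    pole = np.array([0.0, 0.0, 1.0])
    v = np.cross(pole, center)
    s = np.linalg.norm(v)
    c = float(pole @ center)
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return local @ rot.T


_TETRA = np.array([
    [1.0, 1.0, 1.0],
    [1.0, -1.0, -1.0],
    [-1.0, 1.0, -1.0],
    [-1.0, -1.0, 1.0],
]) / np.sqrt(3.0)


def make_scene(config: SimulationConfig) -> SphereScene:
    """Seeded sensor/region geometry for the requested scenario."""
    rng = np.random.default_rng(config.seed)
    if config.scenario == "sim1":
        centers = _TETRA @ _random_rotation(rng).T
        if config.n_regions != 4 or config.n_sensors != 5:
            raise ValueError("sim1 uses 4 regions and 5 sensors")
        sensors = -config.sensor_radius * centers
        sensors += config.sensor_jitter * rng.standard_normal(sensors.shape)
        sensors = np.vstack([sensors, sensors.mean(axis=0, keepdims=True)])
    else:
        if config.n_regions != 2:
            raise ValueError("sim2/sim3 use 2 regions")
        frame = _random_rotation(rng)
        e1, e2, normal = frame[:, 0], frame[:, 1], frame[:, 2]
        k = config.n_sensors
        # sensors occupy an in-plane arc facing the regions so that every
        # object-sensor distance stays moderate (variances well above the
        # cross-covariance scale, keeping the PSD repair a no-op in practice)
        base = rng.uniform(0, 2 * np.pi)
        arc = np.linspace(-0.4, 0.4, k) + 0.02 * rng.standard_normal(k)
        angles = base + arc
        ring = np.outer(np.cos(angles), e1) + np.outer(np.sin(angles), e2)
        if config.scenario == "sim2":
            # tiny off-plane jitter: distances to the mirrored regions stay
            # approximately equal for every sensor
            off_plane = 0.002 * rng.standard_normal(k)
        else:
            # only sensors 1 and 7 (indices 0 and 6) sit exactly in the
            # mirror plane; the rest break the symmetry
            off_plane = 0.35 * np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
            off_plane += config.sensor_jitter * rng.standard_normal(k)
            off_plane[0] = 0.0
            off_plane[6 % k] = 0.0
        sensors = ring + np.outer(off_plane, normal)
        sensors *= config.sensor_radius / np.linalg.norm(sensors, axis=1,
                                                         keepdims=True)
        if config.scenario == "sim3":
            sensors[0] -= (sensors[0] @ normal) * normal
            sensors[6 % k] -= (sensors[6 % k] @ normal) * normal
        in_plane = np.cos(base) * e1 + np.sin(base) * e2
        tilt = np.deg2rad(45.0)
        c1 = np.cos(tilt) * in_plane + np.sin(tilt) * normal
        c2 = np.cos(tilt) * in_plane - np.sin(tilt) * normal  # mirror image
        centers = np.vstack([c1, c2])
    points, labels = [], []
    for r, center in enumerate(centers):
        pts = _cap_samples(center, config.region_angular_radius,
                           config.points_per_region, rng)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        points.append(pts)
        labels.append(np.full(config.points_per_region, r))
    return SphereScene(points=np.vstack(points),
                       region_labels=np.concatenate(labels),
                       sensors=sensors, region_centers=centers,
                       region_radius=config.region_angular_radius)


def _sensor_stds(scene: SphereScene, scale: float) -> np.ndarray:
    """Per (point, sensor) standard deviation scale * exp(-||x - s||^2)."""
    sq = ((scene.points[:, None, :] - scene.sensors[None, :, :]) ** 2).sum(-1)
    return scale * np.exp(-sq)


def observe_sim1(scene: SphereScene, config: SimulationConfig) -> list[ObservationBundle]:
    """Independent-sensor observations: row j ~ N(0, sigma_{ij}^2 I_d)."""
    rng = np.random.default_rng(config.seed + 1)
    stds = _sensor_stds(scene, config.noise_scale)
    n, m = stds.shape
    noise = rng.standard_normal((n, m, config.d))
    return [
        ObservationBundle(features=stds[i][:, None] * noise[i], point_id=str(i))
        for i in range(n)
    ]


def _clip_psd(C: np.ndarray) -> np.ndarray:
    lam, v = np.linalg.eigh(0.5 * (C + C.T))
    if lam.min() >= 0:
        return C
    lam = np.clip(lam, 0.0, None)
    fixed = (v * lam) @ v.T
    return 0.5 * (fixed + fixed.T)


def observe_sim23(scene: SphereScene, config: SimulationConfig
                  ) -> list[ObservationBundle]:
    """Correlated-sensor observations with region-specific cross-covariances.

    Each region draws one symmetric matrix of |N(0, scale)| cross
    covariances; a point's m*d-dimensional covariance has diagonal blocks
    sigma_{ij}^2 I_d and off-diagonal blocks sigma_{kl} I_d, projected to
    the nearest PSD matrix by eigenvalue clipping.
    """
    rng = np.random.default_rng(config.seed + 2)
    m = config.n_sensors
    cross = []
    for _ in range(scene.region_centers.shape[0]):
        entries = np.abs(rng.normal(0.0, config.cov_halfnormal_scale, (m, m)))
        entries = np.triu(entries, k=1)
        cross.append(entries + entries.T)
    stds = _sensor_stds(scene, config.noise_scale)
    bundles = []
    for i in range(scene.points.shape[0]):
        C = cross[int(scene.region_labels[i])].copy()
        np.fill_diagonal(C, stds[i] ** 2)
        C = _clip_psd(C)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(m))
        F = L @ rng.standard_normal((m, config.d))
        bundles.append(ObservationBundle(features=F, point_id=str(i)))
    return bundles


def sample_bimodal(spec: BimodalGaussianSpec, n: int, seed: int = 0
                   ) -> tuple[list[ObservationBundle], np.ndarray]:
    """Draw n labelled bundles from the two-hypothesis Gaussian model.

    Labels are 1 with probability alpha, else 2; each bundle is one draw of
    the m*d-dimensional Gaussian of its hypothesis reshaped to m x d.
    """
    rng = np.random.default_rng(seed)
    m, d = spec.n_features, spec.patch_dim
    labels = np.where(rng.random(n) < spec.alpha, 1, 2)
    chols = [np.linalg.cholesky(spec.cross_covariances[h] + 1e-12 * np.eye(m))
             for h in range(2)]
    bundles = []
    for i in range(n):
        h = labels[i] - 1
        F = spec.means[h][:, None] + chols[h] @ rng.standard_normal((m, d))
        bundles.append(ObservationBundle(features=F, point_id=str(i)))
    return bundles, labels


@dataclass
class SyntheticMultiplexConfig:
    """Parameters of the planted-blob multiplexed image generator."""

    height: int = 224
    width: int = 224
    n_markers: int = 6
    n_blobs: int = 32
    blob_size: int = 10
    indicator_intensity: float = 10.0
    marker_baseline: float = 5.0
    marker_sd: float = 1.0
    correlation: float = 0.95
    sparse_fraction: float = 0.2
    seed: int = 0


def _blob_covariance(cfg: SyntheticMultiplexConfig, label: int) -> np.ndarray:
    """Class-dependent cross-channel covariance among the markers.

    Class 0 correlates marker pair (0,1), class 1 correlates (2,3) -- all
    dense channels, so the sparse markers do not dilute the signal.
    Marginals (variances) are identical, so only the correlation pattern
    distinguishes the classes.
    """
    C = np.eye(cfg.n_markers) * cfg.marker_sd**2
    a, b = (0, 1) if label == 0 else (2, 3)
    C[a, b] = C[b, a] = cfg.correlation * cfg.marker_sd**2
    return C


def make_synthetic_multiplex(cfg: SyntheticMultiplexConfig
                             ) -> tuple[MultiplexImage, np.ndarray, np.ndarray]:
    """An (n_markers + 1)-channel image with planted indicator blobs.

    Returns ``(image, positions, labels)``: the image (channel 0 is the
    indicator), the top-left corners of the planted b x b blobs, and their
    alternating class labels.  Marker channels are zero outside the blobs;
    within each blob, pixels are draws of a correlated Gaussian whose
    correlation pattern depends on the class, and a random fraction of
    pixels in the last half of the marker channels is zeroed to emulate
    sparse-expression markers.
    """
    rng = np.random.default_rng(cfg.seed)
    b = cfg.blob_size
    margin = 2 * b
    n_side = (cfg.height - b) // margin, (cfg.width - b) // margin
    slots = [(r * margin, c * margin) for r in range(n_side[0])
             for c in range(n_side[1])]
    if len(slots) < cfg.n_blobs:
        raise ValueError("blobs do not fit: enlarge the image or reduce n_blobs")
    chosen = rng.choice(len(slots), size=cfg.n_blobs, replace=False)
    positions = np.asarray([slots[i] for i in chosen])
    labels = np.arange(cfg.n_blobs) % 2

    channels = np.zeros((cfg.n_markers + 1, cfg.height, cfg.width))
    # the last two marker channels emulate the sparse-expression regime
    sparse_channels = set(range(cfg.n_markers - 1, cfg.n_markers + 1))
    for (r, c), label in zip(positions, labels):
        channels[0, r : r + b, c : c + b] = (
            cfg.indicator_intensity + rng.uniform(0.0, 1.0, (b, b))
        )
        L = np.linalg.cholesky(_blob_covariance(cfg, int(label))
                               + 1e-12 * np.eye(cfg.n_markers))
        pix = cfg.marker_baseline + (L @ rng.standard_normal((cfg.n_markers, b * b)))
        pix = np.clip(pix, 0.0, None)
        for k in range(cfg.n_markers):
            patch = pix[k].reshape(b, b).copy()
            if (k + 1) in sparse_channels:
                mask = rng.random((b, b)) < cfg.sparse_fraction
                patch[mask] = 0.0
            channels[k + 1, r : r + b, c : c + b] = patch
    names = ["Cytokeratin"] + [f"marker{k}" for k in range(cfg.n_markers)]
    image = MultiplexImage(channels=channels, marker_names=names,
                           indicator_channel="Cytokeratin",
                           subject_id=f"synthetic-{cfg.seed}")
    return image, positions, labels
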