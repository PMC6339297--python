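"""Synthetic micrograph simulator with controlled SNR.

Generates toy volumes, particle placements with random orientations, clean
(noise-free) micrographs with exact ground truth, Gaussian noise scaled to
hit a target SNR, and reference probability maps — so the picker, label
generator and metrics are all testable end-to-end without any downloads.

The simulator is deliberately simple electron optics-wise: particles are
additive projections of a toy volume and noise is white Gaussian.  There is
no CTF, dose or ice modeling; the SNR definition only constrains the ratio
of signal energy to noise energy,

    SNR(dB) = 10 * log10( sum f_hat^2 / sum (f - f_hat)^2 )

where ``f_hat`` is the clean image and ``f`` the noisy one.

Toy particles use a projection-flat radial profile, v(r) ∝ 1/sqrt(R^2 - r^2)
clipped to 1: its line integral along any chord of the ball is constant, so
the particle projects to a uniform disc in every orientation and the
binarized footprint is orientation-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import CapacityError, DomainError
from .formats_io import (
    BinaryLabelMap,
    Micrograph,
    OrientationRecord,
    Pick,
    PickSet,
    ProbabilityMap,
    Volume,
)
from .label_gen import LabelTile, binarize_projection, composite_labels, project_volume

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_toy_volume",
    "place_particles",
    "render_clean",
    "add_noise_to_snr",
    "reference_probability_map",
    "simulate_micrograph",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic micrograph.

    Defaults: a 512 x 512 micrograph carrying 25 particles of radius 12 px
    (box side s = 32, the smallest volume dimension), minimum center
    separation 64 px = 2s, and a target SNR of -10 dB.  A fixed seed makes
    the whole pipeline bitwise deterministic.
    """

    mic_shape: tuple[int, int] = (512, 512)
    particle_radius: int = 12
    n_particles: int = 25
    min_separation: float = 64.0
    snr_db: float = -10.0
    seed: int = 0
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    max_shift: int = 3

    def __post_init__(self) -> None:
        if self.particle_radius < 1 or self.n_particles < 0:
            raise ValueError("particle_radius must be >= 1 and n_particles >= 0")
        if min(self.volume_shape) < 8:
            raise ValueError("volume_shape must be at least 8 per axis")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")

    @property
    def box_size(self) -> int:
        """Particle box side s: the reprojection tile side."""
        return min(self.volume_shape)


@dataclass
class GroundTruth:
    """Everything the simulator knows exactly about one synthetic micrograph."""

    coords: PickSet
    mask: BinaryLabelMap
    clean: Micrograph
    orientations: list[OrientationRecord] = field(default_factory=list)


def _radial_profile(r2: np.ndarray, radius: float) -> np.ndarray:
    """Projection-flat ball: v ∝ 1/sqrt(R^2 - r^2) inside radius, clipped to 1."""
    inside = r2 < radius * radius
    v = np.zeros(r2.shape)
    v[inside] = np.minimum(1.0, 0.25 * radius / np.sqrt(radius * radius - r2[inside]))
    return v


def make_toy_volume(cfg: SimConfig, n_lobes: int | None = None) -> Volume:
    """Seeded toy particle: a union of 1-5 soft-edged ball/ellipsoid lobes near the center.

    The primary lobe is a centered projection-flat ball of
    ``cfg.particle_radius``; extra lobes are smaller ellipsoids offset by up
    to a quarter radius.  Values lie in [0, 1].
    """
    rng = np.random.default_rng(cfg.seed)
    if n_lobes is None:
        n_lobes = int(rng.integers(1, 6))
    d, h, w = cfg.volume_shape
    zz, yy, xx = np.mgrid[0:d, 0:h, 0:w].astype(float)
    cz, cy, cx = (d - 1) / 2.0, (h - 1) / 2.0, (w - 1) / 2.0
    r = float(cfg.particle_radius)
    r2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
    vol = _radial_profile(r2, r)
    for _ in range(n_lobes - 1):
        off = rng.uniform(-r / 4, r / 4, size=3)
        axes = rng.uniform(0.3 * r, 0.7 * r, size=3)
        q2 = (
            ((zz - cz - off[0]) / axes[0]) ** 2
            + ((yy - cy - off[1]) / axes[1]) ** 2
            + ((xx - cx - off[2]) / axes[2]) ** 2
        )
        lobe = np.clip(1.25 * (1.0 - q2), 0.0, 1.0)
        vol = np.maximum(vol, lobe)
    return Volume(np.clip(vol, 0.0, 1.0))


def place_particles(
    cfg: SimConfig, max_attempts_per_particle: int = 10_000
) -> list[tuple[tuple[int, int], OrientationRecord]]:
    """Seeded rejection sampling of particle centers and orientations.

    All pairwise distances are >= ``cfg.min_separation`` and every center
    keeps a full box half-side from the edges.  Each record carries random
    ZYZ Euler angles and an integer translation of at most ``max_shift``
    pixels; the recorded extraction coordinate is center + shift, so the
    translation-adjusted center reproduces the true position.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    h, w = cfg.mic_shape
    margin = cfg.box_size // 2
    if cfg.n_particles * cfg.min_separation ** 2 >= h * w:
        raise CapacityError("requested packing density is infeasible")
    centers: list[tuple[int, int]] = []
    out: list[tuple[tuple[int, int], OrientationRecord]] = []
    min_sq = cfg.min_separation ** 2
    for _ in range(cfg.n_particles):
        for _attempt in range(max_attempts_per_particle):
            x = int(rng.integers(margin, w - margin))
            y = int(rng.integers(margin, h - margin))
            if all((x - px) ** 2 + (y - py) ** 2 >= min_sq for px, py in centers):
                break
        else:
            raise CapacityError(
                f"could not place particle {len(centers) + 1} after "
                f"{max_attempts_per_particle} attempts"
            )
        centers.append((x, y))
        rot, psi = rng.uniform(0, 360, size=2)
        tilt = rng.uniform(0, 180)
        dx = int(rng.integers(-cfg.max_shift, cfg.max_shift + 1))
        dy = int(rng.integers(-cfg.max_shift, cfg.max_shift + 1))
        rec = OrientationRecord(
            rot=float(rot), tilt=float(tilt), psi=float(psi),
            dx=float(dx), dy=float(dy), cx=float(x + dx), cy=float(y + dy),
            micrograph=f"sim_{cfg.seed}",
        )
        out.append(((x, y), rec))
    return out


def render_clean(
    volume: Volume,
    placements: list[tuple[tuple[int, int], OrientationRecord]],
    cfg: SimConfig,
) -> GroundTruth:
    """Render the noise-free micrograph, its mask, and exact coordinates.

    The clean image is the sum of the volume's projections pasted at the
    true centers; the mask is the OR of the binarized projections; the
    coordinate PickSet matches the placements exactly.
    """
    h, w = cfg.mic_shape
    box = cfg.box_size
    clean = np.zeros((h, w))
    tiles: list[LabelTile] = []
    picks: list[Pick] = []
    name = f"sim_{cfg.seed}"
    for (x, y), rec in placements:
        proj = project_volume(volume, rec.rot, rec.tilt, rec.psi, box)
        x0, y0 = x - box // 2, y - box // 2
        clean[y0:y0 + box, x0:x0 + box] += proj
        tiles.append(LabelTile(mask=binarize_projection(proj), record=rec))
        picks.append(Pick(x=x, y=y, score=1.0, box_size=box))
    mask = composite_labels(tiles, h, w, source=name)
    return GroundTruth(
        coords=PickSet(picks, micrograph=name),
        mask=mask,
        clean=Micrograph(clean, name=name),
        orientations=[rec for _, rec in placements],
    )


def add_noise_to_snr(clean: Micrograph, snr_db: float, seed: int = 0) -> Micrograph:
    """Add white Gaussian noise scaled so the measured SNR equals the target.

    The noise draw is rescaled in closed form so that
    sum(noise^2) = sum(clean^2) * 10^(-snr_db / 10) holds exactly, hence the
    energy-ratio SNR of the result matches ``snr_db`` to machine precision.
    """
    signal_energy = float(np.sum(clean.data.astype(np.float64) ** 2))
    if signal_energy == 0.0:
        raise DomainError("SNR is undefined for an all-zero clean image")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(clean.data.shape)
    target_energy = signal_energy * 10.0 ** (-snr_db / 10.0)
    noise *= np.sqrt(target_energy / np.sum(noise ** 2))
    return Micrograph(
        clean.data.astype(np.float64) + noise,
        pixel_size=clean.pixel_size,
        name=clean.name + "_noisy" if clean.name else "noisy",
    )


def reference_probability_map(truth: GroundTruth, blur_sigma: float = 2.0) -> ProbabilityMap:
    """Stand-in for a segmenter's output: the ground-truth mask, Gaussian-blurred
    and rescaled to [0, 1].  ``blur_sigma`` 0 returns the mask itself."""
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    m = truth.mask.data.astype(float)
    if blur_sigma > 0:
        m = ndimage.gaussian_filter(m, blur_sigma)
    peak = m.max()
    if peak > 0:
        m = m / peak
    return ProbabilityMap(np.clip(m, 0.0, 1.0), source=truth.mask.source)


def simulate_micrograph(
    cfg: SimConfig, blur_sigma: float = 2.0, n_lobes: int | None = None
) -> tuple[GroundTruth, Micrograph, ProbabilityMap]:
    """Convenience end-to-end run: volume -> placements -> clean -> noisy + reference map."""
    volume = make_toy_volume(cfg, n_lobes=n_lobes)
    placements = place_particles(cfg)
    truth = render_clean(volume, placements, cfg)
    noisy = add_noise_to_snr(truth.clean, cfg.snr_db, seed=cfg.seed + 2)
    pmap = reference_probability_map(truth, blur_sigma=blur_sigma)
    return truth, noisy, pmap
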