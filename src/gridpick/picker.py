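"""Grid-based local-maximum particle selection from probability density maps.

The pipeline converts a per-pixel particle-probability map into particle
center coordinates in five stages:

1. **score** — every pixel becomes the score of the candidate particle
   centered on it: the Gaussian-weighted sum of map values over the s x s
   particle box, ``score(m, n) = sum_{x,y} W[x, y] * V[m + x, n + y]``.
   The Gaussian weights emphasise the box center, which reduces
   interference from adjacent particles.
2. **grid init** — the map is tiled into grids of side g = floor(s / 2) and
   exactly one candidate is seeded per grid at the cell's score argmax.
   With this grid size two selected particles can overlap by at most
   s^2 / 4 pixels.  A 4096 x 4096 map with g = 100 yields 41 x 41 = 1681
   candidates instead of 16.7 million pixel-wise ones.
3. **ascent** — each candidate independently jumps to the argmax of the
   score map inside a square search window about its position, iterating
   until it is a fixed point (a local maximum) or the iteration cap.
4. **deduplicate** — candidates that converged onto the same maximum are
   merged by greedy non-maximum suppression with a minimum separation.
5. **filter** — candidates below the score threshold (default 0.6) are
   dropped, an optional scoring hook can re-score survivors (the slot where
   a trained false-positive classifier plugs in), and at most ``max_picks``
   (default 500) highest-scoring picks are kept.

All tie-breaks use the lowest row-major linear index, so the whole pipeline
is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .errors import ShapeError
from .formats_io import Pick, PickSet, ProbabilityMap

__all__ = [
    "GaussianScoreKernel",
    "GridSpec",
    "Candidate",
    "PickerConfig",
    "build_kernel",
    "score_map",
    "init_grid_candidates",
    "local_max_ascend",
    "deduplicate",
    "filter_picks",
    "pick_particles",
]

ScorerHook = Callable[["Candidate", np.ndarray], float]


@dataclass(frozen=True)
class GaussianScoreKernel:
    """s x s Gaussian weights, centered, normalized to sum 1."""

    weights: np.ndarray
    sigma: float

    @property
    def size(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class GridSpec:
    """Tiling of an (H, W) map into cells of side g; the last row/column may be partial."""

    g: int
    ny: int
    nx: int

    @classmethod
    def for_map(cls, shape: tuple[int, int], g: int) -> "GridSpec":
        if g < 1:
            raise ValueError("grid side must be >= 1")
        h, w = shape
        return cls(g=g, ny=-(-h // g), nx=-(-w // g))

    @classmethod
    def for_particle_size(cls, shape: tuple[int, int], particle_size: int) -> "GridSpec":
        """Grid side g = floor(s / 2), the largest tiling that bounds pairwise overlap by s^2/4."""
        return cls.for_map(shape, max(1, particle_size // 2))

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny


@dataclass(frozen=True)
class Candidate:
    """A candidate particle center with its current score-map value."""

    x: int
    y: int
    score: float
    converged: bool = False
    n_iters: int = 0


@dataclass(frozen=True)
class PickerConfig:
    """Tunable parameters of the picking pipeline.

    ``particle_size`` is the particle box side s in pixels.  Derived
    defaults: grid side g = s // 2, search radius = g, minimum separation
    s / 2 (which enforces the s^2/4 pairwise overlap bound), Gaussian
    sigma = s / 4.  ``score_threshold`` 0.6 and ``max_picks`` 500 are the
    conventional defaults for the false-positive filtering stage.
    """

    particle_size: int
    score_threshold: float = 0.6
    max_picks: int = 500
    search_radius: int | None = None
    max_iters: int = 100
    min_separation: float | None = None
    sigma: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.particle_size < 1:
            raise ValueError("particle_size must be >= 1")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must lie in [0, 1]")
        if self.max_picks < 1 or self.max_iters < 1:
            raise ValueError("max_picks and max_iters must be >= 1")

    @property
    def grid_side(self) -> int:
        return max(1, self.particle_size // 2)

    @property
    def effective_radius(self) -> int:
        return self.search_radius if self.search_radius is not None else self.grid_side

    @property
    def effective_separation(self) -> float:
        return self.min_separation if self.min_separation is not None else self.particle_size / 2

    @property
    def effective_sigma(self) -> float:
        return self.sigma if self.sigma is not None else max(self.particle_size / 4, 0.5)


def build_kernel(particle_size: int, sigma: float) -> GaussianScoreKernel:
    """Gaussian lattice W[x, y] ∝ exp(-(x^2 + y^2) / (2 sigma^2)) on the s x s box, sum 1."""
    if particle_size < 1:
        raise ValueError("particle_size must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    offsets = np.arange(particle_size) - particle_size // 2
    g1 = np.exp(-(offsets ** 2) / (2.0 * sigma ** 2))
    w = np.outer(g1, g1)
    w /= w.sum()
    return GaussianScoreKernel(weights=w, sigma=float(sigma))


def score_map(pmap: ProbabilityMap | np.ndarray, kernel: GaussianScoreKernel) -> np.ndarray:
    """Candidate score for every pixel: Gaussian-weighted box sum, zero-padded at edges.

    Zero padding treats off-map area as background probability 0, which
    suppresses spurious edge candidates.  Output has the map's shape; with
    a normalized kernel and a probability map input, values stay in [0, 1].
    """
    v = pmap.data if isinstance(pmap, ProbabilityMap) else np.asarray(pmap, dtype=float)
    s = kernel.size
    if v.ndim != 2:
        raise ShapeError(f"probability map must be 2D, got shape {v.shape}")
    before = s // 2
    after = s - 1 - before
    padded = np.pad(v.astype(float), ((before, after), (before, after)))
    out = signal.correlate(padded, kernel.weights, mode="valid", method="auto")
    return out


def init_grid_candidates(score: np.ndarray, grid: GridSpec) -> list[Candidate]:
    """One candidate per grid cell at the cell's score argmax (ties: lowest row-major index)."""
    s = np.asarray(score)  # keep the input dtype; no copy for large maps
    h, w = s.shape
    cands: list[Candidate] = []
    g = grid.g
    for gy in range(grid.ny):
        y0, y1 = gy * g, min((gy + 1) * g, h)
        for gx in range(grid.nx):
            x0, x1 = gx * g, min((gx + 1) * g, w)
            cell = s[y0:y1, x0:x1]
            flat = int(np.argmax(cell))  # first max in row-major order
            dy, dx = divmod(flat, cell.shape[1])
            cands.append(Candidate(x=x0 + dx, y=y0 + dy, score=float(cell[dy, dx])))
    return cands


def _window_argmax(s: np.ndarray, x: int, y: int, radius: int) -> tuple[int, int]:
    h, w = s.shape
    y0, y1 = max(0, y - radius), min(h, y + radius + 1)
    x0, x1 = max(0, x - radius), min(w, x + radius + 1)
    win = s[y0:y1, x0:x1]
    flat = int(np.argmax(win))
    dy, dx = divmod(flat, win.shape[1])
    return x0 + dx, y0 + dy


def local_max_ascend(
    score: np.ndarray,
    candidates: Sequence[Candidate],
    radius: int,
    max_iters: int = 100,
) -> list[Candidate]:
    """Move each candidate to the window argmax until it is a fixed point.

    Candidates are independent (the procedure parallelizes trivially); each
    one's score is non-decreasing across iterations and the loop stops at a
    fixed point or after ``max_iters`` jumps.
    """
    if radius < 1:
        raise ValueError("search radius must be >= 1")
    s = np.asarray(score, dtype=float)
    out: list[Candidate] = []
    for c in candidates:
        x, y = c.x, c.y
        converged = False
        it = 0
        for it in range(1, max_iters + 1):
            nx, ny = _window_argmax(s, x, y, radius)
            if (nx, ny) == (x, y):
                converged = True
                break
            x, y = nx, ny
        out.append(Candidate(x=x, y=y, score=float(s[y, x]), converged=converged, n_iters=it))
    return out


def deduplicate(candidates: Sequence[Candidate], min_separation: float) -> list[Candidate]:
    """Greedy non-maximum suppression: accept in descending score order, keep a
    candidate only if it is >= min_separation (Euclidean) from every accepted one.

    Ties in score are broken by lowest row-major position index, so the
    result is deterministic.
    """
    order = sorted(candidates, key=lambda c: (-c.score, c.y, c.x))
    kept: list[Candidate] = []
    min_sq = min_separation * min_separation
    for c in order:
        if any((c.x - k.x) ** 2 + (c.y - k.y) ** 2 < min_sq for k in kept):
            continue
        kept.append(c)
    return kept


def filter_picks(
    candidates: Sequence[Candidate],
    cfg: PickerConfig,
    scorer: ScorerHook | None = None,
    score: np.ndarray | None = None,
    micrograph: str = "",
) -> PickSet:
    """Threshold, optionally re-score through a hook, cap, and package as a PickSet.

    The hook stands where a trained false-positive classifier would: it
    receives each surviving candidate (plus the score map, if available)
    and returns a replacement score, after which the threshold is applied
    again.  At most ``cfg.max_picks`` highest-scoring picks are kept.
    """
    kept = [c for c in candidates if c.score >= cfg.score_threshold]
    if scorer is not None:
        kept = [replace(c, score=float(scorer(c, score))) for c in kept]
        kept = [c for c in kept if c.score >= cfg.score_threshold]
    kept.sort(key=lambda c: (-c.score, c.y, c.x))
    kept = kept[: cfg.max_picks]
    picks = [Pick(x=c.x, y=c.y, score=c.score, box_size=cfg.particle_size) for c in kept]
    return PickSet(picks, micrograph=micrograph)


def pick_particles(
    pmap: ProbabilityMap,
    cfg: PickerConfig,
    scorer: ScorerHook | None = None,
) -> PickSet:
    """Full picking pipeline: score -> grid init -> ascent -> NMS -> filter.

    Deterministic for fixed inputs; returns picks sorted by descending score.
    """
    kernel = build_kernel(cfg.particle_size, cfg.effective_sigma)
    s = score_map(pmap, kernel)
    grid = GridSpec.for_particle_size(s.shape, cfg.particle_size)
    cands = init_grid_candidates(s, grid)
    cands = local_max_ascend(s, cands, radius=cfg.effective_radius, max_iters=cfg.max_iters)
    cands = deduplicate(cands, cfg.effective_separation)
    name = pmap.source if isinstance(pmap, ProbabilityMap) else ""
    return filter_picks(cands, cfg, scorer=scorer, score=s, micrograph=name)
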