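# Methods

This note records the models, conventions and numerical choices behind
`gridpick`, and what the synthetic tests do and do not demonstrate.

## Coordinate and raster conventions

All coordinates are 0-based with x = column and y = row, and always refer
to particle **centers**. EMAN `.box` files store top-left corners; the
conversion `center = corner + ⌊box/2⌋` happens only at the file boundary,
and uses floor division so odd box sizes stay deterministic in integer
arithmetic. MRC arrays are row-major, (y, x) for 2D and (z, y, x) for 3D;
files are written as MRC2014 mode-2 float32 with the pixel/voxel size
encoded in the cell dimensions, so float32 round trips are bitwise exact.
MRC I/O is delegated to gemmi's CCP4/MRC support; the restricted STAR
dialect (a single particle loop with `rlnCoordinateX/Y` and optionally
`rlnAngleRot/Tilt/Psi`, `rlnOriginX/Y`) is parsed by a small purpose-built
reader.

## Picker

**Scoring.** The candidate score is the Gaussian-weighted box sum
`score(m,n) = Σ W[x,y]·V[m+x,n+y]` with W normalized to Σ W = 1, so scores
of a probability map stay in [0, 1] and the 0.6 threshold is
scale-meaningful. The kernel lattice uses offsets `arange(s) − ⌊s/2⌋`
(for even s the box is half-open on the positive side). Off-map area is
treated as background probability 0 (zero padding), which conservatively
suppresses edge candidates. σ defaults to s/4, placing ≥ 95 % of the kernel
mass inside the particle box; it is configurable.

**Grid initialization.** Grid side g = ⌊s/2⌋ with ceiling division for the
cell counts, so edge pixels belong to partial cells and every pixel is
covered exactly once. This reproduces 41 × 41 = 1681 cells on a 4096×4096
map at g = 100.

**Ascent.** Each candidate jumps to the argmax of the score map in the
square window of per-axis radius g about its position (window ≥ grid size
guarantees escape from the initial cell), iterating to a fixed point or at
most 100 iterations. Because the window always contains the current
position, the score is non-decreasing and termination is guaranteed.
Every argmax tie — in cells, windows, and sorting — is broken by the lowest
row-major linear index, making the whole pipeline deterministic without
any RNG.

**Suppression and filtering.** Greedy NMS in descending score order with
minimum separation s/2, then the 0.6 score threshold, then an optional
re-scoring hook (the seam where a trained false-positive classifier would
sit), then a cap of 500 picks. One honesty note on the classical overlap
argument: Euclidean separation ≥ s/2 bounds the pairwise box-overlap area
by s²/4 only up to a geometric constant (the worst case at distance
exactly s/2 along one axis is s²/2). The s²/4 bound is therefore asserted
*empirically on pipeline outputs* in the acceptance suite — where picks sit
on well-separated maxima it holds with a wide margin — rather than claimed
as a theorem.

## Label generation

Orientations follow the RELION-style ZYZ intrinsic convention
(rot, tilt, psi in degrees); rotation is applied about the volume center
with trilinear interpolation and the projection is the z-axis sum. The
identity rotation takes an exact direct-sum path so no-rotation projections
carry no interpolation error. Translation follows the origin-shift
convention: the true particle center is (cx − dx, cy − dy). The integer
part of the adjusted center sets the paste position; only the subpixel
residual is applied as a bilinear image-space shift. Binarization is Otsu's
threshold on the tile's own histogram (parameter-free; a constant tile has
no foreground and maps to all zeros), applied after the residual shift by
default (configurable, since the opposite order is also defensible).
Overlapping tiles combine by logical OR — labels are a class mask, not
instances — making compositing order-independent. Bilinear shifts are exact
on locally linear images only; round-trip tests therefore use ramp images,
where the interpolation oracle is exact.

## Simulator

The simulator generates what the tests need to close the loop — exact
coordinates, masks, orientations, clean and noisy images — not realistic
electron optics. Defaults are the standard study conditions used
throughout the tests: 512×512 micrographs, 25 particles of radius 12 px in
a 32³ voxel box (particle size s = 32), minimum center separation 64 = 2s,
integer extraction shifts up to ±3 px, target SNR −10 dB.

**Toy particles.** The primary lobe is a ball with the projection-flat
radial profile v(r) ∝ 1/√(R² − r²) (clipped to 1): its line integral along
any chord is constant, so the particle projects to a uniform disc in
*every* orientation. This was chosen because a uniform ball projects to a
dome whose Otsu binarization underestimates the footprint (measured IOU
≈ 0.86–0.88 against the true disc), while the flat profile keeps the
binarized footprint orientation-independent and lets label fidelity be
tested at IOU ≥ 0.9 without slack for profile effects. Multi-lobe volumes
(unions of up to 5 offset ellipsoids) exercise asymmetric shapes where no
analytic footprint is claimed.

**Noise and SNR.** Noise is additive white Gaussian; the draw is rescaled
in closed form so that Σ noise² = Σ clean² · 10^(−SNR/10) holds exactly and
the measured energy-ratio SNR equals the target to machine precision
(float32 storage limits this to ~1e-5 dB). Both the dB scale and the
linear power ratio are exposed (`snr`, `snr_linear`), since "SNR 0.01"
readings in the field usually mean the linear ratio (−20 dB).

**Reference probability maps.** A segmenter stand-in: the ground-truth
mask Gaussian-blurred (σ = 2 px by default) and rescaled to [0, 1]. It has
a perfect signal-to-background separation no real segmenter achieves, so
tests using it validate the *coordinate-extraction* machinery, not
robustness to segmentation errors.

**Determinism.** One `numpy` Generator per operation, seeded from
`SimConfig.seed` with fixed offsets (volume: seed, placement: seed+1,
noise: seed+2), so every artifact is bitwise reproducible.

## Metrics

IOU of two empty masks is defined as 1.0 (perfect agreement on absence)
to avoid 0/0. Pick-to-truth matching is greedy in descending pick score;
a pick claims the nearest unmatched truth center within the distance
threshold (default s/2). When ground-truth centers are at least twice the
threshold apart — true for any non-overlapping particle set — each pick can
reach at most one truth and greedy matching provably attains the optimal
assignment TP count; the test suite verifies this against brute-force
maximum matching. Precision or recall with a zero denominator raises
rather than silently returning 0.

## Layer math

The reference ops fix exact contracts: valid (unpadded) cross-correlation
`Y[i,j] = Σ_m Σ_k Σ_l W[m,k,l]·X[m,i+k,j+l]` (0-based form of the
1-based textbook indexing), LRN divisor `(1 + a·Σ X²)^b` with defaults
a = 1e-4, b = 0.75 and the channel window clipped (not wrapped) at the
boundaries, max pooling with partial edge windows included, and atrous
convolution accumulated directly at dilated tap offsets — deliberately
independent of the zero-inserted-kernel construction so the equivalence
(side K + (K−1)(rate−1), K² free parameters regardless of rate) is a real
cross-check rather than a tautology. Stride and padding are parameters,
not fixed network hyperparameters; training, weights and loss layers are
out of scope.

## Problem sizes

Tests run on 512×512 micrographs with 25 particles, 8–32 px rasters for
oracle comparisons (100 random instances per op), and one 4096×4096 map
for the candidate-count arithmetic; the full suite completes in a few
seconds on one CPU.

## Known limitations

- No CTF, dose, ice or carbon-film modeling; results on synthetic data do
  not predict performance on real micrographs with structured interference.
- The picker's score threshold is calibrated for normalized kernel scores
  on probability-scale maps; maps that are not true probabilities need a
  rescaled threshold.
- The classification-network false-positive filter is an interface
  (`scorer` hook), not an implementation.
- Greedy NMS and greedy matching are deterministic but not globally
  optimal in adversarial geometries (see the matching theorem's separation
  precondition above).
- Micrograph-scale label generation assumes the micrograph's particle list
  is complete; unannotated particles become negative labels.
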