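"""Synthetic ground-truthed tomogram scenes.

A desk-scale forward model for cryo-ET: procedural particle shapes stand in
for macromolecular scattering potentials; particles are placed without
overlap, pasted into a clean volume together with a voxel-level occupancy
map, and the volume is then corrupted by a Fourier-space missing-wedge mask
(single-axis tilt about y, default half-angle 60 degrees) and additive
Gaussian noise.  Ground truth (class, center, box) is returned for every
particle, so localization performance can be scored exactly.

The model deliberately omits electron-optical effects (CTF, detector MTF,
dose); it preserves the two statistical properties the picking method
actually depends on — anisotropic missing-wedge distortion and a
controllable signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ShapeLibraryEntry",
    "SceneConfig",
    "GroundTruthRecord",
    "Tomogram",
    "make_shape_library",
    "place_particles",
    "render_scene",
    "missing_wedge_mask",
    "apply_missing_wedge",
    "synthesize_tomogram",
    "simulate_scene",
    "make_subvolume_pools",
    "make_background_pool",
    "make_scene_pools",
]

#: hard cap on library size; small boxes may saturate below this and raise
MAX_SHAPE_CLASSES = 12


@dataclass(frozen=True)
class ShapeLibraryEntry:
    """One particle species: a non-negative density in a cubic box."""

    class_id: int
    density: np.ndarray          # (box_len,)*3, background exactly 0
    nominal_size: float          # approximate diameter in voxels


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one simulated scene.

    ``noise_sigma`` is the standard deviation of the additive Gaussian noise
    relative to the unit peak contrast of a particle.  ``particles_dark``
    selects the global contrast convention (cryo-ET reconstructions usually
    show protein darker than background).
    """

    dims: tuple[int, int, int]            # (z, y, x) voxels
    counts: dict[int, int]                # class_id -> particle count
    min_separation: float = 16.0
    wedge_half_angle: float = 60.0
    noise_sigma: float = 0.3
    seed: int = 0
    rotate: bool = True
    full_rotation: bool = False           # SO(3) instead of z-only
    particles_dark: bool = True
    #: extra empty border (voxels) beyond the particle-box margin; lets a
    #: scene keep particles inside the sliding-window lattice's reach
    edge_margin: int = 0

    def __post_init__(self):
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be >= 0")
        if not 0.0 < self.wedge_half_angle <= 90.0:
            raise ValueError("wedge_half_angle must be in (0, 90]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class GroundTruthRecord:
    class_id: int
    center: tuple[int, int, int]          # (z, y, x) voxel
    box_len: int


@dataclass
class Tomogram:
    """A 3D scalar grid with voxel-size metadata (Angstrom per voxel)."""

    grid: np.ndarray
    voxel_size: float = 10.0
    particles_dark: bool = True

    def __post_init__(self):
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("tomogram grid contains non-finite values")


# ---------------------------------------------------------------------- #
# shape library

def _coords(box_len: int):
    r = np.arange(box_len) - box_len // 2
    return np.meshgrid(r, r, r, indexing="ij")  # z, y, x


def _ellipsoid(box_len, radii, rng):
    z, y, x = _coords(box_len)
    a, b, c = radii
    return ((z / a) ** 2 + (y / b) ** 2 + (x / c) ** 2 <= 1.0).astype(np.float64)


def _rod(box_len, radius, half_len, axis, rng):
    z, y, x = _coords(box_len)
    ax = [z, y, x]
    along = ax.pop(axis)
    perp = np.sqrt(ax[0] ** 2 + ax[1] ** 2)
    return ((np.abs(along) <= half_len) & (perp <= radius)).astype(np.float64)


def _blob_cluster(box_len, n_blobs, radius, spread, rng):
    z, y, x = _coords(box_len)
    # central blob plus symmetric pairs: center of mass stays at the box
    # center and the center voxel stays inside material
    vol = (z**2 + y**2 + x**2 <= radius**2).astype(np.float64)
    for _ in range(n_blobs):
        off = rng.uniform(-spread, spread, size=3)
        for sgn in (1.0, -1.0):
            vol += ((z - sgn * off[0]) ** 2 + (y - sgn * off[1]) ** 2 +
                    (x - sgn * off[2]) ** 2 <= radius**2)
    return np.clip(vol, 0, 1)


def _cross(box_len, radius, half_len, rng):
    return np.clip(_rod(box_len, radius, half_len, 1, rng) +
                   _rod(box_len, radius, half_len, 2, rng), 0, 1)


def make_shape_library(n_classes: int, box_len: int, seed: int,
                       include_fiducial: bool = False,
                       include_vesicle: bool = False) -> list[ShapeLibraryEntry]:
    """Generate ``n_classes`` pairwise-distinct procedural particle shapes.

    Shapes are unions of ellipsoids, rods, crosses and symmetric blob
    clusters, smoothed and peak-normalized to 1, with a small dense core at
    the box center so every ground-truth center is a strict local maximum of
    the clean density.  Optional extra classes model fiducial gold beads
    (solid dense sphere) and vesicles (spherical shell); they are appended
    after the ``n_classes`` protein-like classes with ids continuing upward.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if box_len < 9 or box_len % 2 == 0:
        raise ValueError("box_len must be odd and >= 9")
    if n_classes > MAX_SHAPE_CLASSES:
        raise ValueError(
            f"n_classes={n_classes} exceeds the generator's repertoire of "
            f"{MAX_SHAPE_CLASSES} distinct shapes")

    rmax = box_len // 2 - 2          # keep support strictly inside the box
    entries = []
    densities: list[np.ndarray] = []
    root = np.random.SeedSequence(seed)
    families = ("ellipsoid", "rod", "ring", "cross", "cluster")
    for cid in range(1, n_classes + 1):
        family = families[(cid - 1) % len(families)]
        # scale ladder across the library: real training sets span a wide
        # molecular-weight range, and at desk-scale voxel counts particle
        # mass/extent is the most robust cue separating species after
        # wedge corruption — so consecutive classes climb in scale as well
        # as cycling through shape families
        tier = min(0.5 + 0.18 * (cid - 1), 1.4)
        # deterministic redraw loop: reject shapes too similar to earlier ones
        for attempt in range(20):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, cid, attempt]))
            vol, size = _make_shape(family, tier, box_len, rmax, rng)
            if all(_ncc(vol, d) < 0.93 for d in densities):
                break
        else:
            raise ValueError(
                f"could not draw a {family} shape distinct from the "
                f"{cid - 1} existing classes; the generator's repertoire "
                f"tops out near {MAX_SHAPE_CLASSES} classes at this box size")
        densities.append(vol)
        entries.append(ShapeLibraryEntry(cid, vol, float(min(size, box_len - 4))))

    next_id = n_classes + 1
    z, y, x = _coords(box_len)
    r = np.sqrt(z**2 + y**2 + x**2)
    if include_fiducial:
        bead = (r <= max(2.0, 0.25 * rmax)).astype(float) * 2.0  # gold: dense
        _zero_border(bead)
        entries.append(ShapeLibraryEntry(next_id, bead, 2 * max(2.0, 0.25 * rmax)))
        next_id += 1
    if include_vesicle:
        shell = ((r <= rmax) & (r >= rmax - 1.5)).astype(float)
        shell = np.maximum(shell, np.exp(-(r**2) / (2 * 1.2**2)))
        _zero_border(shell)
        entries.append(ShapeLibraryEntry(next_id, shell, 2.0 * rmax))
    return entries


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-shape densities."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 1.0


def _make_shape(family: str, scale: float, box_len: int, rmax: int,
                rng: np.random.Generator) -> tuple[np.ndarray, float]:
    scale = scale * rng.uniform(0.95, 1.05)
    if family == "ellipsoid":
        # one deliberately long axis for anisotropy
        radii = np.array([rmax * scale, rmax * scale * rng.uniform(0.35, 0.55),
                          rmax * scale * rng.uniform(0.55, 0.8)])
        rng.shuffle(radii)
        radii = np.clip(radii, 1.5, rmax)
        vol = _ellipsoid(box_len, radii, rng)
        size = 2 * float(np.mean(radii))
    elif family == "rod":
        radius = max(1.5, rmax * scale * rng.uniform(0.25, 0.35))
        half_len = min(float(rmax), max(4.0, rmax * scale * rng.uniform(0.9, 1.2)))
        vol = _rod(box_len, radius, half_len, axis=int(rng.integers(0, 3)), rng=rng)
        size = 2 * half_len
    elif family == "ring":
        # torus in the xy plane: rotationally symmetric about z, hence
        # trivially invariant to in-plane rotation and grossly unlike the
        # solid families
        tube_r = max(0.9, min(rmax * scale * rng.uniform(0.22, 0.32),
                              (rmax - 3.2) / 2))
        # keep the central hole >= ~3 voxels so the center-bump invariant
        # survives smoothing
        ring_r = float(np.clip(rmax * scale * rng.uniform(0.7, 0.85),
                               tube_r + 3.2, rmax - tube_r))
        z, y, x = _coords(box_len)
        hz = tube_r * rng.uniform(0.8, 1.3)       # elliptical tube section
        vol = (((np.sqrt(y**2 + x**2) - ring_r) / tube_r) ** 2
               + (z / hz) ** 2 <= 1.0).astype(float)
        core_r = ring_r - tube_r - 1.0
        if scale > 1.05 and core_r >= 1.2:
            # large rings gain a central body ("planet" variant), keeping
            # the family distinguishable across the scale ladder
            vol = np.clip(vol + (z**2 + y**2 + x**2 <= core_r**2), 0, 1)
        size = 2 * (ring_r + tube_r)
    elif family == "cross":
        # three orthogonal arms of unequal length
        radius = max(1.3, rmax * scale * rng.uniform(0.26, 0.34))
        lens = rmax * scale * rng.uniform(0.7, 1.05, size=3)
        lens = np.clip(lens, 3.0, rmax)
        vol = np.clip(sum(_rod(box_len, radius, lens[a], a, rng)
                          for a in range(3)), 0, 1)
        size = 2 * float(lens.max())
    else:
        radius = max(1.6, rmax * scale * rng.uniform(0.36, 0.44))
        spread = max(1.0, rmax * scale * 0.93 - radius)
        vol = _blob_cluster(box_len, int(rng.integers(2, 4)), radius, spread, rng)
        size = 2 * (spread + radius)
    vol = ndimage.gaussian_filter(vol, sigma=0.7)
    peak = vol.max()
    if peak > 0:
        vol /= peak
    # faint additive center bump: makes the recorded center a strict local
    # maximum of the clean density without acting as a shared bright beacon
    # that would dominate every class's appearance
    z, y, x = _coords(box_len)
    core = np.exp(-(z**2 + y**2 + x**2) / (2 * 1.2**2))
    vol = 0.95 * vol + 0.05 * core
    vol[vol < 5e-3] = 0.0
    _zero_border(vol)
    return vol, size


def _zero_border(vol: np.ndarray) -> None:
    vol[0, :, :] = vol[-1, :, :] = 0.0
    vol[:, 0, :] = vol[:, -1, :] = 0.0
    vol[:, :, 0] = vol[:, :, -1] = 0.0


# ---------------------------------------------------------------------- #
# placement and rendering

class PlacementError(ValueError):
    """Raised when rejection sampling cannot honor the requested counts."""


def place_particles(config: SceneConfig, library: list[ShapeLibraryEntry],
                    max_attempts_per_particle: int = 200) -> list[GroundTruthRecord]:
    """Rejection-sample non-overlapping particle centers.

    Centers are at least ``min_separation`` apart (center-to-center sphere
    proxy) and every particle's box lies fully inside ``dims``.
    """
    if not library:
        raise ValueError("library is empty")
    by_id = {e.class_id: e for e in library}
    unknown = set(config.counts) - set(by_id)
    if unknown:
        raise ValueError(f"counts reference unknown class ids {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    dims = np.asarray(config.dims)
    records: list[GroundTruthRecord] = []
    centers: list[np.ndarray] = []
    total = sum(config.counts.values())
    min_sep2 = config.min_separation**2
    for cid in sorted(config.counts):
        box_len = by_id[cid].density.shape[0]
        margin = box_len // 2 + config.edge_margin
        lo, hi = margin, dims - 1 - margin
        if np.any(hi < lo):
            raise PlacementError(
                f"box of class {cid} (edge {box_len}) does not fit in dims {config.dims}")
        for _ in range(config.counts[cid]):
            for _attempt in range(max_attempts_per_particle):
                c = rng.integers(lo, hi + 1)
                if all(np.sum((c - o) ** 2) >= min_sep2 for o in centers):
                    centers.append(c)
                    records.append(GroundTruthRecord(cid, tuple(int(v) for v in c),
                                                     box_len))
                    break
            else:
                raise PlacementError(
                    f"placed {len(records)} of {total} particles before the "
                    f"attempt budget ran out (class {cid}); reduce counts or "
                    f"min_separation")
    return records


def _rotated_density(density: np.ndarray, rng: np.random.Generator,
                     full_rotation: bool) -> np.ndarray:
    """Random in-plane (xy) rotation; optional full SO(3) rotation."""
    angle = rng.uniform(0.0, 360.0)
    out = ndimage.rotate(density, angle, axes=(1, 2), reshape=False,
                         order=1, mode="constant", cval=0.0)
    if full_rotation:
        out = ndimage.rotate(out, rng.uniform(0.0, 360.0), axes=(0, 1),
                             reshape=False, order=1, mode="constant", cval=0.0)
    return np.clip(out, 0.0, None)


def render_scene(records: list[GroundTruthRecord],
                 library: list[ShapeLibraryEntry],
                 dims: tuple[int, int, int],
                 seed: int = 0, rotate: bool = True,
                 full_rotation: bool = False,
                 occupancy_threshold: float = 0.05,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Paste particle densities into a clean volume + occupancy label map.

    Occupancy labels each voxel with the class id whose (rotated) density
    exceeds ``occupancy_threshold`` there; 0 is background.  Earlier-placed
    particles are never overwritten (placement forbids overlap anyway).
    """
    by_id = {e.class_id: e for e in library}
    clean = np.zeros(dims, dtype=np.float64)
    occupancy = np.zeros(dims, dtype=np.int32)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    for rec in records:
        entry = by_id[rec.class_id]
        dens = entry.density
        if rotate:
            dens = _rotated_density(dens, rng, full_rotation)
        r = rec.box_len // 2
        z, y, x = rec.center
        sl = (slice(z - r, z + r + 1), slice(y - r, y + r + 1),
              slice(x - r, x + r + 1))
        if (z - r < 0 or y - r < 0 or x - r < 0 or
                z + r >= dims[0] or y + r >= dims[1] or x + r >= dims[2]):
            raise ValueError(f"particle box at {rec.center} exceeds dims {dims}")
        clean[sl] += dens
        support = (dens > occupancy_threshold) & (occupancy[sl] == 0)
        occupancy[sl][support] = rec.class_id
    return clean, occupancy


# ---------------------------------------------------------------------- #
# missing wedge + noise

def missing_wedge_mask(dims: tuple[int, int, int],
                       wedge_half_angle: float) -> np.ndarray:
    """Boolean Fourier mask; True = coefficient retained.

    Single-axis tilt about y with half-range ``wedge_half_angle``: a
    coefficient is lost when its (k_z, k_x) direction lies within
    ``90 - wedge_half_angle`` degrees of the k_z axis.  The k_y axis is
    unaffected; the k_z = k_x = 0 line (including DC) is retained.
    """
    if not 0.0 < wedge_half_angle <= 90.0:
        raise ValueError("wedge_half_angle must be in (0, 90]")
    kz = np.fft.fftfreq(dims[0])[:, None, None]
    kx = np.fft.fftfreq(dims[2])[None, None, :]
    if wedge_half_angle == 90.0:
        return np.ones(dims, dtype=bool)
    # lost: angle((kz,kx), kz-axis) < 90 - half_angle  <=>  |kx|*tan(half) < |kz|
    lost = np.abs(kx) * np.tan(np.deg2rad(wedge_half_angle)) < np.abs(kz)
    return np.broadcast_to(~lost, dims).copy()


def apply_missing_wedge(volume: np.ndarray, wedge_half_angle: float) -> np.ndarray:
    mask = missing_wedge_mask(volume.shape, wedge_half_angle)
    return np.real(np.fft.ifftn(np.fft.fftn(volume) * mask))


def synthesize_tomogram(clean_volume: np.ndarray, config: SceneConfig,
                        voxel_size: float = 10.0) -> Tomogram:
    """Missing wedge + Gaussian noise + global contrast convention.

    Noise is drawn from a stream derived from ``config.seed`` (independent
    of the placement stream) so the whole scene is reproducible end to end.
    """
    if not np.all(np.isfinite(clean_volume)):
        raise ValueError("clean_volume contains non-finite values")
    wedged = apply_missing_wedge(np.asarray(clean_volume, dtype=np.float64),
                                 config.wedge_half_angle)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    out = wedged + rng.normal(0.0, config.noise_sigma, size=wedged.shape) \
        if config.noise_sigma > 0 else wedged
    if config.particles_dark:
        out = -out
    return Tomogram(out, voxel_size=voxel_size,
                    particles_dark=config.particles_dark)


def make_subvolume_pools(library: list[ShapeLibraryEntry], n_per_class: int,
                         box_len: int, noise_sigma: float = 0.3,
                         wedge_half_angle: float = 60.0, seed: int = 0,
                         jitter: int = 2, particles_dark: bool = True,
                         ) -> dict[int, list[np.ndarray]]:
    """Per-class pools of normalized training subvolumes.

    Each subvolume holds one particle (random in-plane rotation, center
    jittered by up to ``jitter`` voxels per axis) pushed through the same
    forward model as full scenes — missing wedge, Gaussian noise, contrast
    convention — then z-score normalized, matching what the sliding-window
    embedder feeds the network.
    """
    from .embedding import normalize_subvolume

    pools: dict[int, list[np.ndarray]] = {}
    for entry in library:
        if entry.density.shape[0] > box_len:
            raise ValueError(
                f"class {entry.class_id} box ({entry.density.shape[0]}) "
                f"exceeds subvolume box_len {box_len}")
        rng = np.random.default_rng(np.random.SeedSequence([seed, entry.class_id]))
        pool = []
        r = entry.density.shape[0] // 2
        c = box_len // 2
        for _ in range(n_per_class):
            dens = _rotated_density(entry.density, rng, full_rotation=False)
            vol = np.zeros((box_len,) * 3)
            off = rng.integers(-jitter, jitter + 1, size=3)
            z, y, x = np.clip(c + off, r, box_len - 1 - r)
            vol[z - r:z + r + 1, y - r:y + r + 1, x - r:x + r + 1] = dens
            vol = apply_missing_wedge(vol, wedge_half_angle)
            vol += rng.normal(0.0, noise_sigma, size=vol.shape)
            if particles_dark:
                vol = -vol
            normalized, _ = normalize_subvolume(vol)
            pool.append(normalized)
        pools[entry.class_id] = pool
    return pools


def make_background_pool(n: int, box_len: int, noise_sigma: float = 0.3,
                         seed: int = 0,
                         particles_dark: bool = True) -> list[np.ndarray]:
    """Particle-free (noise-only) subvolumes through the same forward model.

    Training with an explicit background class anchors empty-ice windows in
    their own region of embedding space; without it the embedding of
    background is unconstrained and similarity maps lose contrast.
    """
    from .embedding import normalize_subvolume

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    pool = []
    for _ in range(n):
        vol = rng.normal(0.0, max(noise_sigma, 1e-3), size=(box_len,) * 3)
        if particles_dark:
            vol = -vol
        normalized, _ = normalize_subvolume(vol)
        pool.append(normalized)
    return pool


def make_scene_pools(library: list[ShapeLibraryEntry], n_per_class: int,
                     box_len: int, scene_dims=(64, 64, 64),
                     counts_per_scene: int = 3, min_separation: float = 16.0,
                     noise_sigma: float = 0.2, wedge_half_angle: float = 60.0,
                     seed: int = 0, n_background: int | None = None,
                     jitter: int = 2) -> dict[int, list[np.ndarray]]:
    """Training pools extracted from fully simulated scenes.

    Simulates as many scenes as needed, then cuts normalized ``box_len``
    windows at ground-truth centers (class pools) and at particle-free
    positions (background pool, class id 0).  Unlike per-box rendering,
    windows cut from whole scenes carry the long-range missing-wedge
    streaks and neighbor context the sliding-window embedder will actually
    see, so train and test distributions match.  Extraction windows are
    jittered by up to ``jitter`` voxels per axis: the sliding-window
    lattice never lands exactly on a particle center, so the embedding
    must tolerate sub-stride offsets.
    """
    from .embedding import normalize_subvolume

    if n_background is None:
        n_background = n_per_class
    r = box_len // 2
    dims = np.asarray(scene_dims)
    pools: dict[int, list[np.ndarray]] = {e.class_id: [] for e in library}
    pools[0] = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    scene_idx = 0
    while (any(len(pools[e.class_id]) < n_per_class for e in library)
           or len(pools[0]) < n_background):
        config = SceneConfig(dims=tuple(int(d) for d in dims),
                             counts={e.class_id: counts_per_scene
                                     for e in library},
                             min_separation=min_separation,
                             wedge_half_angle=wedge_half_angle,
                             noise_sigma=noise_sigma,
                             seed=int(rng.integers(0, 2**31)))
        try:
            tomo, _, _, records = simulate_scene(config, library)
        except PlacementError:       # over-dense draw; try a fresh seed
            scene_idx += 1
            continue
        grid = tomo.grid
        centers = np.array([rec.center for rec in records])
        for rec in records:
            if len(pools[rec.class_id]) >= n_per_class:
                continue
            off = rng.integers(-jitter, jitter + 1, size=3) if jitter else 0
            z, y, x = np.clip(np.asarray(rec.center) + off, r, dims - 1 - r)
            cube = grid[z - r:z + r + 1, y - r:y + r + 1, x - r:x + r + 1]
            normalized, degenerate = normalize_subvolume(cube)
            if not degenerate:
                pools[rec.class_id].append(normalized)
        # background: a mix of windows far from every particle and windows
        # centered on a particle's missing-wedge ghost (directly above or
        # below it along z) — the latter are where naive picking produces
        # false positives, so the model must learn them as background.
        # Capped per scene so the pool mixes many noise realizations.
        tries = 0
        scene_bg = 0
        while len(pools[0]) < n_background and tries < 200 and scene_bg < 8:
            tries += 1
            if tries % 2 and len(records):
                rec = records[rng.integers(len(records))]
                off = np.array([int(rng.choice([-1, 1])) * int(rng.integers(6, 11)),
                                int(rng.integers(-2, 3)),
                                int(rng.integers(-2, 3))])
                c = np.clip(np.asarray(rec.center) + off, r, dims - 1 - r)
            else:
                c = rng.integers(r, dims - r)
                if np.min(np.abs(centers - c).max(axis=1)) <= box_len:
                    continue
            cube = grid[c[0] - r:c[0] + r + 1, c[1] - r:c[1] + r + 1,
                        c[2] - r:c[2] + r + 1]
            normalized, degenerate = normalize_subvolume(cube)
            if not degenerate:
                pools[0].append(normalized)
                scene_bg += 1
        scene_idx += 1
        if scene_idx > 10 * (n_per_class // counts_per_scene + 1):
            raise RuntimeError("scene budget exhausted while filling pools")
    return pools


def simulate_scene(config: SceneConfig, library: list[ShapeLibraryEntry],
                   voxel_size: float = 10.0):
    """Full pipeline: place -> render -> wedge + noise.

    Returns ``(tomogram, clean_volume, occupancy_map, records)``.
    Deterministic for a fixed config and library.
    """
    records = place_particles(config, library)
    clean, occupancy = render_scene(records, library, config.dims,
                                    seed=config.seed, rotate=config.rotate,
                                    full_rotation=config.full_rotation)
    tomo = synthesize_tomogram(clean, config, voxel_size=voxel_size)
    return tomo, clean, occupancy, records
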