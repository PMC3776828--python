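"""Visual-hull voxel carving and the likelihood-index volume filter.

The capture region inside the current bounding cube is discretised into
cubic voxels (2 mm edge by default). Each voxel centre is projected into
every camera; the correspondence count C(v) is the number of cameras whose
silhouette contains the projection. The per-voxel likelihood index combines
correspondences with local spatial support,

    L(v) = C(v) + mean of C over the 26-connected neighbours of v,

so N <= max L <= 2N for an N-camera rig. Body voxels are the superlevel set
{L >= tau}; tau starts at the strictest value (max L) and is lowered through
the distinct observed L values until the selected volume enters the band
mu +/- 3 sigma around the expected animal volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .camera import CameraRig, project_points
from .errors import ConfigurationError
from .silhouette import BoundingCube

__all__ = [
    "VoxelGrid",
    "BodyVolume",
    "VolumeStats",
    "carve",
    "carve_multi",
    "likelihood_index",
    "threshold_volume",
    "estimate_volume_stats",
    "save_voxels_csv",
    "save_occupancy",
    "load_occupancy",
]

DEFAULT_VOXEL_EDGE = 2.0  # mm
SIGMA_BAND = 3.0  # half-width of the volume acceptance band, in sigmas
SIGMA_FLOOR_FRAC = 0.01  # sigma floored at 1% of mu (degenerate constant-volume data)


@dataclass(frozen=True)
class VoxelGrid:
    """Regular cubic grid; voxel (i, j, k) has centre origin + (i+.5, j+.5, k+.5)*edge."""

    origin: np.ndarray  # (3,) mm
    edge: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if self.edge <= 0 or any(d < 1 for d in self.dims):
            raise ConfigurationError("voxel grid needs positive edge and dims >= 1")

    @classmethod
    def from_cube(
        cls,
        cube: BoundingCube,
        edge: float = DEFAULT_VOXEL_EDGE,
        z_range: tuple[float, float] | None = None,
    ) -> "VoxelGrid":
        """Grid covering the bounding cube; ``z_range`` optionally clips the
        vertical extent to the physically possible band (floor to arena top)."""
        n = max(int(np.ceil(2.0 * cube.half_extent / edge)), 1)
        origin = cube.center - 0.5 * n * edge
        nz = n
        if z_range is not None:
            z0 = max(origin[2], z_range[0])
            z1 = min(origin[2] + n * edge, z_range[1])
            if z1 <= z0:
                z0, z1 = z_range[0], z_range[0] + edge
            origin = np.array([origin[0], origin[1], z0])
            nz = max(int(np.ceil((z1 - z0) / edge)), 1)
        return cls(origin=origin, edge=edge, dims=(n, n, nz))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def centers(self) -> np.ndarray:
        """(n_voxels, 3) voxel centres in C order (i fastest-varying last)."""
        nx, ny, nz = self.dims
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
        return self.origin + (idx + 0.5) * self.edge


@dataclass
class BodyVolume:
    """Occupied voxel centres for one frame."""

    voxel_centers: np.ndarray  # (n, 3) mm
    edge: float
    tail_mode: str = "with_tail"
    threshold: float = np.nan  # final likelihood threshold tau

    @property
    def count(self) -> int:
        return len(self.voxel_centers)

    @property
    def volume(self) -> float:
        return self.count * self.edge**3

    def centroid(self) -> np.ndarray | None:
        if self.count == 0:
            return None
        return self.voxel_centers.mean(axis=0)


@dataclass(frozen=True)
class VolumeStats:
    mu: float  # mm^3
    sigma: float  # mm^3

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigurationError("sigma must be non-negative")

    def band(self, n_sigma: float = SIGMA_BAND) -> tuple[float, float]:
        return self.mu - n_sigma * self.sigma, self.mu + n_sigma * self.sigma


def carve_multi(
    mask_sets: list[list],
    rig: CameraRig,
    grid: VoxelGrid,
    mask_origins: list[tuple[int, int]] | None = None,
) -> list[np.ndarray]:
    """Correspondence counts for several mask sets sharing one projection pass.

    ``mask_sets[j][i]`` is camera i's silhouette in set j (e.g. with-tail
    and tailless cleanups of the same frame); voxel projections are computed
    once per camera and reused across sets.
    """
    for masks in mask_sets:
        if len(masks) != rig.n:
            raise ConfigurationError(f"got {len(masks)} masks for {rig.n} cameras")
    if mask_origins is None:
        mask_origins = [(0, 0)] * rig.n
    nx, ny, nz = grid.dims
    # voxel-centre coordinates along each grid axis (broadcast, no big matmul)
    gx = (grid.origin[0] + (np.arange(nx, dtype=np.float32) + 0.5) * grid.edge)[:, None, None]
    gy = (grid.origin[1] + (np.arange(ny, dtype=np.float32) + 0.5) * grid.edge)[None, :, None]
    gz = (grid.origin[2] + (np.arange(nz, dtype=np.float32) + 0.5) * grid.edge)[None, None, :]
    counts = [np.zeros(grid.n_voxels, dtype=np.uint8) for _ in mask_sets]
    any_fg = [False] * len(mask_sets)
    for i, (cam, origin) in enumerate(zip(rig, mask_origins)):
        if all(
            masks[i] is None or masks[i].size == 0 or not masks[i].any() for masks in mask_sets
        ):
            continue
        R = cam.rotation.astype(np.float32)
        t = cam.translation.astype(np.float32)
        zc = (R[2, 0] * gx + R[2, 1] * gy + R[2, 2] * gz + t[2]).ravel()
        in_front = zc > 0
        inv = np.where(in_front, 1.0 / np.where(in_front, zc, 1.0), 0.0).astype(np.float32)
        xc = (R[0, 0] * gx + R[0, 1] * gy + R[0, 2] * gz + t[0]).ravel()
        yc = (R[1, 0] * gx + R[1, 1] * gy + R[1, 2] * gz + t[1]).ravel()
        ui = np.floor(
            np.float32(cam.focal[0]) * xc * inv + np.float32(cam.principal_point[0]) + 0.5
        ).astype(np.int32) - origin[1]
        vi = np.floor(
            np.float32(cam.focal[1]) * yc * inv + np.float32(cam.principal_point[1]) + 0.5
        ).astype(np.int32) - origin[0]
        for j, masks in enumerate(mask_sets):
            mask = masks[i]
            if mask is None or mask.size == 0 or not mask.any():
                continue
            any_fg[j] = True
            hh, ww = mask.shape
            inside = in_front & (ui >= 0) & (ui < ww) & (vi >= 0) & (vi < hh)
            hit = np.zeros(grid.n_voxels, dtype=bool)
            hit[inside] = mask[vi[inside], ui[inside]]
            counts[j] += hit
    out = []
    for j, C in enumerate(counts):
        C = C.reshape(grid.dims)
        if any_fg[j] and C.max() < rig.n:
            warnings.warn(
                "no voxel reached full camera correspondence; possible calibration mismatch",
                stacklevel=2,
            )
        out.append(C)
    return out


def carve(
    masks: list,
    rig: CameraRig,
    grid: VoxelGrid,
    mask_origins: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Correspondence counts C for every grid voxel.

    ``masks[i]`` is camera i's binary silhouette (optionally a crop whose
    full-image offset is ``mask_origins[i]``). Warns when no voxel reaches
    full correspondence although silhouettes are non-empty (possible
    calibration mismatch).
    """
    return carve_multi([masks], rig, grid, mask_origins)[0]


def likelihood_index(C: np.ndarray) -> np.ndarray:
    """L = C + mean correspondence count over the 26-neighbourhood.

    The neighbourhood is truncated at grid borders (border voxels average
    over the neighbours that exist).
    """
    Cf = np.asarray(C, dtype=np.float64)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    neigh_sum = ndimage.convolve(Cf, kernel, mode="constant", cval=0.0)
    # neighbour counts are separable: (per-axis run lengths) product minus self
    axes = [np.full(n, 3.0) for n in Cf.shape]
    for a in axes:
        if len(a) >= 1:
            a[0] = min(2.0, len(a))
            a[-1] = min(2.0, len(a))
    neigh_cnt = (
        axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :] - 1.0
    )
    return Cf + neigh_sum / neigh_cnt


def threshold_volume(
    L: np.ndarray,
    stats: VolumeStats,
    grid: VoxelGrid,
    tail_mode: str = "with_tail",
    n_sigma: float = SIGMA_BAND,
) -> BodyVolume:
    """Select body voxels {L >= tau} with the volume-band adaptive threshold.

    tau starts at max L and is lowered through the distinct observed L
    values; iteration stops at the first tau whose selected volume lies
    within mu +/- 3 sigma. If the band is skipped over entirely, the tau
    whose volume is closest to mu is returned.
    """
    Lf = np.asarray(L, dtype=float).ravel()
    vals = Lf[Lf > 0]
    edge = grid.edge
    if vals.size == 0:
        return BodyVolume(np.empty((0, 3)), edge, tail_mode, threshold=np.nan)
    lo, hi = stats.band(n_sigma)
    order = np.sort(vals)[::-1]
    # distinct thresholds, strictest first; volume at tau = count of L >= tau
    taus, first_idx = np.unique(-order, return_index=True)
    taus = -taus  # ascending -> descending
    counts = np.searchsorted(-order, -taus, side="right")
    volumes = counts * edge**3

    inside = (volumes >= lo) & (volumes <= hi)
    if inside.any():
        pick = int(np.argmax(inside))  # first (strictest) tau inside the band
    else:
        pick = int(np.argmin(np.abs(volumes - stats.mu)))
    tau = float(taus[pick])
    idx = np.argwhere(np.asarray(L).reshape(grid.dims) >= tau)
    centers = grid.origin + (idx + 0.5) * edge
    return BodyVolume(centers, edge, tail_mode, threshold=tau)


def estimate_volume_stats(
    volumes,
    prior: VolumeStats | None = None,
) -> VolumeStats:
    """Robust per-trial volume statistics: mu = median, sigma = 1.4826 * MAD.

    ``volumes`` are raw per-frame reconstruction volumes (mm^3) from a
    bootstrap pass at full camera correspondence. With fewer than 10 frames
    the configured prior is returned instead. sigma is floored at 1% of mu
    so constant-volume (noise-free synthetic) data keeps a usable band.
    """
    v = np.asarray(list(volumes), dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 10:
        if prior is None:
            raise ConfigurationError(
                "fewer than 10 frames and no prior volume statistics configured"
            )
        return prior
    mu = float(np.median(v))
    sigma = float(1.4826 * np.median(np.abs(v - mu)))
    sigma = max(sigma, SIGMA_FLOOR_FRAC * mu)
    return VolumeStats(mu=mu, sigma=sigma)


# ---------------------------------------------------------------------------
# Optional exports


def save_voxels_csv(body: BodyVolume, path) -> None:
    """Occupied voxel centres as x_mm,y_mm,z_mm text."""
    np.savetxt(
        path,
        body.voxel_centers,
        delimiter=",",
        header="x_mm,y_mm,z_mm",
        comments="",
        fmt="%.3f",
    )


def save_occupancy(L: np.ndarray, tau: float, grid: VoxelGrid, path) -> None:
    """Binary occupancy dump: a 52-byte header (magic b'VOXM', int32 dims[3],
    float64 origin[3], float64 edge) followed by the packed occupancy bits in
    C order."""
    occ = (np.asarray(L).reshape(grid.dims) >= tau).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(b"VOXM")
        fh.write(np.asarray(grid.dims, dtype=np.int32).tobytes())
        fh.write(np.asarray(grid.origin, dtype=np.float64).tobytes())
        fh.write(np.float64(grid.edge).tobytes())
        fh.write(np.packbits(occ.ravel()).tobytes())


def load_occupancy(path) -> tuple[np.ndarray, VoxelGrid]:
    """Inverse of :func:`save_occupancy`; returns (bool array, grid)."""
    with open(path, "rb") as fh:
        if fh.read(4) != b"VOXM":
            raise ConfigurationError(f"{path}: not an occupancy dump")
        dims = tuple(np.frombuffer(fh.read(12), dtype=np.int32))
        origin = np.frombuffer(fh.read(24), dtype=np.float64)
        edge = float(np.frombuffer(fh.read(8), dtype=np.float64)[0])
        bits = np.frombuffer(fh.read(), dtype=np.uint8)
    grid = VoxelGrid(origin=origin, edge=edge, dims=dims)
    occ = np.unpackbits(bits)[: grid.n_voxels].astype(bool).reshape(grid.dims)
    return occ, grid
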