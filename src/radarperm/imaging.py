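"""Delay-and-sum (DAS) image formation from calibrated radar traces.

The pipeline is: subtract the calibration (empty-scanner) scan, suppress
the dominant skin reflection with a neighbourhood filter, then beamform.
For a candidate permittivity pair the round-trip delay from each antenna
to each pixel is computed through the layered geometry, every trace is
sampled at that delay (linear interpolation) and the samples are summed;
coherent echoes interfere constructively at scatterer locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .phantom import C_MM_PER_S, Phantom, RadarScan, _segment_lengths

__all__ = [
    "GridSpec",
    "ImageGrid",
    "subtract_calibration",
    "suppress_skin",
    "DASReconstructor",
    "das_reconstruct",
    "slice_image",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular reconstruction grid: symmetric extent (mm) and pixel size."""

    extent: float = 50.0
    spacing: float = 1.0
    dim: int = 2

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.extent <= 0:
            raise ValueError("extent and spacing must be positive")
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")

    @property
    def shape(self) -> tuple[int, ...]:
        n = int(round(2 * self.extent / self.spacing))
        return (n,) * self.dim

    @property
    def origin(self) -> np.ndarray:
        return np.full(self.dim, -self.extent)


@dataclass
class ImageGrid:
    """Scattering-intensity image on a regular grid with a region mask.

    Pixel ``index`` has physical centre ``origin + (index + 0.5) * spacing``.
    ``mask`` marks the reconstruction region (inside the skin contour);
    pixels outside it are exactly zero.
    """

    intensities: np.ndarray
    origin: np.ndarray
    pixel_spacing: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.origin = np.atleast_1d(np.asarray(self.origin, dtype=float))
        self.pixel_spacing = np.atleast_1d(np.asarray(self.pixel_spacing, float))
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixel_spacing.size == 1:
            self.pixel_spacing = np.repeat(self.pixel_spacing, self.intensities.ndim)
        if np.any(self.pixel_spacing <= 0):
            raise ValueError("pixel_spacing must be positive")
        if self.mask.shape != self.intensities.shape:
            raise ValueError("mask shape must match intensities")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")

    @property
    def ndim(self) -> int:
        return self.intensities.ndim

    def pixel_centers(self, axis: int) -> np.ndarray:
        n = self.intensities.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.pixel_spacing[axis]

    def argmax_position(self) -> np.ndarray:
        """Physical centre (mm) of the pixel maximising |intensity|."""
        idx = np.unravel_index(np.argmax(np.abs(self.intensities)), self.intensities.shape)
        return self.origin + (np.asarray(idx) + 0.5) * self.pixel_spacing


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def subtract_calibration(scan: RadarScan) -> RadarScan:
    """Remove empty-scanner reflections by subtracting the calibration scan."""
    if scan.calibration_traces is None:
        raise ValueError("scan has no calibration_traces")
    if scan.calibration_traces.shape != scan.traces.shape:
        raise ValueError("calibration_traces shape does not match traces")
    return RadarScan(
        array=scan.array,
        time_axis=scan.time_axis.copy(),
        traces=scan.traces - scan.calibration_traces,
        calibration_traces=None,
    )


# ---------------------------------------------------------------------------
# Skin suppression
# ---------------------------------------------------------------------------

def _skin_window(trace: np.ndarray, smooth: int, threshold: float) -> tuple[int, int]:
    """Contiguous sample span of the primary skin reflection.

    The smoothed rectified envelope is thresholded at ``threshold`` times
    its maximum and the span containing the global maximum is returned as
    half-open indices (start, stop).
    """
    env = uniform_filter1d(np.abs(trace), size=max(smooth, 1))
    peak = int(np.argmax(env))
    level = threshold * env[peak]
    above = env > level
    start = peak
    while start > 0 and above[start - 1]:
        start -= 1
    stop = peak + 1
    while stop < env.size and above[stop]:
        stop += 1
    return start, stop


def suppress_skin(
    scan: RadarScan,
    k_neighbors: int = 4,
    similarity_window: float = 0.1,
    smooth_samples: int = 9,
    pad_samples: int = 25,
) -> RadarScan:
    """Suppress the dominant skin reflection in each trace.

    For every target trace: locate the primary skin-reflection window (the
    contiguous span where the smoothed envelope exceeds ``similarity_window``
    of its maximum, padded by ``pad_samples`` so the reflection's tails are
    covered), pick the ``k_neighbors`` traces most similar inside that
    window (RMS difference), and subtract the least-squares amplitude-scaled
    neighbour average from the target inside the window, cosine-tapered
    over the padded margins.  Samples outside the window — in particular
    later scatterer echoes — are untouched.
    """
    n_ant = scan.traces.shape[0]
    if n_ant < k_neighbors + 1:
        raise ValueError("need at least k_neighbors + 1 traces")
    out = scan.traces.copy()
    n_samp = scan.traces.shape[1]
    for i in range(n_ant):
        target = scan.traces[i]
        core_start, core_stop = _skin_window(target, smooth_samples, similarity_window)
        start = max(core_start - pad_samples, 0)
        stop = min(core_stop + pad_samples, n_samp)
        seg = target[start:stop]

        diffs = np.sqrt(np.mean((scan.traces[:, start:stop] - seg) ** 2, axis=1))
        diffs[i] = np.inf
        neighbors = np.argsort(diffs)[:k_neighbors]
        ref = scan.traces[neighbors, start:stop].mean(axis=0)

        denom = float(ref @ ref)
        scale = float(seg @ ref) / denom if denom > 0 else 0.0

        # Full subtraction across the detected reflection; cosine roll-off
        # confined to the padded margins where the echo is already small.
        taper = np.ones(stop - start)
        m_lo = core_start - start
        m_hi = stop - core_stop
        if m_lo > 0:
            taper[:m_lo] = 0.5 * (1 - np.cos(np.pi * (np.arange(m_lo) + 1) / (m_lo + 1)))
        if m_hi > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(m_hi) + 1) / (m_hi + 1)))
            taper[stop - start - m_hi :] = ramp[::-1]
        out[i, start:stop] = seg - taper * scale * ref
    return RadarScan(
        array=scan.array,
        time_axis=scan.time_axis.copy(),
        traces=out,
        calibration_traces=None
        if scan.calibration_traces is None
        else scan.calibration_traces.copy(),
    )


# ---------------------------------------------------------------------------
# Delay-and-sum reconstruction
# ---------------------------------------------------------------------------

class DASReconstructor:
    """Delay-and-sum beamformer with precomputed path geometry.

    The straight-ray segment lengths (outside / skin / interior) from each
    antenna to each masked pixel depend only on the geometry, so they are
    computed once; reconstructing at a new permittivity pair then costs one
    delay evaluation plus one trace interpolation per antenna.
    """

    def __init__(self, scan: RadarScan, grid_spec: GridSpec, geometry: Phantom):
        self.scan = scan
        self.grid_spec = grid_spec
        self.geometry = geometry

        shape = grid_spec.shape
        origin = grid_spec.origin
        axes = [
            origin[k] + (np.arange(shape[k]) + 0.5) * grid_spec.spacing
            for k in range(grid_spec.dim)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        coords = np.stack([m.ravel() for m in mesh], axis=1)
        r = np.linalg.norm(coords, axis=1)
        self.mask = (r < geometry.interior_radius).reshape(shape)
        self._pixels = coords[self.mask.ravel()]

        n_ant = len(scan.array)
        n_px = self._pixels.shape[0]
        self._l_out = np.empty((n_ant, n_px))
        self._l_skin = np.empty((n_ant, n_px))
        self._l_int = np.empty((n_ant, n_px))
        for i, a in enumerate(scan.array.positions):
            lo, ls, li = _segment_lengths(a, self._pixels, geometry)
            self._l_out[i] = lo
            self._l_skin[i] = ls
            self._l_int[i] = li

    def reconstruct(self, eps_i: float, eps_s: float) -> ImageGrid:
        if eps_i < 1 or eps_s < 1:
            raise ValueError("permittivities must be >= 1")
        delays = (
            2.0
            * (self._l_out + np.sqrt(eps_s) * self._l_skin + np.sqrt(eps_i) * self._l_int)
            / C_MM_PER_S
        )
        t = self.scan.time_axis
        acc = np.zeros(delays.shape[1])
        for i in range(delays.shape[0]):
            # Delays beyond the trace contribute 0.
            acc += np.interp(delays[i], t, self.scan.traces[i], left=0.0, right=0.0)
        img = np.zeros(self.grid_spec.shape)
        img[self.mask] = acc
        return ImageGrid(
            intensities=img,
            origin=self.grid_spec.origin,
            pixel_spacing=np.full(self.grid_spec.dim, self.grid_spec.spacing),
            mask=self.mask.copy(),
        )


def das_reconstruct(
    scan: RadarScan,
    grid_spec: GridSpec,
    eps_i: float,
    eps_s: float,
    phantom_geometry: Phantom,
) -> ImageGrid:
    """One-shot delay-and-sum reconstruction at a candidate permittivity pair."""
    return DASReconstructor(scan, grid_spec, phantom_geometry).reconstruct(eps_i, eps_s)


def slice_image(volume: ImageGrid, axis: int, coordinate: float) -> ImageGrid:
    """Extract the 2D plane of a 3D image nearest to ``coordinate`` (mm)."""
    if volume.ndim != 3:
        raise ValueError("slice_image requires a 3D ImageGrid")
    centers = volume.pixel_centers(axis)
    half = volume.pixel_spacing[axis] / 2
    if coordinate < centers[0] - half or coordinate > centers[-1] + half:
        raise ValueError("coordinate outside the volume")
    idx = int(np.argmin(np.abs(centers - coordinate)))
    keep = [k for k in range(3) if k != axis]
    sl = [slice(None)] * 3
    sl[axis] = idx
    return ImageGrid(
        intensities=volume.intensities[tuple(sl)],
        origin=volume.origin[keep],
        pixel_spacing=volume.pixel_spacing[keep],
        mask=volume.mask[tuple(sl)],
    )
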