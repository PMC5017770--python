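"""Synthetic monostatic radar scans of layered phantoms.

The phantom is a thin skin shell (default 2 mm) of relative permittivity
``eps_s`` enclosing a homogeneous interior of permittivity ``eps_i``, with
optional disc/sphere scatterers standing in for tumours or glands.  A
single antenna is stepped around the target and, at each position, records
the reflections of an ultra-wideband derivative-of-Gaussian pulse.  The
simulator produces per-position reflection traces plus a matching
calibration (empty-scanner) scan, which is all the downstream imaging and
estimation stages need.

Units: lengths in mm, times in s, permittivities dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.constants

__all__ = [
    "C_MM_PER_S",
    "Pulse",
    "Scatterer",
    "Phantom",
    "AntennaArray",
    "RadarScan",
    "make_pulse",
    "pulse_shape",
    "propagation_time",
    "simulate_scan",
    "circular_array",
]

#: Vacuum speed of light in mm/s (geometry is expressed in mm).
C_MM_PER_S = scipy.constants.c * 1e3

#: Pulse width giving a spectral peak near 4 GHz for a derivative-of-Gaussian
#: (peak frequency of the derivative of a Gaussian is 1/(2*pi*sigma)).
DEFAULT_SIGMA_S = 1.0 / (2.0 * np.pi * 4.0e9)

#: Amplitude of the skin reflection relative to a unit-reflectivity
#: scatterer at ~40 mm (whose echo is ~6e-4): the skin dominates raw traces.
SKIN_ECHO_AMPLITUDE = 0.05

#: Empty-scanner self-reflection, present in target and calibration traces
#: alike; calibration subtraction removes it exactly.
SCANNER_ECHO_AMPLITUDE = 0.2
SCANNER_ECHO_DELAY_S = 0.1e-9


@dataclass(frozen=True)
class Pulse:
    """Derivative-of-Gaussian excitation pulse.

    Parameters
    ----------
    sigma : float
        Width of the underlying Gaussian in seconds.
    sample_interval : float
        Trace time step in seconds.
    duration : float
        Total trace length in seconds; must allow the pulse to decay
        (``duration >= 20 * sigma``).
    """

    sigma: float = DEFAULT_SIGMA_S
    sample_interval: float = 5e-12
    duration: float = 5e-9

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("pulse sigma must be positive")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.duration < 20 * self.sigma:
            raise ValueError("duration must be at least 20*sigma")

    @property
    def time_axis(self) -> np.ndarray:
        n = int(round(self.duration / self.sample_interval)) + 1
        return np.arange(n) * self.sample_interval


@dataclass(frozen=True)
class Scatterer:
    """A disc (2D) or sphere (3D) inclusion inside the phantom interior."""

    center: tuple[float, ...]
    radius: float
    reflectivity: float = 1.0


@dataclass(frozen=True)
class Phantom:
    """Layered phantom: skin shell around a homogeneous interior.

    The phantom is centred at the origin.  ``outer_radius`` is the outer
    skin surface; the interior region ends at ``outer_radius -
    skin_thickness``.
    """

    outer_radius: float = 50.0
    skin_thickness: float = 2.0
    skin_permittivity: float = 25.0
    interior_permittivity: float = 2.5
    scatterers: tuple[Scatterer, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.skin_thickness <= 0:
            raise ValueError("skin_thickness must be positive")
        if self.skin_permittivity < 1 or self.interior_permittivity < 1:
            raise ValueError("permittivities must be >= 1")
        if self.outer_radius <= self.skin_thickness:
            raise ValueError("outer_radius must exceed skin_thickness")
        r_in = self.interior_radius
        for s in self.scatterers:
            if np.linalg.norm(s.center) >= r_in:
                raise ValueError(
                    f"scatterer at {s.center} is not strictly inside the interior"
                )

    @property
    def interior_radius(self) -> float:
        return self.outer_radius - self.skin_thickness

    def with_permittivities(self, eps_i: float, eps_s: float) -> "Phantom":
        """Same geometry with candidate permittivities (for reconstruction)."""
        return replace(
            self, interior_permittivity=eps_i, skin_permittivity=eps_s
        )


@dataclass(frozen=True)
class AntennaArray:
    """Monostatic antenna positions (mm), all outside the phantom."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "positions", pos)
        if pos.shape[0] < 3:
            raise ValueError("need at least 3 antenna positions")
        if len({tuple(p) for p in pos}) != pos.shape[0]:
            raise ValueError("antenna positions must be distinct")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def validate_outside(self, phantom: Phantom) -> None:
        r = np.linalg.norm(self.positions, axis=1)
        if np.any(r <= phantom.outer_radius):
            raise ValueError("all antenna positions must lie outside the phantom")


def circular_array(n_antennas: int, radius: float, dim: int = 2) -> AntennaArray:
    """Evenly spaced monostatic positions on a circle of given radius (mm).

    For ``dim == 3`` the circle lies in the z = 0 plane.
    """
    theta = 2 * np.pi * np.arange(n_antennas) / n_antennas
    xy = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    if dim == 3:
        xy = np.column_stack([xy, np.zeros(n_antennas)])
    return AntennaArray(xy)


@dataclass
class RadarScan:
    """Per-antenna-position reflection traces on a shared time axis."""

    array: AntennaArray
    time_axis: np.ndarray
    traces: np.ndarray
    calibration_traces: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.shape != (len(self.array), self.time_axis.size):
            raise ValueError("traces must be shaped (n_antennas, n_samples)")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces contain non-finite values")
        if self.calibration_traces is not None:
            self.calibration_traces = np.asarray(self.calibration_traces, float)
            if self.calibration_traces.shape != self.traces.shape:
                raise ValueError("calibration_traces shape must match traces")
            if not np.all(np.isfinite(self.calibration_traces)):
                raise ValueError("calibration_traces contain non-finite values")

    @property
    def sample_interval(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0])

    def copy(self) -> "RadarScan":
        return RadarScan(
            array=self.array,
            time_axis=self.time_axis.copy(),
            traces=self.traces.copy(),
            calibration_traces=None
            if self.calibration_traces is None
            else self.calibration_traces.copy(),
        )


# ---------------------------------------------------------------------------
# Pulse waveform
# ---------------------------------------------------------------------------

def make_pulse(
    sigma: float, sample_interval: float, duration: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled derivative-of-Gaussian waveform centred at ``duration / 2``.

    Returns ``(time_axis, waveform)`` with the waveform normalised to unit
    peak absolute amplitude.  The waveform has one positive and one negative
    lobe of (nearly) equal magnitude and integrates to ~0.
    """
    pulse = Pulse(sigma=sigma, sample_interval=sample_interval, duration=duration)
    t = pulse.time_axis
    t0 = duration / 2.0
    u = t - t0
    w = -u * np.exp(-(u**2) / (2.0 * sigma**2))
    return t, w / np.abs(w).max()


def pulse_shape(u: np.ndarray, sigma: float) -> np.ndarray:
    """Echo waveform as a function of time-since-arrival ``u`` (seconds).

    The derivative-of-Gaussian is shifted so its *positive peak* sits at
    u = 0: delay-and-sum sampling a trace at the exact round-trip delay then
    reads the echo maximum, making the forward model consistent with plain
    amplitude summation.  Normalised to unit peak.
    """
    v = u - sigma
    return -v * np.exp(-(v**2) / (2.0 * sigma**2)) / (sigma * np.exp(-0.5))


# ---------------------------------------------------------------------------
# Ray delays through the layered phantom
# ---------------------------------------------------------------------------

def _segment_lengths(
    antenna: np.ndarray, points: np.ndarray, phantom: Phantom
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Straight-ray path lengths (mm) outside / in skin / in interior.

    ``points`` is (n, dim); returns three (n,) arrays.  Refraction at the
    skin is ignored (single effective speed per layer along the ray).
    """
    a = np.asarray(antenna, dtype=float)
    p = np.atleast_2d(np.asarray(points, dtype=float))
    d = p - a
    total = np.linalg.norm(d, axis=1)

    def first_crossing(radius: float) -> np.ndarray:
        # Smallest s in (0, 1] with |a + s*d| = radius.
        aa = float(a @ a)
        ad = d @ a
        dd = np.einsum("ij,ij->i", d, d)
        disc = ad**2 - dd * (aa - radius**2)
        disc = np.maximum(disc, 0.0)
        return (-ad - np.sqrt(disc)) / dd

    s_outer = first_crossing(phantom.outer_radius)
    s_inner = first_crossing(phantom.interior_radius)
    l_out = s_outer * total
    l_skin = (s_inner - s_outer) * total
    l_int = (1.0 - s_inner) * total
    return l_out, l_skin, l_int


def propagation_time(
    antenna_position: np.ndarray, point: np.ndarray, phantom: Phantom
) -> float:
    """Round-trip time (s) antenna -> point -> antenna through the layers.

    The straight ray is partitioned into its vacuum, skin and interior
    segments, each traversed at c / sqrt(eps) for that layer.
    """
    a = np.asarray(antenna_position, dtype=float)
    p = np.asarray(point, dtype=float)
    if np.linalg.norm(p) >= phantom.interior_radius:
        raise ValueError("point must lie inside the phantom interior")
    if np.linalg.norm(a) <= phantom.outer_radius:
        raise ValueError("antenna must lie outside the phantom")
    l_out, l_skin, l_int = _segment_lengths(a, p[None, :], phantom)
    n_s = np.sqrt(phantom.skin_permittivity)
    n_i = np.sqrt(phantom.interior_permittivity)
    return float(2.0 * (l_out[0] + n_s * l_skin[0] + n_i * l_int[0]) / C_MM_PER_S)


# ---------------------------------------------------------------------------
# Scan synthesis
# ---------------------------------------------------------------------------

def simulate_scan(
    phantom: Phantom,
    array: AntennaArray,
    pulse: Pulse | None = None,
    seed: int = 0,
    noise_level: float = 0.0,
    skin_echo_amplitude: float = SKIN_ECHO_AMPLITUDE,
) -> RadarScan:
    """Synthesize a monostatic scan of the phantom plus its calibration scan.

    Each target trace is a superposition of

    * one echo per scatterer, delayed by :func:`propagation_time` to its
      centre and attenuated by ``reflectivity / L**2`` (one-way distance L
      in mm),
    * a strong common skin echo at the antenna-to-skin round-trip delay,
    * a fixed empty-scanner self-reflection (also in the calibration), and
    * additive white Gaussian noise with RMS ``noise_level`` times the RMS
      of the noiseless trace ensemble.

    Calibration traces contain only the scanner echo (plus independent
    noise).  Fully deterministic for a fixed ``seed``.
    """
    if pulse is None:
        pulse = Pulse()
    if len(array) == 0:
        raise ValueError("array must contain at least one antenna")
    array.validate_outside(phantom)

    t = pulse.time_axis
    n_ant = len(array)
    traces = np.zeros((n_ant, t.size))
    cal = np.zeros_like(traces)

    # Empty-scanner echo, identical in both scans.
    scanner = SCANNER_ECHO_AMPLITUDE * pulse_shape(t - SCANNER_ECHO_DELAY_S, pulse.sigma)
    traces += scanner
    cal += scanner

    for i, a in enumerate(array.positions):
        # Skin reflection at the antenna-to-skin round trip.
        standoff = np.linalg.norm(a) - phantom.outer_radius
        tau_skin = 2.0 * standoff / C_MM_PER_S
        traces[i] += skin_echo_amplitude * pulse_shape(t - tau_skin, pulse.sigma)

        for s in phantom.scatterers:
            tau = propagation_time(a, np.asarray(s.center, float), phantom)
            dist = np.linalg.norm(a - np.asarray(s.center, float))
            amp = s.reflectivity / dist**2
            traces[i] += amp * pulse_shape(t - tau, pulse.sigma)

    if noise_level > 0:
        rng = np.random.default_rng(seed)
        rms = np.sqrt(np.mean(traces**2))
        traces = traces + rng.normal(0.0, noise_level * rms, traces.shape)
        cal = cal + rng.normal(0.0, noise_level * rms, cal.shape)

    return RadarScan(array=array, time_axis=t.copy(), traces=traces,
                     calibration_traces=cal)
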