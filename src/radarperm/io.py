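"""Scan containers, run configuration and the synthetic fixture generator.

Scans travel as HDF5 (datasets ``/time_axis``, ``/antenna_positions``,
``/traces``, ``/calibration_traces``; units recorded as attributes and
validated on read — silent unit guessing is forbidden) with a plain-CSV
fallback for quick inspection.  Fixtures emulate the simplified layered
cylinder phantom at 2D slice scale: canola-oil interior (eps_i = 2.5)
behind a 2 mm skin (eps_s = 25), with 10 mm scatterers at known positions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .estimator import EstimatorConfig, PermittivityBox
from .imaging import GridSpec
from .phantom import (
    AntennaArray,
    Phantom,
    Pulse,
    RadarScan,
    Scatterer,
    circular_array,
    simulate_scan,
)

__all__ = [
    "read_scan",
    "write_scan",
    "RunConfig",
    "FIXTURE_NAMES",
    "fixture_phantom",
    "make_fixture_scan",
    "generate_fixture",
]

TIME_UNITS = "s"
LENGTH_UNITS = "mm"


class ScanFormatError(ValueError):
    """A scan file is missing a field or carries the wrong units."""


# ---------------------------------------------------------------------------
# Scan containers
# ---------------------------------------------------------------------------

def write_scan(scan: RadarScan, path: str | Path) -> None:
    """Write a scan to HDF5 (`.h5`/`.hdf5`) or CSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _write_scan_h5(scan, path)
    else:
        _write_scan_csv(scan, path)


def read_scan(path: str | Path) -> RadarScan:
    """Read a scan written by :func:`write_scan`; lossless for HDF5."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_scan_h5(path)
    return _read_scan_csv(path)


def _write_scan_h5(scan: RadarScan, path: Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("time_axis", data=scan.time_axis)
        d.attrs["units"] = TIME_UNITS
        d = f.create_dataset("antenna_positions", data=scan.array.positions)
        d.attrs["units"] = LENGTH_UNITS
        f.create_dataset("traces", data=scan.traces)
        if scan.calibration_traces is not None:
            f.create_dataset("calibration_traces", data=scan.calibration_traces)


def _read_scan_h5(path: Path) -> RadarScan:
    with h5py.File(path, "r") as f:
        for name in ("time_axis", "antenna_positions", "traces"):
            if name not in f:
                raise ScanFormatError(f"scan file missing dataset /{name}")
        t_units = f["time_axis"].attrs.get("units")
        if t_units != TIME_UNITS:
            raise ScanFormatError(
                f"time_axis units {t_units!r}, expected {TIME_UNITS!r}"
            )
        p_units = f["antenna_positions"].attrs.get("units")
        if p_units != LENGTH_UNITS:
            raise ScanFormatError(
                f"antenna_positions units {p_units!r}, expected {LENGTH_UNITS!r}"
            )
        time_axis = f["time_axis"][()]
        positions = f["antenna_positions"][()]
        traces = f["traces"][()]
        cal = f["calibration_traces"][()] if "calibration_traces" in f else None
    if not np.all(np.isfinite(traces)):
        raise ScanFormatError("traces contain non-finite values")
    return RadarScan(
        array=AntennaArray(positions),
        time_axis=time_axis,
        traces=traces,
        calibration_traces=cal,
    )


def _write_scan_csv(scan: RadarScan, path: Path) -> None:
    n_ant = len(scan.array)
    cols = [scan.time_axis] + [scan.traces[i] for i in range(n_ant)]
    header = ["time_s"] + [f"trace_{i}" for i in range(n_ant)]
    if scan.calibration_traces is not None:
        cols += [scan.calibration_traces[i] for i in range(n_ant)]
        header += [f"calibration_{i}" for i in range(n_ant)]
    meta = json.dumps({"antenna_positions_mm": scan.array.positions.tolist()})
    with open(path, "w") as fh:
        fh.write(f"# {meta}\n")
        fh.write(",".join(header) + "\n")
        np.savetxt(fh, np.column_stack(cols), delimiter=",", fmt="%.10e")


def _read_scan_csv(path: Path) -> RadarScan:
    with open(path) as fh:
        meta_line = fh.readline()
        if not meta_line.startswith("# "):
            raise ScanFormatError("CSV scan missing antenna-position metadata line")
        meta = json.loads(meta_line[2:])
        header = fh.readline().strip().split(",")
        data = np.loadtxt(fh, delimiter=",")
    if "antenna_positions_mm" not in meta:
        raise ScanFormatError("CSV scan metadata missing antenna_positions_mm")
    positions = np.asarray(meta["antenna_positions_mm"], dtype=float)
    n_ant = positions.shape[0]
    trace_cols = [i for i, h in enumerate(header) if h.startswith("trace_")]
    cal_cols = [i for i, h in enumerate(header) if h.startswith("calibration_")]
    if len(trace_cols) != n_ant:
        raise ScanFormatError("CSV trace column count does not match antennas")
    return RadarScan(
        array=AntennaArray(positions),
        time_axis=data[:, 0],
        traces=data[:, trace_cols].T,
        calibration_traces=data[:, cal_cols].T if cal_cols else None,
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end run description, loadable from a YAML file."""

    phantom: Phantom = field(default_factory=Phantom)
    pulse: Pulse = field(default_factory=Pulse)
    n_antennas: int = 20
    antenna_radius: float = 52.0
    noise_level: float = 0.01
    grid_spec: GridSpec = field(default_factory=GridSpec)
    box: PermittivityBox = field(default_factory=PermittivityBox)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "phantom" in raw:
            ph = dict(raw["phantom"])
            scatterers = tuple(
                Scatterer(tuple(s["center"]), s["radius"], s.get("reflectivity", 1.0))
                for s in ph.pop("scatterers", [])
            )
            kwargs["phantom"] = Phantom(scatterers=scatterers, **ph)
        if "pulse" in raw:
            kwargs["pulse"] = Pulse(**raw["pulse"])
        if "grid_spec" in raw:
            kwargs["grid_spec"] = GridSpec(**raw["grid_spec"])
        if "box" in raw:
            b = raw["box"]
            kwargs["box"] = PermittivityBox(
                eps_i_range=tuple(b["eps_i_range"]),
                eps_s_range=tuple(b["eps_s_range"]),
            )
        if "estimator" in raw:
            kwargs["estimator"] = EstimatorConfig(**raw["estimator"])
        for key in ("n_antennas", "antenna_radius", "noise_level"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "phantom": {
                "outer_radius": self.phantom.outer_radius,
                "skin_thickness": self.phantom.skin_thickness,
                "skin_permittivity": self.phantom.skin_permittivity,
                "interior_permittivity": self.phantom.interior_permittivity,
                "scatterers": [
                    {
                        "center": list(s.center),
                        "radius": s.radius,
                        "reflectivity": s.reflectivity,
                    }
                    for s in self.phantom.scatterers
                ],
            },
            "pulse": asdict(self.pulse),
            "n_antennas": self.n_antennas,
            "antenna_radius": self.antenna_radius,
            "noise_level": self.noise_level,
            "grid_spec": asdict(self.grid_spec),
            "box": {
                "eps_i_range": list(self.box.eps_i_range),
                "eps_s_range": list(self.box.eps_s_range),
            },
            "estimator": asdict(self.estimator),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Fixtures: the simplified layered-cylinder phantom at 2D slice scale
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("single_scatterer", "two_scatterers", "scatterer_plus_gland")

#: Interior is canola oil (eps ~ 2.5); skin shell 2 mm at eps 25.
FIXTURE_EPS_I = 2.5
FIXTURE_EPS_S = 25.0
FIXTURE_OUTER_RADIUS = 50.0
FIXTURE_N_ANTENNAS = 20
FIXTURE_ANTENNA_RADIUS = 52.0
FIXTURE_NOISE_LEVEL = 0.01


def fixture_phantom(name: str) -> Phantom:
    """The phantom behind a named fixture (10 mm scatterers, 40 mm gland)."""
    if name == "single_scatterer":
        scatterers = (Scatterer((25.0, 0.0), 5.0),)
    elif name == "two_scatterers":
        scatterers = (Scatterer((25.0, 15.0), 5.0), Scatterer((5.0, 15.0), 5.0))
    elif name == "scatterer_plus_gland":
        scatterers = (
            Scatterer((17.68, 17.68), 5.0),
            Scatterer((0.0, 0.0), 20.0, reflectivity=0.8),
        )
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return Phantom(
        outer_radius=FIXTURE_OUTER_RADIUS,
        skin_thickness=2.0,
        skin_permittivity=FIXTURE_EPS_S,
        interior_permittivity=FIXTURE_EPS_I,
        scatterers=scatterers,
    )


def make_fixture_scan(name: str, seed: int = 0) -> tuple[RadarScan, dict]:
    """In-memory fixture scan plus its ground-truth parameters."""
    phantom = fixture_phantom(name)
    array = circular_array(FIXTURE_N_ANTENNAS, FIXTURE_ANTENNA_RADIUS)
    scan = simulate_scan(
        phantom, array, Pulse(), seed=seed, noise_level=FIXTURE_NOISE_LEVEL
    )
    truth = {
        "name": name,
        "seed": seed,
        "interior_permittivity": phantom.interior_permittivity,
        "skin_permittivity": phantom.skin_permittivity,
        "outer_radius_mm": phantom.outer_radius,
        "skin_thickness_mm": phantom.skin_thickness,
        "noise_level": FIXTURE_NOISE_LEVEL,
        "scatterers": [
            {
                "center_mm": list(s.center),
                "radius_mm": s.radius,
                "reflectivity": s.reflectivity,
            }
            for s in phantom.scatterers
        ],
    }
    return scan, truth


def generate_fixture(
    name: str, seed: int = 0, out_dir: str | Path = "."
) -> tuple[Path, Path]:
    """Write a fixture scan (HDF5) and its truth file (YAML) to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scan, truth = make_fixture_scan(name, seed)
    scan_path = out_dir / f"{name}_seed{seed}.h5"
    truth_path = out_dir / f"{name}_seed{seed}_truth.yaml"
    write_scan(scan, scan_path)
    with open(truth_path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    return scan_path, truth_path
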