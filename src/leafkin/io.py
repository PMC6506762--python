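"""Readers and writers for experiment bundles.

The canonical on-disk format is a single wide-form CSV holding the
synchronized time base, the object temperature channels and the
environmental drivers:

    time_s, T_leaf_C, T_black_C, T_white_C,
    PPFD_umol_m2_s, T_air_C, RH_percent, P_atm_Pa

Header unit tags are authoritative: ``*_C`` columns are converted to
kelvin and ``RH_percent`` to a fraction on ingestion (``RH_frac`` is
accepted for data already in fractions). Extra ``T_<name>_C`` columns
(replica channels etc.) are picked up as additional objects. Raw
multi-frame TIFF stacks are reduced to per-frame ROI means with a
timestamp sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .signals import EnvironmentTrace, Trace, average_duplicate_times

log = logging.getLogger(__name__)

__all__ = ["ExperimentBundle", "read_bundle", "write_bundle", "extract_roi_means"]

_ENV_COLS = {
    "PPFD_umol_m2_s": "ppfd",
    "T_air_C": "t_air",
    "RH_percent": "rh",
    "RH_frac": "rh",
    "P_atm_Pa": "p_atm",
}


@dataclass
class ExperimentBundle:
    """Environment plus named object temperature traces (SI units).

    All traces share the common time origin of the file (first sample
    at t = 0 unless the file says otherwise); temperatures in kelvin,
    RH as a fraction.
    """

    env: EnvironmentTrace
    objects: dict[str, Trace]
    metadata: dict[str, Any] = field(default_factory=dict)

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.objects]
        if missing:
            raise KeyError(f"bundle is missing object trace(s): {missing}")


def read_bundle(path: str | Path) -> ExperimentBundle:
    """Read a wide-form CSV bundle, validating units and monotonicity."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ("time_s", "PPFD_umol_m2_s", "T_air_C", "P_atm_Pa"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column '{col}'")
    if "RH_percent" not in df.columns and "RH_frac" not in df.columns:
        raise ValueError(f"{path.name}: missing required column 'RH_percent' (or 'RH_frac')")
    if df.isna().any().any():
        raise ValueError(f"{path.name}: missing values are not allowed")

    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path.name}: 'time_s' must be strictly increasing")

    if "RH_frac" in df.columns:
        rh = df["RH_frac"].to_numpy(dtype=float)
        if np.any(rh > 1.5):
            raise ValueError(
                f"{path.name}: RH_frac contains values > 1.5; the column is "
                f"declared a fraction but looks like percent"
            )
    else:
        rh = df["RH_percent"].to_numpy(dtype=float) / 100.0

    env = EnvironmentTrace(
        t=t,
        ppfd=df["PPFD_umol_m2_s"].to_numpy(dtype=float),
        t_air=df["T_air_C"].to_numpy(dtype=float) + 273.15,
        rh=rh,
        p_atm=df["P_atm_Pa"].to_numpy(dtype=float),
    )
    objects = {}
    for col in df.columns:
        if col.startswith("T_") and col.endswith("_C") and col != "T_air_C":
            name = col[2:-2]
            objects[name] = Trace(t, df[col].to_numpy(dtype=float) + 273.15,
                                  channel=f"T_{name}")
    log.info("read %s: %d samples, objects %s", path.name, t.size, sorted(objects))
    return ExperimentBundle(env=env, objects=objects,
                            metadata={"source": str(path), "n_samples": int(t.size)})


def write_bundle(bundle: ExperimentBundle, path: str | Path,
                 metadata_path: str | Path | None = None) -> None:
    """Write a bundle back to the wide-form CSV schema (°C, percent)."""
    path = Path(path)
    env = bundle.env
    data = {"time_s": env.t,
            **{f"T_{name}_C": tr.y - 273.15 for name, tr in bundle.objects.items()},
            "PPFD_umol_m2_s": env.ppfd,
            "T_air_C": env.t_air - 273.15,
            "RH_percent": env.rh * 100.0,
            "P_atm_Pa": env.p_atm}
    for name, tr in bundle.objects.items():
        if tr.t.shape != env.t.shape or np.any(np.abs(tr.t - env.t) > 1e-9):
            raise ValueError(f"object '{name}' is not on the bundle's time base")
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")
    if metadata_path is not None:
        Path(metadata_path).write_text(json.dumps(bundle.metadata, indent=2,
                                                  default=str))


def bundle_from_simulation(sim) -> ExperimentBundle:
    """Wrap a :class:`leafkin.synthetic.SimulatedExperiment` for I/O."""
    return ExperimentBundle(env=sim.env, objects=dict(sim.traces),
                            metadata={"seed": sim.truth.get("seed"),
                                      "synthetic": True})


def extract_roi_means(stack: str | Path | np.ndarray,
                      roi: tuple[int, int, int, int] | np.ndarray,
                      timestamps: np.ndarray,
                      celsius: bool = False) -> Trace:
    """Reduce a multi-frame thermal TIFF stack to a per-frame ROI mean.

    ``roi`` is either a rectangle ``(row0, row1, col0, col1)`` (half-open)
    or a boolean mask of the frame shape. Pixel values are taken as
    temperatures, kelvin by default (``celsius=True`` converts).
    """
    if isinstance(stack, (str, Path)):
        import tifffile

        frames = tifffile.imread(str(stack))
    else:
        frames = np.asarray(stack)
    if frames.ndim == 2:
        frames = frames[None]
    timestamps = np.asarray(timestamps, dtype=float)
    if frames.shape[0] != timestamps.size:
        raise ValueError(
            f"frame count ({frames.shape[0]}) != timestamp count ({timestamps.size})"
        )
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != frames.shape[1:]:
            raise ValueError("mask shape does not match frame shape")
        if not roi.any():
            raise ValueError("ROI mask selects no pixels")
        vals = frames[:, roi].mean(axis=1)
    else:
        r0, r1, c0, c1 = (int(v) for v in roi)
        if not (0 <= r0 < r1 <= frames.shape[1] and 0 <= c0 < c1 <= frames.shape[2]):
            raise ValueError("ROI rectangle out of frame bounds or empty")
        vals = frames[:, r0:r1, c0:c1].reshape(frames.shape[0], -1).mean(axis=1)
    t, y = average_duplicate_times(timestamps, vals)
    if celsius:
        y = y + 273.15
    return Trace(t, y, channel="T_roi")
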