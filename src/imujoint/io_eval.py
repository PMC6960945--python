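"""File I/O, configuration and evaluation metrics.

On-disk formats (all plain CSV with a header row, '.' decimal, SI units):

* IMU series: ``t,gx,gy,gz,ax,ay,az`` (s, rad/s, m/s^2)
* orientation truth: ``t`` followed by row-major DCM entries per link,
  ``{link}_r{row}{col}`` for links ``i`` and ``j``
* joint angles: ``t,alpha_deg,beta_deg,gamma_deg,flag`` (flag bit 1 =
  constraint update skipped, bit 2 = gimbal lock)

Angles are stored and reported in degrees; everything else stays SI.
Evaluation is RMSE of the joint Euler angles on wrapped (shortest-arc)
differences.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .attitude import GmParams
from .pipeline import JointAngleSeries, PipelineConfig
from .simulate import ImuSeries, SimConfig, TwoLinkTruth

__all__ = [
    "MalformedFileError",
    "MisalignedSeriesError",
    "RmseReport",
    "rmse_euler",
    "wrap_angle",
    "read_imu_csv",
    "write_imu_csv",
    "read_truth_csv",
    "write_truth_csv",
    "read_angles_csv",
    "write_angles_csv",
    "write_report",
    "load_config",
]

IMU_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az"]
ANGLE_COLUMNS = ["t", "alpha_deg", "beta_deg", "gamma_deg", "flag"]


class MalformedFileError(ValueError):
    """Raised for files that do not match the package's CSV interfaces."""


class MisalignedSeriesError(ValueError):
    """Raised when two series do not share a time base."""


# ---------------------------------------------------------------------------
# metrics

def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles (rad) to (-pi, pi]."""
    return -((np.pi - np.asarray(a)) % (2.0 * np.pi) - np.pi)


@dataclass
class RmseReport:
    """Per-angle joint RMSE (degrees) with optional per-link yaw diagnostics."""

    roll: float
    pitch: float
    yaw: float
    average: float
    yaw_link_i: float | None = None
    yaw_link_j: float | None = None

    def as_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        return {k: (None if v is None else float(v)) for k, v in out.items()}


def _rmse_wrapped(est: np.ndarray, truth: np.ndarray) -> float:
    d = wrap_angle(np.asarray(est) - np.asarray(truth))
    return float(np.sqrt(np.mean(d**2)))


def rmse_euler(
    est: JointAngleSeries,
    truth_euler: np.ndarray,
    truth_t: np.ndarray | None = None,
    truth_yaw_i: np.ndarray | None = None,
    truth_yaw_j: np.ndarray | None = None,
) -> RmseReport:
    """Joint-angle RMSE (deg) of an estimate against truth Euler angles (rad).

    ``truth_euler`` is (n, 3) with columns [alpha, beta, gamma].  Differences
    are wrapped to the shortest arc before squaring; the average is the
    arithmetic mean of the three per-angle RMSEs.
    """
    if truth_t is not None:
        if len(truth_t) != len(est.t) or np.max(np.abs(truth_t - est.t)) > 1e-6:
            raise MisalignedSeriesError("estimate and truth time bases differ")
    if len(truth_euler) != len(est.t):
        raise MisalignedSeriesError("estimate and truth lengths differ")
    yaw = np.rad2deg(_rmse_wrapped(est.alpha, truth_euler[:, 0]))
    pitch = np.rad2deg(_rmse_wrapped(est.beta, truth_euler[:, 1]))
    roll = np.rad2deg(_rmse_wrapped(est.gamma, truth_euler[:, 2]))
    rep = RmseReport(
        roll=roll, pitch=pitch, yaw=yaw, average=(roll + pitch + yaw) / 3.0
    )
    if truth_yaw_i is not None:
        rep.yaw_link_i = np.rad2deg(_rmse_wrapped(est.yaw_i, truth_yaw_i))
    if truth_yaw_j is not None:
        rep.yaw_link_j = np.rad2deg(_rmse_wrapped(est.yaw_j, truth_yaw_j))
    return rep


# ---------------------------------------------------------------------------
# CSV readers/writers

def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    try:
        # round_trip parsing keeps write->read lossless at double precision
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise MalformedFileError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MalformedFileError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise MalformedFileError(f"{path}: no data rows")
    coerced = df[columns].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        # +2: header line and 1-based numbering
        raise MalformedFileError(
            f"{path}: malformed value at line {int(np.argmax(bad.values)) + 2}"
        )
    df[columns] = coerced
    return df


def _check_uniform(t: np.ndarray, path) -> None:
    if len(t) >= 2:
        steps = np.diff(t)
        if np.max(np.abs(steps - steps[0])) > 1e-6:
            raise MalformedFileError(f"{path}: non-uniform sampling in 't'")


def read_imu_csv(path) -> ImuSeries:
    """Read an IMU series; warns when accelerometer units look non-SI."""
    df = _read_csv(path, IMU_COLUMNS)
    t = df["t"].to_numpy(float)
    _check_uniform(t, path)
    acc = df[["ax", "ay", "az"]].to_numpy(float)
    med = float(np.median(np.linalg.norm(acc, axis=1)))
    if not 5.0 <= med <= 15.0:
        warnings.warn(
            f"{path}: median ||y_A|| = {med:.3g} m/s^2 outside [5, 15]; "
            "check units (expected m/s^2 including gravity)",
            stacklevel=2,
        )
    return ImuSeries(t=t, gyro=df[["gx", "gy", "gz"]].to_numpy(float), acc=acc)


def write_imu_csv(path, series: ImuSeries) -> None:
    df = pd.DataFrame(
        np.column_stack([series.t, series.gyro, series.acc]), columns=IMU_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_truth_csv(path, truth: TwoLinkTruth) -> None:
    """Write two-link orientation truth as flattened row-major DCM entries."""
    cols = {"t": truth.t}
    for name, link in (("i", truth.link_i), ("j", truth.link_j)):
        flat = link.R.reshape(len(truth.t), 9)
        for r in range(3):
            for c in range(3):
                cols[f"{name}_r{r}{c}"] = flat[:, 3 * r + c]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_truth_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read orientation truth -> (t, R_i (n,3,3), R_j (n,3,3))."""
    names = [f"{s}_r{r}{c}" for s in "ij" for r in range(3) for c in range(3)]
    df = _read_csv(path, ["t"] + names)
    t = df["t"].to_numpy(float)
    _check_uniform(t, path)
    R_i = df[names[:9]].to_numpy(float).reshape(-1, 3, 3)
    R_j = df[names[9:]].to_numpy(float).reshape(-1, 3, 3)
    return t, R_i, R_j


def write_angles_csv(path, series: JointAngleSeries) -> None:
    flag = series.skipped.astype(int) | (series.gimbal.astype(int) << 1)
    df = pd.DataFrame(
        {
            "t": series.t,
            "alpha_deg": np.rad2deg(series.alpha),
            "beta_deg": np.rad2deg(series.beta),
            "gamma_deg": np.rad2deg(series.gamma),
            "flag": flag,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_angles_csv(path) -> JointAngleSeries:
    df = _read_csv(path, ANGLE_COLUMNS)
    t = df["t"].to_numpy(float)
    _check_uniform(t, path)
    flag = df["flag"].to_numpy(int)
    n = len(t)
    return JointAngleSeries(
        t=t,
        alpha=np.deg2rad(df["alpha_deg"].to_numpy(float)),
        beta=np.deg2rad(df["beta_deg"].to_numpy(float)),
        gamma=np.deg2rad(df["gamma_deg"].to_numpy(float)),
        yaw_i=np.full(n, np.nan),
        yaw_j=np.full(n, np.nan),
        skipped=(flag & 1).astype(bool),
        gimbal=(flag & 2).astype(bool),
    )


def write_report(path, report: dict | RmseReport) -> None:
    if isinstance(report, RmseReport):
        report = report.as_dict()
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


# ---------------------------------------------------------------------------
# configuration

def _build(cls, section: dict, **extra):
    known = {f.name for f in fields(cls)}
    bad = set(section) - known
    if bad:
        raise MalformedFileError(f"unknown {cls.__name__} keys: {sorted(bad)}")
    kw = {k: (tuple(v) if isinstance(v, list) else v) for k, v in section.items()}
    return cls(**{**kw, **extra})


def load_config(path) -> dict:
    """Load the YAML configuration file.

    Sections ``sim``, ``filter``, ``calibration`` and ``eval`` are all
    optional; missing values fall back to the package defaults (the
    validation-trial conditions).  Returns a dict with a ``SimConfig`` under
    ``"sim"``, a ``PipelineConfig`` under ``"filter"`` and plain dicts for
    the rest.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise MalformedFileError(f"{path}: top level must be a mapping")
    filt = dict(raw.get("filter", {}))
    gm = GmParams(**filt.pop("gm")) if "gm" in filt else GmParams()
    return {
        "sim": _build(SimConfig, raw.get("sim", {})),
        "filter": _build(PipelineConfig, filt, gm=gm),
        "calibration": dict(raw.get("calibration", {})),
        "eval": dict(raw.get("eval", {})),
    }
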