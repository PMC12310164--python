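"""Time-indexed keypoint trajectories for one walking trial.

The central in-memory container is :class:`KeypointTrajectorySet`: a uniform
time grid at the camera frame rate, one (x, y) position and one confidence
per BODY_25 keypoint per frame, and a boolean missing mask. Positions are in
image pixels (origin top-left, y down) until converted to meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import body25
from .errors import GaitPoseError


@dataclass
class KeypointTrajectorySet:
    """Positions, confidences and missingness for the 25 BODY_25 keypoints.

    Attributes
    ----------
    times : (n_frames,) float array, seconds, uniform grid at ``frame_rate``.
    positions : (n_frames, 25, 2) float array of (x, y).
    confidence : (n_frames, 25) float array in [0, 1].
    missing : (n_frames, 25) bool array; True where the keypoint is absent
        (pose-estimator sentinel or confidence below threshold).
    frame_rate : sampling rate in Hz.
    units : 'px' or 'm'.
    meta : free-form trial metadata (participant, condition, hemiparetic
        side, provenance of processing steps, ...).
    interpolated : (n_frames, 25) bool array flagging gap-filled cells.
    """

    times: np.ndarray
    positions: np.ndarray
    confidence: np.ndarray
    missing: np.ndarray
    frame_rate: float
    units: str = "px"
    meta: dict[str, Any] = field(default_factory=dict)
    interpolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n = self.times.shape[0]
        if self.positions.shape != (n, body25.N_KEYPOINTS, 2):
            raise GaitPoseError(
                f"positions shape {self.positions.shape} != ({n}, 25, 2)"
            )
        if self.confidence.shape != (n, body25.N_KEYPOINTS):
            raise GaitPoseError("confidence shape mismatch")
        if self.missing.shape != (n, body25.N_KEYPOINTS):
            raise GaitPoseError("missing mask shape mismatch")
        if n >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or np.ptp(dt) > 1e-9:
                raise GaitPoseError("times must be strictly increasing and uniform")
        if self.interpolated is None:
            self.interpolated = np.zeros_like(self.missing)

    # -- convenience accessors -------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    def x(self, keypoint: int | str) -> np.ndarray:
        """Forward (horizontal image) coordinate of one keypoint, NaN where
        missing."""
        k = body25.INDEX[keypoint] if isinstance(keypoint, str) else keypoint
        out = self.positions[:, k, 0].copy()
        out[self.missing[:, k]] = np.nan
        return out

    def y(self, keypoint: int | str) -> np.ndarray:
        k = body25.INDEX[keypoint] if isinstance(keypoint, str) else keypoint
        out = self.positions[:, k, 1].copy()
        out[self.missing[:, k]] = np.nan
        return out

    def xy(self, keypoint: int | str) -> np.ndarray:
        k = body25.INDEX[keypoint] if isinstance(keypoint, str) else keypoint
        out = self.positions[:, k, :].copy()
        out[self.missing[:, k]] = np.nan
        return out

    def copy(self) -> "KeypointTrajectorySet":
        return KeypointTrajectorySet(
            times=self.times.copy(),
            positions=self.positions.copy(),
            confidence=self.confidence.copy(),
            missing=self.missing.copy(),
            frame_rate=self.frame_rate,
            units=self.units,
            meta=dict(self.meta),
            interpolated=None if self.interpolated is None else self.interpolated.copy(),
        )

    def add_provenance(self, step: str) -> None:
        self.meta.setdefault("provenance", [])
        self.meta["provenance"] = list(self.meta["provenance"]) + [step]

    # -- tidy CSV serialization ------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: frame, time_s, keypoint, x, y, confidence, missing."""
        n, k = self.n_frames, body25.N_KEYPOINTS
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n), k),
                "time_s": np.repeat(self.times, k),
                "keypoint": np.tile(np.array(body25.KEYPOINT_NAMES), n),
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
                "confidence": self.confidence.ravel(),
                "missing": self.missing.ravel(),
                "interpolated": self.interpolated.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.insert(0, "units", self.units)
        df.to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, frame_rate: float, units: str = "px", meta=None
    ) -> "KeypointTrajectorySet":
        frames = np.sort(df["frame"].unique())
        n = len(frames)
        kidx = df["keypoint"].map(body25.INDEX).to_numpy()
        fidx = df["frame"].to_numpy()
        positions = np.zeros((n, body25.N_KEYPOINTS, 2))
        confidence = np.zeros((n, body25.N_KEYPOINTS))
        missing = np.ones((n, body25.N_KEYPOINTS), dtype=bool)
        interp = np.zeros((n, body25.N_KEYPOINTS), dtype=bool)
        positions[fidx, kidx, 0] = df["x"].to_numpy()
        positions[fidx, kidx, 1] = df["y"].to_numpy()
        confidence[fidx, kidx] = df["confidence"].to_numpy()
        missing[fidx, kidx] = df["missing"].to_numpy().astype(bool)
        if "interpolated" in df:
            interp[fidx, kidx] = df["interpolated"].to_numpy().astype(bool)
        times = np.sort(df["time_s"].unique())
        return cls(
            times=times,
            positions=positions,
            confidence=confidence,
            missing=missing,
            frame_rate=frame_rate,
            units=units,
            meta=meta or {},
            interpolated=interp,
        )

    @classmethod
    def from_csv(cls, path, frame_rate: float, meta=None) -> "KeypointTrajectorySet":
        df = pd.read_csv(path)
        units = str(df["units"].iloc[0]) if "units" in df else "px"
        return cls.from_frame(df, frame_rate=frame_rate, units=units, meta=meta)
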