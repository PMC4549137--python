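"""Per-subject ROI time series and rigid-body motion traces, with TSV I/O.

A :class:`RoiTimeSeries` is a T x R matrix (T volumes, R regions) sampled
at repetition time ``tr`` seconds; ``kept_frames`` records which volumes
survive motion censoring.  A :class:`MotionTrace` holds the six rigid-body
realignment parameters per volume (translations in mm, rotations in rad).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MOTION_COLUMNS = ("trans_x_mm", "trans_y_mm", "trans_z_mm",
                  "rot_x_rad", "rot_y_rad", "rot_z_rad")


@dataclass
class RoiTimeSeries:
    data: np.ndarray          # T x R
    tr: float                 # seconds
    region_names: list[str]
    kept_frames: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (volumes x regions)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time-series data contains non-finite values")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 volumes")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if len(self.region_names) != self.data.shape[1]:
            raise ValueError("region_names length does not match column count")
        if self.kept_frames is None:
            self.kept_frames = np.arange(self.data.shape[0])
        else:
            self.kept_frames = np.asarray(self.kept_frames, dtype=int)
            kf = self.kept_frames
            if kf.size and (np.any(np.diff(kf) <= 0) or kf[0] < 0
                            or kf[-1] >= self.data.shape[0]):
                raise ValueError("kept_frames must be a strictly increasing "
                                 "subset of 0..T-1")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def kept_data(self) -> np.ndarray:
        """Rows of ``data`` at the retained frames."""
        return self.data[self.kept_frames]

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        return RoiTimeSeries(data, self.tr, list(self.region_names),
                             self.kept_frames.copy())

    def select_regions(self, positions: Sequence[int]) -> "RoiTimeSeries":
        positions = list(positions)
        return RoiTimeSeries(self.data[:, positions], self.tr,
                             [self.region_names[i] for i in positions],
                             self.kept_frames.copy())

    # --- I/O: TSV matrix with region-name header + sidecar JSON with tr ---

    def to_tsv(self, path) -> None:
        path = Path(path)
        pd.DataFrame(self.data, columns=self.region_names).to_csv(
            path, sep="\t", index=False, float_format="%.10g")
        sidecar = {"tr_seconds": self.tr,
                   "kept_frames": self.kept_frames.tolist()}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_tsv(cls, path) -> "RoiTimeSeries":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        if df.isna().any().any():
            raise ValueError(f"non-numeric or missing cells in {path}")
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar_path}")
        sidecar = json.loads(sidecar_path.read_text())
        kept = sidecar.get("kept_frames")
        return cls(df.to_numpy(dtype=float), float(sidecar["tr_seconds"]),
                   list(df.columns),
                   None if kept is None else np.asarray(kept, dtype=int))


@dataclass
class MotionTrace:
    """Six rigid-body parameters per volume."""

    params: np.ndarray  # T x 6

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be T x 6")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters contain non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.params, columns=list(MOTION_COLUMNS)).to_csv(
            path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "MotionTrace":
        df = pd.read_csv(path, sep="\t")
        missing = set(MOTION_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"motion table missing columns {sorted(missing)}")
        return cls(df[list(MOTION_COLUMNS)].to_numpy(dtype=float))
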