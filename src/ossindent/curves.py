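"""Force–depth curve container and delimited-text I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

PHASES = ("loading", "hold", "unloading", "drift_hold")

#: default column names of the curve CSV dialect written by the simulator
CURVE_COLUMNS = ("time_s", "load_mN", "depth_nm")


@dataclass
class IndentationCurve:
    """One indentation site: sampled (time, load, depth) plus phase labels.

    ``time`` is strictly increasing (s), ``load`` in mN, ``depth`` in nm.
    ``phase`` holds one of :data:`PHASES` per sample once the curve has been
    segmented; unsegmented raw curves carry an empty phase array.
    """

    time: np.ndarray
    load: np.ndarray
    depth: np.ndarray
    phase: np.ndarray | None = None
    specimen: str = ""
    compartment: str = ""          # "cortical" | "cancellous"
    site: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if not (self.time.shape == self.load.shape == self.depth.shape):
            raise ValueError("time, load and depth must have equal length")
        if self.time.ndim != 1:
            raise ValueError("curve arrays must be one-dimensional")
        if not np.all(np.isfinite(self.load)) or not np.all(np.isfinite(self.depth)):
            raise ValueError("load and depth must be finite")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=object)
            if self.phase.shape != self.time.shape:
                raise ValueError("phase labels must match sample count")

    def __len__(self) -> int:
        return self.time.size

    @property
    def is_segmented(self) -> bool:
        return self.phase is not None

    def phase_mask(self, name: str) -> np.ndarray:
        if self.phase is None:
            raise ValueError("curve has not been segmented")
        if name not in PHASES:
            raise ValueError(f"unknown phase {name!r}")
        return self.phase == name

    def phase_slice(self, name: str) -> "IndentationCurve":
        m = self.phase_mask(name)
        return IndentationCurve(
            self.time[m], self.load[m], self.depth[m],
            phase=self.phase[m], specimen=self.specimen,
            compartment=self.compartment, site=self.site, meta=dict(self.meta),
        )

    def replace(self, **kw) -> "IndentationCurve":
        data = dict(
            time=self.time, load=self.load, depth=self.depth, phase=self.phase,
            specimen=self.specimen, compartment=self.compartment,
            site=self.site, meta=dict(self.meta),
        )
        data.update(kw)
        return IndentationCurve(**data)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time_s": self.time, "load_mN": self.load, "depth_nm": self.depth}
        )
        if self.phase is not None:
            df["phase"] = self.phase
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        aliases: Mapping[str, str] | None = None,
        **meta,
    ) -> "IndentationCurve":
        """Read a curve CSV.

        ``aliases`` maps non-standard column names onto the canonical
        ``time_s``/``load_mN``/``depth_nm`` trio, e.g.
        ``{"t": "time_s", "P": "load_mN"}``.
        """
        df = pd.read_csv(path)
        if aliases:
            df = df.rename(columns=dict(aliases))
        missing = [c for c in CURVE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing curve columns {missing}")
        phase = df["phase"].to_numpy(dtype=object) if "phase" in df.columns else None
        return cls(
            df["time_s"].to_numpy(float),
            df["load_mN"].to_numpy(float),
            df["depth_nm"].to_numpy(float),
            phase=phase,
            **meta,
        )
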