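"""Aligned multichannel time-series container and plain-text I/O.

A :class:`TimeSeriesSet` holds a (time x channels) matrix of real values
together with channel names, the sampling interval (1 for maps) and a
``meta`` record sufficient to regenerate a simulated set bit-exactly
(system name, parameters, seed, resolved initial state).

On disk a set is a delimited UTF-8 text file — header row of channel
names, one row per time step, '.' decimal separator — with an optional
JSON sidecar ``<name>.meta.json`` carrying ``dt`` and ``meta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class TimeSeriesSet:
    values: np.ndarray
    channel_names: list[str]
    dt: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise DataError("values must be a (time x channels) matrix")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.values.shape[1]:
            raise DataError(
                f"{len(self.channel_names)} channel names for "
                f"{self.values.shape[1]} columns"
            )
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"missing or non-finite value at row {bad[0]}, "
                f"channel {self.channel_names[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 1-D array (a view, do not mutate)."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise DataError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channel_names)

    # ---- plain-text round trip -------------------------------------

    def to_csv(self, path: str | Path) -> Path:
        """Write values as CSV plus a JSON sidecar with dt and meta."""
        path = Path(path)
        # %.17g round-trips float64 exactly through text
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(
            json.dumps({"dt": self.dt, "meta": _jsonable(self.meta)}, indent=1)
        )
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeSeriesSet":
        """Read a delimited text file with a header row of channel names.

        Non-numeric or missing cells raise :class:`DataError` naming the
        offending row and column.
        """
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        values = np.empty(df.shape, dtype=float)
        for j, col in enumerate(df.columns):
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = numeric.isna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise DataError(
                    f"non-numeric or missing value in column {col!r}, "
                    f"data row {row} of {path.name}"
                )
            values[:, j] = numeric.to_numpy()
        dt, meta = 1.0, {}
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if sidecar.exists():
            payload = json.loads(sidecar.read_text())
            dt = float(payload.get("dt", 1.0))
            meta = payload.get("meta", {})
        return cls(values, list(df.columns), dt=dt, meta=meta)


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays for JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
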