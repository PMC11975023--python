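"""The common currency of the pipeline: firing-rate tensors with odor labels.

An :class:`ActivityDataset` holds a nonnegative firing-rate tensor of shape
``(neurons, time bins, trials, odors)`` in Hz, together with the frame rate,
the stimulus-onset time and the odor panel.  Both the synthetic generator and
the spiking simulator produce this type; every analytic consumes it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import OdorPanel


@dataclass
class ActivityDataset:
    rates: np.ndarray          # (n_neurons, n_bins, n_trials, n_odors), Hz
    frame_rate: float          # Hz
    panel: OdorPanel
    onset_time: float = 0.0    # stimulus onset, s from recording start
    provenance: str = "synthetic"   # "synthetic" | "simulated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 4:
            raise ValueError("rates must be (neurons, bins, trials, odors)")
        if self.rates.shape[3] != self.panel.n_odors:
            raise ValueError(
                f"tensor has {self.rates.shape[3]} odors, panel has "
                f"{self.panel.n_odors}"
            )
        if np.any(self.rates < 0):
            raise ValueError("firing rates must be nonnegative")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def n_trials(self) -> int:
        return self.rates.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Bin-center times in seconds from recording start."""
        return (np.arange(self.n_bins) + 0.5) / self.frame_rate

    def odor_slab(self, odor: str) -> np.ndarray:
        """Rates for one odor, shape (neurons, bins, trials)."""
        return self.rates[..., self.panel.index(odor)]

    # ------------------------------------------------------------------ io
    def to_xarray(self):
        import xarray as xr

        return xr.DataArray(
            self.rates,
            dims=("neuron", "time", "trial", "odor"),
            coords={
                "neuron": np.arange(self.n_neurons),
                "time": self.times,
                "trial": np.arange(self.n_trials),
                "odor": list(self.panel.odor_ids),
            },
            name="rate_hz",
            attrs={
                "frame_rate_hz": self.frame_rate,
                "onset_time_s": self.onset_time,
                "provenance": self.provenance,
            },
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat long-format export: one row per neuron-bin-trial-odor."""
        da = self.to_xarray()
        return da.to_dataframe().reset_index()

    def _labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "odor": list(self.panel.odor_ids),
                "odor_class": [self.panel.class_of[o] for o in self.panel.odor_ids],
                "role": [self.panel.conditioning.get(o, "") for o in self.panel.odor_ids],
            }
        )

    def save(self, path) -> None:
        """Write a chunked named-dimension array store plus a sidecar label CSV."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        ds = self.to_xarray().to_dataset()
        ds.to_zarr(path / "rates.zarr", mode="w")
        self._labels_frame().to_csv(path / "odor_labels.csv", index=False)
        (path / "meta.json").write_text(
            json.dumps(
                {
                    "frame_rate_hz": self.frame_rate,
                    "onset_time_s": self.onset_time,
                    "provenance": self.provenance,
                    "meta": self.meta,
                }
            )
        )

    @classmethod
    def load(cls, path) -> "ActivityDataset":
        import xarray as xr

        path = Path(path)
        ds = xr.open_zarr(path / "rates.zarr")
        labels = pd.read_csv(path / "odor_labels.csv").fillna("")
        meta = json.loads((path / "meta.json").read_text())
        panel = OdorPanel(
            tuple(labels["odor"]),
            dict(zip(labels["odor"], labels["odor_class"])),
            {o: r for o, r in zip(labels["odor"], labels["role"]) if r},
        )
        return cls(
            rates=np.asarray(ds["rate_hz"].transpose("neuron", "time", "trial", "odor")),
            frame_rate=meta["frame_rate_hz"],
            panel=panel,
            onset_time=meta["onset_time_s"],
            provenance=meta["provenance"],
            meta=meta.get("meta", {}),
        )
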