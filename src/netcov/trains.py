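"""Spike-train container shared by the Hawkes and LIF simulators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeTrains"]


@dataclass
class SpikeTrains:
    """Flat list of spikes ``(time_ms, neuron_id)``, ids 0-based, times sorted."""

    times: np.ndarray
    ids: np.ndarray
    duration: float
    n_neurons: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=int)

    def rates(self) -> np.ndarray:
        """Per-neuron mean rate in 1/ms."""
        counts = np.bincount(self.ids, minlength=self.n_neurons)
        return counts / self.duration

    def binned(self, bin_width: float, indices=None, mean: bool = False) -> np.ndarray:
        """Binned rate signals ``counts / bin_width`` (1/ms units).

        With ``mean=True`` returns the 1-D signal averaged over ``indices``
        (population-mean rate); otherwise a matrix, one row per neuron.
        """
        nb = int(round(self.duration / bin_width))
        edges = np.arange(nb + 1) * bin_width
        if indices is None:
            indices = np.arange(self.n_neurons)
        indices = np.asarray(indices)
        if mean:
            sel = np.isin(self.ids, indices)
            counts, _ = np.histogram(self.times[sel], bins=edges)
            return counts / (bin_width * indices.size)
        out = np.empty((indices.size, nb))
        for row, j in enumerate(indices):
            counts, _ = np.histogram(self.times[self.ids == j], bins=edges)
            out[row] = counts / bin_width
        return out

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_ms": self.times, "neuron_id": self.ids}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path, duration: float, n_neurons: int) -> "SpikeTrains":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["time_ms"].to_numpy(), df["neuron_id"].to_numpy(),
                   duration, n_neurons)
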