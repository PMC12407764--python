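"""The Recording container: per-cell spike-count rasters with trial metadata.

A Recording is the lingua franca of every analysis stage.  It holds a
(cells x frames) spike-count matrix at a fixed frame duration (22 ms by
default, emulating deconvolved two-photon rasters), cell positions in
micrometres, the indices of target cells (TCs), and a trial table of
stimulation onsets.  Recordings are produced by the lattice simulator, the
fixture generator, or read from HDF5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Recording:
    counts: np.ndarray                 # (n_cells, n_frames) non-negative ints
    positions: np.ndarray              # (n_cells, 2) in micrometres
    tc_indices: np.ndarray             # cell indices of the targets
    trials: pd.DataFrame | None = None  # columns: tc, onset_frame
    frame_ms: float = 22.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.positions = np.asarray(self.positions, dtype=float)
        self.tc_indices = np.asarray(self.tc_indices, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x frames)")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")
        if self.positions.shape != (self.counts.shape[0], 2):
            raise ValueError("positions must be (n_cells, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.tc_indices.size and (self.tc_indices.min() < 0 or
                                     self.tc_indices.max() >= self.n_cells):
            raise ValueError("tc_indices out of range")
        if self.trials is not None and len(self.trials):
            if not {"tc", "onset_frame"} <= set(self.trials.columns):
                raise ValueError("trials needs columns 'tc' and 'onset_frame'")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_frames(self) -> int:
        return self.counts.shape[1]

    @property
    def non_tc_indices(self) -> np.ndarray:
        mask = np.ones(self.n_cells, dtype=bool)
        mask[self.tc_indices] = False
        return np.flatnonzero(mask)

    def population_trace(self, exclude_tcs: bool | None = None) -> np.ndarray:
        """Summed spike counts per frame.

        By default TCs are excluded whenever stimulation trials are present
        (they carry the injected drive), and included otherwise.
        """
        if exclude_tcs is None:
            exclude_tcs = self.trials is not None and len(self.trials) > 0
        cells = self.non_tc_indices if exclude_tcs else np.arange(self.n_cells)
        return self.counts[cells].sum(axis=0)
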