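"""In-memory container for labelled fixed-width sequence windows.

A :class:`LabeledDataset` holds equal-length DNA windows with binary labels
(bound / unbound), optional per-base chromatin tracks aligned to the windows,
and — when the windows come from the synthetic generator — the offset at
which a motif instance was planted, so recovery can be verified exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabeledDataset"]


@dataclass
class LabeledDataset:
    sequences: list[str]
    labels: np.ndarray                      # (N,) int8, 1 = bound
    window_length: int
    ids: list[str] = field(default_factory=list)
    tracks: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (N, n)
    plant_offsets: np.ndarray | None = None  # (N,) int, -1 where nothing planted

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.sequences) != len(self.labels):
            raise ValueError("sequences and labels differ in length")
        for s in self.sequences:
            if len(s) != self.window_length:
                raise ValueError(
                    f"window of length {len(s)} != declared {self.window_length}")
        if not self.ids:
            self.ids = [f"w{i:06d}" for i in range(len(self.sequences))]

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_pos(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels == 0).sum())

    def gc_content(self) -> np.ndarray:
        """Per-window GC fraction."""
        return np.array([
            (s.count("G") + s.count("C")) / len(s) for s in self.sequences
        ])

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            sequences=[self.sequences[i] for i in idx],
            labels=self.labels[idx],
            window_length=self.window_length,
            ids=[self.ids[i] for i in idx],
            tracks={k: v[idx] for k, v in self.tracks.items()},
            plant_offsets=(None if self.plant_offsets is None
                           else self.plant_offsets[idx]),
        )

    def positives(self) -> "LabeledDataset":
        return self.subset(np.flatnonzero(self.labels == 1))

    def track_matrix(self, names: list[str]) -> np.ndarray:
        """Stack named tracks into an (N, n, c) array in the given order."""
        missing = [n for n in names if n not in self.tracks]
        if missing:
            raise KeyError(f"missing tracks: {', '.join(missing)}")
        return np.stack([self.tracks[n] for n in names], axis=-1)
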