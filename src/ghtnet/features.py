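"""Chromatin feature channels: DNA shape, signal tracks, normalization.

DNA shape descriptors (helix twist, roll, minor groove width, ...) are
predictable from sequence through a pentamer lookup table: position i of a
sequence takes the table value of the pentamer centred on i, with the two
bases at each end filled by edge replication.  The 14 features (13 shapes +
electrostatic potential) fall into three structural categories used for
contribution analysis:

* inter-bp (between adjacent base pairs): HelT, Rise, Roll, Shift, Slide, Tilt
* intra-bp (within a base pair): Buckle, Opening, ProT, Shear, Stagger, Stretch
* minor groove geometry / electrostatics: MGW, EP

All channels — shape, histone marks, accessibility, conservation — are
min-max normalized to [0,1] per feature over the training dataset; the
(min, max) statistics are stored so held-out or transferred data is rescaled
with training statistics (values beyond the training range clip to [0,1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import LabeledDataset

__all__ = [
    "SHAPE_FEATURES",
    "SHAPE_CATEGORIES",
    "ShapeCatalog",
    "FeatureNormalizer",
    "compute_shape_features",
    "attach_shape_tracks",
    "extract_signal",
    "assemble_feature_matrix",
]

SHAPE_FEATURES = [
    "HelT", "Rise", "Roll", "Shift", "Slide", "Tilt",
    "Buckle", "Opening", "ProT", "Shear", "Stagger", "Stretch",
    "MGW", "EP",
]

SHAPE_CATEGORIES = {
    "inter_bp": ["HelT", "Rise", "Roll", "Shift", "Slide", "Tilt"],
    "intra_bp": ["Buckle", "Opening", "ProT", "Shear", "Stagger", "Stretch"],
    "mgw_ep": ["MGW", "EP"],
}


class ShapeCatalog:
    """Pentamer → 14-feature lookup with N-handling.

    Pentamers containing N (or any non-ACGT base) take the per-feature mean
    over the whole table, so windows touching assembly gaps are kept.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [f for f in SHAPE_FEATURES if f not in table.columns]
        if missing:
            raise ValueError(f"catalog lacks features: {missing}")
        self.table = table[SHAPE_FEATURES]
        self._values = self.table.to_numpy(dtype=np.float64)
        self._index = {p: i for i, p in enumerate(self.table.index)}
        self._mean = self._values.mean(axis=0)

    @property
    def feature_names(self) -> list[str]:
        return list(SHAPE_FEATURES)

    def category_of(self, feature: str) -> str:
        for cat, feats in SHAPE_CATEGORIES.items():
            if feature in feats:
                return cat
        raise KeyError(feature)

    def lookup(self, pentamer: str) -> np.ndarray:
        i = self._index.get(pentamer.upper())
        if i is None:
            return self._mean
        return self._values[i]

    @classmethod
    def from_tsv(cls, path) -> "ShapeCatalog":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g")


def compute_shape_features(sequence: str, catalog: ShapeCatalog) -> np.ndarray:
    """Per-base shape features via sliding pentamer lookup.

    Returns an (L, 14) array; positions 0-1 and L-2, L-1 replicate the first
    and last defined pentamer value respectively, so every feature vector has
    the same length as the sequence.
    """
    L = len(sequence)
    if L < 5:
        raise ValueError(f"sequence of length {L} < 5 has no pentamer")
    sequence = sequence.upper()
    out = np.empty((L, len(SHAPE_FEATURES)))
    for i in range(2, L - 2):
        out[i] = catalog.lookup(sequence[i - 2:i + 3])
    out[0] = out[1] = out[2]
    out[L - 1] = out[L - 2] = out[L - 3]
    return out


def attach_shape_tracks(dataset: LabeledDataset,
                        catalog: ShapeCatalog) -> LabeledDataset:
    """Compute shape features for every window and attach them as tracks."""
    N, n = len(dataset), dataset.window_length
    stack = np.empty((N, n, len(SHAPE_FEATURES)))
    for i, seq in enumerate(dataset.sequences):
        stack[i] = compute_shape_features(seq, catalog)
    for j, feat in enumerate(SHAPE_FEATURES):
        if feat in dataset.tracks:
            raise ValueError(f"duplicate track name {feat!r}")
        dataset.tracks[feat] = stack[:, :, j]
    return dataset


@dataclass
class FeatureNormalizer:
    """Per-channel min-max statistics fit on a training dataset."""

    stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def fit(self, tracks: dict[str, np.ndarray]) -> "FeatureNormalizer":
        self.stats = {
            name: (float(np.min(v)), float(np.max(v)))
            for name, v in tracks.items()
        }
        return self

    def transform(self, tracks: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for name, v in tracks.items():
            if name not in self.stats:
                raise KeyError(f"no statistics for channel {name!r}")
            lo, hi = self.stats[name]
            if hi - lo < 1e-12:
                out[name] = np.full_like(np.asarray(v, dtype=np.float64), 0.5)
            else:
                out[name] = np.clip((np.asarray(v, dtype=np.float64) - lo)
                                    / (hi - lo), 0.0, 1.0)
        return out

    def fit_transform(self, tracks):
        return self.fit(tracks).transform(tracks)


def normalize_tracks(dataset: LabeledDataset,
                     normalizer: FeatureNormalizer | None = None
                     ) -> tuple[LabeledDataset, FeatureNormalizer]:
    """Min-max rescale every attached track to [0,1] over the dataset.

    When ``normalizer`` is given its stored training statistics are applied
    (with clipping); otherwise statistics are fit on this dataset.  Constant
    channels map to 0.5.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if normalizer is None:
        normalizer = FeatureNormalizer().fit(dataset.tracks)
    dataset.tracks = normalizer.transform(dataset.tracks)
    return dataset, normalizer


def extract_signal(intervals: list[tuple[str, int, int, float]],
                   contig: str, start: int, end: int) -> np.ndarray:
    """Per-base signal over [start, end) from bedGraph-style intervals.

    ``intervals`` is a list of (contig, start, end, value) records (see
    :func:`ghtnet.io.read_bedgraph`); bases not covered by any record are 0.
    """
    if end <= start:
        raise ValueError("window end must exceed start")
    out = np.zeros(end - start)
    for c, s, e, v in intervals:
        if c != contig or e <= start or s >= end:
            continue
        out[max(s, start) - start:min(e, end) - start] = v
    return out


def assemble_feature_matrix(dataset: LabeledDataset,
                            selected: list[str]) -> np.ndarray:
    """Stack the selected channels into an (N, n, c) array in stated order.

    The feature branch needs at least one channel; requesting none (use the
    sequence-only model instead) or an unattached channel is an error.
    """
    if not selected:
        raise ValueError("feature branch requires at least one channel; "
                         "use the sequence-only model for no-feature runs")
    return dataset.track_matrix(list(selected))
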