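"""Synthetic benchmark generator for TF binding-site prediction.

Real training data for this problem are ChIP-seq peak windows: 101-bp
sequences centred on a binding peak (positives) paired with GC-matched
background windows (negatives), plus per-base chromatin tracks (histone
marks, DNase accessibility, conservation) around each window.  This module
generates datasets with that statistical structure — a position weight
matrix (PWM) instance planted in every positive window, negatives drawn from
a GC-matched i.i.d. background, and label-correlated smooth signal tracks —
so that every downstream stage (encoding, model training, attention and
motif interpretation) can be exercised and verified offline against known
ground truth.

The background model is i.i.d. bases with P(G)=P(C)=gc/2; GC matching of
negatives is enforced by per-window rejection sampling against the mean GC
of the positive set.  Motif instances are drawn column-wise from the PWM,
i.e. positions are independent — exactly the generative model a PWM encodes,
which makes motif-recovery tests exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import LabeledDataset

__all__ = [
    "PlantedMotif",
    "TrackModel",
    "generate_planted_motif_dataset",
    "generate_tracks",
    "generate_shape_table",
    "generate_fusion_dataset",
    "ctcf_like_pwm",
    "SHAPE_FEATURE_RANGES",
]

BASES = "ACGT"


@dataclass
class PlantedMotif:
    """A motif to plant: column-stochastic PWM plus an offset distribution.

    ``plant_span`` is the (lo, hi) inclusive range of 0-based start offsets;
    by default the central span 30–70 of a 101-bp window so that flanks
    remain on both sides for attention-enrichment comparisons.
    """

    pwm: np.ndarray                    # (L_m, 4), columns A,C,G,T
    name: str = "motif"
    plant_span: tuple[int, int] = (30, 70)

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("pwm must be an (L, 4) matrix over A,C,G,T")
        if (self.pwm < 0).any():
            raise ValueError("pwm entries must be nonnegative")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every pwm row (position) must sum to 1")

    @property
    def length(self) -> int:
        return self.pwm.shape[0]

    def information_content(self) -> float:
        """Total information content in bits (uniform background)."""
        p = np.clip(self.pwm, 1e-12, 1.0)
        return float((2.0 + (p * np.log2(p)).sum(axis=1)).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=1))

    def sample(self, rng: np.random.Generator) -> str:
        """Draw one instance column-wise from the PWM."""
        return "".join(
            BASES[rng.choice(4, p=self.pwm[i])] for i in range(self.length)
        )


@dataclass
class TrackModel:
    """Generative model for one per-base signal track.

    kind='peak_bump' produces a centred Gaussian bump of the given amplitude
    (scaled by ``label_effect`` on positive windows) plus Gaussian noise —
    the shape of ChIP/DNase signal around a peak summit.  'flat' is a
    constant level, 'noise' is pure Gaussian noise; both ignore the label.
    """

    kind: str = "peak_bump"
    amplitude: float = 1.0
    center_sd: float = 15.0
    noise_sd: float = 0.1
    label_effect: float = 1.0

    def __post_init__(self):
        if self.kind not in ("peak_bump", "flat", "noise"):
            raise ValueError(f"unknown track kind {self.kind!r}")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be nonnegative")

    def simulate(self, n: int, labels: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
        N = len(labels)
        noise = rng.normal(0.0, self.noise_sd, size=(N, n)) if self.noise_sd else 0.0
        if self.kind == "noise":
            return np.asarray(noise) + np.zeros((N, n))
        if self.kind == "flat":
            return np.full((N, n), self.amplitude) + noise
        pos = np.arange(n)
        bump = np.exp(-0.5 * ((pos - (n - 1) / 2.0) / self.center_sd) ** 2)
        amp = np.where(labels == 1, self.amplitude * self.label_effect,
                       self.amplitude)
        return amp[:, None] * bump[None, :] + noise


def _random_sequence(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A,C,G,T
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=p))


def generate_planted_motif_dataset(
    n_pos: int,
    n_neg: int,
    window_length: int = 101,
    motif: PlantedMotif | None = None,
    background_gc: float = 0.45,
    gc_tolerance: float = 0.05,
    seed: int = 0,
    max_tries: int = 500,
) -> LabeledDataset:
    """Generate peak-style positives with one planted motif instance each and
    GC-matched background negatives.

    Every positive window contains exactly one PWM instance at a start offset
    drawn from the motif's plant-span distribution; each negative is accepted
    only if its GC content lies within ``gc_tolerance`` of the positive-set
    mean GC, so the group means match within the tolerance by construction.
    Fully reproducible from ``seed``.
    """
    if motif is None:
        motif = ctcf_like_pwm()
    if not 0 < background_gc < 1:
        raise ValueError("background_gc must lie in (0, 1)")
    if motif.length > window_length:
        raise ValueError(
            f"motif length {motif.length} exceeds window length {window_length}")
    rng = np.random.default_rng(seed)

    lo, hi = motif.plant_span
    hi = min(hi, window_length - motif.length)
    lo = min(lo, hi)
    if lo < 0:
        raise ValueError("motif does not fit the window at any plant offset")

    sequences: list[str] = []
    offsets: list[int] = []
    for _ in range(n_pos):
        bg = _random_sequence(window_length, background_gc, rng)
        off = int(rng.integers(lo, hi + 1))
        inst = motif.sample(rng)
        sequences.append(bg[:off] + inst + bg[off + motif.length:])
        offsets.append(off)

    if n_pos > 0:
        target_gc = float(np.mean([
            (s.count("G") + s.count("C")) / window_length for s in sequences
        ]))
    else:
        target_gc = background_gc

    best_gap = np.inf
    for _ in range(n_neg):
        for attempt in range(max_tries):
            s = _random_sequence(window_length, background_gc, rng)
            gc = (s.count("G") + s.count("C")) / window_length
            gap = abs(gc - target_gc)
            best_gap = min(best_gap, gap)
            if gap <= gc_tolerance:
                sequences.append(s)
                offsets.append(-1)
                break
        else:
            raise RuntimeError(
                f"could not draw a negative within GC tolerance "
                f"{gc_tolerance} of {target_gc:.3f} after {max_tries} tries "
                f"(closest gap {best_gap:.3f})")

    labels = np.array([1] * n_pos + [0] * n_neg, dtype=np.int8)
    return LabeledDataset(
        sequences=sequences,
        labels=labels,
        window_length=window_length,
        plant_offsets=np.array(offsets, dtype=int),
    )


def generate_tracks(
    dataset: LabeledDataset,
    models: dict[str, TrackModel] | list[tuple[str, TrackModel]],
    seed: int = 0,
) -> LabeledDataset:
    """Attach one simulated per-base track per named model to the dataset.

    Track values are stored at base resolution with the same length as the
    window.  Duplicate track names (including names already attached) are
    rejected.
    """
    if isinstance(models, dict):
        items = list(models.items())
    else:
        items = list(models)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate track names in model list")
    rng = np.random.default_rng(seed)
    for name, model in items:
        if name in dataset.tracks:
            raise ValueError(f"duplicate track name {name!r}")
        dataset.tracks[name] = model.simulate(
            dataset.window_length, dataset.labels, rng)
    return dataset


#: Realistic value ranges for the 13 structural descriptors + electrostatic
#: potential, in their native units (degrees for angular parameters,
#: angstroms for translations and MGW, kT/e for EP).
SHAPE_FEATURE_RANGES: dict[str, tuple[float, float]] = {
    "HelT": (30.0, 40.0),
    "Rise": (3.1, 3.6),
    "Roll": (-10.0, 10.0),
    "Shift": (-1.0, 1.0),
    "Slide": (-2.0, 1.0),
    "Tilt": (-5.0, 5.0),
    "Buckle": (-15.0, 15.0),
    "Opening": (-5.0, 5.0),
    "ProT": (-18.0, 0.0),
    "Shear": (-1.0, 1.0),
    "Stagger": (-1.0, 1.0),
    "Stretch": (-0.5, 0.5),
    "MGW": (4.0, 6.5),
    "EP": (-10.0, -2.0),
}


def generate_shape_table(seed: int = 0) -> "pandas.DataFrame":
    """Generate a synthetic pentamer → shape-feature lookup table.

    Assigns each of the 4^5 = 1024 ACGT pentamers a value for each of the 14
    features (13 helical-structure descriptors + electrostatic potential),
    drawn uniformly from that feature's realistic range.  This is a synthetic
    stand-in with the same interface and value scales as Monte-Carlo-derived
    pentamer tables; it carries no real structural information.
    """
    import itertools
    import pandas as pd

    rng = np.random.default_rng(seed)
    pentamers = ["".join(p) for p in itertools.product(BASES, repeat=5)]
    data = {
        feat: rng.uniform(lo, hi, size=len(pentamers))
        for feat, (lo, hi) in SHAPE_FEATURE_RANGES.items()
    }
    return pd.DataFrame(data, index=pd.Index(pentamers, name="pentamer"))


def ctcf_like_pwm(strength: float = 0.85) -> PlantedMotif:
    """A 19-bp CTCF-like PWM built from the canonical core consensus.

    Each position gives probability ``strength`` to the consensus base and
    splits the rest uniformly; at the default strength the total information
    content is ~21 bits, comparable to the real CTCF motif.
    """
    consensus = "CCACCAGGGGGCGCTGTTG"
    rest = (1.0 - strength) / 3.0
    pwm = np.full((len(consensus), 4), rest)
    for i, b in enumerate(consensus):
        pwm[i, BASES.index(b)] = strength
    return PlantedMotif(pwm=pwm, name="CTCF_like")


def generate_fusion_dataset(
    n_pos: int,
    n_neg: int,
    window_length: int = 101,
    motif: PlantedMotif | None = None,
    background_gc: float = 0.45,
    track_model: TrackModel | None = None,
    track_name: str = "dnase",
    seed: int = 0,
) -> LabeledDataset:
    """Dataset where the label requires BOTH a (weak) motif and a track signal.

    Positives carry a planted motif instance and an elevated signal bump.
    Half the negatives carry the motif but baseline signal, the other half
    the elevated signal but no motif — so neither the sequence branch nor the
    feature branch alone can separate the classes perfectly, while their
    fusion can.  Used to demonstrate the value of multi-feature fusion.
    """
    if motif is None:
        motif = ctcf_like_pwm(strength=0.7)   # weak motif
    if track_model is None:
        track_model = TrackModel(kind="peak_bump", amplitude=1.0,
                                 center_sd=15.0, noise_sd=0.35, label_effect=2.0)
    rng = np.random.default_rng(seed)

    lo, hi = motif.plant_span
    hi = min(hi, window_length - motif.length)

    sequences, offsets, labels, has_signal = [], [], [], []
    for i in range(n_pos):
        bg = _random_sequence(window_length, background_gc, rng)
        off = int(rng.integers(lo, hi + 1))
        sequences.append(bg[:off] + motif.sample(rng) + bg[off + motif.length:])
        offsets.append(off)
        labels.append(1)
        has_signal.append(True)
    for i in range(n_neg):
        with_motif = i % 2 == 0
        bg = _random_sequence(window_length, background_gc, rng)
        if with_motif:
            off = int(rng.integers(lo, hi + 1))
            bg = bg[:off] + motif.sample(rng) + bg[off + motif.length:]
            offsets.append(off)
        else:
            offsets.append(-1)
        sequences.append(bg)
        labels.append(0)
        has_signal.append(not with_motif)

    labels = np.array(labels, dtype=np.int8)
    ds = LabeledDataset(sequences=sequences, labels=labels,
                        window_length=window_length,
                        plant_offsets=np.array(offsets))
    # signal follows has_signal, not the label
    sig = np.array(has_signal)
    n = window_length
    pos = np.arange(n)
    bump = np.exp(-0.5 * ((pos - (n - 1) / 2.0) / track_model.center_sd) ** 2)
    amp = np.where(sig, track_model.amplitude * track_model.label_effect,
                   track_model.amplitude)
    noise = rng.normal(0.0, track_model.noise_sd, size=(len(labels), n))
    ds.tracks[track_name] = amp[:, None] * bump[None, :] + noise
    return ds
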