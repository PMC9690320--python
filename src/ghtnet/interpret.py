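"""Model interpretation: attention-based region importance and motif
extraction from convolution detectors.

Attention maps from every layer and head of the sequence branch are averaged
into one n x n map per window; its column mean — how much attention each
position *receives* — is normalized to sum 1 and read as a per-position
importance profile over the window.

Motif extraction follows the three-step convolution-kernel procedure
popularized by DeepBind-style models: (i) detectors are candidate motif
scanners because of the global max pooling; (ii) for each detector, let l be
the maximum activation over the whole positive set — every positive sequence
whose own maximum activation exceeds 0.7*l contributes the detector-width
subsequence under its activation peak (one site per sequence, the maximum);
(iii) the aligned sites form a position frequency matrix, converted to a
probability matrix with a pseudocount, which can be compared internally by a
best-offset Pearson score or exported in MEME minimal format for external
comparison tools (TOMTOM against JASPAR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import LabeledDataset
from .model import GHTNet

__all__ = [
    "AttentionProfile", "Motif",
    "attention_scores", "attention_profiles", "extract_motifs",
    "pfm_to_ppm", "information_content", "motif_similarity",
]

BASES = "ACGT"


@dataclass
class AttentionProfile:
    window_id: str
    scores: np.ndarray   # (n,), nonnegative, sums to 1


@dataclass
class Motif:
    detector_id: int
    pfm: np.ndarray              # (L_d, 4) counts
    ppm: np.ndarray              # (L_d, 4) probabilities
    n_sites: int
    information_content: float   # bits
    threshold_l: float           # detector's maximum activation l

    @property
    def width(self) -> int:
        return self.pfm.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.ppm.argmax(axis=1))


def attention_scores(maps: list[np.ndarray]) -> np.ndarray:
    """Collapse attention maps into one importance score per position.

    ``maps`` holds per-layer arrays shaped (h, n, n) or (B, h, n, n); all
    layers and heads are averaged element-wise, then the column mean gives
    the attention received per position, normalized to sum 1.  Batched input
    returns a (B, n) array of profiles.
    """
    if not maps:
        raise ValueError("no attention maps given")
    mean_map = np.mean([m.mean(axis=-3) for m in maps], axis=0)
    received = mean_map.mean(axis=-2)            # column mean
    return received / received.sum(axis=-1, keepdims=True)


def attention_profiles(model: GHTNet, X_seq: np.ndarray,
                       X_feat: np.ndarray | None = None,
                       ids: list[str] | None = None,
                       branch: str = "sequence",
                       batch_size: int = 256) -> list[AttentionProfile]:
    """Attention importance profiles for a batch of windows."""
    out = []
    N = X_seq.shape[0]
    for s in range(0, N, batch_size):
        sl = slice(s, min(s + batch_size, N))
        _, attn, _ = model.forward(
            X_seq[sl], None if X_feat is None else X_feat[sl])
        profiles = attention_scores(attn[branch])
        for i in range(profiles.shape[0]):
            wid = ids[s + i] if ids else f"w{s + i:06d}"
            out.append(AttentionProfile(window_id=wid, scores=profiles[i]))
    return out


def pfm_to_ppm(pfm: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Counts -> probabilities, column-wise with a pseudocount."""
    pfm = np.asarray(pfm, dtype=float)
    if (pfm < 0).any():
        raise ValueError("pfm counts must be nonnegative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    totals = pfm.sum(axis=1, keepdims=True)
    if pseudocount == 0 and (totals == 0).any():
        raise ValueError("all-zero pfm column with zero pseudocount")
    return (pfm + pseudocount) / (totals + 4 * pseudocount)


def information_content(ppm: np.ndarray) -> float:
    """Total IC in bits relative to a uniform background."""
    p = np.clip(np.asarray(ppm, dtype=float), 1e-12, 1.0)
    return float((2.0 + (p * np.log2(p)).sum(axis=1)).sum())


def detector_activations(model: GHTNet, X_seq: np.ndarray,
                         X_feat: np.ndarray | None = None,
                         branch: str = "sequence",
                         batch_size: int = 256) -> np.ndarray:
    """Per-position detector activation profiles, (N, n, n_detectors)."""
    chunks = []
    for s in range(0, X_seq.shape[0] if X_seq is not None
                   else X_feat.shape[0], batch_size):
        sl = slice(s, s + batch_size)
        _, _, prof = model.forward(
            None if X_seq is None else X_seq[sl],
            None if X_feat is None else X_feat[sl])
        chunks.append(prof[branch])
    return np.concatenate(chunks, axis=0)


def extract_motifs(model: GHTNet, positives: LabeledDataset,
                   X_seq: np.ndarray, X_feat: np.ndarray | None = None,
                   activation_fraction: float = 0.7,
                   min_sites: int = 10,
                   pseudocount: float = 1.0) -> tuple[list[Motif], dict]:
    """Extract one motif per sufficiently-supported detector.

    Applies the 0.7*l activation rule over the positive set (see module
    docstring); detectors with fewer than ``min_sites`` contributing
    sequences are skipped and counted in the returned summary.
    """
    if len(positives) == 0:
        raise ValueError("positives dataset is empty")
    act = detector_activations(model, X_seq, X_feat)   # (N, n, F)
    N, n, F = act.shape
    w = model.config.detector_width
    half = w // 2
    motifs: list[Motif] = []
    skipped = 0
    for det in range(F):
        a = act[:, :, det]
        l = float(a.max())
        if l <= 0:
            skipped += 1
            continue
        seq_max = a.max(axis=1)
        seq_arg = a.argmax(axis=1)
        chosen = np.flatnonzero(seq_max > activation_fraction * l)
        counts = np.zeros((w, 4))
        n_sites = 0
        for i in chosen:
            # detector output at position p sees tokens centred on p; clip
            # the window so the site lies fully inside the sequence
            start = int(np.clip(seq_arg[i] - half, 0, n - w))
            site = positives.sequences[i][start:start + w]
            ok = True
            for j, b in enumerate(site):
                if b not in BASES:
                    ok = False
                    break
            if not ok:
                continue
            for j, b in enumerate(site):
                counts[j, BASES.index(b)] += 1
            n_sites += 1
        if n_sites < min_sites:
            skipped += 1
            continue
        ppm = pfm_to_ppm(counts, pseudocount)
        motifs.append(Motif(detector_id=det, pfm=counts, ppm=ppm,
                            n_sites=n_sites,
                            information_content=information_content(ppm),
                            threshold_l=l))
    return motifs, {"n_detectors": F, "n_emitted": len(motifs),
                    "n_skipped": skipped}


def _revcomp(ppm: np.ndarray) -> np.ndarray:
    # reverse positions and swap A<->T, C<->G
    return ppm[::-1, ::-1]


def motif_similarity(ppm_a: np.ndarray, ppm_b: np.ndarray,
                     min_overlap: int = 4) -> float:
    """Best-offset Pearson correlation between two probability matrices.

    All alignments with at least ``min_overlap`` overlapping columns are
    scored in both orientations (ppm_b also reverse-complemented); the
    aligned columns are flattened and Pearson-correlated, and the maximum
    over offsets and orientations is returned.
    """
    a = np.asarray(ppm_a, dtype=float)
    for name, m in (("ppm_a", a), ("ppm_b", np.asarray(ppm_b, dtype=float))):
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{name} rows must sum to 1")
    La, Lb = a.shape[0], np.asarray(ppm_b).shape[0]
    if min(La, Lb) < min_overlap:
        raise ValueError("matrices too short for the required overlap")
    best = -1.0
    for b in (np.asarray(ppm_b, dtype=float), _revcomp(np.asarray(ppm_b))):
        for offset in range(-(Lb - min_overlap), La - min_overlap + 1):
            lo_a, hi_a = max(0, offset), min(La, offset + Lb)
            if hi_a - lo_a < min_overlap:
                continue
            seg_a = a[lo_a:hi_a].ravel()
            seg_b = b[lo_a - offset:hi_a - offset].ravel()
            sa, sb = seg_a.std(), seg_b.std()
            if sa < 1e-12 or sb < 1e-12:
                continue
            r = float(np.corrcoef(seg_a, seg_b)[0, 1])
            best = max(best, r)
    return best
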