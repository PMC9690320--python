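"""Readers and writers for the interchange formats the pipeline speaks:
FASTA, BED, bedGraph, TSV embedding/shape tables, MEME minimal motifs, and
JASPAR PFMs.

Coordinates are BED-style 0-based half-open throughout.  Synthetic datasets
are written as FASTA (window id in the header) plus BED6 on a synthetic
contig, one window per ``window_length`` stride, with the label in the score
column; tracks go to one bedGraph file per channel on the same coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .datasets import LabeledDataset

__all__ = [
    "read_fasta", "write_fasta", "read_bed", "write_bed",
    "read_bedgraph", "write_bedgraph", "write_dataset", "read_dataset",
    "write_meme", "read_meme", "read_jaspar",
]

_VALID = set("ACGTN")


def read_fasta(path) -> list[tuple[str, str]]:
    """Ordered (id, uppercased sequence) records; duplicate ids rejected."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains illegal characters {sorted(bad)}")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for s in range(0, len(seq), 80):
                fh.write(seq[s:s + 80] + "\n")


@dataclass
class BedInterval:
    contig: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."


def read_bed(path) -> list[BedInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: end {end} <= start {start}")
            out.append(BedInterval(
                contig, start, end,
                parts[3] if len(parts) > 3 else ".",
                float(parts[4]) if len(parts) > 4 else 0.0,
                parts[5] if len(parts) > 5 else "."))
    return out


def write_bed(path, intervals: list[BedInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}"
                     f"\t{score}\t{iv.strand}\n")


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, "
                                 f"got {len(parts)}")
            try:
                rec = (parts[0], int(parts[1]), int(parts[2]),
                       float(parts[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if rec[2] <= rec[1]:
                raise ValueError(f"{path}:{lineno}: empty interval")
            out.append(rec)
    return out


def write_bedgraph(path, intervals) -> None:
    with open(path, "w") as fh:
        for contig, start, end, value in intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# dataset round trip on a synthetic contig


def write_dataset(dataset: LabeledDataset, outdir,
                  contig: str = "chrS") -> None:
    """Write FASTA + BED6 (+ one bedGraph per track) for a dataset.

    Windows are laid head-to-tail along a synthetic contig; the BED score
    column carries the binary label.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = dataset.window_length
    write_fasta(outdir / "windows.fa",
                zip(dataset.ids, dataset.sequences))
    write_bed(outdir / "windows.bed", [
        BedInterval(contig, i * n, (i + 1) * n, dataset.ids[i],
                    float(dataset.labels[i]))
        for i in range(len(dataset))
    ])
    for name, values in dataset.tracks.items():
        recs = []
        for i in range(len(dataset)):
            base = i * n
            for j in range(n):
                recs.append((contig, base + j, base + j + 1,
                             float(values[i, j])))
        write_bedgraph(outdir / f"track_{name}.bedGraph", recs)


def read_dataset(outdir, contig: str = "chrS") -> LabeledDataset:
    """Rebuild a dataset written by :func:`write_dataset`."""
    outdir = Path(outdir)
    records = read_fasta(outdir / "windows.fa")
    beds = read_bed(outdir / "windows.bed")
    n = beds[0].end - beds[0].start
    ds = LabeledDataset(
        sequences=[seq for _, seq in records],
        labels=np.array([int(iv.score) for iv in beds], dtype=np.int8),
        window_length=n,
        ids=[rid for rid, _ in records],
    )
    from .features import extract_signal
    for track_path in sorted(outdir.glob("track_*.bedGraph")):
        name = track_path.stem[len("track_"):]
        intervals = read_bedgraph(track_path)
        ds.tracks[name] = np.stack([
            extract_signal(intervals, contig, i * n, (i + 1) * n)
            for i in range(len(ds))
        ])
    return ds


# ---------------------------------------------------------------------------
# motif formats


def write_meme(path, motifs, background=None) -> None:
    """Write motifs in MEME minimal format (letter-probability matrices)."""
    motifs = list(motifs)
    if not motifs:
        raise ValueError("no motifs to write")
    bg = background or {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {A:.5f} C {C:.5f} G {G:.5f} T {T:.5f}\n\n".format(**bg))
        for m in motifs:
            name = f"detector_{m.detector_id}"
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                     f"nsites= {m.n_sites} E= 0\n")
            for row in m.ppm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> dict[str, np.ndarray]:
    """Parse a MEME minimal file into name -> (w, 4) probability matrices."""
    motifs: dict[str, np.ndarray] = {}
    name, rows, expect = None, [], 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                rows, expect = [], int(line.split("w=")[1].split()[0])
            elif name is not None and expect and line \
                    and line[0] in "0123456789.":
                rows.append([float(x) for x in line.split()])
                if len(rows) == expect:
                    motifs[name] = np.array(rows)
                    name, rows, expect = None, [], 0
    return motifs


def read_jaspar(path) -> dict[str, np.ndarray]:
    """Read JASPAR-format PFMs: name -> (w, 4) count matrix (A,C,G,T)."""
    out: dict[str, np.ndarray] = {}
    name, rows = None, {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name and len(rows) == 4:
                    out[name] = np.stack([rows[b] for b in "ACGT"], axis=1)
                name, rows = line[1:].split()[0], {}
            else:
                base = line[0].upper()
                nums = line.split("[")[1].split("]")[0] if "[" in line \
                    else line[1:]
                rows[base] = np.array([float(x) for x in nums.split()])
    if name and len(rows) == 4:
        out[name] = np.stack([rows[b] for b in "ACGT"], axis=1)
    return out
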