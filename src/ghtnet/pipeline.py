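"""End-to-end reproducible runs driven by a single config mapping.

A run config is a YAML mapping with stage sections (simulate, encode, model,
training, interpret) plus a global seed and output directory.  Unknown keys
are rejected before any computation; the resolved config is persisted next
to the outputs so every artifact can be regenerated from it.
"""

from __future__ import annotations

import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .datasets import LabeledDataset
from .encoding import SkipgramConfig
from .features import normalize_tracks
from .model import GHTNetConfig
from .synthetic import (PlantedMotif, TrackModel, ctcf_like_pwm,
                        generate_planted_motif_dataset, generate_tracks)
from .training import (TrainingConfig, cross_validate, fit_embeddings,
                       prepare_inputs)
from .interpret import extract_motifs
from . import io as gio

__all__ = ["DEFAULT_CONFIG", "resolve_config", "run_pipeline",
           "simulate_from_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "ghtnet_run",
    "simulate": {
        "n_pos": 500,
        "n_neg": 500,
        "window_length": 101,
        "background_gc": 0.45,
        "gc_tolerance": 0.05,
        "motif_strength": 0.85,
        "tracks": {},          # name -> TrackModel fields
    },
    "encode": {
        "k": 3,
        "dim": 16,
        "window": 2,
        "max_per_dataset": 5000,
        "max_epochs": 5,
    },
    "model": {
        "n_layers": 2,
        "n_heads": 4,
        "cffn_hidden": 64,
        "cffn_kernel": 3,
        "n_detectors": 16,
        "detector_width": 15,
        "mlp_hidden": [64],
        "dropout": 0.2,
        "tie_branches": False,
        "channels": [],        # feature channels; [] = sequence-only
    },
    "training": {
        "batch_size": 64,
        "lr_start": 1.0e-4,
        "lr_peak": 5.0e-4,
        "warmup_epochs": 10,
        "weight_decay": 0.01,
        "patience": 5,
        "max_epochs": 15,
        "folds": 5,
        "n_folds": 1,          # folds actually trained in this run
    },
    "interpret": {
        "activation_fraction": 0.7,
        "min_sites": 10,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        if key not in base:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict) and key != "tracks":
            if not isinstance(value, dict):
                raise TypeError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge(base[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def resolve_config(user_config: dict | None = None,
                   seed: int | None = None,
                   outdir: str | None = None) -> dict:
    cfg = _merge(DEFAULT_CONFIG, user_config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    if outdir is not None:
        cfg["outdir"] = str(outdir)
    return cfg


def simulate_from_config(cfg: dict, seed: int) -> LabeledDataset:
    sim = cfg["simulate"]
    motif = ctcf_like_pwm(strength=sim["motif_strength"])
    ds = generate_planted_motif_dataset(
        n_pos=sim["n_pos"], n_neg=sim["n_neg"],
        window_length=sim["window_length"], motif=motif,
        background_gc=sim["background_gc"],
        gc_tolerance=sim["gc_tolerance"], seed=seed)
    if sim["tracks"]:
        models = {name: TrackModel(**fields)
                  for name, fields in sim["tracks"].items()}
        generate_tracks(ds, models, seed=seed + 1)
    return ds


def run_pipeline(user_config: dict | None = None, seed: int | None = None,
                 outdir: str | None = None, log=print) -> Path:
    """simulate -> encode -> train -> evaluate -> interpret, with artifacts.

    Every artifact is stamped with the seed, a config hash, and the package
    version; per-stage wall time is logged.  Returns the output directory.
    """
    cfg = resolve_config(user_config, seed=seed, outdir=outdir)
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    stamp = {"seed": seed, "version": __version__,
             "config_hash": hex(abs(hash(json.dumps(cfg, sort_keys=True,
                                                    default=str))))[2:18]}

    timings = {}

    def stage(name):
        log(f"[{name}] ...")
        timings[name] = time.time()

    def done(name):
        timings[name] = round(time.time() - timings[name], 2)
        log(f"[{name}] {timings[name]} s")

    try:
        stage("simulate")
        ds = simulate_from_config(cfg, seed)
        gio.write_dataset(ds, out / "data")
        done("simulate")

        stage("encode")
        enc = cfg["encode"]
        emb = fit_embeddings(
            ds, k=enc["k"],
            config=SkipgramConfig(window=enc["window"], d=enc["dim"],
                                  max_epochs=enc["max_epochs"]),
            max_per_dataset=enc["max_per_dataset"], seed=seed)
        emb.to_frame().to_csv(out / "embeddings.tsv", sep="\t",
                              float_format="%.6g")
        done("encode")

        stage("train")
        mdl = dict(cfg["model"])
        channels = list(mdl.pop("channels"))
        if channels:
            ds, _ = normalize_tracks(ds)
        model_cfg = GHTNetConfig(
            k=enc["k"], d=enc["dim"], mlp_hidden=tuple(mdl.pop("mlp_hidden")),
            n_feature_channels=len(channels), **mdl)
        tr = dict(cfg["training"])
        n_folds = tr.pop("n_folds")
        train_cfg = TrainingConfig(seed=seed, **tr)
        X_seq, X_feat = prepare_inputs(ds, emb, channels)
        report, models = cross_validate(model_cfg, X_seq, X_feat, ds.labels,
                                        train_cfg, seed=seed,
                                        n_folds=n_folds)
        done("train")

        stage("evaluate")
        metrics = {**stamp, **report.to_dict()}
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2)
        done("evaluate")

        stage("interpret")
        pos = ds.positives()
        Xp_seq, Xp_feat = prepare_inputs(pos, emb, channels)
        motifs, summary = extract_motifs(
            models[0], pos, Xp_seq, Xp_feat,
            activation_fraction=cfg["interpret"]["activation_fraction"],
            min_sites=cfg["interpret"]["min_sites"])
        if motifs:
            gio.write_meme(out / "motifs.meme", motifs)
        with open(out / "interpret_summary.json", "w") as fh:
            json.dump({**stamp, **summary}, fh, indent=2)
        done("interpret")
    except Exception as exc:
        with open(out / "run_log.json", "w") as fh:
            json.dump({"stamp": stamp, "timings": timings,
                       "failed": repr(exc)}, fh, indent=2)
        raise RuntimeError(
            f"pipeline stage failed ({exc}); partial logs in {out}") from exc

    with open(out / "run_log.json", "w") as fh:
        json.dump({"stamp": stamp, "timings": timings, "failed": None},
                  fh, indent=2)
    return out
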