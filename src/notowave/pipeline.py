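"""End-to-end orchestration: synth → call → score → linkage → estimate → select.

Every stochastic stage draws its RNG stream from a single master seed, and a
JSON run manifest records the configuration snapshot, per-stage seeds,
timings and output paths, so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ModelConfig
from .containers import StateLattice
from .calling import binarize
from .estimation import collect_differences, fit_p
from .io import (
    load_config_file,
    read_lattice,
    read_traces,
    write_json,
    write_lattice,
    write_table,
    write_traces,
    write_transitions,
)
from .linkage import NullSpec, linkage_curves
from .scoring import pooled_intervals, interval_distribution, window_series
from .selection import select
from .simulator import CANDIDATES_8CELL
from .synth import TraceNoiseSpec, generate_lattice, render_traces

MODES = ("synthetic", "from-traces", "from-lattice")

_SECTIONS = {
    "model": set(ModelConfig.__dataclass_fields__),
    "noise": set(TraceNoiseSpec.__dataclass_fields__),
    "calling": {"persistence"},
    "scoring": {"window", "landmark"},
    "linkage": {"q", "reps", "window"},
    "selection": {"candidates", "reps"},
    "inputs": {"traces", "lattice"},
}


def validate_config(raw: dict) -> dict:
    """Reject unknown sections/keys (typo guard); fill in defaults."""
    for section, keys in raw.items():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(keys, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        unknown = set(keys) - _SECTIONS[section]
        if unknown:
            raise ValueError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    cfg = {s: dict(raw.get(s, {})) for s in _SECTIONS}
    cfg["calling"].setdefault("persistence", 5)
    cfg["scoring"].setdefault("window", 8)
    cfg["scoring"].setdefault("landmark", "lower")
    cfg["linkage"].setdefault("q", 0.9)
    cfg["linkage"].setdefault("reps", 10_000)
    cfg["linkage"].setdefault("window", cfg["scoring"]["window"])
    cfg["selection"].setdefault("candidates", list(CANDIDATES_8CELL))
    cfg["selection"].setdefault("reps", 300)
    return cfg


def run_pipeline(
    config: dict | str | Path | None = None,
    mode: str = "synthetic",
    out_dir: str | Path = "pipeline_out",
    seed: int | None = None,
) -> dict:
    """Run the full analysis; returns (and writes) the run manifest."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if isinstance(config, (str, Path)):
        config = load_config_file(config)
    cfg = validate_config(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] >> 1)
        for name, child in zip(
            ("synth", "traces", "linkage", "selection"), master.spawn(4)
        )
    }
    model = ModelConfig(**{**cfg["model"], "seed": stage_seeds["synth"]})
    manifest: dict = {
        "version": __version__,
        "mode": mode,
        "seed": seed,
        "stage_seeds": stage_seeds,
        "config": {**cfg, "model": asdict(model)},
        "outputs": {},
        "timings_s": {},
    }

    def _stage(name):
        t0 = time.perf_counter()

        def done(**outputs):
            manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
            for k, p in outputs.items():
                manifest["outputs"][k] = str(p)

        return done

    truth = None
    if mode == "synthetic":
        done = _stage("synth")
        lattice, truth = generate_lattice(model)
        traces = render_traces(
            truth, TraceNoiseSpec(**cfg["noise"]), model, seed=stage_seeds["traces"]
        )
        write_lattice(lattice, out / "true_lattice.tsv")
        write_transitions(truth, out / "true_transitions.tsv")
        write_traces(traces, out / "traces.tsv")
        done(true_lattice=out / "true_lattice.tsv",
             true_transitions=out / "true_transitions.tsv",
             traces=out / "traces.tsv")
    elif mode == "from-traces":
        if not cfg["inputs"].get("traces"):
            raise ValueError("from-traces mode requires inputs.traces")
        traces = read_traces(cfg["inputs"]["traces"], dt=model.dt)
    else:  # from-lattice
        if not cfg["inputs"].get("lattice"):
            raise ValueError("from-lattice mode requires inputs.lattice")

    if mode == "from-lattice":
        lattice = read_lattice(cfg["inputs"]["lattice"], dt=model.dt)
        transitions = lattice.entry_frames()
    else:
        done = _stage("calling")
        lattice, transitions = binarize(traces, persistence=cfg["calling"]["persistence"])
        write_lattice(lattice, out / "called_lattice.tsv")
        write_transitions(transitions, out / "called_transitions.tsv")
        done(called_lattice=out / "called_lattice.tsv",
             called_transitions=out / "called_transitions.tsv")

    done = _stage("scoring")
    ws = window_series(
        lattice, window=cfg["scoring"]["window"], landmark=cfg["scoring"]["landmark"]
    )
    intervals = pooled_intervals(lattice, landmark="pgc")
    write_table(ws, out / "window_series.tsv")
    write_table(
        pd.DataFrame({"interval_frames": intervals}), out / "pgc_intervals.tsv"
    )
    done(window_series=out / "window_series.tsv", pgc_intervals=out / "pgc_intervals.tsv")

    done = _stage("linkage")
    curves = linkage_curves(
        ws,
        NullSpec(
            mode="random",
            q=cfg["linkage"]["q"],
            reps=cfg["linkage"]["reps"],
            window=cfg["linkage"]["window"],
            seed=stage_seeds["linkage"],
        ),
    )
    write_table(curves, out / "linkage_curves.tsv")
    done(linkage_curves=out / "linkage_curves.tsv")

    done = _stage("estimation")
    sample = collect_differences(transitions)
    if len(sample) > 0:
        fit = fit_p(sample)
        fit_payload = {
            "p_hat": fit.p_hat, "rss": fit.rss,
            "n_samples": fit.n_samples, "boundary": fit.boundary,
            "n_excluded": sample.n_excluded,
        }
    else:
        fit_payload = {"p_hat": None, "note": "no doubly-called positions"}
    write_json(fit_payload, out / "fit.json")
    done(fit=out / "fit.json")

    done = _stage("selection")
    if intervals.size:
        experimental = interval_distribution(intervals, dt=model.dt)
        result = select(
            experimental,
            candidates=cfg["selection"]["candidates"],
            config=model.with_(seed=None),
            reps=cfg["selection"]["reps"],
            seed=stage_seeds["selection"],
        )
        sel_payload = {
            "selected_z": result.selected,
            "models": result.summary().to_dict(orient="records"),
            "ks_table": result.ks_table.to_dict(orient="records"),
        }
    else:
        sel_payload = {"selected_z": None, "note": "no PGC intervals observed"}
    write_json(sel_payload, out / "selection.json")
    done(selection=out / "selection.json")

    write_json(manifest, out / "manifest.json")
    manifest["outputs"]["manifest"] = str(out / "manifest.json")
    return manifest
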