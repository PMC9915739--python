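"""End-to-end orchestration of synthetic reproduction runs.

A run is described by a YAML/dict config: a global seed, a stage list and
per-stage parameter blocks.  Stages execute in dependency order on a shared
context; every output file is recorded in a manifest with SHA-256 checksums
so a rerun with the same config and seed is bit-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import detect_arm_entries, score_alternation, segment_trials, \
    trial_bins, trials_to_frame
from .calcium import estimate_baseline_stats, detect_events, events_to_frame
from .ensemble import alternation_selectivity, build_spatial_map, \
    compare_peak_proportions, peak_position_distribution, plot_raster
from .errors import ConfigurationError
from .morphology import count_cells, detect_axons, detect_boutons, \
    normalize_metrics
from .stats import GroupSample, report as stats_report
from .synthetic import BehaviorSimConfig, ImageSimConfig, TraceSimConfig, \
    simulate_arm_entries, simulate_morphology_image, simulate_trace_set, \
    simulate_trajectory, write_ground_truth_json

__all__ = ["RunConfig", "validate", "run", "demo_config", "config_hash"]

_KNOWN_STAGES = (
    "simulate_behavior",
    "behavior",
    "simulate_traces",
    "events",
    "ensemble",
    "simulate_morphology",
    "morphology",
    "report",
)

_REQUIRES = {
    "simulate_behavior": (),
    "behavior": ("simulate_behavior",),
    "simulate_traces": ("simulate_behavior",),
    "events": ("simulate_traces",),
    "ensemble": ("simulate_traces", "behavior"),
    "simulate_morphology": (),
    "morphology": ("simulate_morphology",),
    "report": (),
}

_BLOCK_KEYS = {
    "behavior_sim": {
        "groups", "n_sessions", "session_duration", "arm_length", "arm_width",
        "mean_dwell", "speed", "frame_rate", "n_entries", "p_alternate",
    },
    "trace_sim": {
        "n_neurons", "n_bins", "tuning_center", "tuning_width",
        "event_amplitude", "peak_event_rate", "base_rate", "kernel_rise",
        "kernel_decay", "noise_sd", "frac_selective", "selective_gain",
    },
    "morphology_sim": {
        "groups", "n_animals_per_group", "n_sections", "image_shape",
        "pixel_size", "n_axons", "axon_intensity", "axon_length_um",
        "boutons_per_100um", "bouton_amplitude", "bouton_sigma",
        "background_sd", "background_level", "n_cells", "cell_intensity",
        "cell_sigma", "curvature", "write_images",
    },
    "behavior": {"entry_fraction", "stop_speed", "terminal_fraction",
                 "sustain_s"},
    "events": {"deriv_window", "peak_k", "deriv_k"},
    "ensemble": {"n_bins", "center_bins", "selectivity_k"},
    "report": set(),
}

_TOP_KEYS = {"seed", "stages"} | set(_BLOCK_KEYS)


@dataclass
class RunConfig:
    """Validated run configuration."""

    seed: int
    stages: list[str]
    raw: dict

    @property
    def hash(self) -> str:
        return config_hash(self.raw)

    def block(self, name: str) -> dict:
        return dict(self.raw.get(name, {}))


def config_hash(cfg: dict) -> str:
    """SHA-256 of the canonical JSON form; stable under key reordering."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def demo_config() -> dict:
    """A small two-group end-to-end demo configuration."""
    return {
        "seed": 7,
        "stages": list(_KNOWN_STAGES),
        "behavior_sim": {
            "groups": {"ctrl": 0.67, "mutant": 0.53},
            "n_sessions": 2,
            "session_duration": 480.0,
        },
        "trace_sim": {"n_neurons": 40, "frac_selective": 0.2,
                      "noise_sd": 0.05},
        "morphology_sim": {
            "groups": {"ctrl": 1.0, "mutant": 0.84},
            "n_animals_per_group": 3,
            "n_sections": 1,
            "image_shape": [256, 256],
            "n_axons": 3,
            "n_cells": 12,
        },
        "ensemble": {"center_bins": [8, 9, 10]},
    }


def _load(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def validate(config) -> RunConfig:
    """Validate a config path or dict; raises ConfigurationError on problems.

    Checks top-level and per-block keys (unknown keys rejected), stage names
    and dependencies, and constructs the underlying simulation configs so
    all type/range invariants are applied before any stage runs.
    """
    cfg = _load(config)
    errors: list[str] = []
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown top-level key(s): {sorted(unknown)}")
    seed = cfg.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append("seed must be a nonnegative integer")
    stages = list(cfg.get("stages", _KNOWN_STAGES))
    for s in stages:
        if s not in _KNOWN_STAGES:
            errors.append(f"unknown stage: {s!r}")
    seen: set[str] = set()
    for s in stages:
        for dep in _REQUIRES.get(s, ()):
            if dep not in seen:
                errors.append(f"stage {s!r} requires missing stage {dep!r}")
        seen.add(s)
    for block, allowed in _BLOCK_KEYS.items():
        extra = set(cfg.get(block, {})) - allowed
        if extra:
            errors.append(f"unknown key(s) in {block!r}: {sorted(extra)}")
    if not errors:
        # range checks via the dataclass invariants
        try:
            b = dict(cfg.get("behavior_sim", {}))
            groups = b.pop("groups", {"ctrl": b.pop("p_alternate", 0.5)})
            for label, p in groups.items():
                BehaviorSimConfig(p_alternate=float(p), seed=0, **b)
            t = dict(cfg.get("trace_sim", {}))
            TraceSimConfig(seed=0, **t)
            m = dict(cfg.get("morphology_sim", {}))
            m.pop("groups", None)
            m.pop("n_animals_per_group", None)
            m.pop("n_sections", None)
            m.pop("write_images", None)
            if "image_shape" in m:
                m["image_shape"] = tuple(m["image_shape"])
            ImageSimConfig(seed=0, **m)
        except (ConfigurationError, TypeError, ValueError) as exc:
            errors.append(str(exc))
    if errors:
        raise ConfigurationError("; ".join(errors))
    return RunConfig(seed=int(seed), stages=stages, raw=cfg)


def _child_seed(seed: int, *stream: int) -> int:
    return int(np.random.default_rng([seed, *stream]).integers(2 ** 31))


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate_behavior(rc: RunConfig, ctx: dict, out: Path) -> None:
    blk = rc.block("behavior_sim")
    groups = blk.pop("groups", {"ctrl": blk.pop("p_alternate", 0.5)})
    n_sessions = int(blk.pop("n_sessions", 1))
    ctx["sessions"] = {}
    for gi, (label, p_alt) in enumerate(sorted(groups.items())):
        for s in range(n_sessions):
            bcfg = BehaviorSimConfig(
                p_alternate=float(p_alt),
                seed=_child_seed(rc.seed, 0, gi, s),
                **blk,
            )
            entries, gt = simulate_arm_entries(bcfg)
            traj = simulate_trajectory(entries, bcfg)
            stem = out / f"traj_{label}_s{s}"
            traj.to_csv(f"{stem}.csv")
            write_ground_truth_json(gt, f"{stem}_truth.json")
            ctx["sessions"][(label, s)] = {"traj": traj, "truth": gt,
                                           "cfg": bcfg}


def _stage_behavior(rc: RunConfig, ctx: dict, out: Path) -> None:
    blk = rc.block("behavior")
    seg_keys = {k: blk[k] for k in ("stop_speed", "terminal_fraction",
                                    "sustain_s") if k in blk}
    ctx["behavior"] = {}
    rows = []
    for (label, s), sess in sorted(ctx["sessions"].items()):
        traj = sess["traj"]
        entries = detect_arm_entries(
            traj, entry_fraction=blk.get("entry_fraction", 0.2)
        )
        score = score_alternation(entries)
        trials, n_aborted = segment_trials(traj, entries, **seg_keys)
        bins = trial_bins(traj, trials)
        entries.to_csv(out / f"entries_{label}_s{s}.csv")
        _write_csv(trials_to_frame(trials), out / f"trials_{label}_s{s}.csv")
        bin_rows = [
            {"trial": tr.index, "frame": tr.start_frame + j, "bin": int(b)}
            for tr, bb in zip(trials, bins) for j, b in enumerate(bb)
        ]
        _write_csv(pd.DataFrame(bin_rows), out / f"bins_{label}_s{s}.csv")
        ctx["behavior"][(label, s)] = {
            "entries": entries, "score": score, "trials": trials,
            "bins": bins, "n_aborted": n_aborted,
        }
        rows.append({"group": label, "session": s,
                     "alternation_percent": score.percent,
                     "n_entries": score.n_entries,
                     "n_aborted_trials": n_aborted})
    _write_csv(pd.DataFrame(rows), out / "alternation_summary.csv")


def _stage_simulate_traces(rc: RunConfig, ctx: dict, out: Path) -> None:
    blk = rc.block("trace_sim")
    ctx["traces"] = {}
    groups = sorted({label for (label, _) in ctx["sessions"]})
    for gi, label in enumerate(groups):
        traj = ctx["sessions"][(label, 0)]["traj"]
        tcfg = TraceSimConfig(seed=_child_seed(rc.seed, 1, gi), **blk)
        ts, gt = simulate_trace_set(traj, tcfg)
        ts.to_hdf5(out / f"traces_{label}.h5")
        write_ground_truth_json(gt, out / f"traces_{label}_truth.json")
        ctx["traces"][label] = {"traces": ts, "truth": gt, "cfg": tcfg}


def _stage_events(rc: RunConfig, ctx: dict, out: Path) -> None:
    blk = rc.block("events")
    ctx["events"] = {}
    for label, tr in sorted(ctx["traces"].items()):
        ts = tr["traces"]
        events = []
        for i in range(ts.n_neurons):
            stats = estimate_baseline_stats(
                ts.dff[i], ts.frame_rate, blk.get("deriv_window", 0.2)
            )
            events.extend(
                detect_events(
                    ts.dff[i], ts.frame_rate, stats,
                    deriv_window=blk.get("deriv_window", 0.2),
                    peak_k=blk.get("peak_k", 3.0),
                    deriv_k=blk.get("deriv_k", 5.0),
                    neuron_id=i,
                )
            )
        _write_csv(events_to_frame(events, ts.frame_rate),
                   out / f"events_{label}.csv")
        summary = pd.DataFrame({
            "neuron": np.arange(ts.n_neurons),
            "activity_sd": [float(np.std(ts.dff[i], ddof=1))
                            for i in range(ts.n_neurons)],
            "n_events": np.bincount(
                [e.neuron_id for e in events], minlength=ts.n_neurons),
        })
        _write_csv(summary, out / f"activity_summary_{label}.csv")
        ctx["events"][label] = events


def _stage_ensemble(rc: RunConfig, ctx: dict, out: Path) -> None:
    blk = rc.block("ensemble")
    n_bins = int(blk.get("n_bins", 20))
    ctx["ensemble"] = {}
    for label, tr in sorted(ctx["traces"].items()):
        beh = ctx["behavior"][(label, 0)]
        amap = build_spatial_map(tr["traces"], beh["trials"], beh["bins"],
                                 n_bins=n_bins)
        peaks = peak_position_distribution(amap)
        _write_csv(peaks.to_frame(), out / f"peak_distribution_{label}.csv")
        sel = None
        if amap.n_labeled(True) >= 2 and amap.n_labeled(False) >= 2:
            sel = alternation_selectivity(amap, k=blk.get("selectivity_k", 2.0))
            _write_csv(sel.to_frame(), out / f"selectivity_{label}.csv")
        plot_raster(amap, out / f"raster_{label}.png")
        ctx["ensemble"][label] = {"map": amap, "peaks": peaks,
                                  "selectivity": sel}
    labels = sorted(ctx["ensemble"])
    if len(labels) == 2 and "center_bins" in blk:
        a, b = (ctx["ensemble"][l]["peaks"] for l in labels)
        cmp_ = compare_peak_proportions(a.peak_bins, b.peak_bins,
                                        blk["center_bins"], n_bins=n_bins)
        with open(out / "peak_comparison.json", "w") as fh:
            json.dump(
                {"groups": labels, "statistic": cmp_.statistic, "df": cmp_.df,
                 "p_value": cmp_.p_value, "table": cmp_.table.tolist(),
                 "center_bins": list(blk["center_bins"]),
                 "low_expected": cmp_.low_expected},
                fh, indent=1, sort_keys=True,
            )


def _stage_simulate_morphology(rc: RunConfig, ctx: dict, out: Path) -> None:
    blk = rc.block("morphology_sim")
    groups = blk.pop("groups", {"ctrl": 1.0})
    n_animals = int(blk.pop("n_animals_per_group", 2))
    n_sections = int(blk.pop("n_sections", 1))
    write_images = bool(blk.pop("write_images", False))
    if "image_shape" in blk:
        blk["image_shape"] = tuple(blk["image_shape"])
    n_cells = int(blk.pop("n_cells", 12))
    base_density = float(blk.pop("boutons_per_100um", 5.0))
    ctx["morph_images"] = []
    for gi, (label, density_scale) in enumerate(sorted(groups.items())):
        for a in range(n_animals):
            animal = f"{label}{a}"
            for sec in range(n_sections):
                icfg = ImageSimConfig(
                    boutons_per_100um=base_density * float(density_scale),
                    n_cells=0,
                    seed=_child_seed(rc.seed, 2, gi, a, sec),
                    **blk,
                )
                img, gt = simulate_morphology_image(icfg)
                if write_images:
                    img.to_tiff(out / f"section_{animal}_c{sec}.tif")
                ctx["morph_images"].append(
                    {"animal": animal, "group": label, "region": "cortex",
                     "section": sec, "image": img, "truth": gt}
                )
            mb_kwargs = dict(blk)
            mb_kwargs.update(n_axons=0, boutons_per_100um=0.0,
                             n_cells=n_cells,
                             seed=_child_seed(rc.seed, 3, gi, a))
            mcfg = ImageSimConfig(**mb_kwargs)
            mimg, mgt = simulate_morphology_image(mcfg)
            if write_images:
                mimg.to_tiff(out / f"section_{animal}_mb.tif")
            ctx["morph_images"].append(
                {"animal": animal, "group": label, "region": "midbrain",
                 "section": 0, "image": mimg, "truth": mgt}
            )
    ctx["morph_groups"] = sorted(groups)


def _stage_morphology(rc: RunConfig, ctx: dict, out: Path) -> None:
    rows = []
    for rec in ctx["morph_images"]:
        img = rec["image"]
        if rec["region"] == "cortex":
            _, n_boutons = detect_boutons(img)
            _, length = detect_axons(img)
            n_cells = 0
        else:
            n_boutons, length = 0, 0.0
            _, n_cells = count_cells(img)
        rows.append(
            {"animal": rec["animal"], "group": rec["group"],
             "region": rec["region"], "section": rec["section"],
             "bouton_count": n_boutons, "axon_length_um": length,
             "cell_count": n_cells}
        )
    sections = pd.DataFrame(rows)
    _write_csv(sections, out / "morphology_sections.csv")
    control = ctx["morph_groups"][0]
    per_animal, summary = normalize_metrics(sections, control_group=control)
    _write_csv(per_animal, out / "morphology_per_animal.csv")
    _write_csv(summary, out / "morphology_groups.csv")
    ctx["morphology"] = {"sections": sections, "per_animal": per_animal,
                         "summary": summary, "control": control}


def _stage_report(rc: RunConfig, ctx: dict, out: Path) -> None:
    outputs: dict[str, list[GroupSample]] = {}
    if "behavior" in ctx:
        by_group: dict[str, list[float]] = {}
        entries_by_group: dict[str, list[float]] = {}
        for (label, _), beh in sorted(ctx["behavior"].items()):
            if not beh["score"].insufficient:
                by_group.setdefault(label, []).append(beh["score"].percent)
            entries_by_group.setdefault(label, []).append(
                float(beh["score"].n_entries)
            )
        outputs["alternation_percent"] = [
            GroupSample(g, v) for g, v in sorted(by_group.items())
        ]
        outputs["total_entries"] = [
            GroupSample(g, v) for g, v in sorted(entries_by_group.items())
        ]
    if "morphology" in ctx:
        pa = ctx["morphology"]["per_animal"]
        ok = pa[~pa.excluded]
        outputs["bouton_density_pct_ctrl"] = [
            GroupSample(g, sub.bouton_density_pct_ctrl.to_numpy())
            for g, sub in ok.groupby("group")
        ]
    stats_report(outputs, out_dir=out)
    ctx["report"] = outputs


_STAGE_FUNCS: dict[str, Callable] = {
    "simulate_behavior": _stage_simulate_behavior,
    "behavior": _stage_behavior,
    "simulate_traces": _stage_simulate_traces,
    "events": _stage_events,
    "ensemble": _stage_ensemble,
    "simulate_morphology": _stage_simulate_morphology,
    "morphology": _stage_morphology,
    "report": _stage_report,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config, out_dir) -> Path:
    """Execute a full run; returns the run directory.

    Validation happens before any stage executes.  On a stage failure a
    partial manifest with a failure record is still written, then the error
    propagates.
    """
    rc = validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx: dict = {}
    failure = None
    try:
        for stage in rc.stages:
            _STAGE_FUNCS[stage](rc, ctx, out)
    except Exception as exc:
        failure = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        files = sorted(
            p for p in out.rglob("*")
            if p.is_file() and p.name not in ("manifest.json", "log.json")
        )
        manifest = {
            "config_hash": rc.hash,
            "seed": rc.seed,
            "stages": rc.stages,
            "version": __version__,
            "failure": failure,
            "files": {str(p.relative_to(out)): _sha256(p) for p in files},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        with open(out / "log.json", "w") as fh:
            json.dump({"seed": rc.seed, "config": rc.raw,
                       "config_hash": rc.hash, "failure": failure},
                      fh, indent=1, sort_keys=True, default=str)
    return out
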