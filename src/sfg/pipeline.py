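"""End-to-end run: generate stimuli, simulate sessions, analyse, manifest.

Every stage derives its RNG from the master seed, so re-running an
identical configuration reproduces every CSV/JSON byte (and WAV bit)
exactly.  A ``state.json`` marker records completed stages; a crashed run
can be resumed without redoing finished work.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import io as sfg_io
from .analysis import DetectionModel
from .config import RunConfig, save_config
from .session import simulate_session
from .stimgen import (
    ChordTimebase,
    StimulusSpec,
    build_frequency_pool,
    generate_stimulus_set,
)

__all__ = ["run_end_to_end"]

_STAGES = ("stimuli", "sessions", "analysis")


def _stage_seeds(master_seed: int) -> dict[str, int]:
    """Independent per-stage seeds derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0]) for stage, child in zip(_STAGES, children)
    }


def _load_state(out_dir: Path) -> dict:
    state_path = out_dir / "state.json"
    if state_path.exists():
        with open(state_path) as fh:
            return json.load(fh)
    return {"completed": []}


def _mark_done(out_dir: Path, state: dict, stage: str) -> None:
    state["completed"].append(stage)
    with open(out_dir / "state.json", "w") as fh:
        json.dump(state, fh, indent=1)


def run_end_to_end(config: RunConfig, resume: bool = True) -> dict:
    """Execute a full reproducible run; returns a summary of artifacts.

    Stages: (1) stimulus generation (WAV + sidecars + manifest CSV),
    (2) K simulated sessions (CSV logs + JSON headers), (3) behavioural
    analysis (per-coherence summary CSV, ANOVA report JSON, plots).  With
    ``n_sessions == 0`` the analysis is skipped with a notice.  Finishes
    by writing a checksum manifest over all documented outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # resolved copy is written inside out_dir, so record the location as "."
    # to keep the file (and its checksum) independent of where the run lives
    save_config(dataclasses.replace(config, out_dir="."), out_dir / "config.resolved.yaml")
    seeds = _stage_seeds(config.seed)
    state = _load_state(out_dir) if resume else {"completed": []}
    outputs: list[Path] = [out_dir / "config.resolved.yaml"]
    notices: list[str] = []

    # -- stimuli ------------------------------------------------------------
    stim_dir = out_dir / "stimuli"
    sc = config.stimuli
    if "stimuli" not in state["completed"]:
        pool = build_frequency_pool(sc.f_min, sc.f_max, sc.steps_per_octave)
        timebase = ChordTimebase(sc.chord_duration, sc.ramp_duration, sc.sample_rate)
        template = (
            StimulusSpec.behavioural("figure", coherence=sc.coherence_levels[0],
                                     figure_len_chords=sc.figure_len_chords)
            if sc.variant == "behavioural"
            else StimulusSpec.imaging("figure")
        )
        stimuli = generate_stimulus_set(
            sc.n_per_condition, template,
            rng=np.random.default_rng(seeds["stimuli"]),
            coherence_levels=sc.coherence_levels if sc.variant == "behavioural" else None,
            pool=pool, timebase=timebase,
        )
        sfg_io.write_stimulus_set(stimuli, stim_dir, float32=sc.float32_wav)
        _mark_done(out_dir, state, "stimuli")
    outputs += sorted(stim_dir.glob("*.json")) + [stim_dir / "stimuli.csv"]
    outputs += sorted(stim_dir.glob("*.wav"))

    # -- sessions -----------------------------------------------------------
    sess_dir = out_dir / "sessions"
    if config.n_sessions > 0 and "sessions" not in state["completed"]:
        rng = np.random.default_rng(seeds["sessions"])
        for i in range(config.n_sessions):
            session = simulate_session(
                config.task, config.observer, f"s{i:03d}", rng
            )
            sfg_io.write_session(session, sess_dir)
        _mark_done(out_dir, state, "sessions")
    if config.n_sessions > 0:
        outputs += sorted(sess_dir.glob("*.csv")) + sorted(sess_dir.glob("*.json"))

    # -- analysis -----------------------------------------------------------
    results = None
    if config.n_sessions > 0:
        ana_dir = out_dir / "analysis"
        if "analysis" not in state["completed"]:
            ana_dir.mkdir(parents=True, exist_ok=True)
            ac = config.analysis
            sessions = [sfg_io.read_session(p) for p in sorted(sess_dir.glob("*.csv"))]
            model = DetectionModel(
                sessions,
                output_latency=ac.output_latency,
                exclude_below=ac.exclude_below,
                sphericity_alpha=ac.sphericity_alpha,
                correction=ac.correction,
            )
            results = model.fit(n_boot=ac.n_boot, ci_level=ac.ci_level,
                                rng=np.random.default_rng(seeds["analysis"]))
            results.table.to_csv(ana_dir / "summary_by_coherence.csv", index=False)
            with open(ana_dir / "anova.json", "w") as fh:
                json.dump(results.anova_report(), fh, indent=1, sort_keys=True)
            with open(ana_dir / "summary.txt", "w") as fh:
                fh.write(results.summary() + "\n")
            try:
                from .plotting import save_standard_figures
                save_standard_figures(results, sessions, ana_dir,
                                      rt_bin_width=ac.rt_bin_width)
            except Exception as exc:          # plotting must never void a run
                notices.append(f"plotting failed: {exc}")
            _mark_done(out_dir, state, "analysis")
        outputs += [ana_dir / "summary_by_coherence.csv", ana_dir / "anova.json",
                    ana_dir / "summary.txt"]
        outputs += sorted(ana_dir.glob("*.png"))
    else:
        notices.append("n_sessions = 0: stimuli only, analysis skipped")

    manifest_path = sfg_io.write_manifest(out_dir, [p for p in outputs if p.exists()])
    return {
        "out_dir": str(out_dir),
        "manifest": str(manifest_path),
        "stage_seeds": seeds,
        "notices": notices,
        "results": results,
    }
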