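"""File formats: WAV audio, stimulus sidecars/manifests, session logs.

All text outputs are deterministic for a fixed run so that checksums can
certify reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .session import SessionData, TaskDesign, ObserverParams, TRIAL_COLUMNS
from .stimgen import Stimulus

__all__ = [
    "write_wav",
    "write_stimulus",
    "write_stimulus_set",
    "write_session",
    "read_session",
    "sha256_of",
    "write_manifest",
]


def write_wav(path, samples: np.ndarray, sample_rate: float, float32: bool = False) -> None:
    """Write a mono RIFF WAV at the given rate (16-bit PCM by default)."""
    path = Path(path)
    if float32:
        wavfile.write(path, int(sample_rate), samples.astype(np.float32))
    else:
        clipped = np.clip(samples, -1.0, 1.0)
        wavfile.write(path, int(sample_rate), np.round(clipped * 32767).astype(np.int16))


def _spec_dict(stim: Stimulus) -> dict:
    d = dataclasses.asdict(stim.spec)
    if d.get("figure_channels") is not None:
        d["figure_channels"] = list(d["figure_channels"])
    if isinstance(d.get("elements_per_chord"), tuple):
        d["elements_per_chord"] = list(d["elements_per_chord"])
    return d


def write_stimulus(stim: Stimulus, out_dir, stimulus_id: str, float32: bool = False) -> dict:
    """Write one stimulus (WAV + JSON sidecar); returns its manifest row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wav_path = out_dir / f"{stimulus_id}.wav"
    if len(stim.samples):
        write_wav(wav_path, stim.samples, stim.sample_rate, float32)
    sidecar = {
        "stimulus_id": stimulus_id,
        "spec": _spec_dict(stim),
        "scale": stim.scale,
        "sample_rate": stim.sample_rate,
        "duration": stim.duration,
    }
    with open(out_dir / f"{stimulus_id}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    spec = stim.spec
    onset_s = (
        None if spec.figure_onset_chord is None else spec.figure_onset_chord * 0.05
    )
    return {
        "stimulus_id": stimulus_id,
        "condition": spec.condition,
        "coherence": spec.coherence,
        "onset_s": onset_s,
        "seed": spec.seed,
        "wav_path": wav_path.name if len(stim.samples) else "",
    }


def write_stimulus_set(stimuli: list[Stimulus], out_dir, float32: bool = False) -> pd.DataFrame:
    """Write a stimulus set plus its CSV manifest; returns the manifest."""
    out_dir = Path(out_dir)
    rows = [
        write_stimulus(s, out_dir, f"stim{i:04d}_{s.spec.condition}", float32)
        for i, s in enumerate(stimuli)
    ]
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "stimuli.csv", index=False)
    return manifest


def write_session(session: SessionData, out_dir) -> Path:
    """Write a session log (CSV trials + JSON header); returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{session.session_id}.csv"
    session.to_dataframe().to_csv(csv_path, index=False)
    header = {
        "session_id": session.session_id,
        "subject_id": session.subject_id,
        "n_trials": len(session),
        "design": dataclasses.asdict(session.design),
        "observer": dataclasses.asdict(session.observer) if session.observer else None,
    }
    with open(out_dir / f"{session.session_id}.json", "w") as fh:
        json.dump(header, fh, indent=1, sort_keys=True)
    return csv_path


def read_session(csv_path) -> SessionData:
    """Read a session log written by :func:`write_session` (or compatible CSV)."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session log {csv_path} lacks columns: {missing}")
    design, observer = TaskDesign(), None
    header_path = csv_path.with_suffix(".json")
    if header_path.exists():
        with open(header_path) as fh:
            header = json.load(fh)
        d = dict(header.get("design") or {})
        for key in ("coherence_levels", "onset_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        design = TaskDesign(**d)
        if header.get("observer"):
            observer = ObserverParams(**header["observer"])
    session = SessionData.from_dataframe(df, design, observer)
    if "session_id" not in df.columns:
        session.session_id = csv_path.stem
    return session


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(out_dir, files: list[Path]) -> Path:
    """Checksum manifest covering every documented output file."""
    out_dir = Path(out_dir)
    manifest = {
        str(Path(f).relative_to(out_dir)): sha256_of(f) for f in sorted(files)
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path
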