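"""Stochastic figure-ground (SFG) stimulus synthesis.

An SFG stimulus is a sequence of short multi-tone chords.  Each chord is a
sum of pure tones drawn from a fixed log-spaced frequency pool ("ground"
elements).  In *figure* stimuli a subset of frequency channels repeats
identically across a window of consecutive chords; this temporally coherent
component ("figure") is the detection target.  Control stimuli contain only
random ground elements.

Two stimulus recipes are implemented:

behavioural
    60 chords (3 s), a fixed 15 elements in every chord.  Figure elements
    *replace* ground elements ("incorporated"), so every chord carries
    exactly 15 tones regardless of condition or coherence — the per-chord
    energy carries no cue to the figure.

imaging
    120 chords (6 s), a random 5-15 ground elements per chord.  From chord
    40 for 40 chords (2 s), 10 extra elements are *appended on top* of the
    ground: the same 10 channels every chord (figure) or 10 freshly drawn
    channels per chord (control).  Per-chord element counts rise during the
    window in both conditions.

All randomness flows through a caller-supplied :class:`numpy.random.Generator`
or the seed recorded in the :class:`StimulusSpec`, so any stimulus can be
regenerated bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FrequencyPool",
    "ChordTimebase",
    "StimulusSpec",
    "ElementMatrix",
    "Stimulus",
    "build_frequency_pool",
    "sample_ground_chord",
    "make_behavioural_stimulus",
    "make_imaging_stimulus",
    "build_element_matrix",
    "synthesize_waveform",
    "generate_stimulus_set",
]

#: Default pool bounds and spacing (Hz, steps per octave).
DEFAULT_F_MIN = 179.0
DEFAULT_F_MAX = 7246.0
DEFAULT_STEPS_PER_OCTAVE = 24

#: Behavioural recipe constants.
BEHAV_N_CHORDS = 60
BEHAV_ELEMENTS_PER_CHORD = 15
BEHAV_COHERENCES = (4, 6, 8, 10, 12)
BEHAV_FIGURE_LEN_CHORDS = 20          # 1 s figure at 50-ms chords
BEHAV_ONSET_CHORD_RANGE = (6, 40)     # 0.3-2.0 s, inclusive, on chord grid

#: Imaging recipe constants.
IMAGING_N_CHORDS = 120
IMAGING_ELEMENTS_RANGE = (5, 15)
IMAGING_COHERENCE = 10
IMAGING_ONSET_CHORD = 40
IMAGING_FIGURE_LEN_CHORDS = 40


class ParameterError(ValueError):
    """Invalid stimulus parameterization."""


@dataclass(frozen=True)
class FrequencyPool:
    """Fixed lattice of allowable tone frequencies.

    Frequencies form an ascending geometric series starting at ``f_min``
    with ratio ``2**(1/steps_per_octave)``, truncated at the last term
    not exceeding ``f_max``.
    """

    frequencies: np.ndarray
    f_min: float
    f_max: float
    steps_per_octave: int

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if f.ndim != 1 or len(f) < 1:
            raise ParameterError("frequency pool must be a non-empty 1-d array")
        ratios = f[1:] / f[:-1]
        expected = 2.0 ** (1.0 / self.steps_per_octave)
        if len(f) > 1 and not np.allclose(ratios, expected, rtol=1e-9):
            raise ParameterError("pool spacing is not a constant fraction of an octave")

    def __len__(self) -> int:
        return len(self.frequencies)


def build_frequency_pool(
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    steps_per_octave: int = DEFAULT_STEPS_PER_OCTAVE,
) -> FrequencyPool:
    """Build the log-spaced tone-frequency pool.

    The pool is the geometric series ``f_min * 2**(k/steps_per_octave)``
    for ``k = 0, 1, 2, ...`` truncated at the last term ``<= f_max``.  With
    the default bounds (179-7246 Hz, 24 steps/octave) this yields exactly
    129 frequencies.  Note the printed endpoints are not a whole number of
    1/24-octave steps apart, so the topmost pool entry falls slightly below
    the nominal upper bound; generating upward from ``f_min`` keeps the
    inter-element spacing exact.
    """
    if not (0 < f_min < f_max):
        raise ParameterError(f"require 0 < f_min < f_max, got ({f_min}, {f_max})")
    if steps_per_octave < 1:
        raise ParameterError(f"steps_per_octave must be >= 1, got {steps_per_octave}")
    # Tolerate float rounding when the bounds are an exact number of steps apart.
    k_max = int(np.floor(steps_per_octave * np.log2(f_max / f_min) * (1 + 1e-12)))
    k = np.arange(k_max + 1)
    freqs = f_min * 2.0 ** (k / steps_per_octave)
    return FrequencyPool(freqs, f_min=f_min, f_max=f_max, steps_per_octave=steps_per_octave)


@dataclass(frozen=True)
class ChordTimebase:
    """Temporal layout of one chord: duration, on/off ramp, sample rate."""

    chord_duration: float = 0.05
    ramp_duration: float = 0.01
    sample_rate: float = 44100.0

    def __post_init__(self) -> None:
        if 2 * self.ramp_duration > self.chord_duration:
            raise ParameterError("onset+offset ramps exceed chord duration")
        n = self.chord_duration * self.sample_rate
        if abs(n - round(n)) > 1e-9:
            raise ParameterError("chord duration must span an integer number of samples")

    @property
    def samples_per_chord(self) -> int:
        return int(round(self.chord_duration * self.sample_rate))

    @property
    def ramp_samples(self) -> int:
        return int(round(self.ramp_duration * self.sample_rate))


@dataclass(frozen=True)
class StimulusSpec:
    """Symbolic description of one stimulus; sufficient for bit-exact regeneration."""

    variant: str                       # "behavioural" | "imaging"
    condition: str                     # "figure" | "control"
    n_chords: int
    coherence: int = 0                 # figure channels; 0 for control
    figure_onset_chord: int | None = None
    figure_len_chords: int = 0
    elements_per_chord: int | tuple[int, int] = BEHAV_ELEMENTS_PER_CHORD
    figure_channels: tuple[int, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("behavioural", "imaging"):
            raise ParameterError(f"unknown variant {self.variant!r}")
        if self.condition not in ("figure", "control"):
            raise ParameterError(f"unknown condition {self.condition!r}")
        if self.condition == "figure":
            if self.coherence < 1:
                raise ParameterError("figure condition requires coherence >= 1")
            if self.figure_len_chords < 1:
                raise ParameterError("figure condition requires a figure window")
            if self.figure_onset_chord is not None and (
                self.figure_onset_chord + self.figure_len_chords > self.n_chords
            ):
                raise ParameterError("figure window extends past the stimulus")
        if self.variant == "behavioural":
            if not isinstance(self.elements_per_chord, int):
                raise ParameterError("behavioural variant uses a fixed element count")
            if self.condition == "figure" and self.coherence > self.elements_per_chord:
                raise ParameterError(
                    f"coherence {self.coherence} exceeds the {self.elements_per_chord} "
                    "elements available per chord"
                )

    @classmethod
    def behavioural(
        cls,
        condition: str,
        coherence: int = 0,
        figure_onset_chord: int | None = None,
        figure_len_chords: int = BEHAV_FIGURE_LEN_CHORDS,
        seed: int | None = None,
    ) -> "StimulusSpec":
        """Behavioural recipe: 60 chords, 15 elements each, incorporated figure."""
        return cls(
            variant="behavioural",
            condition=condition,
            n_chords=BEHAV_N_CHORDS,
            coherence=coherence if condition == "figure" else 0,
            figure_onset_chord=figure_onset_chord,
            figure_len_chords=figure_len_chords if condition == "figure" else 0,
            elements_per_chord=BEHAV_ELEMENTS_PER_CHORD,
            seed=seed,
        )

    @classmethod
    def imaging(cls, condition: str, seed: int | None = None) -> "StimulusSpec":
        """Imaging recipe: 120 chords, 5-15 ground elements, 10 appended in chords 40-79."""
        return cls(
            variant="imaging",
            condition=condition,
            n_chords=IMAGING_N_CHORDS,
            coherence=IMAGING_COHERENCE if condition == "figure" else 0,
            figure_onset_chord=IMAGING_ONSET_CHORD,
            figure_len_chords=IMAGING_FIGURE_LEN_CHORDS,
            elements_per_chord=IMAGING_ELEMENTS_RANGE,
            seed=seed,
        )


@dataclass(frozen=True)
class ElementMatrix:
    """Chord-by-channel occupancy of a stimulus.

    ``occupancy[i, j]`` is True when pool frequency ``i`` sounds in chord
    ``j``.  ``figure_mask`` marks elements belonging to the coherent figure;
    ``appended_mask`` marks elements added on top of the ground layer
    (imaging variant only; includes both coherent and shuffled extras).
    The ground layer is ``occupancy & ~appended_mask & ~figure_mask``.
    """

    occupancy: np.ndarray
    figure_mask: np.ndarray
    appended_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        fig = np.asarray(self.figure_mask, dtype=bool)
        app = self.appended_mask
        app = np.zeros_like(occ) if app is None else np.asarray(app, dtype=bool)
        if occ.shape != fig.shape or occ.shape != app.shape:
            raise ParameterError("occupancy/figure/appended masks must share a shape")
        if np.any(fig & ~occ) or np.any(app & ~occ):
            raise ParameterError("figure/appended masks must be subsets of occupancy")
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "figure_mask", fig)
        object.__setattr__(self, "appended_mask", app)

    @property
    def n_chords(self) -> int:
        return self.occupancy.shape[1]

    @property
    def pool_size(self) -> int:
        return self.occupancy.shape[0]

    @property
    def ground_mask(self) -> np.ndarray:
        return self.occupancy & ~self.appended_mask & ~self.figure_mask

    def elements_per_chord(self) -> np.ndarray:
        """Total element count in each chord."""
        return self.occupancy.sum(axis=0)

    def ground_elements_per_chord(self) -> np.ndarray:
        """Ground-layer element count in each chord (appended/figure excluded)."""
        return self.ground_mask.sum(axis=0)


@dataclass(frozen=True)
class Stimulus:
    """A rendered stimulus: spec, element matrix, waveform and metadata."""

    spec: StimulusSpec
    matrix: ElementMatrix
    samples: np.ndarray
    sample_rate: float
    scale: float          # global factor applied to the raw tone sum

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def raw_samples(self) -> np.ndarray:
        """Waveform before global normalization (unit-amplitude tone sum)."""
        return self.samples / self.scale

    def per_chord_rms(self, raw: bool = True) -> np.ndarray:
        """Root-mean-square level of each chord.

        With ``raw=True`` the per-file normalization constant is divided
        out, so levels are comparable across stimuli.
        """
        x = self.raw_samples() if raw else self.samples
        return np.sqrt((x.reshape(self.matrix.n_chords, -1) ** 2).mean(axis=1))


def _as_rng(rng: np.random.Generator | int | None, seed: int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is not None:
        return np.random.default_rng(rng)
    return np.random.default_rng(seed)


def sample_ground_chord(
    pool: FrequencyPool,
    n_elements: int,
    excluded: Iterable[int] = (),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n_elements`` distinct pool indices uniformly, avoiding ``excluded``.

    Returns a sorted integer array of channel indices.
    """
    rng = _as_rng(rng, None)
    excluded = np.asarray(sorted(set(excluded)), dtype=int)
    available = np.setdiff1d(np.arange(len(pool)), excluded, assume_unique=True)
    if n_elements > len(available):
        raise ParameterError(
            f"cannot draw {n_elements} elements from {len(available)} available channels"
        )
    return np.sort(rng.choice(available, size=n_elements, replace=False))


def build_element_matrix(
    spec: StimulusSpec,
    pool: FrequencyPool,
    rng: np.random.Generator | None = None,
) -> tuple[ElementMatrix, StimulusSpec]:
    """Sample the chord-by-channel occupancy for ``spec``.

    Returns the matrix together with a resolved copy of the spec in which
    any deferred random choices (behavioural figure onset, figure channels)
    have been filled in.
    """
    rng = _as_rng(rng, spec.seed)
    if spec.variant == "behavioural":
        return _behavioural_matrix(spec, pool, rng)
    return _imaging_matrix(spec, pool, rng)


def _behavioural_matrix(
    spec: StimulusSpec, pool: FrequencyPool, rng: np.random.Generator
) -> tuple[ElementMatrix, StimulusSpec]:
    n_el = spec.elements_per_chord
    occ = np.zeros((len(pool), spec.n_chords), dtype=bool)
    fig = np.zeros_like(occ)

    if spec.condition == "figure":
        onset = spec.figure_onset_chord
        if onset is None:
            lo, hi = BEHAV_ONSET_CHORD_RANGE
            hi = min(hi, spec.n_chords - spec.figure_len_chords)
            onset = int(rng.integers(lo, hi + 1))
        if spec.figure_channels is not None:
            channels = np.asarray(spec.figure_channels, dtype=int)
        else:
            channels = sample_ground_chord(pool, spec.coherence, rng=rng)
        window = range(onset, onset + spec.figure_len_chords)
        for j in range(spec.n_chords):
            if j in window:
                # figure channels replace ground elements: totals stay at n_el
                occ[channels, j] = True
                fig[channels, j] = True
                ground = sample_ground_chord(pool, n_el - spec.coherence, channels, rng)
            else:
                ground = sample_ground_chord(pool, n_el, rng=rng)
            occ[ground, j] = True
        spec = replace(
            spec, figure_onset_chord=onset, figure_channels=tuple(int(c) for c in channels)
        )
    else:
        for j in range(spec.n_chords):
            occ[sample_ground_chord(pool, n_el, rng=rng), j] = True

    return ElementMatrix(occ, fig), spec


def _imaging_matrix(
    spec: StimulusSpec, pool: FrequencyPool, rng: np.random.Generator
) -> tuple[ElementMatrix, StimulusSpec]:
    lo, hi = spec.elements_per_chord
    onset = spec.figure_onset_chord if spec.figure_onset_chord is not None else IMAGING_ONSET_CHORD
    n_extra = spec.coherence if spec.condition == "figure" else IMAGING_COHERENCE
    # control stimuli receive shuffled extras in the same window as figures
    window_len = spec.figure_len_chords or IMAGING_FIGURE_LEN_CHORDS
    window = range(onset, onset + window_len)

    occ = np.zeros((len(pool), spec.n_chords), dtype=bool)
    fig = np.zeros_like(occ)
    app = np.zeros_like(occ)

    if spec.condition == "figure":
        if spec.figure_channels is not None:
            channels = np.asarray(spec.figure_channels, dtype=int)
        else:
            channels = sample_ground_chord(pool, n_extra, rng=rng)
        spec = replace(spec, figure_channels=tuple(int(c) for c in channels))
    else:
        channels = None

    for j in range(spec.n_chords):
        n_ground = int(rng.integers(lo, hi + 1))
        if j in window:
            if channels is not None:
                # coherent extras: same channels every chord; ground avoids them
                # so an element is never doubled within a chord
                ground = sample_ground_chord(pool, n_ground, channels, rng)
                extra = channels
                fig[extra, j] = True
            else:
                ground = sample_ground_chord(pool, n_ground, rng=rng)
                extra = sample_ground_chord(pool, n_extra, ground, rng)
            occ[ground, j] = True
            occ[extra, j] = True
            app[extra, j] = True
        else:
            occ[sample_ground_chord(pool, n_ground, rng=rng), j] = True

    return ElementMatrix(occ, fig, app), spec


def synthesize_waveform(
    matrix: ElementMatrix,
    pool: FrequencyPool,
    timebase: ChordTimebase | None = None,
    scale: float | None = None,
) -> tuple[np.ndarray, float]:
    """Render an element matrix to audio samples.

    Every occupied cell contributes one unit-amplitude pure tone at its
    pool frequency lasting one chord, gated by a raised-cosine onset and
    offset ramp; chords are concatenated without crossfade.  The summed
    waveform is multiplied by a single global ``scale`` — by default
    ``1/max|x|`` so the peak is exactly full-scale — and both the samples
    and the scale used are returned, so relative chord levels can always
    be recovered.
    """
    timebase = timebase or ChordTimebase()
    if matrix.pool_size != len(pool):
        raise ParameterError(
            f"matrix has {matrix.pool_size} channels but pool has {len(pool)}"
        )
    n = timebase.samples_per_chord
    nr = timebase.ramp_samples
    t = np.arange(n) / timebase.sample_rate
    env = np.ones(n)
    if nr > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] = ramp
        env[-nr:] = ramp[::-1]

    out = np.zeros(matrix.n_chords * n)
    for j in range(matrix.n_chords):
        freqs = pool.frequencies[matrix.occupancy[:, j]]
        if len(freqs) == 0:
            continue
        chord = np.sin(2.0 * np.pi * np.outer(freqs, t)).sum(axis=0)
        out[j * n : (j + 1) * n] = env * chord

    if scale is None:
        peak = np.abs(out).max()
        scale = 1.0 / peak if peak > 0 else 1.0
    return out * scale, float(scale)


def _make_stimulus(
    spec: StimulusSpec,
    rng: np.random.Generator | None,
    pool: FrequencyPool | None,
    timebase: ChordTimebase | None,
    render: bool,
) -> Stimulus:
    pool = pool or build_frequency_pool()
    timebase = timebase or ChordTimebase()
    matrix, resolved = build_element_matrix(spec, pool, rng)
    if render:
        samples, scale = synthesize_waveform(matrix, pool, timebase)
    else:
        samples, scale = np.zeros(0), 1.0
    return Stimulus(resolved, matrix, samples, timebase.sample_rate, scale)


def make_behavioural_stimulus(
    spec: StimulusSpec,
    rng: np.random.Generator | None = None,
    pool: FrequencyPool | None = None,
    timebase: ChordTimebase | None = None,
    render: bool = True,
) -> Stimulus:
    """Sample and render one behavioural-variant stimulus.

    Figure elements are incorporated into the 15-element chords (they
    replace ground elements), so figure and control stimuli are matched in
    per-chord element count and hence in sound level.
    """
    if spec.variant != "behavioural":
        raise ParameterError("spec.variant must be 'behavioural'")
    return _make_stimulus(spec, rng, pool, timebase, render)


def make_imaging_stimulus(
    spec: StimulusSpec,
    rng: np.random.Generator | None = None,
    pool: FrequencyPool | None = None,
    timebase: ChordTimebase | None = None,
    render: bool = True,
) -> Stimulus:
    """Sample and render one imaging-variant stimulus.

    Ten extra elements per chord are appended on top of the 5-15-element
    ground during chords 40-79: the same ten channels throughout the window
    (figure) or ten freshly drawn channels per chord (control).
    """
    if spec.variant != "imaging":
        raise ParameterError("spec.variant must be 'imaging'")
    return _make_stimulus(spec, rng, pool, timebase, render)


def generate_stimulus_set(
    n_per_condition: int,
    spec_template: StimulusSpec,
    rng: np.random.Generator | int | None = None,
    coherence_levels: Sequence[int] | None = None,
    pool: FrequencyPool | None = None,
    timebase: ChordTimebase | None = None,
    render: bool = True,
) -> list[Stimulus]:
    """Generate ``n_per_condition`` figure and control stimuli.

    For behavioural sets a list of ``coherence_levels`` may be given;
    figure stimuli then cycle through the levels.  Each stimulus receives
    its own recorded seed drawn from the master RNG, so any single stimulus
    can be regenerated bit-exactly from its spec alone.
    """
    if n_per_condition < 1:
        raise ParameterError("n_per_condition must be >= 1")
    rng = _as_rng(rng, None)
    maker = (
        make_behavioural_stimulus
        if spec_template.variant == "behavioural"
        else make_imaging_stimulus
    )
    stimuli: list[Stimulus] = []
    for condition in ("figure", "control"):
        for i in range(n_per_condition):
            changes: dict = {"condition": condition, "seed": int(rng.integers(0, 2**63))}
            if condition == "control":
                changes.update(coherence=0, figure_len_chords=0,
                               figure_onset_chord=None, figure_channels=None)
            else:
                if coherence_levels is not None:
                    changes["coherence"] = int(coherence_levels[i % len(coherence_levels)])
                elif spec_template.coherence < 1:
                    changes["coherence"] = (
                        IMAGING_COHERENCE
                        if spec_template.variant == "imaging"
                        else BEHAV_COHERENCES[i % len(BEHAV_COHERENCES)]
                    )
                if spec_template.figure_len_chords < 1:
                    changes["figure_len_chords"] = (
                        IMAGING_FIGURE_LEN_CHORDS
                        if spec_template.variant == "imaging"
                        else BEHAV_FIGURE_LEN_CHORDS
                    )
            spec = replace(spec_template, **changes)
            stimuli.append(maker(spec, pool=pool, timebase=timebase, render=render))
    return stimuli
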