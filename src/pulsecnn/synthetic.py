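"""Synthetic arterial pulse-wave generator.

Real radial pulse recordings (cuff/tonometry devices) are rarely shareable, so
this module emulates the statistical structure the rest of the pipeline
assumes: multi-cycle pressure-like records built from the three classical
sub-waves of one arterial cycle — the percussion wave (main systolic peak),
the tidal wave (late-systolic reflection) and the dicrotic wave (diastolic
rebound) — each modelled as a Gaussian bump on the unit cycle.  Class-specific
morphologies (healthy, hypertensive, atherosclerotic, ...) are encoded as
component parameter sets; per-cycle jitter reproduces the "local time
shifting" that makes template matching brittle; additive white noise and a
low-frequency sinusoidal baseline wander exercise the wavelet denoiser.

Cohort generation attaches disease labels and physiological parameters
(blood pressure, CAVI, baPWV, blood viscosity) consistent with each subject's
intended pattern, including comorbid subjects that downstream screening must
exclude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PulseComponentSpec",
    "Jitter",
    "PulseClassSpec",
    "SubjectProfile",
    "RawPulseSignal",
    "DATASET1_SPECS",
    "DATASET2_SPECS",
    "CLASS_SPECS",
    "DISEASE_FOR_PATTERN",
    "OUT_OF_RANGE_FOR_PATTERN",
    "IN_RANGES",
    "OUT_RANGES",
    "snr_db_to_noise_sd",
    "generate_cycle",
    "generate_record",
    "generate_cohort",
]

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PulseComponentSpec:
    """One Gaussian sub-wave of a pulse cycle.

    Parameters are relative to the cycle: ``center`` and ``width`` are
    fractions of the cycle duration, ``amplitude`` is relative to the
    percussion peak (so the percussion component has amplitude 1).
    """

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if not self.amplitude >= 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not 0 < self.center < 1:
            raise ValueError(f"center must lie in (0, 1), got {self.center}")
        if not 0 < self.width < 0.5:
            raise ValueError(f"width must lie in (0, 0.5), got {self.width}")


@dataclass(frozen=True)
class Jitter:
    """Relative standard deviations applied per component draw."""

    amplitude: float = 0.0
    center: float = 0.0
    width: float = 0.0


@dataclass(frozen=True)
class PulseClassSpec:
    """Mean morphology + variability of one pulse-wave pattern.

    ``components`` are ordered percussion, tidal, dicrotic; the percussion
    amplitude must be the maximum so every cycle has a dominant systolic peak.
    """

    label: str
    components: tuple[PulseComponentSpec, ...]
    jitter: Jitter = Jitter()
    cycle_duration_s: tuple[float, float] = (0.8, 0.08)  # mean, sd

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError("a pulse class needs at least one component")
        amps = [c.amplitude for c in self.components]
        if amps[0] < max(amps):
            raise ValueError(
                "percussion (first) component must carry the maximum amplitude"
            )
        mean, sd = self.cycle_duration_s
        if mean <= 0 or sd < 0:
            raise ValueError("cycle duration mean must be > 0 and sd >= 0")


@dataclass
class RawPulseSignal:
    """A multi-cycle sampled pulse record.

    ``true_boundaries`` (cycle-start sample indices) and ``clean`` (the
    noise-free concatenated cycles) exist only for synthetic records and feed
    the segmentation / denoising oracles.
    """

    samples: np.ndarray
    fs: float
    true_boundaries: np.ndarray | None = None
    true_label: str | None = None
    subject_id: str | None = None
    clean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.true_boundaries is not None:
            b = np.asarray(self.true_boundaries, dtype=int)
            if len(b) and (np.any(np.diff(b) <= 0) or b[0] < 0 or b[-1] >= len(self.samples)):
                raise ValueError("boundaries must be strictly increasing and in range")
            self.true_boundaries = b


@dataclass
class SubjectProfile:
    """Disease labels and physiological parameters of one cohort subject."""

    subject_id: str
    diseases: frozenset[str]
    systolic: float
    diastolic: float
    cavi: float
    bapwv: float
    viscosity: float
    label: str | None = None          # intended pulse pattern (synthetic truth)
    record: RawPulseSignal | None = None

    def __post_init__(self) -> None:
        self.diseases = frozenset(self.diseases)
        if not self.systolic > self.diastolic > 0:
            raise ValueError("require systolic > diastolic > 0")
        for name in ("cavi", "bapwv", "viscosity"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive")


# ---------------------------------------------------------------------------
# Default class morphologies
# ---------------------------------------------------------------------------
#
# The mean shapes below are qualitative: a healthy cycle has a sharp percussion
# peak, a modest tidal shoulder and a clear dicrotic wave; hypertension raises
# the tidal wave toward the percussion peak; arterial stiffening broadens the
# systolic complex and flattens the dicrotic wave; hyperlipidaemia slows the
# diastolic decay; diabetes gives a narrow systolic peak with an early, merged
# dicrotic wave.  They are design defaults of this generator, not measurements.

_J1 = Jitter(amplitude=0.05, center=0.03, width=0.05)

# A real pulse cycle starts at the foot of the systolic upstroke, so every
# percussion component is onset-aligned: center = 0.02 + 2.3 * width places
# the start of the rise just after the cycle boundary for every class, and
# all components decay to (near) zero at both cycle edges so concatenated
# cycles join continuously.

DATASET1_SPECS: dict[str, PulseClassSpec] = {
    "H1": PulseClassSpec("H1", (
        PulseComponentSpec(1.00, 0.135, 0.050),
        PulseComponentSpec(0.32, 0.380, 0.095),
        PulseComponentSpec(0.26, 0.640, 0.070),
    ), _J1),
    "Hn": PulseClassSpec("Hn", (
        PulseComponentSpec(1.00, 0.158, 0.060),
        PulseComponentSpec(0.78, 0.340, 0.100),
        PulseComponentSpec(0.14, 0.680, 0.070),
    ), _J1),
    "At": PulseClassSpec("At", (
        PulseComponentSpec(1.00, 0.204, 0.080),
        PulseComponentSpec(0.52, 0.460, 0.140),
        PulseComponentSpec(0.07, 0.720, 0.080),
    ), _J1),
    "Ha": PulseClassSpec("Ha", (
        PulseComponentSpec(1.00, 0.170, 0.065),
        PulseComponentSpec(0.30, 0.420, 0.150),
        PulseComponentSpec(0.48, 0.630, 0.100),
    ), _J1),
    "Td": PulseClassSpec("Td", (
        PulseComponentSpec(1.00, 0.124, 0.045),
        PulseComponentSpec(0.18, 0.360, 0.080),
        PulseComponentSpec(0.33, 0.550, 0.060),
    ), _J1),
    "HCA": PulseClassSpec("HCA", (
        PulseComponentSpec(1.00, 0.186, 0.072),
        PulseComponentSpec(0.82, 0.410, 0.130),
        PulseComponentSpec(0.10, 0.710, 0.085),
    ), _J1),
}

# Single-parameter patterns share a near-common stiffened morphology and a
# larger jitter, so between-class differences are comparable to within-class
# variability.  This emulates the mutual interference of BP/CAVI/baPWV/BV
# patterns: a classifier should find these measurably harder than the
# disease-based classes above.
_J2 = Jitter(amplitude=0.12, center=0.05, width=0.10)

DATASET2_SPECS: dict[str, PulseClassSpec] = {
    "H2": PulseClassSpec("H2", (
        PulseComponentSpec(1.00, 0.135, 0.050),
        PulseComponentSpec(0.32, 0.380, 0.095),
        PulseComponentSpec(0.26, 0.640, 0.070),
    ), _J2),
    "BP": PulseClassSpec("BP", (
        PulseComponentSpec(1.00, 0.170, 0.065),
        PulseComponentSpec(0.70, 0.380, 0.110),
        PulseComponentSpec(0.18, 0.660, 0.075),
    ), _J2),
    "CAVI": PulseClassSpec("CAVI", (
        PulseComponentSpec(1.00, 0.170, 0.065),
        PulseComponentSpec(0.62, 0.400, 0.110),
        PulseComponentSpec(0.18, 0.660, 0.075),
    ), _J2),
    "baPWV": PulseClassSpec("baPWV", (
        PulseComponentSpec(1.00, 0.181, 0.070),
        PulseComponentSpec(0.58, 0.380, 0.110),
        PulseComponentSpec(0.18, 0.660, 0.075),
    ), _J2),
    "BV": PulseClassSpec("BV", (
        PulseComponentSpec(1.00, 0.170, 0.065),
        PulseComponentSpec(0.64, 0.380, 0.110),
        PulseComponentSpec(0.24, 0.650, 0.075),
    ), _J2),
}

CLASS_SPECS: dict[str, PulseClassSpec] = {**DATASET1_SPECS, **DATASET2_SPECS}

# Disease sets implied by each pattern label.
DISEASE_FOR_PATTERN: dict[str, frozenset[str]] = {
    "H1": frozenset(),
    "Hn": frozenset({"hypertension"}),
    "At": frozenset({"atherosclerosis"}),
    "Ha": frozenset({"hyperlipidaemia"}),
    "Td": frozenset({"type 2 diabetes"}),
    "HCA": frozenset({"hypertension", "atherosclerosis"}),
    "H2": frozenset(),
    "BP": frozenset(),
    "CAVI": frozenset(),
    "baPWV": frozenset(),
    "BV": frozenset(),
}

# Which physiological parameters each pattern pushes out of range.
OUT_OF_RANGE_FOR_PATTERN: dict[str, frozenset[str]] = {
    "H1": frozenset(), "H2": frozenset(),
    "Hn": frozenset({"bp"}), "BP": frozenset({"bp"}),
    "At": frozenset({"cavi"}), "CAVI": frozenset({"cavi"}),
    "Td": frozenset({"bapwv"}), "baPWV": frozenset({"bapwv"}),
    "Ha": frozenset({"viscosity"}), "BV": frozenset({"viscosity"}),
    "HCA": frozenset({"bp", "cavi"}),
}

# Sampling ranges on either side of the screening thresholds
# (systolic/diastolic mmHg > 140/90, CAVI > 9.0, baPWV > 1400 cm/s, BV > 5.0).
IN_RANGES = {
    "systolic": (105.0, 135.0), "diastolic": (62.0, 85.0),
    "cavi": (6.5, 8.5), "bapwv": (1100.0, 1350.0), "viscosity": (3.5, 4.7),
}
OUT_RANGES = {
    "systolic": (145.0, 180.0), "diastolic": (92.0, 105.0),
    "cavi": (9.3, 11.5), "bapwv": (1450.0, 1800.0), "viscosity": (5.3, 6.5),
}

# Abbreviations accepted in comorbidity mixes ("Td+Hn", "diabetic foot", ...).
_COMORBID_ABBREV = {
    "Hn": "hypertension",
    "At": "atherosclerosis",
    "Ha": "hyperlipidaemia",
    "Td": "type 2 diabetes",
    "HF": "heart failure",
    "diabetic foot": "diabetic foot disease",
}

_DISEASE_TO_PARAM = {
    "hypertension": "bp",
    "atherosclerosis": "cavi",
    "type 2 diabetes": "bapwv",
    "hyperlipidaemia": "viscosity",
}


# ---------------------------------------------------------------------------
# Waveform generation
# ---------------------------------------------------------------------------


def snr_db_to_noise_sd(snr_db: float) -> float:
    """Relative noise sd (fraction of clean-signal RMS) for a target SNR."""
    return 10.0 ** (-snr_db / 20.0)


# Slope-onset constant: a Gaussian bump's rise becomes detectable about
# 2.3 widths before its center, so onset = center - _ONSET_K * width.
_ONSET_K = 2.3


def _jittered(comp: PulseComponentSpec, jit: Jitter, rng: np.random.Generator,
              anchor_onset: bool = False) -> PulseComponentSpec:
    """Draw a jittered copy of a component.

    With ``anchor_onset`` (used for the percussion wave) the center is re-tied
    to the component's slope onset after the width draw: the systolic foot
    anchors a pulse cycle, so beat-to-beat variability widens or delays the
    peak without moving the start of the upstroke.
    """
    a = comp.amplitude * max(0.0, 1.0 + jit.amplitude * rng.standard_normal())
    c = float(np.clip(comp.center * (1.0 + jit.center * rng.standard_normal()), 0.02, 0.98))
    w = max(1e-3, comp.width * (1.0 + jit.width * rng.standard_normal()))
    w = min(w, 0.499)
    if anchor_onset:
        onset = comp.center - _ONSET_K * comp.width
        c = float(np.clip(onset + _ONSET_K * w, 0.02, 0.98))
    return PulseComponentSpec(a, c, w)


def generate_cycle(spec: PulseClassSpec, n_points: int, rng: np.random.Generator) -> np.ndarray:
    """One pulse cycle: sum of jittered Gaussian sub-waves on a uniform grid.

    The grid covers [0, 1) so consecutive cycles concatenate without a
    duplicated endpoint.  Deterministic for a given ``rng`` state.
    """
    if n_points < 16:
        raise ValueError(f"n_points must be >= 16, got {n_points}")
    t = np.arange(n_points) / n_points
    out = np.zeros(n_points)
    for k, comp in enumerate(spec.components):
        j = _jittered(comp, spec.jitter, rng, anchor_onset=(k == 0))
        out += j.amplitude * np.exp(-0.5 * ((t - j.center) / j.width) ** 2)
    return out


def generate_record(
    spec: PulseClassSpec,
    n_cycles: int,
    noise_sd: float = 0.0,
    wander_amplitude: float = 0.0,
    fs: float = 100.0,
    rng: np.random.Generator | None = None,
    subject_id: str | None = None,
) -> RawPulseSignal:
    """Concatenate jittered cycles and add noise plus baseline wander.

    ``noise_sd`` is the white-noise standard deviation as a fraction of the
    clean signal's RMS (so ``noise_sd = 10**(-snr/20)`` hits a target SNR in
    dB); ``wander_amplitude`` scales a 0.3 Hz sinusoid relative to the clean
    peak amplitude.
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    if rng is None:
        rng = np.random.default_rng()
    mean_s, sd_s = spec.cycle_duration_s
    durations = np.clip(rng.normal(mean_s, sd_s, size=n_cycles), 0.3, None)
    lengths = np.maximum(16, np.rint(durations * fs).astype(int))
    cycles = [generate_cycle(spec, int(n), rng) for n in lengths]
    clean = np.concatenate(cycles)
    boundaries = np.concatenate(([0], np.cumsum(lengths)[:-1]))

    samples = clean.copy()
    t = np.arange(len(clean)) / fs
    if wander_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        samples = samples + wander_amplitude * clean.max() * np.sin(2 * np.pi * 0.3 * t + phase)
    if noise_sd > 0:
        rms = float(np.sqrt(np.mean(clean**2)))
        samples = samples + rng.normal(0.0, noise_sd * rms, size=len(clean))

    return RawPulseSignal(
        samples=samples, fs=fs, true_boundaries=boundaries,
        true_label=spec.label, subject_id=subject_id, clean=clean,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _diseases_for_code(code: str) -> frozenset[str]:
    if code in DISEASE_FOR_PATTERN:
        return DISEASE_FOR_PATTERN[code]
    if code in _COMORBID_ABBREV:
        return frozenset({_COMORBID_ABBREV[code]})
    parts = [p.strip() for p in code.split("+")]
    out: set[str] = set()
    for p in parts:
        out.add(_COMORBID_ABBREV.get(p, p))
    return frozenset(out)


def _draw_parameters(out_params: frozenset[str], rng: np.random.Generator) -> dict[str, float]:
    vals: dict[str, float] = {}
    for name in ("systolic", "diastolic", "cavi", "bapwv", "viscosity"):
        key = "bp" if name in ("systolic", "diastolic") else name
        rng_lo, rng_hi = (OUT_RANGES if key in out_params else IN_RANGES)[name]
        vals[name] = float(rng.uniform(rng_lo, rng_hi))
    return vals


def generate_cohort(
    class_mix: Mapping[str, int],
    comorbidity_mix: Mapping[str, int] | None = None,
    parameter_model: Mapping[str, frozenset[str]] | None = None,
    rng: np.random.Generator | None = None,
    n_cycles_per_subject: int = 12,
    noise_sd: float = 0.05,
    wander_amplitude: float = 0.05,
    fs: float = 100.0,
) -> list[SubjectProfile]:
    """Emit a labelled cohort of subjects with attached pulse records.

    ``class_mix`` maps pattern labels (keys of :data:`CLASS_SPECS`) to subject
    counts; ``comorbidity_mix`` maps '+'-joined abbreviations or free-text
    disease names to counts (those subjects exist to be excluded by
    screening).  ``parameter_model`` overrides which parameters a pattern
    pushes out of range.  Deterministic given ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng()
    param_model = dict(OUT_OF_RANGE_FOR_PATTERN)
    if parameter_model:
        param_model.update(parameter_model)

    cohort: list[SubjectProfile] = []
    idx = 0

    def _emit(label: str, diseases: frozenset[str], out_params: frozenset[str],
              spec: PulseClassSpec) -> None:
        nonlocal idx
        idx += 1
        sid = f"S{idx:04d}"
        vals = _draw_parameters(out_params, rng)
        record = generate_record(
            spec, n_cycles_per_subject, noise_sd=noise_sd,
            wander_amplitude=wander_amplitude, fs=fs, rng=rng, subject_id=sid,
        )
        record.true_label = label
        cohort.append(SubjectProfile(
            subject_id=sid, diseases=diseases, label=label, record=record, **vals,
        ))

    for label, count in class_mix.items():
        if count < 0:
            raise ValueError("subject counts must be >= 0")
        spec = CLASS_SPECS[label]
        out_params = param_model.get(label, frozenset())
        for _ in range(count):
            _emit(label, DISEASE_FOR_PATTERN.get(label, frozenset()), out_params, spec)

    for code, count in (comorbidity_mix or {}).items():
        if count < 0:
            raise ValueError("subject counts must be >= 0")
        diseases = _diseases_for_code(code)
        out_params = frozenset(
            _DISEASE_TO_PARAM[d] for d in diseases if d in _DISEASE_TO_PARAM
        )
        # waveform: reuse the spec of the first recognised single-disease
        # pattern, else the healthy shape — screening discards these anyway
        spec = DATASET1_SPECS["H1"]
        for abbr, disease in _COMORBID_ABBREV.items():
            if disease in diseases and abbr in DATASET1_SPECS:
                spec = DATASET1_SPECS[abbr]
                break
        spec = replace(spec, label=code)
        for _ in range(count):
            _emit(code, diseases, out_params, spec)

    return cohort
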