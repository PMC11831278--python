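"""Synthetic multichannel EEG with planted microstate dynamics.

The generator emulates a two-group (patients with methamphetamine use
disorder vs. healthy controls), three-condition (eyes-closed resting,
drug-cue, neutral-cue) study: per subject and condition one continuous
recording whose scalp topography switches between four canonical template
maps (classes A-D) according to a semi-Markov chain with Gamma-distributed
dwell times.  Each dwell rides on a sinusoidal carrier (default 10 Hz, so
the alpha band carries the planted structure) plus white sensor noise.

Because every planted label sequence is reproducible from the study seed,
every downstream stage — filtering, segmentation, back-fitting, parameter
estimation, classification — can be validated against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from microband.containers import Recording

CLASS_NAMES = ("A", "B", "C", "D")


# ---------------------------------------------------------------------------
# channel layout and canonical template maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelLayout:
    """Scalp sensor layout on the unit disc (front of head at +y)."""

    names: tuple[str, ...]
    xy: np.ndarray  # (n_channels, 2)

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "xy", xy)
        if len(self.names) != len(set(self.names)):
            raise ValueError("channel names must be unique")
        if xy.shape != (len(self.names), 2):
            raise ValueError("xy must be (n_channels, 2)")
        if np.any(np.hypot(xy[:, 0], xy[:, 1]) > 1.0 + 1e-9):
            raise ValueError("all channel positions must lie in the unit disc")
        if len(self.names) < 8:
            raise ValueError("need at least 8 channels")

    @property
    def n_channels(self) -> int:
        return len(self.names)


def make_layout(n_channels: int = 31) -> ChannelLayout:
    """Deterministic layout: one central channel plus concentric rings.

    Channels are placed at the centre and on rings of radius 0.4, 0.7 and
    1.0, distributed proportionally to ring circumference, equally spaced
    in angle starting at the front of the head (+y).
    """
    if n_channels < 8:
        raise ValueError("n_channels must be >= 8")
    radii = (0.4, 0.7, 1.0)
    remaining = n_channels - 1
    weights = np.array(radii) / sum(radii)
    counts = np.floor(weights * remaining).astype(int)
    # largest-remainder apportionment of the leftover slots
    leftover = remaining - counts.sum()
    order = np.argsort(-(weights * remaining - counts))
    for i in range(leftover):
        counts[order[i % 3]] += 1
    pts = [(0.0, 0.0)]
    for r, m in zip(radii, counts):
        ang = np.pi / 2 - 2 * np.pi * np.arange(m) / max(m, 1)
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    xy = np.array(pts)
    names = tuple(f"EEG{i + 1:03d}" for i in range(n_channels))
    return ChannelLayout(names=names, xy=xy)


@dataclass(frozen=True)
class CanonicalTemplates:
    """Four canonical microstate topographies (rows A, B, C, D).

    Each row is average-referenced (zero mean across channels) and
    unit-norm, so polarity-invariant cosine fitting is well defined.
    """

    maps: np.ndarray  # (4, n_channels)
    labels: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        object.__setattr__(self, "maps", maps)
        if maps.shape[0] != len(self.labels):
            raise ValueError("one row per label required")
        if np.max(np.abs(maps.mean(axis=1))) > 1e-9:
            raise ValueError("templates must be average-referenced")
        if np.max(np.abs(np.linalg.norm(maps, axis=1) - 1)) > 1e-9:
            raise ValueError("templates must be unit-norm")

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


def _center_normalize(rows: np.ndarray) -> np.ndarray:
    rows = rows - rows.mean(axis=1, keepdims=True)
    return rows / np.linalg.norm(rows, axis=1, keepdims=True)


def make_canonical_templates(layout: ChannelLayout) -> CanonicalTemplates:
    """Construct the four canonical class topographies on a layout.

    The geometry is a documented stand-in for the classical A-D patterns:
    A is a left-posterior/right-anterior gradient (x + y), B its mirror
    (-x + y), C a posterior-anterior gradient (y) and D a central bump
    (1 - 2 r^2).  Each map is average-referenced and unit-normalized.
    """
    x, y = layout.xy[:, 0], layout.xy[:, 1]
    r2 = x ** 2 + y ** 2
    raw = np.vstack([x + y, -x + y, y, 1.0 - 2.0 * r2])
    return CanonicalTemplates(maps=_center_normalize(raw))


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _uniform_offdiag(k: int) -> np.ndarray:
    t = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(t, 0.0)
    return t


@dataclass(frozen=True)
class DynamicsSpec:
    """Semi-Markov microstate dynamics for one group x condition cell.

    Parameters
    ----------
    mean_duration_ms
        Per-class mean dwell time in ms (must lie in (20, 400)).
    duration_shape
        Gamma shape parameter of the dwell-time law; scale is
        ``mean / shape`` so the mean is exact and the coefficient of
        variation is ``1/sqrt(shape)``.
    transition
        ``k x k`` row-stochastic matrix with zero diagonal.
    carrier_freq_hz
        Frequency of the sinusoidal carrier each dwell rides on.
    snr
        Amplitude signal-to-noise ratio: sensor noise has per-channel
        standard deviation ``amplitude_uv / snr``.
    amplitude_uv
        Peak map amplitude in microvolts (template maps are unit-norm).
    """

    mean_duration_ms: np.ndarray = field(
        default_factory=lambda: np.full(4, 100.0))
    duration_shape: float = 20.0
    transition: np.ndarray | None = None
    carrier_freq_hz: float = 10.0
    snr: float = 5.0
    amplitude_uv: float = 10.0

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean_duration_ms, dtype=float)
        object.__setattr__(self, "mean_duration_ms", mean)
        k = mean.size
        if np.any(mean <= 20.0) or np.any(mean >= 400.0):
            raise ValueError("mean durations must lie in (20, 400) ms")
        if self.duration_shape <= 0:
            raise ValueError("duration_shape must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        t = self.transition
        t = _uniform_offdiag(k) if t is None else np.asarray(t, dtype=float)
        object.__setattr__(self, "transition", t)
        if t.shape != (k, k):
            raise ValueError("transition matrix shape must match class count")
        if np.any(np.abs(np.diag(t)) > 0):
            raise ValueError("transition diagonal must be zero")
        if np.max(np.abs(t.sum(axis=1) - 1)) > 1e-9:
            raise ValueError("transition rows must sum to 1")

    @property
    def k(self) -> int:
        return self.mean_duration_ms.size

    def with_mean_durations(self, mean_duration_ms) -> "DynamicsSpec":
        return replace(self, mean_duration_ms=np.asarray(mean_duration_ms, float))


def sample_state_sequence(
    spec: DynamicsSpec,
    duration_s: float,
    fs: float,
    rng_seed,
) -> np.ndarray:
    """Sample one per-sample class-label sequence from the semi-Markov chain.

    Dwell lengths are Gamma(shape, mean/shape) in ms, rounded to at least
    one sample; the successor state is drawn from the (zero-diagonal)
    transition row of the current state.  Returns an int array of length
    ``round(duration_s * fs)``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(rng_seed)
    n = int(round(duration_s * fs))
    k = spec.k
    scale_ms = spec.mean_duration_ms / spec.duration_shape
    labels = np.empty(n, dtype=np.int64)
    pos = 0
    state = int(rng.integers(k))
    while pos < n:
        dwell_ms = rng.gamma(spec.duration_shape, scale_ms[state])
        dwell = max(1, int(round(dwell_ms * fs / 1000.0)))
        end = min(n, pos + dwell)
        labels[pos:end] = state
        pos = end
        state = int(rng.choice(k, p=spec.transition[state]))
    return labels


def _segment_bounds(labels: np.ndarray) -> np.ndarray:
    """Start indices of each maximal same-label run, plus the end sentinel."""
    change = np.flatnonzero(np.diff(labels)) + 1
    return np.concatenate([[0], change, [labels.size]])


def synthesize_epoch(
    labels: np.ndarray,
    templates: CanonicalTemplates,
    spec: DynamicsSpec,
    fs: float,
    rng_seed,
) -> np.ndarray:
    """Render one label sequence into a multichannel voltage segment.

    ``v(t) = a sin(2 pi f t + phi_seg) T_{s(t)} + (a/snr) eps(t)`` with the
    carrier phase redrawn uniformly per dwell segment and i.i.d. standard
    normal sensor noise per channel and sample.  Returns ``(C, N)`` in uV.
    """
    labels = np.asarray(labels)
    if labels.max() >= templates.maps.shape[0]:
        raise ValueError("label exceeds template count")
    rng = np.random.default_rng(rng_seed)
    n = labels.size
    c = templates.n_channels
    t = np.arange(n) / fs
    bounds = _segment_bounds(labels)
    phase = np.empty(n)
    for s0, s1 in zip(bounds[:-1], bounds[1:]):
        phase[s0:s1] = rng.uniform(0.0, 2.0 * np.pi)
    carrier = spec.amplitude_uv * np.sin(
        2.0 * np.pi * spec.carrier_freq_hz * t + phase)
    signal = templates.maps[labels].T * carrier  # (C, N)
    noise = (spec.amplitude_uv / spec.snr) * rng.standard_normal((c, n))
    return signal + noise


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """The emulated study layout.

    Defaults mirror the emulated protocol: 20 subjects per group, three
    conditions, 15 seven-second trials per condition, 1000 Hz acquisition,
    31 scalp data channels, a 10-minute resting run, and cue trials of
    7 s image-on separated by 7 s gaps.  Ages are drawn per group from
    normal distributions (patients 36.9 +/- 7.7 y, controls 26.1 +/- 4.2 y).
    """

    n_per_group: int = 20
    groups: tuple[str, str] = ("MUD", "HC")
    conditions: tuple[str, ...] = ("resting", "drug", "neutral")
    trials_per_condition: int = 15
    trial_s: float = 7.0
    gap_s: float = 7.0
    fs_hz: float = 1000.0
    n_channels: int = 31
    resting_duration_s: float = 600.0
    age_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"MUD": (36.90, 7.72), "HC": (26.10, 4.2)})

    def __post_init__(self) -> None:
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.fs_hz < 250:
            raise ValueError("fs_hz must be >= 250")
        min_rest = self.trials_per_condition * self.trial_s
        if self.resting_duration_s < min_rest:
            raise ValueError(
                f"resting run must cover at least {min_rest:.0f} s")

    @property
    def n_subjects(self) -> int:
        return self.n_per_group * len(self.groups)

    def cue_duration_s(self) -> float:
        return self.trials_per_condition * (self.trial_s + self.gap_s)

    def subject_ids(self) -> list[tuple[str, str]]:
        """(subject_id, group) pairs in deterministic order."""
        out = []
        for g in self.groups:
            out.extend((f"{g}{i + 1:02d}", g) for i in range(self.n_per_group))
        return out


def _normalize_specs(
    specs, design: StudyDesign
) -> dict[tuple[str, str], DynamicsSpec]:
    """Accept one spec for all cells or a {(group, condition): spec} map."""
    if isinstance(specs, DynamicsSpec):
        return {(g, c): specs for g in design.groups for c in design.conditions}
    out = {}
    for g in design.groups:
        for c in design.conditions:
            try:
                out[(g, c)] = specs[(g, c)]
            except KeyError as exc:
                raise KeyError(f"no DynamicsSpec for cell {(g, c)}") from exc
    return out


class SyntheticStudy:
    """Lazy, seed-deterministic synthetic study.

    Recordings are regenerated on demand from per-recording seed streams,
    so a 120-recording study never needs to be held in memory at once.
    """

    def __init__(self, design: StudyDesign, specs, seed: int,
                 layout: ChannelLayout | None = None):
        self.design = design
        self.specs = _normalize_specs(specs, design)
        self.seed = int(seed)
        self.layout = layout or make_layout(design.n_channels)
        self.templates = make_canonical_templates(self.layout)
        age_rng = np.random.default_rng(
            np.random.SeedSequence((self.seed, 0xA6E)))
        rows = []
        for sid, g in design.subject_ids():
            mean, sd = design.age_mean_sd[g]
            rows.append({"subject": sid, "group": g,
                         "age": float(age_rng.normal(mean, sd))})
        self.subjects = pd.DataFrame(rows)

    # -- seed plumbing ----------------------------------------------------
    def _index(self, subject: str, condition: str) -> tuple[int, int]:
        sids = [sid for sid, _ in self.design.subject_ids()]
        return sids.index(subject), self.design.conditions.index(condition)

    def _rng_seed(self, subject: str, condition: str, stream: int):
        i, j = self._index(subject, condition)
        return np.random.SeedSequence((self.seed, i, j, stream))

    # -- generation -------------------------------------------------------
    def _duration_s(self, condition: str) -> float:
        if condition == "resting":
            return self.design.resting_duration_s
        return self.design.cue_duration_s()

    def planted_labels(self, subject: str, condition: str) -> np.ndarray:
        """Regenerate the planted per-sample label sequence (at fs_hz)."""
        group = subject.rstrip("0123456789")
        spec = self.specs[(group, condition)]
        return sample_state_sequence(
            spec, self._duration_s(condition), self.design.fs_hz,
            self._rng_seed(subject, condition, 0))

    def recording(self, subject: str, condition: str) -> Recording:
        group = subject.rstrip("0123456789")
        spec = self.specs[(group, condition)]
        labels = self.planted_labels(subject, condition)
        data = synthesize_epoch(labels, self.templates, spec,
                                self.design.fs_hz,
                                self._rng_seed(subject, condition, 1))
        return Recording(data=data, fs=self.design.fs_hz,
                         ch_names=self.layout.names, subject=subject,
                         group=group, condition=condition)

    def iter_recordings(self) -> Iterator[Recording]:
        for sid, _ in self.design.subject_ids():
            for cond in self.design.conditions:
                yield self.recording(sid, cond)

    @property
    def design_table(self) -> pd.DataFrame:
        """One row per subject x condition with group and age metadata."""
        rows = []
        for _, srow in self.subjects.iterrows():
            for cond in self.design.conditions:
                rows.append({"subject": srow.subject, "group": srow.group,
                             "condition": cond, "age": srow.age})
        return pd.DataFrame(rows)

    @property
    def n_recordings(self) -> int:
        return self.design.n_subjects * len(self.design.conditions)


def synthesize_study(design: StudyDesign, specs, seed: int,
                     layout: ChannelLayout | None = None) -> SyntheticStudy:
    """Build a lazy synthetic study (recordings, design table, ages)."""
    return SyntheticStudy(design, specs, seed, layout=layout)


# ---------------------------------------------------------------------------
# dynamics-level fast feature generator
# ---------------------------------------------------------------------------

def simulate_feature_table(
    design: StudyDesign,
    specs_by_cell: Mapping[tuple[str, str, str], DynamicsSpec] | DynamicsSpec,
    seed: int,
    bands: tuple[str, ...] = ("theta", "alpha", "beta", "gamma", "all"),
    fs: float = 250.0,
    fit_corr_mean: float = 0.85,
    fit_corr_sd: float = 0.05,
) -> pd.DataFrame:
    """Generate a per-epoch microstate feature table straight from dynamics.

    This reduced path skips voltage synthesis and back-fitting: for every
    subject x condition x trial x band it draws an independent label
    sequence from the cell's dynamics and computes the 17 microstate
    parameters from the planted labels, with a jittered fit quality for
    the GEV terms.  It is the fast input for classifier and covariate
    behaviour studies where the EEG rendering itself is not under test.

    ``specs_by_cell`` maps ``(group, condition, band)`` to a DynamicsSpec
    (a single spec is broadcast to every cell).
    """
    from microband.microstate import compute_parameters

    if isinstance(specs_by_cell, DynamicsSpec):
        specs_by_cell = {
            (g, c, b): specs_by_cell
            for g in design.groups for c in design.conditions for b in bands}
    root = np.random.SeedSequence(seed)
    age_rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xA6E)))
    ages = {}
    for sid, g in design.subject_ids():
        mean, sd = design.age_mean_sd[g]
        ages[sid] = float(age_rng.normal(mean, sd))

    rows = []
    counter = 0
    n = int(round(design.trial_s * fs))
    t = np.arange(n) / fs
    for sid, g in design.subject_ids():
        for cond in design.conditions:
            for band in bands:
                spec = specs_by_cell[(g, cond, band)]
                for trial in range(design.trials_per_condition):
                    ss = np.random.SeedSequence((int(seed), 0xF0, counter))
                    counter += 1
                    rng = np.random.default_rng(ss)
                    labels = sample_state_sequence(
                        spec, design.trial_s, fs, rng)
                    fit = np.clip(
                        rng.normal(fit_corr_mean, fit_corr_sd, n), 0.0, 1.0)
                    gfp = np.abs(np.sin(
                        2 * np.pi * spec.carrier_freq_hz * t
                        + rng.uniform(0, 2 * np.pi))) + 0.05
                    feats = compute_parameters(labels, fit, gfp, fs,
                                               k=spec.k)
                    row = {"subject": sid, "group": g, "condition": cond,
                           "band": band, "trial": trial, "age": ages[sid]}
                    row.update(feats)
                    rows.append(row)
    del root
    return pd.DataFrame(rows)
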