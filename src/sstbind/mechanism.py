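"""Binding-mechanism analysis of trajectories via the salt-bridge distance d_SB.

A trajectory is reduced to a d_SB time series; binding modes appear as peaks
of the d_SB distribution (Gaussian kernel density estimate), frames are
classified into mode windows with hysteresis, and association/dissociation
events are read off the resulting timeline.  The mode vocabulary follows the
external (lid-bound) → intermediate (≈10 Å, ≈5–6 Å) → internal (salt bridge
formed, ≈3 Å) picture of peptide entry into a GPCR pocket.

States are an explicit density-peak substitute for reading modes off a d_SB
plot by eye; windows, boundaries and hysteresis are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import DsbSpec
from .structio import Trajectory

__all__ = [
    "DsbSeries",
    "ModeState",
    "ModeStateSet",
    "ModeTimeline",
    "TransitionEvent",
    "dsb_timeseries",
    "min_dsb_frame",
    "detect_states",
    "classify_frames",
    "detect_transitions",
]

UNASSIGNED = "unassigned"


@dataclass
class DsbSeries:
    """Per-frame d_SB values (Å) with times (ns)."""

    times: np.ndarray
    values: np.ndarray
    spec: DsbSpec | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.values) and self.values.min() <= 0:
            raise ValueError("d_SB values must be positive")

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time_ns\tvalue_A\n")
            for t, v in zip(self.times, self.values):
                fh.write(f"{t:.6f}\t{v:.6f}\n")


@dataclass
class ModeState:
    label: str
    center: float       # Å
    half_width: float   # Å

    def contains(self, value: float, slack: float = 0.0) -> bool:
        return abs(value - self.center) <= self.half_width + slack


@dataclass
class ModeStateSet:
    """Ordered binding-mode windows (centers strictly increasing)."""

    states: list[ModeState]
    hysteresis: float = 0.5

    def __post_init__(self) -> None:
        centers = [s.center for s in self.states]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("state centers must be strictly increasing")
        for a, b in zip(self.states, self.states[1:]):
            if a.center + a.half_width + self.hysteresis > b.center - b.half_width - self.hysteresis:
                raise ValueError(
                    f"state windows {a.label}/{b.label} overlap after hysteresis"
                )

    def __len__(self) -> int:
        return len(self.states)

    def by_label(self, label: str) -> ModeState:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]


@dataclass
class ModeTimeline:
    """Frame-wise state labels with occupancy and dwell statistics."""

    times: np.ndarray
    labels: list[str]
    states: ModeStateSet

    @property
    def occupancies(self) -> dict[str, float]:
        """Fraction of frames per label, unassigned included; sums to 1."""
        n = len(self.labels)
        out: dict[str, float] = {s.label: 0.0 for s in self.states.states}
        out[UNASSIGNED] = 0.0
        for lab in self.labels:
            out[lab] = out.get(lab, 0.0) + 1.0
        return {k: v / n for k, v in out.items()}

    @property
    def segments(self) -> list[tuple[str, float, float]]:
        """Dwell segments (label, start ns, end ns) partitioning the time axis.

        Each segment spans from its first frame's time to the next segment's
        first frame time; the last segment is closed with the trailing frame
        spacing.
        """
        if not self.labels:
            return []
        t = self.times
        dt = t[-1] - t[-2] if len(t) > 1 else 1.0
        out: list[tuple[str, float, float]] = []
        start = 0
        for i in range(1, len(self.labels) + 1):
            if i == len(self.labels) or self.labels[i] != self.labels[start]:
                end_time = t[i] if i < len(self.labels) else t[-1] + dt
                out.append((self.labels[start], float(t[start]), float(end_time)))
                start = i
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time_ns\tstate\n")
            for t, lab in zip(self.times, self.labels):
                fh.write(f"{t:.6f}\t{lab}\n")


@dataclass
class TransitionEvent:
    kind: str          # association | dissociation
    from_state: str
    to_state: str
    time: float        # ns


# --------------------------------------------------------------------------


def dsb_timeseries(traj: Trajectory, spec: DsbSpec | None = None, dt: float = 0.1) -> DsbSeries:
    """One d_SB value per trajectory frame."""
    spec = spec or DsbSpec()
    i, j = spec.resolve(traj.topology)
    values = np.array([float(np.linalg.norm(f[i] - f[j])) for f in traj.frames])
    return DsbSeries(times=traj.frame_times(dt), values=values, spec=spec)


def min_dsb_frame(series: DsbSeries) -> tuple[int, float]:
    """Global-minimum frame (earliest on ties) and its d_SB value."""
    if len(series) == 0:
        raise ValueError("empty d_SB series")
    idx = int(np.argmin(series.values))
    return idx, float(series.values[idx])


def _gaussian_kde(values: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    z = (grid[:, None] - values[None, :]) / bandwidth
    return np.exp(-0.5 * z * z).sum(axis=1) / (len(values) * bandwidth * np.sqrt(2 * np.pi))


def detect_states(
    series: DsbSeries,
    bandwidth: float = 0.3,
    min_peak_occupancy: float = 0.05,
    internal_max: float = 4.0,
    external_min: float = 15.0,
    max_half_width: float = 1.5,
    hysteresis: float = 0.5,
    grid_step: float = 0.02,
) -> ModeStateSet:
    """Identify binding-mode states as KDE peaks of the d_SB distribution.

    Peaks holding at least ``min_peak_occupancy`` of the samples within their
    window become states.  Labels by center rank: the smallest center is
    ``internal`` when ≤ ``internal_max``; the largest is ``external`` when
    ≥ ``external_min``; remaining states are ``intermediate_near`` /
    ``intermediate_far`` in order of increasing center.
    """
    v = series.values
    if len(v) < 2:
        raise ValueError("state detection requires at least 2 frames")
    if len(v) < 100:
        warnings.warn(f"only {len(v)} frames; state detection is unreliable below ~100", stacklevel=2)
    grid = np.arange(v.min() - 3 * bandwidth, v.max() + 3 * bandwidth + grid_step, grid_step)
    dens = _gaussian_kde(v, grid, bandwidth)
    # interior local maxima of the density
    peak_idx = [
        i for i in range(1, len(grid) - 1) if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]
    ]
    centers = sorted(float(grid[i]) for i in peak_idx)

    # window half-widths: capped, and shrunk so neighboring windows stay
    # disjoint after hysteresis
    kept: list[tuple[float, float]] = []
    for k, c in enumerate(centers):
        hw = max_half_width
        if k > 0:
            hw = min(hw, (c - centers[k - 1]) / 2 - hysteresis)
        if k < len(centers) - 1:
            hw = min(hw, (centers[k + 1] - c) / 2 - hysteresis)
        hw = max(hw, bandwidth)  # never narrower than the kernel
        occ = float(np.mean(np.abs(v - c) <= hw))
        if occ >= min_peak_occupancy:
            kept.append((c, hw))

    # merge any windows that ended up overlapping (closely spaced noise peaks)
    merged: list[tuple[float, float]] = []
    for c, hw in kept:
        if merged and c - hw <= merged[-1][0] + merged[-1][1] + hysteresis:
            c0, hw0 = merged[-1]
            # keep the denser of the two peaks
            d0 = _gaussian_kde(v, np.array([c0]), bandwidth)[0]
            d1 = _gaussian_kde(v, np.array([c]), bandwidth)[0]
            merged[-1] = (c, hw) if d1 > d0 else (c0, hw0)
        else:
            merged.append((c, hw))

    if not merged:
        raise ValueError("no state passed the minimum-occupancy filter")

    n = len(merged)
    labels = [""] * n
    lo = 0
    hi = n
    if merged[0][0] <= internal_max:
        labels[0] = "internal"
        lo = 1
    if merged[-1][0] >= external_min and labels[-1] == "":
        labels[-1] = "external"
        hi = n - 1
    mids = list(range(lo, hi))
    mid_names = ["intermediate_near", "intermediate_far"]
    for k, i in enumerate(mids):
        labels[i] = mid_names[k] if k < 2 and len(mids) <= 2 else f"intermediate_{k + 1}"
    states = [ModeState(lab, c, hw) for lab, (c, hw) in zip(labels, merged)]
    return ModeStateSet(states=states, hysteresis=hysteresis)


def classify_frames(series: DsbSeries, states: ModeStateSet, hysteresis: float | None = None) -> ModeTimeline:
    """Assign each frame to the state window containing its d_SB value.

    A frame outside every window but within ``hysteresis`` of the current
    state's boundary keeps the current state; otherwise it is unassigned.
    """
    if len(states) == 0:
        raise ValueError("state set is empty")
    hyst = states.hysteresis if hysteresis is None else hysteresis
    labels: list[str] = []
    current: ModeState | None = None
    for v in series.values:
        hit = next((s for s in states.states if s.contains(v)), None)
        if hit is None and current is not None and current.contains(v, slack=hyst):
            hit = current
        labels.append(hit.label if hit is not None else UNASSIGNED)
        current = hit if hit is not None else current
    return ModeTimeline(times=series.times, labels=labels, states=states)


def detect_transitions(timeline: ModeTimeline, min_dwell: float = 0.0) -> list[TransitionEvent]:
    """State changes whose flanking dwells both last at least ``min_dwell`` ns.

    Unassigned stretches are transparent.  ``association`` moves to a
    smaller-center state (deeper in the pocket), ``dissociation`` to larger.
    """
    segs = [
        (lab, start, end)
        for lab, start, end in timeline.segments
        if lab != UNASSIGNED and (end - start) >= min_dwell
    ]
    out: list[TransitionEvent] = []
    for (lab_a, _sa, _ea), (lab_b, sb, _eb) in zip(segs, segs[1:]):
        if lab_a == lab_b:
            continue
        ca = timeline.states.by_label(lab_a).center
        cb = timeline.states.by_label(lab_b).center
        out.append(
            TransitionEvent(
                kind="association" if cb < ca else "dissociation",
                from_state=lab_a,
                to_state=lab_b,
                time=float(sb),
            )
        )
    return out
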