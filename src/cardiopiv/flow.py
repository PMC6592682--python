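"""Cross-sectional flow rates and harmonic analysis of pulsatile flow.

Velocity fields measured per cardiac phase are integrated across user-drawn
cross-section lines, Q = ∫ v⃗·n⃗ dl, averaged over several lines (and stacks)
per heart region, and summarized over one cycle by the fundamental harmonic
index FHI = Q₁/Q₀ — the amplitude of the flow oscillation at the heart rate
relative to the time-averaged flow.  FHI ≪ 1 indicates steady forward flow;
FHI > 1 indicates flow that reverses during part of the cycle.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

__all__ = [
    "CrossSection",
    "FlowProfile",
    "HarmonicResult",
    "FlowRateResult",
    "SectionCoverageError",
    "UndefinedFHIError",
    "sample_velocity",
    "flow_rate",
    "flow_profile",
    "fundamental_harmonic_index",
]


class SectionCoverageError(ValueError):
    """Raised when too few section sample points land on valid vectors."""


class UndefinedFHIError(ValueError):
    """Raised when the mean flow is too close to zero for Q1/Q0 to mean anything."""


@dataclasses.dataclass(frozen=True)
class CrossSection:
    """A measurement line from point ``a`` to ``b`` (µm, image x/y axes).

    The unit normal is the 90° counter-clockwise rotation of the a→b
    direction, (tx, ty) → (−ty, tx); set ``flip`` to reverse it so that
    anterograde flow comes out positive for however the line was drawn.
    """

    a: tuple[float, float]
    b: tuple[float, float]
    flip: bool = False
    label: str = "other"

    def __post_init__(self) -> None:
        if self.length == 0:
            raise ValueError("cross-section endpoints coincide")

    @property
    def length(self) -> float:
        a, b = np.asarray(self.a, float), np.asarray(self.b, float)
        return float(np.hypot(*(b - a)))

    @property
    def tangent(self) -> np.ndarray:
        a, b = np.asarray(self.a, float), np.asarray(self.b, float)
        return (b - a) / self.length

    @property
    def normal(self) -> np.ndarray:
        tx, ty = self.tangent
        n = np.array([-ty, tx])
        return -n if self.flip else n

    def reversed(self) -> "CrossSection":
        """The same line drawn from b to a (normal negated)."""
        return CrossSection(a=self.b, b=self.a, flip=self.flip, label=self.label)

    def sample_points(self, dl: float) -> np.ndarray:
        """Points a + s·t̂ for s = 0, dl, 2dl, … < |b−a| (rectangle rule).

        The far endpoint is excluded: each sample represents the ``dl`` of
        section length it starts, so the discrete integral Σ v·n dl is a
        left Riemann sum over [0, |b−a|).
        """
        if not dl > 0:
            raise ValueError("dl must be > 0")
        s = np.arange(0.0, self.length - 1e-9 * max(self.length, 1.0), dl)
        a = np.asarray(self.a, float)
        return a[None, :] + s[:, None] * self.tangent[None, :]

    def to_dict(self) -> dict:
        return {"a": list(self.a), "b": list(self.b), "flip": self.flip, "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "CrossSection":
        return cls(a=tuple(d["a"]), b=tuple(d["b"]), flip=d.get("flip", False),
                   label=d.get("label", "other"))


@dataclasses.dataclass
class FlowProfile:
    """Phase-ordered flow over one cardiac cycle.

    ``Q`` holds the length-normalized mean normal velocity (µm/s) at each
    phase; ``Q_raw`` (µm²/s), when present, the un-normalized line integral.
    """

    phase: np.ndarray  # (N,) in [0, 1), strictly increasing
    Q: np.ndarray  # (N,) µm/s
    Q_raw: np.ndarray | None = None  # (N,) µm²/s
    units: str = "um/s"
    n_sections_averaged: int = 1
    n_stacks: int = 1

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, float)
        self.Q = np.asarray(self.Q, float)
        if self.phase.shape != self.Q.shape or self.phase.size < 4:
            raise ValueError("phase and Q must have equal length >= 4")
        if np.any(np.diff(self.phase) <= 0) or self.phase[0] < 0 or self.phase[-1] >= 1:
            raise ValueError("phases must be strictly increasing within [0, 1)")


@dataclasses.dataclass(frozen=True)
class HarmonicResult:
    """Fourier summary of one cycle: mean flow, fundamental amplitude, ratio."""

    Q0: float  # time-averaged flow (signed)
    Q1: float  # amplitude of the fundamental harmonic, >= 0
    FHI: float  # Q1 / |Q0|


@dataclasses.dataclass(frozen=True)
class FlowRateResult:
    Q: float  # length-normalized mean normal velocity, µm/s
    Q_raw: float  # line integral Σ v·n dl, µm²/s
    length_included: float  # µm of the section actually integrated
    n_samples: int
    n_excluded: int


def _field_bin_arrays(field, phase_bin: int):
    u = field.u_um_s[phase_bin]
    v = field.v_um_s[phase_bin]
    valid = field.valid[phase_bin]
    return u, v, valid


def sample_velocity(field, section: CrossSection, phase_bin: int, dl: float | None = None):
    """Bilinearly interpolate the phase-bin velocity onto section samples.

    Returns ``(points_um, velocities_um_s, included)``.  A sample is included
    only when its four surrounding grid nodes are all valid and the sample
    lies inside the grid extent.  More than half the samples excluded raises
    :class:`SectionCoverageError`.
    """
    if dl is None:
        dl = 4.0 * field.pixel_size  # default sample spacing: 4 px
    pts = section.sample_points(dl)
    xg = np.asarray(field.x, float) * field.pixel_size
    yg = np.asarray(field.y, float) * field.pixel_size
    u, v, valid = _field_bin_arrays(field, phase_bin)

    xs, ys = pts[:, 0], pts[:, 1]
    inside = (xs >= xg[0]) & (xs <= xg[-1]) & (ys >= yg[0]) & (ys <= yg[-1])
    if not inside.any():
        raise SectionCoverageError(
            f"section {section.label!r} lies outside the velocity-field extent"
        )
    ix = np.clip(np.searchsorted(xg, xs, side="right") - 1, 0, len(xg) - 2)
    iy = np.clip(np.searchsorted(yg, ys, side="right") - 1, 0, len(yg) - 2)
    fx = (xs - xg[ix]) / (xg[ix + 1] - xg[ix])
    fy = (ys - yg[iy]) / (yg[iy + 1] - yg[iy])

    def interp(a):
        return (
            a[iy, ix] * (1 - fx) * (1 - fy)
            + a[iy, ix + 1] * fx * (1 - fy)
            + a[iy + 1, ix] * (1 - fx) * fy
            + a[iy + 1, ix + 1] * fx * fy
        )

    corners_ok = valid[iy, ix] & valid[iy, ix + 1] & valid[iy + 1, ix] & valid[iy + 1, ix + 1]
    included = inside & corners_ok
    vel = np.column_stack([interp(np.nan_to_num(u)), interp(np.nan_to_num(v))])
    if included.sum() < 0.5 * len(pts):
        raise SectionCoverageError(
            f"section {section.label!r} insufficiently covered: "
            f"{len(pts) - int(included.sum())}/{len(pts)} samples excluded"
        )
    return pts, vel, included


def flow_rate(field, section: CrossSection, phase_bin: int, dl: float | None = None) -> FlowRateResult:
    """Flow rate through a section at one cardiac phase.

    The raw rate is the discrete line integral ``Q_raw = Σ (v⃗·n⃗) dl`` over
    included samples (rectangle rule); the headline ``Q`` divides by the
    included length, giving the mean normal velocity in µm/s, the unit flow
    rates are plotted in.
    """
    if dl is None:
        dl = 4.0 * field.pixel_size
    pts, vel, included = sample_velocity(field, section, phase_bin, dl)
    vn = vel @ section.normal
    q_raw = float(np.sum(vn[included]) * dl)
    length = float(included.sum() * dl)
    return FlowRateResult(
        Q=q_raw / length,
        Q_raw=q_raw,
        length_included=length,
        n_samples=len(pts),
        n_excluded=int(len(pts) - included.sum()),
    )


def flow_profile(
    fields,
    sections: Sequence[CrossSection],
    dl: float | None = None,
    region: str | None = None,
) -> FlowProfile:
    """Phase-resolved flow averaged over several sections (and stacks).

    ``fields`` is one per-phase velocity field or a list of them (one per
    z-stack, equal weights).  Sections failing on more than 25% of phase
    bins are dropped with a warning; 3–5 sections from at least two stacks
    is the recommended protocol and anything else warns but proceeds.
    """
    field_list = fields if isinstance(fields, (list, tuple)) else [fields]
    secs = [s for s in sections if region is None or s.label == region]
    if not secs:
        raise ValueError("no sections to integrate")
    if not 3 <= len(secs) <= 5:
        warnings.warn(
            f"{len(secs)} section(s) given; 3-5 measurements per region are recommended",
            stacklevel=2,
        )
    if len(field_list) < 2:
        warnings.warn(
            "profile from a single stack; at least two stacks are recommended", stacklevel=2
        )
    n_bins = field_list[0].n_phase_bins
    per_section = []  # (n_bins,) arrays averaged over stacks
    per_section_raw = []
    for sec in secs:
        qs = np.full((len(field_list), n_bins), np.nan)
        qraw = np.full_like(qs, np.nan)
        for i, field in enumerate(field_list):
            for b in range(n_bins):
                try:
                    res = flow_rate(field, sec, b, dl)
                except SectionCoverageError:
                    continue
                qs[i, b] = res.Q
                qraw[i, b] = res.Q_raw
        failed = np.mean(np.isnan(qs)) if qs.size else 1.0
        if failed > 0.25:
            warnings.warn(
                f"section {sec.label!r} ({sec.a}->{sec.b}) dropped: "
                f"failed on {failed:.0%} of phase bins",
                stacklevel=2,
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_section.append(np.nanmean(qs, axis=0))
            per_section_raw.append(np.nanmean(qraw, axis=0))
    if not per_section:
        raise SectionCoverageError("all sections dropped; no flow profile")
    q = np.nanmean(np.vstack(per_section), axis=0)
    q_raw = np.nanmean(np.vstack(per_section_raw), axis=0)
    if np.any(np.isnan(q)):
        # a bin uncovered by every surviving section: fill by periodic interpolation
        ph = np.arange(n_bins, dtype=float)
        bad = np.isnan(q)
        q[bad] = np.interp(ph[bad], ph[~bad], q[~bad], period=n_bins)
        q_raw[bad] = np.interp(ph[bad], ph[~bad], q_raw[~bad], period=n_bins)
    phase = (np.arange(n_bins) + 0.5) / n_bins  # pair (k, k+1) measures mid-interval
    return FlowProfile(
        phase=phase,
        Q=q,
        Q_raw=q_raw,
        n_sections_averaged=len(per_section),
        n_stacks=len(field_list),
    )


def fundamental_harmonic_index(profile: FlowProfile) -> HarmonicResult:
    """FHI = Q₁/Q₀ from the discrete Fourier transform of one cycle.

    With ``c_m = (1/N) Σ_k Q_k exp(−2πi k m/N)``: Q₀ = Re c₀ (the signed
    time-averaged flow), Q₁ = 2|c₁| (so a pure cosine of amplitude A gives
    Q₁ = A), and FHI = Q₁/|Q₀|.  Profiles sampled non-uniformly in phase are
    linearly resampled onto a uniform grid first.  A mean flow within 1e−9
    of the waveform scale raises :class:`UndefinedFHIError`.
    """
    phase = profile.phase
    q = profile.Q
    n = len(q)
    uniform = np.allclose(np.diff(phase), np.diff(phase)[0], rtol=0, atol=1e-12)
    if not uniform:
        grid = phase[0] + np.arange(n) / n
        grid = np.mod(grid, 1.0)
        order = np.argsort(grid)
        q = np.interp(grid[order], phase, q, period=1.0)
    c = np.fft.fft(q) / n
    q0 = float(c[0].real)
    q1 = float(2.0 * np.abs(c[1]))
    scale = float(np.max(np.abs(q))) if np.max(np.abs(q)) > 0 else 1.0
    if abs(q0) < 1e-9 * scale:
        raise UndefinedFHIError("undefined FHI: near-zero mean flow")
    return HarmonicResult(Q0=q0, Q1=q1, FHI=q1 / abs(q0))
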