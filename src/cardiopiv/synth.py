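"""Synthetic beating-heart particle movies with known ground truth.

This module emulates confocal recordings of fluorescently labeled red blood
cells advected through a cardiac chamber: a prescribed, exactly periodic 2-D
flow field transports point tracers inside an axis-aligned lumen, and frames
are rendered as Gaussian particle images with additive background and noise.
Every generated movie carries the analytic velocity field it was built from,
so downstream PIV, flow-rate and harmonic analyses can be tested against a
known answer.

Two physiological regimes are provided:

* ``control`` — forward-only pulsatile flow (oscillation amplitude below the
  mean), as in an uninjured heart;
* ``ablated`` — strongly oscillatory flow whose velocity changes sign during
  part of the cycle (retrograde flow), as after ventricular injury.

Coordinates are physical (µm), with x along the flow axis and y across the
lumen; images follow the raster convention (row = y, column = x, pixel
centers at integer pixel coordinates).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import tifffile
from scipy.special import erf

from .flow import FlowProfile

__all__ = [
    "Harmonic",
    "FlowFieldSpec",
    "ParticleCloud",
    "AcquisitionParams",
    "SyntheticRecording",
    "make_particle_cloud",
    "advect",
    "render_frame",
    "generate_sequence",
    "make_waveform",
]

Bounds = tuple[float, float, float, float]  # (x0, x1, y0, y1) in µm

_KINDS = ("uniform", "shear", "poiseuille", "pulsatile_forward", "pulsatile_oscillatory")


@dataclasses.dataclass(frozen=True)
class Harmonic:
    """One temporal Fourier component of the centerline waveform."""

    index: int
    amplitude: float  # µm/s
    phase: float = 0.0  # rad


@dataclasses.dataclass(frozen=True)
class FlowFieldSpec:
    """Analytic, exactly periodic 2-D flow in an axis-aligned lumen.

    The velocity is unidirectional along x and separable,
    ``u(x, y, t) = w(t) * f(y)``, where ``w`` is the centerline waveform
    (mean plus cosine harmonics) and ``f`` the cross-lumen profile selected
    by ``kind``.  Outside the lumen the velocity is identically zero.

    Parameters
    ----------
    kind
        One of ``uniform`` (plug), ``shear`` (linear ramp across the lumen),
        ``poiseuille`` (parabolic), ``pulsatile_forward`` or
        ``pulsatile_oscillatory`` (parabolic profile with a time-varying
        waveform).
    mean_speed
        Time-averaged centerline speed, µm/s.
    period
        Cycle duration in seconds; the field satisfies
        ``v(x, t) = v(x, t + period)`` exactly.
    lumen
        Axis-aligned lumen bounds ``(x0, x1, y0, y1)`` in µm.
    harmonics
        Cosine harmonics added to the mean.
    """

    kind: str
    mean_speed: float
    period: float
    lumen: Bounds
    harmonics: tuple[Harmonic, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown flow kind {self.kind!r}; expected one of {_KINDS}")
        if not self.period > 0:
            raise ValueError("period must be > 0")
        x0, x1, y0, y1 = self.lumen
        if not (x1 > x0 and y1 > y0):
            raise ValueError("degenerate lumen bounds")
        if self.peak_speed < 0:
            raise ValueError("peak_speed must be >= 0")

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def steady(cls, kind: str, peak_speed: float, lumen: Bounds, period: float = 1.0) -> "FlowFieldSpec":
        """Time-constant flow (trivially periodic with any period)."""
        return cls(kind=kind, mean_speed=peak_speed, period=period, lumen=lumen)

    @classmethod
    def pulsatile(
        cls,
        mean_speed: float,
        osc_amplitude: float,
        period: float,
        lumen: Bounds,
        phase: float = 0.0,
    ) -> "FlowFieldSpec":
        """Single-harmonic pulsatile Poiseuille flow.

        ``osc_amplitude < mean_speed`` gives a forward-only (control-like)
        field; ``osc_amplitude > mean_speed`` a sign-changing (ablated-like)
        field.
        """
        kind = "pulsatile_forward" if osc_amplitude <= mean_speed else "pulsatile_oscillatory"
        return cls(
            kind=kind,
            mean_speed=mean_speed,
            period=period,
            lumen=lumen,
            harmonics=(Harmonic(1, osc_amplitude, phase),),
        )

    @classmethod
    def from_retrograde_fraction(
        cls, mean_speed: float, retrograde_fraction: float, period: float, lumen: Bounds
    ) -> "FlowFieldSpec":
        """Single-harmonic flow reversed for a given fraction of the cycle.

        For ``w(t) = m + A cos(2πt/T)`` the reversed fraction is
        ``1 - arccos(-m/A)/π``, so ``A = m / cos(π r)`` for ``r < 1/2``.
        """
        if not 0.0 <= retrograde_fraction < 0.5:
            raise ValueError("retrograde_fraction must lie in [0, 0.5) for a positive-mean waveform")
        if retrograde_fraction == 0.0:
            return cls.pulsatile(mean_speed, 0.0, period, lumen)
        amp = mean_speed / math.cos(math.pi * retrograde_fraction)
        return cls.pulsatile(mean_speed, amp, period, lumen)

    # ------------------------------------------------------------------ #
    # derived quantities

    @property
    def peak_speed(self) -> float:
        """Maximum centerline speed over the cycle (µm/s)."""
        if not self.harmonics:
            return abs(self.mean_speed)
        t = np.linspace(0.0, self.period, 720, endpoint=False)
        return float(np.abs(self.waveform(t)).max())

    @property
    def retrograde_fraction(self) -> float:
        """Fraction of the cycle with reversed (negative) centerline flow."""
        t = np.linspace(0.0, self.period, 7200, endpoint=False)
        return float(np.mean(self.waveform(t) < 0))

    @property
    def analytic_fhi(self) -> float:
        """Fundamental harmonic index of the waveform, ``2|c1| / |c0|``."""
        if self.mean_speed == 0:
            raise ZeroDivisionError("undefined FHI: zero mean flow")
        a1 = sum(h.amplitude for h in self.harmonics if h.index == 1)
        return abs(a1) / abs(self.mean_speed)

    def waveform(self, t) -> np.ndarray:
        """Centerline speed w(t) in µm/s (vectorized over ``t``)."""
        t = np.asarray(t, dtype=float)
        w = np.full(t.shape, float(self.mean_speed))
        for h in self.harmonics:
            w = w + h.amplitude * np.cos(2 * np.pi * h.index * t / self.period + h.phase)
        return w

    def _profile(self, y: np.ndarray) -> np.ndarray:
        """Cross-lumen envelope f(y); zero outside the lumen."""
        _, _, y0, y1 = self.lumen
        yn = (y - y0) / (y1 - y0)
        inside = (yn >= 0) & (yn <= 1)
        if self.kind == "uniform":
            f = np.ones_like(yn)
        elif self.kind == "shear":
            f = yn
        else:  # poiseuille and pulsatile kinds
            f = 4.0 * yn * (1.0 - yn)
        return np.where(inside, f, 0.0)

    def evaluate(self, points: np.ndarray, t: float) -> np.ndarray:
        """Velocity (µm/s) at ``points`` (N, 2) = (x, y) µm at time ``t`` s."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x0, x1, _, _ = self.lumen
        inside_x = (pts[:, 0] >= x0) & (pts[:, 0] <= x1)
        u = float(self.waveform(t)) * self._profile(pts[:, 1]) * inside_x
        out = np.zeros_like(pts)
        out[:, 0] = u
        return out

    def sample_on_grid(self, x: np.ndarray, y: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Velocity components on the tensor grid ``y × x`` (µm) at time t."""
        xx, yy = np.meshgrid(np.asarray(x, float), np.asarray(y, float))
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        v = self.evaluate(pts, t)
        return v[:, 0].reshape(xx.shape), v[:, 1].reshape(xx.shape)

    def mean_normal_velocity(self, t) -> np.ndarray:
        """Lumen-averaged axial velocity at time t (spatial mean of w·f)."""
        factor = {"uniform": 1.0, "shear": 0.5}.get(self.kind, 2.0 / 3.0)
        return self.waveform(t) * factor

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "mean_speed": self.mean_speed,
            "period": self.period,
            "lumen": list(self.lumen),
            "harmonics": [[h.index, h.amplitude, h.phase] for h in self.harmonics],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FlowFieldSpec":
        return cls(
            kind=d["kind"],
            mean_speed=d["mean_speed"],
            period=d["period"],
            lumen=tuple(d["lumen"]),
            harmonics=tuple(Harmonic(*h) for h in d.get("harmonics", [])),
        )


@dataclasses.dataclass
class ParticleCloud:
    """A set of point tracers (positions in µm) standing in for blood cells."""

    positions: np.ndarray  # (N, 2) = (x, y) µm
    diameters: np.ndarray  # (N,) µm
    brightness: np.ndarray  # (N,) arbitrary intensity units (integrated spot mass)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float)).reshape(-1, 2)
        self.diameters = np.broadcast_to(
            np.asarray(self.diameters, dtype=float), (len(self.positions),)
        ).copy()
        self.brightness = np.broadcast_to(
            np.asarray(self.brightness, dtype=float), (len(self.positions),)
        ).copy()

    def __len__(self) -> int:
        return len(self.positions)


@dataclasses.dataclass(frozen=True)
class AcquisitionParams:
    """Camera/scan settings of the emulated recording.

    Defaults follow a resonance-scanner acquisition of the beating heart:
    512 × 128 px at 1.75 µm/px, ~67 frames per second.
    """

    image_shape: tuple[int, int] = (128, 512)  # (height, width) px
    pixel_size: float = 1.75  # µm/px
    frame_interval: float = 15.0  # ms
    n_frames: int = 510
    noise_sigma: float = 0.0  # intensity units
    background_level: float = 0.0  # intensity units

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    @property
    def fov(self) -> Bounds:
        """Field of view in µm, (x0, x1, y0, y1)."""
        h, w = self.image_shape
        return (0.0, w * self.pixel_size, 0.0, h * self.pixel_size)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def make_particle_cloud(
    density: float,
    fov: Bounds,
    seed: int | np.random.Generator,
    *,
    margin: float = 0.0,
    diameter: float = 5.25,
    brightness: float = 100.0,
    brightness_cv: float = 0.2,
) -> ParticleCloud:
    """Scatter tracers uniformly over ``fov`` widened by ``margin`` along x.

    The particle count is Poisson with mean ``density × area`` of the widened
    region; positions, diameters and brightnesses are drawn deterministically
    from ``seed``.  The default diameter (3 px at 1.75 µm/px) gives a Gaussian
    spot of σ ≈ 1.3 px, wide enough for subpixel peak fitting.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    x0, x1, y0, y1 = fov
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate field of view")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xa, xb = x0 - margin, x1 + margin
    area = (xb - xa) * (y1 - y0)
    n = int(rng.poisson(density * area)) if density > 0 else 0
    pos = np.empty((n, 2))
    pos[:, 0] = rng.uniform(xa, xb, size=n)
    pos[:, 1] = rng.uniform(y0, y1, size=n)
    bright = brightness * np.exp(rng.normal(0.0, brightness_cv, size=n)) if n else np.empty(0)
    return ParticleCloud(
        positions=pos,
        diameters=np.full(n, float(diameter)),
        brightness=bright,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


def advect(
    cloud: ParticleCloud,
    flow: FlowFieldSpec,
    t0: float,
    dt: float,
    *,
    wrap: Bounds | None = None,
    max_step: float | None = None,
) -> ParticleCloud:
    """Advance tracers through the flow from ``t0`` to ``t0 + dt`` by RK4.

    The fixed integration step is at most ``dt/4`` (or ``max_step`` if
    smaller).  When ``wrap`` bounds are given, particles leaving the widened
    domain along x are recycled at the opposite (inflow) edge, keeping the
    seeding density stationary.  The channel is treated as extending axially
    beyond the imaged lumen crop: velocities are evaluated with x clamped
    into the lumen's x-range, so tracers in the margin bands keep moving
    (the cross-lumen profile depends only on y).
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    step = dt / 4.0
    if max_step is not None:
        step = min(step, max_step)
    n_steps = max(4, int(math.ceil(dt / step)))
    h = dt / n_steps
    lx0, lx1, _, _ = flow.lumen

    def field(p: np.ndarray, t: float) -> np.ndarray:
        q = p.copy()
        q[:, 0] = np.clip(q[:, 0], lx0, lx1)
        return flow.evaluate(q, t)

    pos = cloud.positions.copy()
    t = t0
    for _ in range(n_steps):
        k1 = field(pos, t)
        k2 = field(pos + 0.5 * h * k1, t + 0.5 * h)
        k3 = field(pos + 0.5 * h * k2, t + 0.5 * h)
        k4 = field(pos + h * k3, t + h)
        pos += (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    if wrap is not None:
        wx0, wx1, _, _ = wrap
        width = wx1 - wx0
        pos[:, 0] = wx0 + np.mod(pos[:, 0] - wx0, width)
    return ParticleCloud(pos, cloud.diameters.copy(), cloud.brightness.copy(), cloud.seed)


def render_frame(
    cloud: ParticleCloud,
    acq: AcquisitionParams,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Render tracers as pixel-integrated Gaussian spots.

    Each particle contributes an isotropic Gaussian of σ = diameter/2.355
    whose mass (integral over the plane) equals its brightness; the Gaussian
    is integrated exactly over each pixel via the error function.  A constant
    background and zero-mean Gaussian noise are added, and the result is
    clipped at zero.
    """
    h, w = acq.image_shape
    frame = np.zeros((h, w), dtype=float)
    if len(cloud) > 0:
        px = cloud.positions[:, 0] / acq.pixel_size  # column coordinate
        py = cloud.positions[:, 1] / acq.pixel_size  # row coordinate
        sigma = (cloud.diameters / 2.355) / acq.pixel_size  # px
        # one stamp radius for all particles (diameters are typically equal)
        r = int(np.ceil(4.0 * sigma.max())) + 1
        offs = np.arange(-r, r + 1)
        cx = np.round(px).astype(int)
        cy = np.round(py).astype(int)
        s2 = sigma[:, None] * math.sqrt(2.0)
        # pixel i integrates [i-1/2, i+1/2]; mass fraction from erf differences
        ex = 0.5 * (
            erf((cx[:, None] + offs[None, :] + 0.5 - px[:, None]) / s2)
            - erf((cx[:, None] + offs[None, :] - 0.5 - px[:, None]) / s2)
        )
        ey = 0.5 * (
            erf((cy[:, None] + offs[None, :] + 0.5 - py[:, None]) / s2)
            - erf((cy[:, None] + offs[None, :] - 0.5 - py[:, None]) / s2)
        )
        stamps = cloud.brightness[:, None, None] * ey[:, :, None] * ex[:, None, :]
        rows, cols = np.broadcast_arrays(
            cy[:, None, None] + offs[None, :, None],
            cx[:, None, None] + offs[None, None, :],
        )
        ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        np.add.at(frame, (rows[ok], cols[ok]), stamps[ok])
    frame += acq.background_level
    if acq.noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        frame += rng.normal(0.0, acq.noise_sigma, size=frame.shape)
    return np.clip(frame, 0.0, None)


@dataclasses.dataclass
class SyntheticRecording:
    """A generated movie together with the analytic flow that produced it."""

    stack: "FrameStack"  # noqa: F821 - forward ref, defined in cardiopiv.piv
    flow: FlowFieldSpec
    acq: AcquisitionParams
    times: np.ndarray  # (n_frames,) s
    seed: int
    density: float

    def ground_truth_displacement(self, x_px: np.ndarray, y_px: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Mean px/frame displacement between frames k and k+1 on a pixel grid."""
        dt = self.acq.frame_interval / 1000.0
        xs = np.asarray(x_px, float) * self.acq.pixel_size
        ys = np.asarray(y_px, float) * self.acq.pixel_size
        # average the field over the inter-frame interval (trapezoid on 5 points)
        ts = self.times[k] + dt * np.linspace(0, 1, 5)
        u = np.zeros((len(ys), len(xs)))
        v = np.zeros_like(u)
        wts = np.array([0.5, 1, 1, 1, 0.5]) / 4.0
        for t, wt in zip(ts, wts):
            uu, vv = self.flow.sample_on_grid(xs, ys, t)
            u += wt * uu
            v += wt * vv
        scale = dt / self.acq.pixel_size
        return u * scale, v * scale

    def write(self, outdir: str | Path, stem: str = "movie") -> dict[str, Path]:
        """Write the TIFF stack, sidecar JSON and ground-truth CSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tif = outdir / f"{stem}.tif"
        tifffile.imwrite(tif, self.stack.frames.astype(np.float32))
        sidecar = outdir / f"{stem}.json"
        sidecar.write_text(
            json.dumps(
                {
                    "acquisition": self.acq.to_dict(),
                    "flow": self.flow.to_dict(),
                    "seed": self.seed,
                    "density": self.density,
                },
                indent=2,
            )
        )
        # ground-truth field sampled on the final-pass PIV grid, one cycle
        import pandas as pd

        xs = np.arange(8, self.acq.image_shape[1] - 7, 4)
        ys = np.arange(8, self.acq.image_shape[0] - 7, 4)
        rows = []
        n_per_cycle = max(1, int(round(self.flow.period / (self.acq.frame_interval / 1000.0))))
        for k in range(min(n_per_cycle, self.stack.n_frames - 1)):
            u, v = self.ground_truth_displacement(xs, ys, k)
            xx, yy = np.meshgrid(xs, ys)
            rows.append(
                pd.DataFrame(
                    {
                        "t_s": self.times[k],
                        "x_px": xx.ravel(),
                        "y_px": yy.ravel(),
                        "u_px_frame": u.ravel(),
                        "v_px_frame": v.ravel(),
                    }
                )
            )
        csv = outdir / f"{stem}_truth.csv"
        pd.concat(rows, ignore_index=True).to_csv(csv, index=False, float_format="%.6g")
        return {"tiff": tif, "sidecar": sidecar, "truth": csv}


def generate_sequence(
    flow: FlowFieldSpec,
    acq: AcquisitionParams,
    density: float,
    seed: int,
    *,
    tissue: bool = True,
    tissue_density: float | None = None,
    tissue_amplitude: float | None = None,
) -> SyntheticRecording:
    """Generate a particle movie advected by ``flow`` under ``acq`` settings.

    Tracers are seeded only inside the lumen (blood cells stay in the blood),
    advected frame to frame with RK4 and recycled at the inflow edge of a
    margin band so the seeding density stays stationary.  When ``tissue`` is
    true and the flow is time-varying, a band of static-density "tissue"
    particles outside the lumen oscillates laterally with zero net drift at
    the cardiac period, emulating periodic myocardial wall motion; this is
    what gives the whole image the cycle-to-cycle similarity that temporal
    alignment relies on.

    Raises ``ValueError`` when a time-varying flow is not covered for at
    least two periods.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    span = acq.n_frames * acq.frame_interval / 1000.0
    periodic = bool(flow.harmonics)
    if periodic and span < 2 * flow.period:
        raise ValueError(
            f"recording spans {span:.3g} s but must cover at least two flow periods "
            f"(period = {flow.period:.3g} s)"
        )
    ss = np.random.SeedSequence(seed)
    rng_cloud, rng_tissue, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]

    dt = acq.frame_interval / 1000.0
    fx0, fx1, fy0, fy1 = acq.fov
    lx0, lx1, ly0, ly1 = flow.lumen
    # seeding region: lumen clipped to the field of view in y, widened in x
    max_disp = flow.peak_speed * dt
    margin = max(8 * acq.pixel_size, 1.5 * max_disp + 4 * 5.25)
    seed_region = (max(fx0, lx0), min(fx1, lx1), max(fy0, ly0), min(fy1, ly1))
    cloud = make_particle_cloud(density, seed_region, rng_cloud, margin=margin)
    wrap = (seed_region[0] - margin, seed_region[1] + margin, seed_region[2], seed_region[3])

    # tissue band: everything in the FOV outside the lumen (in y)
    tissue_base = None
    if tissue and periodic:
        # the myocardial wall is denser and brighter than the tracer-seeded
        # blood, which is what gives whole-image frames their cycle-to-cycle
        # similarity despite tracer turnover
        t_dens = 2.0 * density if tissue_density is None else tissue_density
        bands = []
        if ly0 > fy0:
            bands.append((fx0, fx1, fy0, ly0))
        if ly1 < fy1:
            bands.append((fx0, fx1, ly1, fy1))
        clouds = [make_particle_cloud(t_dens, b, rng_tissue, brightness=150.0) for b in bands]
        if clouds:
            tissue_base = ParticleCloud(
                np.vstack([c.positions for c in clouds]) if clouds else np.empty((0, 2)),
                np.concatenate([c.diameters for c in clouds]),
                np.concatenate([c.brightness for c in clouds]),
            )
    amp = 5.0 * acq.pixel_size if tissue_amplitude is None else tissue_amplitude

    frames = np.empty((acq.n_frames, *acq.image_shape))
    times = np.arange(acq.n_frames) * dt
    current = cloud
    for k, t in enumerate(times):
        render_cloud = current
        if tissue_base is not None:
            # elliptical wall trajectory: zero net drift, and the offset only
            # repeats at true period multiples (no mirrored-phase aliasing)
            theta = 2 * math.pi * t / flow.period
            tpos = tissue_base.positions.copy()
            tpos[:, 0] += amp * math.sin(theta)
            tpos[:, 1] += 0.4 * amp * math.cos(theta)
            render_cloud = ParticleCloud(
                np.vstack([current.positions, tpos]),
                np.concatenate([current.diameters, tissue_base.diameters]),
                np.concatenate([current.brightness, tissue_base.brightness]),
            )
        frames[k] = render_frame(render_cloud, acq, rng_noise)
        if k + 1 < acq.n_frames:
            current = advect(current, flow, t, dt, wrap=wrap)

    from .piv import FrameStack  # local import to avoid a cycle at module load

    stack = FrameStack(frames=frames, pixel_size=acq.pixel_size, frame_interval=acq.frame_interval)
    return SyntheticRecording(
        stack=stack, flow=flow, acq=acq, times=times, seed=seed, density=density
    )


def make_waveform(
    kind: str, mean_flow: float, osc_amplitude: float, n_samples: int
) -> FlowProfile:
    """One cycle of a single-harmonic flow waveform Q(t) = mean + amp·cos.

    ``control`` requires amplitude < mean (forward-only flow); ``ablated``
    requires amplitude > mean (sign-changing, partly retrograde flow).  The
    analytic fundamental harmonic index of either waveform is
    ``amplitude / mean`` by construction.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    if kind == "control":
        if not osc_amplitude < mean_flow:
            raise ValueError("control waveform requires osc_amplitude < mean_flow")
    elif kind == "ablated":
        if not osc_amplitude > mean_flow:
            raise ValueError("ablated waveform requires osc_amplitude > mean_flow")
    else:
        raise ValueError(f"kind must be 'control' or 'ablated', got {kind!r}")
    phase = np.arange(n_samples) / n_samples
    q = mean_flow + osc_amplitude * np.cos(2 * np.pi * phase)
    return FlowProfile(phase=phase, Q=q, n_sections_averaged=1, n_stacks=1)
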