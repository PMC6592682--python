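"""Multigrid ensemble particle image velocimetry for periodic (cardiac) flows.

The estimator follows the classic interrogation-window scheme: a window of
one frame is matched against a search region of the next frame by zero-mean
normalized cross-correlation (ZNCC), and the correlation peak gives the local
displacement.  Two extensions make this workable on sparse, noisy movies of
blood cells in a beating heart:

* **ensemble correlation** — frames are first aligned to the cardiac cycle
  (the period is estimated from whole-image temporal self-similarity) and the
  correlation planes of all window pairs sampling the *same cardiac phase*
  across all cycles are averaged before peak detection;
* **multigrid refinement** — correlation passes run over progressively
  smaller windows, each pass re-centering the interrogation windows of the
  next using its own velocity estimate, so the final pass only measures a
  small residual displacement.

Conventions: 0-based pixel indices, pixel centers at integer coordinates,
x = column, y = row; displacements are positive rightward/downward and are
expressed in px/frame, with exact conversion to µm/s through the stack
calibration.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.fft
from scipy.ndimage import maximum_filter

__all__ = [
    "FrameStack",
    "CycleAlignment",
    "InterrogationGrid",
    "CorrelationPlane",
    "EnsemblePlanes",
    "PeakFit",
    "VelocityField",
    "AperiodicStackError",
    "DegenerateWindowError",
    "EmptyPhaseBinError",
    "AllVectorsInvalidError",
    "align_cycles",
    "correlate_window_pair",
    "ensemble_correlation",
    "locate_peak",
    "multigrid_piv",
    "validate_vectors",
]

DEFAULT_SCHEDULE = ((48, 24), (32, 12), (16, 4))

SOURCE_MEASURED = 0
SOURCE_INTERPOLATED = 1


class AperiodicStackError(ValueError):
    """No cardiac period could be detected in the movie."""


class DegenerateWindowError(ValueError):
    """A correlation plane with no usable signal (zero-variance window)."""


class EmptyPhaseBinError(ValueError):
    """A phase bin contains no frame pairs to pool."""


class AllVectorsInvalidError(ValueError):
    """Vector validation rejected every vector of a field."""


# --------------------------------------------------------------------------- #
# containers


@dataclasses.dataclass
class FrameStack:
    """A uniformly sampled time-lapse of 2-D intensity frames.

    ``pixel_size`` is in µm/px and ``frame_interval`` in ms.
    """

    frames: np.ndarray  # (n_frames, h, w)
    pixel_size: float
    frame_interval: float
    z_index: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a (n_frames >= 2, h, w) array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __getitem__(self, sl) -> "FrameStack":
        return FrameStack(self.frames[sl], self.pixel_size, self.frame_interval, self.z_index)

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_size: float, frame_interval: float,
                  z_index: int | None = None) -> "FrameStack":
        import tifffile

        return cls(tifffile.imread(path), pixel_size, frame_interval, z_index)


@dataclasses.dataclass
class CycleAlignment:
    """Estimated cardiac period and the phase/bin assignment of every frame."""

    period: float  # frames (real-valued)
    phase_of_frame: np.ndarray  # (n,) in [0, 1)
    bin_of_frame: np.ndarray  # (n,) ints in [0, n_phase_bins)
    n_phase_bins: int
    similarity_lags: np.ndarray | None = None
    similarity: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.phase_of_frame)

    @property
    def n_cycles(self) -> float:
        return self.n_frames / self.period

    @classmethod
    def steady(cls, n_frames: int) -> "CycleAlignment":
        """Degenerate alignment for a steady flow: one bin holding all pairs."""
        return cls(
            period=float(n_frames),
            phase_of_frame=np.zeros(n_frames),
            bin_of_frame=np.zeros(n_frames, dtype=int),
            n_phase_bins=1,
        )

    @classmethod
    def from_period(cls, period: float, n_frames: int, n_phase_bins: int | None = None) -> "CycleAlignment":
        """Alignment from a known period (e.g. synthetic ground truth)."""
        if not period >= 4:
            raise ValueError("period must be >= 4 frames")
        nb = int(round(period)) if n_phase_bins is None else int(n_phase_bins)
        phase = np.mod(np.arange(n_frames) / period, 1.0)
        bins = _phase_bins(phase, nb)
        return cls(period=float(period), phase_of_frame=phase, bin_of_frame=bins, n_phase_bins=nb)


@dataclasses.dataclass
class InterrogationGrid:
    """Regular grid of square interrogation-window centers."""

    window_size: int
    spacing: int
    x: np.ndarray  # (nx,) center columns
    y: np.ndarray  # (ny,) center rows
    pass_index: int = 0

    def __post_init__(self) -> None:
        if self.spacing > self.window_size:
            raise ValueError("spacing must be <= window_size (windows tile or overlap)")

    @classmethod
    def cover(cls, frame_shape: tuple[int, int], window_size: int, spacing: int,
              pass_index: int = 0) -> "InterrogationGrid":
        h, w = frame_shape
        half = window_size // 2
        rest = window_size - half
        if h < window_size or w < window_size:
            raise ValueError(
                f"frame {h}x{w} too small for {window_size}-px interrogation windows"
            )
        xs = np.arange(half, w - rest + 1, spacing)
        ys = np.arange(half, h - rest + 1, spacing)
        return cls(window_size=window_size, spacing=spacing, x=xs, y=ys, pass_index=pass_index)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.y), len(self.x))

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (cy, cx) center arrays in raster order."""
        xx, yy = np.meshgrid(self.x, self.y)
        return yy.ravel(), xx.ravel()


@dataclasses.dataclass
class CorrelationPlane:
    """ZNCC values over integer displacement lags, (0,0) at the plane center."""

    values: np.ndarray  # (2R+1, 2R+1); row = y-lag + R, col = x-lag + R
    search_radius: int
    n_pairs_pooled: int = 1
    degenerate: bool = False

    def __post_init__(self) -> None:
        r = self.search_radius
        if self.values.shape != (2 * r + 1, 2 * r + 1):
            raise ValueError("correlation plane shape inconsistent with search radius")


@dataclasses.dataclass(frozen=True)
class PeakFit:
    """Subpixel displacement located on a correlation plane."""

    dx: float
    dy: float
    value: float
    peak_ratio: float
    border_limited: bool = False


@dataclasses.dataclass
class VelocityField:
    """Per-phase velocity vectors on an interrogation grid.

    ``u``/``v`` are in px/frame with shape (n_phase_bins, ny, nx); µm/s
    values follow exactly from the calibration via ``u_um_s``/``v_um_s``.
    ``source`` distinguishes measured vectors from ones replaced during
    validation.
    """

    x: np.ndarray  # (nx,) center columns, px
    y: np.ndarray  # (ny,) center rows, px
    u: np.ndarray  # (B, ny, nx) px/frame, x-component
    v: np.ndarray  # (B, ny, nx) px/frame, y-component
    valid: np.ndarray  # (B, ny, nx) bool
    source: np.ndarray  # (B, ny, nx) uint8; 0 measured, 1 interpolated
    peak_ratio: np.ndarray  # (B, ny, nx)
    pixel_size: float  # µm/px
    frame_interval: float  # ms
    period: float | None = None
    window_size: int | None = None
    spacing: int | None = None

    @property
    def n_phase_bins(self) -> int:
        return self.u.shape[0]

    @property
    def _um_s_scale(self) -> float:
        return self.pixel_size / (self.frame_interval / 1000.0)

    @property
    def u_um_s(self) -> np.ndarray:
        return self.u * self._um_s_scale

    @property
    def v_um_s(self) -> np.ndarray:
        return self.v * self._um_s_scale

    def to_dataframe(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x, self.y)
        rows = []
        for b in range(self.n_phase_bins):
            rows.append(
                pd.DataFrame(
                    {
                        "phase_bin": b,
                        "x_px": xx.ravel(),
                        "y_px": yy.ravel(),
                        "u_px_per_frame": self.u[b].ravel(),
                        "v_px_per_frame": self.v[b].ravel(),
                        "u_um_s": self.u_um_s[b].ravel(),
                        "v_um_s": self.v_um_s[b].ravel(),
                        "valid": self.valid[b].ravel(),
                        "source": self.source[b].ravel(),
                        "peak_ratio": self.peak_ratio[b].ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_flow_spec(
        cls,
        flow,
        x_px: np.ndarray,
        y_px: np.ndarray,
        pixel_size: float,
        frame_interval: float,
        n_phase_bins: int = 1,
        period: float | None = None,
        valid_mask: np.ndarray | None = None,
    ) -> "VelocityField":
        """Sample an analytic flow onto a grid (ground-truth field for tests).

        Bins sample the flow at mid-bin times of one cycle; a steady flow may
        use a single bin.
        """
        x_px = np.asarray(x_px, float)
        y_px = np.asarray(y_px, float)
        T = flow.period if period is None else period
        scale = (frame_interval / 1000.0) / pixel_size  # µm/s -> px/frame
        u = np.empty((n_phase_bins, len(y_px), len(x_px)))
        v = np.empty_like(u)
        for b in range(n_phase_bins):
            t = (b + 0.5) / n_phase_bins * T
            uu, vv = flow.sample_on_grid(x_px * pixel_size, y_px * pixel_size, t)
            u[b] = uu * scale
            v[b] = vv * scale
        valid = np.ones(u.shape, dtype=bool)
        if valid_mask is not None:
            valid &= np.asarray(valid_mask, bool)[None, :, :]
        return cls(
            x=x_px, y=y_px, u=u, v=v, valid=valid,
            source=np.zeros(u.shape, dtype=np.uint8),
            peak_ratio=np.full(u.shape, np.inf),
            pixel_size=pixel_size, frame_interval=frame_interval, period=T,
        )


def _phase_bins(phase: np.ndarray, nb: int) -> np.ndarray:
    """Bin phases into nb bins partitioning [0, 1), robust to float jitter."""
    bins = np.floor(phase * nb + 1e-9).astype(int)
    return np.minimum(bins % nb, nb - 1)


# --------------------------------------------------------------------------- #
# temporal alignment


def align_cycles(
    stack: FrameStack,
    n_phase_bins: int | None = None,
    *,
    min_period: int = 4,
    similarity_floor: float = 0.2,
) -> CycleAlignment:
    """Estimate the cardiac period and assign every frame a phase.

    The mean normalized whole-image correlation ⟨corr(frame_k, frame_{k+L})⟩
    is computed for every lag L; the period is the smallest local maximum
    within 0.05 of the best peak, refined to sub-frame precision by parabolic
    interpolation and then polished against the highest usable harmonic of
    itself (the peak near m×period, divided by m), which divides the
    interpolation error by m.

    Raises :class:`AperiodicStackError` when no lag is at least
    ``similarity_floor`` above the baseline (median) similarity, and
    ``ValueError`` when the stack cannot contain two periods.
    """
    n = stack.n_frames
    max_lag = n // 2
    if max_lag < min_period:
        raise ValueError("stack shorter than two candidate periods")
    flat = stack.frames.reshape(n, -1).astype(np.float32)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1)
    if not np.any(norms > 1e-12 * (1 + np.abs(stack.frames).max())):
        raise AperiodicStackError("aperiodic stack: frames have no intensity structure")
    safe = np.where(norms > 0, norms, 1.0)
    flat /= safe[:, None]
    gram = flat @ flat.T
    lags = np.arange(1, max_lag + 1)
    sim = np.array([float(np.diagonal(gram, offset=int(L)).mean()) for L in lags])

    baseline = float(np.median(sim))
    floor = baseline + similarity_floor
    is_peak = np.zeros(len(sim), dtype=bool)
    is_peak[1:-1] = (sim[1:-1] > sim[:-2]) & (sim[1:-1] >= sim[2:])
    is_peak &= lags >= min_period
    is_peak &= sim >= floor
    if not is_peak.any():
        raise AperiodicStackError(
            "aperiodic stack: no whole-image similarity peak above the floor "
            f"({similarity_floor:.2f} over baseline {baseline:.2f})"
        )
    best = sim[is_peak].max()
    candidates = np.where(is_peak & (sim >= best - 0.05))[0]
    i0 = int(candidates.min())

    def _refine(i: int) -> float:
        if 0 < i < len(sim) - 1:
            denom = sim[i - 1] - 2 * sim[i] + sim[i + 1]
            if denom < 0:
                return float(lags[i]) + 0.5 * (sim[i - 1] - sim[i + 1]) / denom
        return float(lags[i])

    period = _refine(i0)
    # polish against higher multiples of the period: the similarity peak near
    # m*T localizes T with m-fold smaller interpolation error
    m = 1
    while 2 * m * period <= max_lag - 3:
        m *= 2
        center = int(round(m * period))
        lo = max(0, center - 1 - 3)
        hi = min(len(sim), center - 1 + 4)
        j = lo + int(np.argmax(sim[lo:hi]))
        if sim[j] < floor:
            m //= 2
            break
        period = _refine(j) / m
    if period < min_period:
        raise AperiodicStackError(f"detected period {period:.2f} frames is below {min_period}")

    nb = int(round(period)) if n_phase_bins is None else int(n_phase_bins)
    phase = np.mod(np.arange(n) / period, 1.0)
    bins = _phase_bins(phase, nb)
    return CycleAlignment(
        period=float(period),
        phase_of_frame=phase,
        bin_of_frame=bins,
        n_phase_bins=nb,
        similarity_lags=lags,
        similarity=sim,
    )


# --------------------------------------------------------------------------- #
# window correlation (batched FFT ZNCC)


def _gather(frame: np.ndarray, sy: np.ndarray, sx: np.ndarray, size: int) -> np.ndarray:
    """Stack windows frame[sy:sy+size, sx:sx+size] for every start pair."""
    r = np.arange(size)
    return frame[sy[:, None, None] + r[None, :, None], sx[:, None, None] + r[None, None, :]]


def _zncc_planes(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    cy: np.ndarray,
    cx: np.ndarray,
    window_size: int,
    search_radius: int,
    pred_dx: np.ndarray,
    pred_dy: np.ndarray,
):
    """Batched ZNCC planes for many interrogation windows of one frame pair.

    For each window the template (window of ``frame_a``) is correlated
    against the ``(w+2R)``-px search region of ``frame_b`` centered at the
    predictor-shifted position; the plane holds the normalized correlation
    coefficient at every integer residual lag in [−R, R]².

    Returns ``(planes (N, 2R+1, 2R+1), ok (N,), degenerate (N,))`` where
    ``ok`` is False for windows whose (shifted) region leaves the frame.
    """
    h, w_img = frame_a.shape
    w = int(window_size)
    R = int(search_radius)
    W = w + 2 * R
    half = w // 2

    say = cy - half
    sax = cx - half
    sby = say - R + pred_dy
    sbx = sax - R + pred_dx
    ok = (
        (say >= 0) & (sax >= 0) & (say + w <= h) & (sax + w <= w_img)
        & (sby >= 0) & (sbx >= 0) & (sby + W <= h) & (sbx + W <= w_img)
    )
    say_c = np.clip(say, 0, h - w)
    sax_c = np.clip(sax, 0, w_img - w)
    sby_c = np.clip(sby, 0, h - W)
    sbx_c = np.clip(sbx, 0, w_img - W)

    A = _gather(np.asarray(frame_a, float), say_c, sax_c, w)
    B = _gather(np.asarray(frame_b, float), sby_c, sbx_c, W)

    A = A - A.mean(axis=(1, 2), keepdims=True)
    norm_a = np.sqrt((A * A).sum(axis=(1, 2)))
    scale = np.abs(A).max(axis=(1, 2)) + np.abs(B).max(axis=(1, 2))
    degenerate = norm_a <= 1e-12 * (1.0 + scale) * w

    # linear cross-correlation C[u, v] = sum_ij A[i, j] * B[i+u, j+v]
    S = scipy.fft.next_fast_len(W + w - 1)
    FA = scipy.fft.rfft2(A[:, ::-1, ::-1], s=(S, S))
    FB = scipy.fft.rfft2(B, s=(S, S))
    conv = scipy.fft.irfft2(FA * FB, s=(S, S))
    C = conv[:, w - 1 : w + 2 * R, w - 1 : w + 2 * R]

    # sliding w×w sums of B and B² via integral images
    pad = np.zeros((B.shape[0], W + 1, W + 1))
    pad[:, 1:, 1:] = B
    I1 = pad.cumsum(axis=1).cumsum(axis=2)
    pad[:, 1:, 1:] = B * B
    I2 = pad.cumsum(axis=1).cumsum(axis=2)

    def patch_sums(I):
        return (
            I[:, w : w + 2 * R + 1, w : w + 2 * R + 1]
            - I[:, 0 : 2 * R + 1, w : w + 2 * R + 1]
            - I[:, w : w + 2 * R + 1, 0 : 2 * R + 1]
            + I[:, 0 : 2 * R + 1, 0 : 2 * R + 1]
        )

    S1 = patch_sums(I1)
    S2 = patch_sums(I2)
    var_b = np.clip(S2 - S1 * S1 / (w * w), 0.0, None)
    denom = norm_a[:, None, None] * np.sqrt(var_b)
    tiny = 1e-12 * (1.0 + scale[:, None, None] ** 2) * w * w
    planes = np.where(denom > tiny, C / np.where(denom > 0, denom, 1.0), 0.0)
    planes = np.clip(planes, -1.0, 1.0)
    planes[degenerate] = 0.0
    planes[~ok] = 0.0
    return planes, ok, degenerate


def correlate_window_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    center: tuple[int, int],
    window_size: int,
    search_radius: int,
    predictor_shift: tuple[int, int] = (0, 0),
) -> CorrelationPlane:
    """ZNCC plane of one interrogation window between two frames.

    ``center`` is (cx, cy) and ``predictor_shift`` (dx, dy) in px.  The
    matching window of ``frame_b`` is pre-shifted by the predictor, so the
    plane measures the residual displacement.  Both windows must lie inside
    their frames; a zero-variance template yields a degenerate (all-zero)
    plane.
    """
    cx, cy = center
    dx, dy = predictor_shift
    planes, ok, degen = _zncc_planes(
        np.asarray(frame_a, float),
        np.asarray(frame_b, float),
        np.array([cy]),
        np.array([cx]),
        window_size,
        search_radius,
        np.array([int(dx)]),
        np.array([int(dy)]),
    )
    if not ok[0]:
        raise ValueError("interrogation window (after predictor shift) leaves the frame")
    return CorrelationPlane(
        values=planes[0], search_radius=search_radius, n_pairs_pooled=1,
        degenerate=bool(degen[0]),
    )


@dataclasses.dataclass
class EnsemblePlanes:
    """Phase-pooled correlation planes for every window of a grid."""

    values: np.ndarray  # (ny, nx, 2R+1, 2R+1)
    search_radius: int
    n_pairs_pooled: int
    ok: np.ndarray  # (ny, nx) window geometry valid
    degenerate: np.ndarray  # (ny, nx) no usable signal in any pooled pair
    grid: InterrogationGrid
    phase_bin: int

    def plane(self, iy: int, ix: int) -> CorrelationPlane:
        return CorrelationPlane(
            values=self.values[iy, ix],
            search_radius=self.search_radius,
            n_pairs_pooled=self.n_pairs_pooled,
            degenerate=bool(self.degenerate[iy, ix]),
        )


def ensemble_correlation(
    stack: FrameStack,
    alignment: CycleAlignment,
    grid: InterrogationGrid,
    phase_bin: int,
    *,
    search_radius: int = 4,
    predictor: np.ndarray | None = None,
) -> EnsemblePlanes:
    """Average correlation planes over all same-phase frame pairs.

    Every consecutive pair (k, k+1) whose first frame falls in ``phase_bin``
    contributes one ZNCC plane per window; the ensemble plane is their
    arithmetic mean.  ``predictor``, shape (ny, nx, 2) of integer (dx, dy),
    pre-shifts the second window of each pair.
    """
    ks = np.where(alignment.bin_of_frame[: stack.n_frames - 1] == phase_bin)[0]
    if len(ks) == 0:
        raise EmptyPhaseBinError(f"phase bin {phase_bin} contains no frame pairs")
    cy, cx = grid.centers()
    ny, nx = grid.shape
    if predictor is None:
        pdx = np.zeros(ny * nx, dtype=int)
        pdy = np.zeros(ny * nx, dtype=int)
    else:
        pred = np.asarray(predictor)
        pdx = np.rint(pred[..., 0]).astype(int).ravel()
        pdy = np.rint(pred[..., 1]).astype(int).ravel()
    acc = None
    degen_all = None
    ok_all = None
    for k in ks:
        planes, ok, degen = _zncc_planes(
            stack.frames[k], stack.frames[k + 1], cy, cx,
            grid.window_size, search_radius, pdx, pdy,
        )
        acc = planes if acc is None else acc + planes
        degen_all = degen if degen_all is None else (degen_all & degen)
        ok_all = ok if ok_all is None else (ok_all & ok)
    r = search_radius
    return EnsemblePlanes(
        values=(acc / len(ks)).reshape(ny, nx, 2 * r + 1, 2 * r + 1),
        search_radius=r,
        n_pairs_pooled=len(ks),
        ok=ok_all.reshape(ny, nx),
        degenerate=degen_all.reshape(ny, nx),
        grid=grid,
        phase_bin=phase_bin,
    )


# --------------------------------------------------------------------------- #
# peak location


def _subpixel_1d(lo: float, c: float, hi: float) -> float:
    """Three-point Gaussian fit, parabolic fallback for non-positive triplets."""
    if lo > 0 and c > 0 and hi > 0:
        llo, lc, lhi = np.log(lo), np.log(c), np.log(hi)
        denom = llo + lhi - 2 * lc
        if denom < 0:
            return float(np.clip(0.5 * (llo - lhi) / denom, -1.0, 1.0))
    denom = lo + hi - 2 * c
    if denom < 0:
        return float(np.clip(0.5 * (lo - hi) / denom, -1.0, 1.0))
    return 0.0


def locate_peak(plane: CorrelationPlane) -> PeakFit:
    """Find the correlation peak with subpixel (3-point Gaussian) refinement.

    Ties between equal maxima break toward the smaller displacement
    magnitude, then lexicographically on (dx, dy).  A peak on the search
    border is returned at integer precision and flagged ``border_limited``.
    ``peak_ratio`` is the highest local maximum divided by the second
    highest (∞ when there is no second local maximum).
    """
    if plane.degenerate:
        raise DegenerateWindowError("degenerate window: no correlation signal")
    vals = plane.values
    r = plane.search_radius
    vmax = vals.max()
    if vals.min() == vmax:
        raise DegenerateWindowError("degenerate window: flat correlation plane")
    iy, ix = np.where(vals == vmax)
    dxs, dys = ix - r, iy - r
    order = np.lexsort((dys, dxs, dxs * dxs + dys * dys))
    j = order[0]
    iy, ix = int(iy[j]), int(ix[j])
    dx, dy = float(ix - r), float(iy - r)

    # peak ratio over 3x3 local maxima
    local_max = (maximum_filter(vals, size=3, mode="constant", cval=-np.inf) == vals)
    peak_vals = np.sort(vals[local_max])[::-1]
    if len(peak_vals) >= 2 and peak_vals[1] > 0:
        ratio = float(peak_vals[0] / peak_vals[1])
    else:
        ratio = np.inf

    on_border = iy in (0, 2 * r) or ix in (0, 2 * r)
    if on_border:
        return PeakFit(dx=dx, dy=dy, value=float(vmax), peak_ratio=ratio, border_limited=True)
    dx += _subpixel_1d(vals[iy, ix - 1], vals[iy, ix], vals[iy, ix + 1])
    dy += _subpixel_1d(vals[iy - 1, ix], vals[iy, ix], vals[iy + 1, ix])
    return PeakFit(dx=dx, dy=dy, value=float(vmax), peak_ratio=ratio, border_limited=False)


# --------------------------------------------------------------------------- #
# vector validation


def validate_vectors(
    field: VelocityField, threshold: float = 2.0, *, noise_floor: float = 0.1
) -> VelocityField:
    """Normalized-median outlier test over each vector's 8-neighborhood.

    A vector is flagged when its deviation from the neighborhood median,
    normalized by the median neighbour fluctuation plus ``noise_floor``
    (px/frame), exceeds ``threshold``.  Flagging requires at least six valid
    neighbours — with fewer, the neighbourhood median is dominated by one
    side of any local gradient and the test misfires (grid edges are
    therefore replaced-only, never flagged).  Flagged and already-invalid
    vectors are replaced by the component-wise median of their valid
    neighbours and tagged as interpolated; validity flags are preserved in
    the output.
    """
    B, ny, nx = field.u.shape
    u = field.u.copy()
    v = field.v.copy()
    valid = field.valid.copy()
    source = field.source.copy()

    def neighbor_stack(a: np.ndarray) -> np.ndarray:
        """(8, ny, nx) neighbour values with NaN outside the grid."""
        p = np.full((ny + 2, nx + 2), np.nan)
        p[1:-1, 1:-1] = a
        shifts = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
        return np.stack([p[1 + dy : 1 + dy + ny, 1 + dx : 1 + dx + nx] for dy, dx in shifts])

    import warnings as _warnings

    for b in range(B):
        ub = np.where(valid[b], u[b], np.nan)
        vb = np.where(valid[b], v[b], np.nan)
        nu = neighbor_stack(ub)
        nv = neighbor_stack(vb)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            med_u = np.nanmedian(nu, axis=0)
            med_v = np.nanmedian(nv, axis=0)
            fluct = np.hypot(nu - med_u[None], nv - med_v[None])
            rm = np.nanmedian(fluct, axis=0)
        n_neighbors = np.sum(~np.isnan(nu), axis=0)
        resid = np.hypot(u[b] - med_u, v[b] - med_v)
        with np.errstate(invalid="ignore"):
            flagged = valid[b] & (resid / (rm + noise_floor) > threshold) & (n_neighbors >= 6)
        to_replace = flagged | ~valid[b]
        # neighbour medians computed from pre-replacement values
        repl_u = med_u
        repl_v = med_v
        if np.any(valid[b] & ~flagged):
            fill_u = float(np.median(u[b][valid[b] & ~flagged]))
            fill_v = float(np.median(v[b][valid[b] & ~flagged]))
        else:
            raise AllVectorsInvalidError(f"phase bin {b}: all vectors invalid after validation")
        u[b] = np.where(to_replace, np.where(np.isnan(repl_u), fill_u, repl_u), u[b])
        v[b] = np.where(to_replace, np.where(np.isnan(repl_v), fill_v, repl_v), v[b])
        valid[b] = valid[b] & ~flagged
        source[b] = np.where(to_replace, SOURCE_INTERPOLATED, source[b])
    return VelocityField(
        x=field.x, y=field.y, u=u, v=v, valid=valid, source=source,
        peak_ratio=field.peak_ratio, pixel_size=field.pixel_size,
        frame_interval=field.frame_interval, period=field.period,
        window_size=field.window_size, spacing=field.spacing,
    )


# --------------------------------------------------------------------------- #
# multigrid driver


def _bilinear_to(xs_old, ys_old, a, xs_new, ys_new):
    """Bilinear resampling of a 2-D grid field, edge-clamped."""
    xi = np.clip(np.searchsorted(xs_old, xs_new, side="right") - 1, 0, len(xs_old) - 2)
    yi = np.clip(np.searchsorted(ys_old, ys_new, side="right") - 1, 0, len(ys_old) - 2)
    fx = np.clip((xs_new - xs_old[xi]) / (xs_old[xi + 1] - xs_old[xi]), 0.0, 1.0)
    fy = np.clip((ys_new - ys_old[yi]) / (ys_old[yi + 1] - ys_old[yi]), 0.0, 1.0)
    fx2 = fx[None, :]
    fy2 = fy[:, None]
    xi2 = xi[None, :]
    yi2 = yi[:, None]
    return (
        a[yi2, xi2] * (1 - fx2) * (1 - fy2)
        + a[yi2, xi2 + 1] * fx2 * (1 - fy2)
        + a[yi2 + 1, xi2] * (1 - fx2) * fy2
        + a[yi2 + 1, xi2 + 1] * fx2 * fy2
    )


def multigrid_piv(
    stack: FrameStack,
    alignment: CycleAlignment,
    schedule: Sequence[tuple[int, int]] = DEFAULT_SCHEDULE,
    *,
    search_radius: int = 12,
    refinement_search_radius: int = 4,
    mask: np.ndarray | None = None,
    validation_threshold: float = 2.0,
    return_all_passes: bool = False,
):
    """Multigrid ensemble PIV over all cardiac phase bins.

    The default schedule starts at 48×48-px windows with 24-px separation and
    refines to 16×16-px windows with 4-px separation (one intermediate stage
    at 32/12 limits pair loss between the endpoints).  Pass 1 correlates with
    zero predictor and a wide search radius; each later pass bilinearly
    interpolates the previous (validated) field onto its finer grid, rounds
    it to integer window offsets, and correlates only the residual.  Vectors
    failing the normalized-median test are replaced before being used as
    predictors.

    ``mask`` (bool, frame-shaped, True = analyse) restricts estimation to
    windows whose centers lie inside the region of interest.
    """
    schedule = [(int(w), int(s)) for w, s in schedule]
    if not schedule:
        raise ValueError("empty multigrid schedule")
    for (w0, _), (w1, _) in zip(schedule, schedule[1:]):
        if w1 > w0:
            raise ValueError("schedule window sizes must be non-increasing")
    h, w_img = stack.frame_shape
    if h < schedule[0][0] or w_img < schedule[0][0]:
        raise ValueError("frame too small for the first interrogation window")

    B = alignment.n_phase_bins
    prev_field: VelocityField | None = None
    fields = []
    for p, (wsize, spacing) in enumerate(schedule):
        grid = InterrogationGrid.cover((h, w_img), wsize, spacing, pass_index=p)
        ny, nx = grid.shape
        radius = search_radius if p == 0 else refinement_search_radius
        if mask is not None:
            keep = np.asarray(mask, bool)[np.ix_(grid.y, grid.x)]
        else:
            keep = np.ones((ny, nx), dtype=bool)

        u = np.zeros((B, ny, nx))
        v = np.zeros((B, ny, nx))
        valid = np.zeros((B, ny, nx), dtype=bool)
        ratio = np.zeros((B, ny, nx))
        for b in range(B):
            if prev_field is None:
                pred = np.zeros((ny, nx, 2))
            else:
                pred = np.stack(
                    [
                        _bilinear_to(prev_field.x, prev_field.y, prev_field.u[b], grid.x, grid.y),
                        _bilinear_to(prev_field.x, prev_field.y, prev_field.v[b], grid.x, grid.y),
                    ],
                    axis=-1,
                )
            pred_int = np.rint(pred).astype(int)
            try:
                ens = ensemble_correlation(
                    stack, alignment, grid, b, search_radius=radius, predictor=pred_int
                )
            except EmptyPhaseBinError:
                continue
            for iy in range(ny):
                for ix in range(nx):
                    if not keep[iy, ix] or not ens.ok[iy, ix] or ens.degenerate[iy, ix]:
                        continue
                    try:
                        fit = locate_peak(ens.plane(iy, ix))
                    except DegenerateWindowError:
                        continue
                    u[b, iy, ix] = pred_int[iy, ix, 0] + fit.dx
                    v[b, iy, ix] = pred_int[iy, ix, 1] + fit.dy
                    ratio[b, iy, ix] = fit.peak_ratio if np.isfinite(fit.peak_ratio) else np.inf
                    valid[b, iy, ix] = not fit.border_limited
        field = VelocityField(
            x=grid.x.astype(float), y=grid.y.astype(float), u=u, v=v, valid=valid,
            source=np.zeros(u.shape, dtype=np.uint8), peak_ratio=ratio,
            pixel_size=stack.pixel_size, frame_interval=stack.frame_interval,
            period=alignment.period, window_size=wsize, spacing=spacing,
        )
        field = validate_vectors(field, threshold=validation_threshold)
        fields.append(field)
        prev_field = field
    return fields if return_all_passes else fields[-1]
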