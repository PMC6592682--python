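"""End-to-end runs: config validation, stage orchestration, run manifests.

A run goes simulate (optional) → cycle alignment → multigrid ensemble PIV →
flow profiles → FHI, writing every intermediate artifact as CSV/JSON/TIFF
plus a manifest with checksums so identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .flow import CrossSection, flow_profile, fundamental_harmonic_index
from .piv import CycleAlignment, FrameStack, align_cycles, multigrid_piv
from .synth import AcquisitionParams, FlowFieldSpec, generate_sequence

logger = logging.getLogger("cardiopiv")

#: px/frame -> µm/s for the default calibration (1.75 µm/px, 15 ms/frame)
_PXF = 1.75 / 0.015

#: Demo regime waveforms (centerline mean / oscillation amplitude, µm/s).
#: Peak displacement is kept near one quarter of the final 16-px window,
#: the standard PIV capture-range rule.  Control: amplitude < mean
#: (forward-only flow, analytic FHI 0.5).  Ablated: amplitude > mean
#: (sign-changing, partly retrograde flow, analytic FHI 2.0).
REGIMES = {
    "control": {"mean": (8.0 / 3.0) * _PXF, "amplitude": (4.0 / 3.0) * _PXF},
    "ablated": {"mean": (4.0 / 3.0) * _PXF, "amplitude": (8.0 / 3.0) * _PXF},
}

STEADY_KINDS = ("uniform", "shear", "poiseuille")


@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    out: str = "run_out"
    seed: int = 0
    pixel_size: float = 1.75  # µm/px
    frame_interval: float = 15.0  # ms
    stack: str | None = None  # input TIFF (omit when simulating)
    simulate: dict | None = None  # {regime, frames, image_shape, density, ...}
    schedule: str = "48:24,32:12,16:4"
    bins: int | str = "auto"
    search_radius: int = 12
    sections: str | list | None = "auto"  # JSON path, inline list, or "auto"
    mask: str | None = None  # lumen mask TIFF (optional)
    quant: dict | None = None  # optional: {eda, esa} and/or {image, roi}
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class RunManifest:
    """Record of a completed run: config snapshot, timings, checksums."""

    config: dict
    version: str
    seed: int
    timings: dict[str, float]
    outputs: dict[str, str]  # relative path -> sha256
    warnings: list[str]
    results: dict[str, Any]

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @staticmethod
    def verify(path: Path) -> bool:
        """Re-hash every referenced output and compare with the manifest."""
        data = json.loads(Path(path).read_text())
        root = Path(path).parent
        return all(
            _sha256(root / rel) == digest for rel, digest in data["outputs"].items()
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def parse_schedule(text: str) -> list[tuple[int, int]]:
    """Parse '48:24,32:12,16:4' into [(48, 24), (32, 12), (16, 4)]."""
    out = []
    for part in str(text).split(","):
        w, s = part.strip().split(":")
        out.append((int(w), int(s)))
    return out


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems (empty iff the config is runnable)."""
    problems: list[str] = []
    if not config.pixel_size > 0:
        problems.append("pixel_size: must be > 0 (µm/px)")
    if not config.frame_interval > 0:
        problems.append("frame_interval: must be > 0 (ms)")
    try:
        sched = parse_schedule(config.schedule)
        for (w0, _), (w1, _) in zip(sched, sched[1:]):
            if w1 > w0:
                problems.append(
                    "schedule: window sizes must be non-increasing "
                    f"(got {config.schedule!r}); list coarse-to-fine"
                )
                break
        for w, s in sched:
            if s > w:
                problems.append(f"schedule: spacing {s} exceeds window size {w}")
    except (ValueError, AttributeError):
        problems.append("schedule: expected 'W:S,W:S,...' pairs of integers")
    if config.simulate is None and config.stack is None:
        problems.append("stack: provide an input TIFF or a simulate block")
    if config.stack is not None and not Path(config.stack).exists():
        problems.append(f"stack: file not found: {config.stack}")
    if config.simulate is not None:
        regime = config.simulate.get("regime")
        if regime not in (*REGIMES, *STEADY_KINDS):
            problems.append(
                f"simulate.regime: {regime!r} not one of {sorted((*REGIMES, *STEADY_KINDS))}"
            )
    if isinstance(config.sections, str) and config.sections != "auto":
        if not Path(config.sections).exists():
            problems.append(f"sections: file not found: {config.sections}")
    if config.sections is None and config.simulate is None:
        problems.append("sections: required when analysing a supplied stack")
    if config.mask is not None and not Path(config.mask).exists():
        problems.append(f"mask: file not found: {config.mask}")
    if config.quant is not None:
        q = config.quant
        if "eda" in q or "esa" in q:
            if not ({"eda", "esa"} <= set(q)):
                problems.append("quant: fractional area change needs both eda and esa")
        if "image" in q:
            if not Path(q["image"]).exists():
                problems.append(f"quant.image: file not found: {q['image']}")
            if "roi" not in q:
                problems.append("quant: an image needs a roi JSON (measurement + backgrounds)")
            elif not Path(q["roi"]).exists():
                problems.append(f"quant.roi: file not found: {q['roi']}")
    if config.bins != "auto":
        try:
            if int(config.bins) < 1:
                problems.append("bins: must be >= 1 or 'auto'")
        except (TypeError, ValueError):
            problems.append("bins: must be an integer or 'auto'")
    return problems


# --------------------------------------------------------------------------- #
# simulation defaults


def build_flow_spec(sim: dict, acq: AcquisitionParams) -> FlowFieldSpec:
    """Flow field for a simulate block; the lumen defaults to the central
    ~58% of the image height (walls at the top/bottom bands)."""
    h, w = acq.image_shape
    px = acq.pixel_size
    lumen = tuple(sim.get("lumen", (0.0, w * px, round(0.21 * h) * px, round(0.79 * h) * px)))
    regime = sim["regime"]
    period = float(sim.get("period_s", 30 * acq.frame_interval / 1000.0))
    if regime in STEADY_KINDS:
        peak = float(sim.get("peak_speed", 3.0 * px / (acq.frame_interval / 1000.0)))
        return FlowFieldSpec.steady(regime, peak, lumen, period=period)
    params = REGIMES[regime]
    return FlowFieldSpec.pulsatile(
        float(sim.get("mean_speed", params["mean"])),
        float(sim.get("osc_amplitude", params["amplitude"])),
        period,
        lumen,
    )


def demo_config(regime: str, out: str | Path, seed: int = 0, frames: int = 310) -> RunConfig:
    """A compact, fully simulated run for one flow regime.

    Uses a 192×96-px field of view (10 cardiac cycles at 30 frames/cycle)
    so a full multigrid PIV run completes in well under a minute.
    """
    return RunConfig(
        out=str(out),
        seed=seed,
        simulate={
            "regime": regime,
            "frames": frames,
            "image_shape": [96, 192],
            "density": 0.012,
            "noise_sigma": 2.0,
            "background_level": 10.0,
        },
    )


def _auto_sections(flow: FlowFieldSpec, acq: AcquisitionParams) -> list[CrossSection]:
    """Vertical measurement lines across the inner lumen at four stations."""
    px = acq.pixel_size
    _, _, ly0, ly1 = flow.lumen
    height = ly1 - ly0
    y_top = ly0 + 0.18 * height
    y_bot = ly1 - 0.18 * height
    w_um = acq.image_shape[1] * px
    xs = np.linspace(0.35 * w_um, 0.7 * w_um, 4)
    # drawn bottom-to-top so the normal (+90° CCW of a→b) points along +x
    return [
        CrossSection(a=(float(x), float(y_bot)), b=(float(x), float(y_top)), label="ventricle")
        for x in xs
    ]


# --------------------------------------------------------------------------- #
# pipeline


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages of a run and write artifacts + manifest.

    Raises ``ValueError`` listing problems when the config is invalid, and
    :class:`StageError` naming the stage on failure (partial outputs are
    kept in the output directory).
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config:\n" + "\n".join(f"  - {p}" for p in problems))
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}
    caught: list[str] = []
    results: dict[str, Any] = {}

    def _record(path: Path) -> None:
        outputs[str(path.relative_to(outdir))] = _sha256(path)

    def _stage(name):
        class _Timer:
            def __enter__(self_t):
                self_t.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self_t

            def __exit__(self_t, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_t.t0, 3)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Timer()

    flow_spec: FlowFieldSpec | None = None
    acq: AcquisitionParams | None = None

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        with _stage("simulate" if config.simulate else "load"):
            if config.simulate:
                sim = config.simulate
                acq = AcquisitionParams(
                    image_shape=tuple(sim.get("image_shape", (128, 512))),
                    pixel_size=config.pixel_size,
                    frame_interval=config.frame_interval,
                    n_frames=int(sim.get("frames", 510)),
                    noise_sigma=float(sim.get("noise_sigma", 2.0)),
                    background_level=float(sim.get("background_level", 10.0)),
                )
                flow_spec = build_flow_spec(sim, acq)
                rec = generate_sequence(
                    flow_spec, acq, float(sim.get("density", 0.012)), seed=config.seed
                )
                stack = rec.stack
                for p in rec.write(outdir).values():
                    _record(p)
            else:
                stack = FrameStack.from_tiff(
                    config.stack, config.pixel_size, config.frame_interval
                )

        with _stage("align"):
            steady = flow_spec is not None and not flow_spec.harmonics
            if steady:
                alignment = CycleAlignment.steady(stack.n_frames)
            else:
                nb = None if config.bins == "auto" else int(config.bins)
                alignment = align_cycles(stack, n_phase_bins=nb)
            align_path = outdir / "alignment.json"
            align_path.write_text(
                json.dumps(
                    {
                        "period_frames": alignment.period,
                        "n_cycles": alignment.n_cycles,
                        "n_phase_bins": alignment.n_phase_bins,
                    },
                    indent=2,
                )
            )
            _record(align_path)
            results["period_frames"] = alignment.period

        with _stage("piv"):
            mask = None
            if config.mask is not None:
                import tifffile

                mask = tifffile.imread(config.mask).astype(bool)
            field = multigrid_piv(
                stack,
                alignment,
                parse_schedule(config.schedule),
                search_radius=int(config.search_radius),
                mask=mask,
            )
            fields_path = outdir / "fields.csv"
            field.to_dataframe().to_csv(fields_path, index=False, float_format="%.9g")
            _record(fields_path)

        with _stage("flow"):
            if config.sections == "auto":
                if flow_spec is None:
                    raise ValueError("auto sections require a simulated run")
                sections = _auto_sections(flow_spec, acq)
            elif isinstance(config.sections, (list, tuple)):
                sections = [CrossSection.from_dict(d) for d in config.sections]
            else:
                data = json.loads(Path(config.sections).read_text())
                sections = [CrossSection.from_dict(d) for d in data]
            profile = flow_profile(field, sections)
            prof_path = outdir / "profile.csv"
            pd.DataFrame(
                {
                    "region": sections[0].label,
                    "phase": profile.phase,
                    "Q_norm_um_s": profile.Q,
                    "Q_raw_um2_s": profile.Q_raw,
                }
            ).to_csv(prof_path, index=False, float_format="%.9g")
            _record(prof_path)

        with _stage("fhi"):
            harm = fundamental_harmonic_index(profile)
            fhi_path = outdir / "fhi.csv"
            pd.DataFrame(
                [
                    {
                        "region": sections[0].label,
                        "Q0": harm.Q0,
                        "Q1": harm.Q1,
                        "FHI": harm.FHI,
                    }
                ]
            ).to_csv(fhi_path, index=False, float_format="%.9g")
            _record(fhi_path)
            results["Q0_um_s"] = harm.Q0
            results["Q1_um_s"] = harm.Q1
            results["FHI"] = harm.FHI
            if flow_spec is not None and flow_spec.harmonics:
                results["FHI_analytic"] = flow_spec.analytic_fhi

        if config.quant is not None:
            with _stage("quant"):
                from .quant import (RegionOfInterest, corrected_mean_intensity,
                                    fractional_area_change, max_intensity_projection)

                q = config.quant
                rows = []
                if "eda" in q:
                    rows.append({
                        "metric": "FAC_percent",
                        "value": fractional_area_change(float(q["eda"]), float(q["esa"])),
                    })
                if "image" in q:
                    import tifffile

                    img = tifffile.imread(q["image"])
                    if img.ndim == 3:
                        img = max_intensity_projection(img)
                    polys = [RegionOfInterest.from_dict(d)
                             for d in json.loads(Path(q["roi"]).read_text())]
                    meas = corrected_mean_intensity(img, polys[0], polys[1:])
                    rows.append({"metric": "corrected_per_area",
                                 "value": meas.corrected_per_area})
                    rows.append({"metric": "background_mean",
                                 "value": meas.background_mean})
                quant_path = outdir / "quant.csv"
                pd.DataFrame(rows).to_csv(quant_path, index=False, float_format="%.9g")
                _record(quant_path)
                results["quant"] = {r["metric"]: r["value"] for r in rows}

        caught = [str(w.message) for w in wlist]

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        seed=config.seed,
        timings=timings,
        outputs=outputs,
        warnings=caught,
        results=results,
    )
    manifest.write(outdir / "run_manifest.json")
    return manifest
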