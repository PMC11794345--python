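"""End-to-end orchestration: scene -> frames -> StO2 maps -> statistics.

The stage order is fixed: demodulate -> profilometry-correct -> calibrate ->
invert -> unmix -> analyze.  A single configuration object carries every
tunable; all randomness flows from its one seed through named substreams,
so identical config + seed gives identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from . import io as skio
from .analysis import cell_summaries, correlation_matrix, detect_demarcation, two_way_anova
from .calibration import PhantomReference, calibrate_reflectance
from .demodulation import (
    FilterSpec,
    demodulate_sfdi_3phase,
    demodulate_stack_ssop,
    extract_phase_3step,
)
from .inversion import build_lut, invert_reflectance
from .oxygenation import load_extinction_table, sto2_timecourse, unmix_chromophores
from .profilometry import CorrectionModel, carrier_phase, phase_to_height, profile_correct
from .scenes import (
    AcquisitionSpec,
    FrameStack,
    FULL_SHAPE,
    NoiseModel,
    QUARTER_SHAPE,
    SceneSpec,
    make_ischemia_scene,
    render_frames,
    render_phantom_stack,
)
from .study import StudySpec, simulate_study, TIMEPOINTS

logger = logging.getLogger("ssoptk")


class PipelineStageError(RuntimeError):
    """Raised when a stage fails; names the stage and the offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {detail}")


@dataclass
class PipelineConfig:
    """Serializable configuration of one pipeline run."""

    resolution: str = "quarter"  # 'quarter' (256x320) or 'full' (1024x1280)
    method: str = "sfdi"  # 'sfdi' | 'ssop'
    wavelengths: tuple[int, int] = (665, 860)
    fx: float = 0.2  # modulation frequency, mm^-1
    noise_kind: str = "gaussian"
    noise_sigma: float = 0.005
    triangulation_angle_deg: float = 15.0
    profile_correction: bool = True
    lut_points: int = 128
    phantom_mu_a: dict = field(default_factory=lambda: {665: 0.01, 860: 0.01})
    phantom_mu_s: dict = field(default_factory=lambda: {665: 1.2, 860: 1.2})
    phantom_smooth_px: float = 8.0
    demarcation_threshold: float = 25.0
    n_animals_per_group: int = 6
    seed: int = 0
    log_level: str = "INFO"

    @property
    def shape(self) -> tuple[int, int]:
        return {"quarter": QUARTER_SHAPE, "full": FULL_SHAPE}[self.resolution]

    def acquisition(self, seed: int) -> AcquisitionSpec:
        return AcquisitionSpec(
            wavelengths=tuple(self.wavelengths),
            spatial_frequencies=(0.0, self.fx),
            noise=NoiseModel(kind=self.noise_kind, sigma=self.noise_sigma),
            triangulation_angle_deg=self.triangulation_angle_deg,
            seed=seed,
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["wavelengths"] = list(d["wavelengths"])
        d["phantom_mu_a"] = {str(k): v for k, v in d["phantom_mu_a"].items()}
        d["phantom_mu_s"] = {str(k): v for k, v in d["phantom_mu_s"].items()}
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["wavelengths"] = tuple(d.get("wavelengths", (665, 860)))
        for key in ("phantom_mu_a", "phantom_mu_s"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


def _substream_seed(seed: int, label: str) -> int:
    """Stable per-stage substream seed (< 2^31) from the run seed."""
    tag = zlib.crc32(label.encode())
    h = np.random.SeedSequence([seed, tag])
    return int(h.generate_state(1)[0] % (2**31))


def make_phantom_reference(
    config: PipelineConfig, seed: int
) -> tuple[PhantomReference, FrameStack]:
    """Render and demodulate the calibration phantom.

    The homogeneous flat phantom has spatially smooth true modulation, so
    its measured maps are low-pass filtered (``phantom_smooth_px``) before
    use: this suppresses injection of the phantom's own sensor noise into
    every calibrated image while leaving slowly-varying illumination gain
    (which the calibration ratio must cancel) untouched.
    """
    acq = config.acquisition(seed)
    stack, _ = render_phantom_stack(
        config.phantom_mu_a, config.phantom_mu_s, acq, shape=config.shape
    )
    modulation = {}
    for wl in config.wavelengths:
        if config.method == "sfdi":
            maps = demodulate_sfdi_3phase(stack, wl, config.fx)
        else:
            maps = demodulate_stack_ssop(stack, wl, config.fx)
        if config.phantom_smooth_px > 0:
            maps.m_dc = gaussian_filter(maps.m_dc, config.phantom_smooth_px, mode="nearest")
            maps.m_ac = gaussian_filter(maps.m_ac, config.phantom_smooth_px, mode="nearest")
        modulation[wl] = maps
    return PhantomReference(
        mu_a=config.phantom_mu_a, mu_s_prime=config.phantom_mu_s,
        modulation=modulation,
    ), stack


def process_stack(
    stack: FrameStack,
    phantom: PhantomReference,
    config: PipelineConfig,
    lut=None,
):
    """Frame stack -> oxygenation maps, running every processing stage."""
    fx = config.fx
    wl_red, wl_nir = config.wavelengths

    try:
        mods = {}
        for wl in config.wavelengths:
            if config.method == "sfdi":
                mods[wl] = demodulate_sfdi_3phase(stack, wl, fx)
            elif config.method == "ssop":
                mods[wl] = demodulate_stack_ssop(stack, wl, fx)
            else:
                raise ValueError(f"unknown method '{config.method}'")
    except Exception as exc:
        raise PipelineStageError("demodulation", str(exc)) from exc

    if config.profile_correction:
        try:
            phase = extract_phase_3step(stack, wl_red, fx)
            ref = carrier_phase(stack.shape, fx, stack.pixel_pitch)
            height = phase_to_height(phase, ref, config.triangulation_angle_deg)
            model = CorrectionModel()
            mods = {wl: profile_correct(m, height, model) for wl, m in mods.items()}
        except Exception as exc:
            raise PipelineStageError("profilometry", str(exc)) from exc
    else:
        height = None

    try:
        refl = {wl: calibrate_reflectance(m, phantom, fx) for wl, m in mods.items()}
    except Exception as exc:
        raise PipelineStageError("calibration", str(exc)) from exc

    try:
        if lut is None:
            lut = build_lut(fx, n_mu_a=config.lut_points, n_mu_s=config.lut_points)
        props = {wl: invert_reflectance(r, lut) for wl, r in refl.items()}
    except Exception as exc:
        raise PipelineStageError("inversion", str(exc)) from exc

    try:
        ext = load_extinction_table()
        oxy = unmix_chromophores(
            props[wl_red].mu_a, props[wl_nir].mu_a, ext,
            wavelengths=(wl_red, wl_nir),
            valid=props[wl_red].valid & props[wl_nir].valid,
        )
    except Exception as exc:
        raise PipelineStageError("oxygenation", str(exc)) from exc

    return {"modulation": mods, "height": height, "reflectance": refl,
            "properties": props, "oxygenation": oxy, "lut": lut}


def run_virtual_experiment(
    group: str,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Complete virtual occlusion experiment for one group.

    Renders the three timepoint scenes, runs the imaging pipeline on each,
    simulates the lobe-level study table, and runs the statistics stage.
    Self-contained: needs no external files.
    """
    config = config or PipelineConfig()
    _setup_logging(config, outdir)
    logger.info("virtual experiment: group=%s resolution=%s method=%s seed=%d",
                group, config.resolution, config.method, config.seed)

    phantom, _ = make_phantom_reference(config, _substream_seed(config.seed, "phantom"))
    lut = build_lut(config.fx, n_mu_a=config.lut_points, n_mu_s=config.lut_points)

    maps_by_tp = {}
    per_tp = {}
    lobe_masks = None
    for tp in TIMEPOINTS:
        try:
            scene = make_ischemia_scene(group, tp, shape=config.shape)
        except Exception as exc:
            raise PipelineStageError("scene", f"{group}/{tp}: {exc}") from exc
        lobe_masks = scene.lobe_masks
        acq = config.acquisition(_substream_seed(config.seed, f"render-{tp}"))
        stack = render_frames(scene, acq)
        result = process_stack(stack, phantom, config, lut=lut)
        per_tp[tp] = result
        maps_by_tp[tp] = result["oxygenation"]
        logger.info("processed %s/%s", group, tp)

    timecourse = sto2_timecourse(maps_by_tp, lobe_masks)
    demarcation = detect_demarcation(
        maps_by_tp["T1"], threshold=config.demarcation_threshold,
        pixel_pitch=150.0 / config.shape[1],
    )

    study = simulate_study(
        StudySpec(
            n_animals_per_group=config.n_animals_per_group,
            seed=_substream_seed(config.seed, "study"),
        )
    )
    cells, deltas = cell_summaries(study)
    anova = two_way_anova(study, response="sto2", group=group)
    corr = correlation_matrix(study)

    outputs = {
        "group": group,
        "config": config,
        "oxygenation": maps_by_tp,
        "timecourse": timecourse,
        "demarcation": demarcation,
        "study_table": study,
        "cells": cells,
        "deltas": deltas,
        "anova": anova,
        "correlations": corr,
    }
    if outdir is not None:
        _persist(outputs, per_tp, Path(outdir), config)
    return outputs


def _setup_logging(config: PipelineConfig, outdir) -> None:
    logger.setLevel(config.log_level)
    if not logger.handlers:
        logger.addHandler(logging.StreamHandler())
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(Path(outdir) / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)


def _persist(outputs: dict, per_tp: dict, outdir: Path, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    for tp, result in per_tp.items():
        skio.write_map(result["oxygenation"].sto2, outdir / f"sto2_{tp}.tiff")
    skio.write_study_table(outputs["study_table"], outdir / "study_table.csv")
    outputs["timecourse"].to_csv(outdir / "timecourse.csv", index=False)
    outputs["cells"].to_csv(outdir / "cell_summaries.csv", index=False)
    outputs["deltas"].to_csv(outdir / "deltas.csv", index=False)
    outputs["anova"].comparisons.to_csv(outdir / "comparisons.csv", index=False)
    outputs["correlations"].to_csv(outdir / "correlations.csv", index=False)
    manifest = {
        "group": outputs["group"],
        "seed": config.seed,
        "stages": ["demodulation", "profilometry", "calibration",
                   "inversion", "oxygenation", "statistics"],
        "demarcation_sharpness": float(outputs["demarcation"].sharpness)
        if np.isfinite(outputs["demarcation"].sharpness) else None,
        "files": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
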