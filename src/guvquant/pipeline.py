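"""Validated configuration and the end-to-end quantification pipeline.

One YAML config drives simulate -> quantify -> report; unknown keys are
rejected before any stage runs, every output file carries a short hash of
the resolved config, and a per-stage log records how many GUVs were
detected, excluded, and called phase-separated.  Given the same config and
seed the output CSVs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pydantic
from pydantic import BaseModel, ConfigDict

from . import binding as _binding
from . import phases as _phases
from .detect import DetectionConfig, detect_guvs, estimate_solution_intensity
from .errors import ConfigError, QuantificationError
from .image import MARKER, MultiChannelImage, read_image
from .rim import extract_rim_profile

log = logging.getLogger("guvquant")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChannelsSection(_Section):
    marker: int = 0
    lectin_1: int = 1
    lectin_2: int | None = None

    def roles(self) -> dict[str, int]:
        roles = {"marker": self.marker, "lectin_1": self.lectin_1}
        if self.lectin_2 is not None:
            roles["lectin_2"] = self.lectin_2
        return roles


class DetectionSection(_Section):
    radius_min: float = 10.0
    radius_max: float = 40.0
    radius_step: float = 1.0
    score_threshold: float = 0.25
    canny_sigma: float = 2.0
    border_margin: float = 3.0
    exterior_margin: float = 5.0
    saturation_level: float | None = None

    def to_config(self) -> DetectionConfig:
        return DetectionConfig(**self.model_dump())


class ProfilingSection(_Section):
    n_bins: int = 360
    band_halfwidth: float = 3.0
    rim_stat: str = "max"


class PhasesSection(_Section):
    min_contrast_ratio: float = 2.0
    min_arc_fraction: float = 0.05
    smooth_bins: int = 5
    marker_phase: str = "ld"

    def to_config(self) -> _phases.PhaseConfig:
        return _phases.PhaseConfig(**self.model_dump())


class StatisticsSection(_Section):
    test: str = "mannwhitney"


class PipelineConfig(_Section):
    channels: ChannelsSection = ChannelsSection()
    detection: DetectionSection = DetectionSection()
    profiling: ProfilingSection = ProfilingSection()
    phases: PhasesSection = PhasesSection()
    statistics: StatisticsSection = StatisticsSection()
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        try:
            return cls.model_validate(raw or {})
        except pydantic.ValidationError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")


def quantify_guv_image(image: MultiChannelImage, config: PipelineConfig,
                       condition: str = "", image_id: str = ""
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run detection -> solution -> profiling -> phases -> binding on one
    image; returns (per-GUV table, per-bin profile table)."""
    detections = detect_guvs(image, config.detection.to_config())
    usable = [d for d in detections if d.ok]
    log.info("image %s: %d detections, %d usable, %d excluded by QC",
             image_id, len(detections), len(usable),
             len(detections) - len(usable))
    solution = {role: estimate_solution_intensity(
        image, detections, role, margin=config.detection.exterior_margin)
        for role in image.lectin_roles}

    guv_rows, profile_rows = [], []
    n_phase_separated = 0
    for guv_id, det in enumerate(usable):
        profile = extract_rim_profile(
            image, det, n_bins=config.profiling.n_bins,
            band_halfwidth=config.profiling.band_halfwidth,
            stat=config.profiling.rim_stat)
        labeling = _phases.segment_phases(profile, config.phases.to_config())
        n_phase_separated += labeling.mode == "phase_separated"
        result = _binding.per_phase_binding(profile, labeling, solution,
                                            guv_id=guv_id)
        row = {
            "image_id": image_id, "condition": condition, "guv_id": guv_id,
            "center_x": det.center_xy[0], "center_y": det.center_xy[1],
            "radius_px": det.radius, "score": det.score,
            "phase_mode": labeling.mode,
        }
        for role in image.lectin_roles:
            row[f"be_{role}"] = result.binding_efficiency.get(role, np.nan)
            for phase in ("ld", "lo"):
                row[f"be_{role}_{phase}"] = result.per_phase.get(role, {}).get(
                    phase, np.nan)
            row[f"solution_{role}"] = solution[role]
        if len(image.lectin_roles) == 2:
            seg = _binding.segregation_profile(profile, *image.lectin_roles)
            row["segregation_corr"] = seg.correlation
        guv_rows.append(row)

        pf = profile.to_frame()
        pf.insert(0, "guv_id", guv_id)
        pf.insert(0, "image_id", image_id)
        pf["phase"] = labeling.labels
        profile_rows.append(pf)

    log.info("image %s: %d phase-separated GUVs", image_id, n_phase_separated)
    guv_df = pd.DataFrame(guv_rows)
    profile_df = (pd.concat(profile_rows, ignore_index=True)
                  if profile_rows else pd.DataFrame())
    return guv_df, profile_df


def _overlay_png(image: MultiChannelImage, guv_df: pd.DataFrame,
                 path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(image.channel(MARKER), cmap="gray")
    for _, row in guv_df.iterrows():
        circle = plt.Circle((row.center_x, row.center_y), row.radius_px,
                            fill=False, color="cyan", lw=1)
        ax.add_patch(circle)
        ax.annotate(str(int(row.guv_id)), (row.center_x, row.center_y),
                    color="yellow", ha="center", va="center", fontsize=8)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def run_pipeline(config: PipelineConfig, inputs: list[str | Path],
                 outdir: str | Path, condition: str = "",
                 overlay: bool = True) -> dict[str, Path]:
    """Quantify one or more GUV images and write result CSVs.

    ``inputs`` are TIFF paths with channel-role sidecars (the config's
    channel section is the fallback when no sidecar exists).  Outputs:
    ``guvs.csv`` (one row per usable GUV), ``profiles.csv`` (per-bin), and
    a QC overlay PNG per image.  Raises with the failing image identified.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    guv_tables, profile_tables = [], []
    outputs: dict[str, Path] = {}
    for path in inputs:
        path = Path(path)
        try:
            sidecar = path.with_suffix(".channels.yaml")
            if sidecar.exists():
                image = read_image(path)
            else:
                image = read_image(path, channel_roles=config.channels.roles(),
                                   pixel_size=0.1)
            guv_df, profile_df = quantify_guv_image(
                image, config, condition=condition, image_id=path.stem)
        except QuantificationError as exc:
            raise QuantificationError(f"image {path.name}: {exc}") from exc
        guv_tables.append(guv_df)
        profile_tables.append(profile_df)
        if overlay and not guv_df.empty:
            overlay_path = outdir / f"{path.stem}_overlay.png"
            _overlay_png(image, guv_df, overlay_path)
            outputs[f"overlay_{path.stem}"] = overlay_path

    guvs = pd.concat([t for t in guv_tables if not t.empty],
                     ignore_index=True) if any(not t.empty for t in guv_tables) \
        else pd.DataFrame()
    profiles = pd.concat([t for t in profile_tables if not t.empty],
                         ignore_index=True) if any(not t.empty for t in profile_tables) \
        else pd.DataFrame()
    guvs_path = outdir / "guvs.csv"
    profiles_path = outdir / "profiles.csv"
    _write_csv(guvs, guvs_path, cfg_hash)
    _write_csv(profiles, profiles_path, cfg_hash)
    outputs["guvs"] = guvs_path
    outputs["profiles"] = profiles_path
    return outputs
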