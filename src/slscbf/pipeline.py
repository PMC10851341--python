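"""Configuration-driven orchestration of the full mode comparison.

For every mass in a (simulated) cohort and each band (fundamental /
harmonic), produces the five imaging modes (B-mode, SLSC, M-SLSC,
r-SLSC, R-SLSC), the per-mass metric table, per-metric threshold
classification, confusion counts and sensitivity/specificity, CSV
tables, log-compressed PNG exports and a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beamform import (
    DEFAULT_DYNAMIC_RANGE_DB,
    DEFAULT_KERNEL_LENGTH,
    coherence_stack,
    das_beamform,
    display_process,
    envelope_detect,
    m_slsc_image,
    select_M,
    slsc_image,
)
from .metrics import (
    DEFAULT_THRESHOLDS,
    EllipseROI,
    classify_mass,
    confusion_from_labels,
    contrast,
    gcnr,
    lag_one_coherence_map,
    mean_loc,
    roi_mask,
    sensitivity_specificity,
    validate_roi_pair,
)
from .rf_data import AcquisitionGeometry, make_fundamental, make_harmonic
from .rpca import RpcaConfig, denoise_stack, r_slsc_image, robust_slsc_image
from .simulator import DESK_GEOMETRY, CohortEntry, make_cohort

COHERENCE_MODES = ("SLSC", "M-SLSC", "r-SLSC", "R-SLSC")
ALL_MODES = ("B-mode",) + COHERENCE_MODES

#: nearest-edge lateral separation used when auto-placing the tissue ROI
DEFAULT_ROI_SEPARATION_MM = 1.2
#: mass ROI semi-axes as a fraction of the mass ellipse semi-axes
DEFAULT_ROI_SHRINK = 0.75


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully defaulted run parameters."""

    geometry: AcquisitionGeometry = DESK_GEOMETRY
    n_fluid: int = 7
    n_solid: int = 28
    M_slsc: int | None = None  # default: select_M(0.10)
    M_weighted: int | None = None  # default: select_M(0.30)
    kernel_length: int = DEFAULT_KERNEL_LENGTH
    rpca: RpcaConfig = field(default_factory=RpcaConfig)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    dynamic_range_db: float = DEFAULT_DYNAMIC_RANGE_DB
    output_dir: str = "slscbf_run"
    seed: int = 0
    modes: tuple[str, ...] = COHERENCE_MODES
    bands: tuple[str, ...] = ("fundamental", "harmonic")
    write_images: bool = True

    def effective_M_slsc(self) -> int:
        return self.M_slsc if self.M_slsc is not None else select_M(self.geometry, 0.10)

    def effective_M_weighted(self) -> int:
        return self.M_weighted if self.M_weighted is not None else select_M(self.geometry, 0.30)


def validate_config(raw: dict) -> RunConfig:
    """Fill defaults and range-check a raw key-value configuration."""
    raw = dict(raw)
    geometry_kwargs = raw.pop("geometry", {})
    geometry = (
        dataclasses.replace(DESK_GEOMETRY, **geometry_kwargs)
        if isinstance(geometry_kwargs, dict)
        else geometry_kwargs
    )
    rpca_kwargs = raw.pop("rpca", {})
    rpca = RpcaConfig(**rpca_kwargs) if isinstance(rpca_kwargs, dict) else rpca_kwargs

    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    config = RunConfig(geometry=geometry, rpca=rpca, **raw)

    if config.kernel_length < 1 or config.kernel_length % 2 == 0:
        raise ValueError(f"config field 'kernel_length': must be odd and >= 1, got {config.kernel_length}")
    for name in ("n_fluid", "n_solid"):
        if getattr(config, name) < 0:
            raise ValueError(f"config field {name!r}: must be non-negative")
    for key in ("loc", "contrast_difference", "gcnr"):
        if key not in config.thresholds:
            raise ValueError(f"config field 'thresholds': missing {key!r}")
    if config.dynamic_range_db <= 0:
        raise ValueError("config field 'dynamic_range_db': must be positive")
    for M in (config.effective_M_slsc(), config.effective_M_weighted()):
        if not (1 <= M <= geometry.n_receive_elements - 1):
            raise ValueError(f"config field 'M': {M} outside [1, N-1]")
    for mode in config.modes:
        if mode not in COHERENCE_MODES:
            raise ValueError(f"config field 'modes': unknown mode {mode!r}")
    return config


def default_roi_pair(
    config,
    geometry: AcquisitionGeometry,
    separation_mm: float = DEFAULT_ROI_SEPARATION_MM,
    shrink: float = DEFAULT_ROI_SHRINK,
) -> tuple[EllipseROI, EllipseROI]:
    """Mass ROI inside the mass ellipse plus a matched lateral tissue ROI."""
    cz, cx = config.mass_center_mm
    semi = (config.mass_semi_axes_mm[0] * shrink, config.mass_semi_axes_mm[1] * shrink)
    mass = EllipseROI((cz, cx), semi, role="mass")
    offset = 2.0 * semi[1] + separation_mm
    halfspan = (geometry.n_scan_lines - 1) / 2.0 * geometry.scan_line_spacing_mm
    tx = cx + offset
    if tx + semi[1] > halfspan:  # no room on the right; flip side
        tx = cx - offset
    tissue = EllipseROI((cz, tx), semi, role="tissue")
    validate_roi_pair(mass, tissue)
    return mass, tissue


def evaluate_mass(
    entry: CohortEntry,
    run: RunConfig,
    rois: tuple[EllipseROI, EllipseROI] | None = None,
    images_out: dict | None = None,
) -> list[dict]:
    """All metric rows (one per band and coherence mode) for one mass."""
    if rois is None:
        rois = default_roi_pair(entry.config, run.geometry)
    mass_roi, tissue_roi = rois
    M_short = run.effective_M_slsc()
    M_long = run.effective_M_weighted()
    need_rpca = bool({"r-SLSC", "R-SLSC"} & set(run.modes))
    M_stack = M_long if ({"M-SLSC", "r-SLSC", "R-SLSC"} & set(run.modes)) else M_short

    rows: list[dict] = []
    frames = {}
    if "fundamental" in run.bands:
        frames["fundamental"] = make_fundamental(entry.pair)
    if "harmonic" in run.bands:
        frames["harmonic"] = make_harmonic(entry.pair)
    for band, frame in frames.items():
        bmode = envelope_detect(das_beamform(frame))
        stack = coherence_stack(frame, M=M_stack, kernel_length=run.kernel_length)
        loc_map_img = lag_one_coherence_map(frame, kernel_length=run.kernel_length)
        loc_value = mean_loc(loc_map_img, mass_roi)
        bmode_contrast = contrast(bmode, mass_roi, tissue_roi)

        images = {"B-mode": bmode}
        if "SLSC" in run.modes:
            images["SLSC"] = slsc_image(stack, M=M_short)
        if "M-SLSC" in run.modes:
            images["M-SLSC"] = m_slsc_image(stack, M=M_long)
        rpca_diag = None
        if need_rpca:
            denoised, rpca_diag = denoise_stack(stack, run.rpca)
            if "r-SLSC" in run.modes:
                images["r-SLSC"] = r_slsc_image(stack, run.rpca, denoised=denoised)
            if "R-SLSC" in run.modes:
                images["R-SLSC"] = robust_slsc_image(stack, run.rpca, M=M_long, denoised=denoised)
        if images_out is not None:
            images_out[(entry.mass_id, band)] = images

        for mode in run.modes:
            img = images[mode]
            mode_contrast = contrast(img, mass_roi, tissue_roi)
            cd = bmode_contrast - mode_contrast
            g = gcnr(img, mass_roi, tissue_roi)
            predicted = classify_mass(loc_value, cd, g, run.thresholds)
            row = {
                "mass_id": entry.mass_id,
                "truth": entry.label,
                "band": band,
                "mode": mode,
                "bmode_contrast_db": bmode_contrast,
                "contrast_db": mode_contrast,
                "contrast_difference_db": cd,
                "mean_loc": loc_value,
                "gcnr": g,
                "pred_loc": predicted["loc"],
                "pred_contrast_difference": predicted["contrast_difference"],
                "pred_gcnr": predicted["gcnr"],
            }
            if rpca_diag is not None:
                row["rpca_iterations"] = rpca_diag.iterations
                row["rpca_residual"] = rpca_diag.residual
                row["rpca_rank"] = rpca_diag.rank
            rows.append(row)
    return rows


def summarize_confusion(table: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity/specificity per (metric, band, mode), mixed excluded.

    LOC depends only on the band, but is tabulated per mode for a
    uniform report layout.
    """
    records = []
    for (band, mode), group in table.groupby(["band", "mode"], sort=True):
        for metric in ("loc", "contrast_difference", "gcnr"):
            pairs = list(zip(group["truth"], group[f"pred_{metric}"]))
            counts = confusion_from_labels(pairs)
            perf = sensitivity_specificity(counts)
            records.append(
                {
                    "metric": metric,
                    "band": band,
                    "mode": mode,
                    "TP": counts.TP,
                    "FN": counts.FN,
                    "TN": counts.TN,
                    "FP": counts.FP,
                    "sensitivity": perf.sensitivity,
                    "specificity": perf.specificity,
                }
            )
    return pd.DataFrame.from_records(records)


def _config_digest(run: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(run), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _export_image(img, path: Path, dynamic_range_db: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import image as mpimg

    shown = display_process(img, dynamic_range_db)
    mpimg.imsave(path, shown.values, cmap="gray", vmin=-dynamic_range_db, vmax=0.0)


def run_comparison(run: RunConfig, cohort: list[CohortEntry] | None = None) -> dict:
    """Execute the full comparison; write tables, images and manifest.

    Returns a report dict with the per-mass table, the confusion
    summary, per-mass failures, and the manifest.
    """
    out = Path(run.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = make_cohort(run.n_fluid, run.n_solid, seed=run.seed, geometry=run.geometry)

    all_rows: list[dict] = []
    failures: dict[int, str] = {}
    images_out: dict = {}
    for entry in cohort:
        try:
            all_rows.extend(
                evaluate_mass(entry, run, images_out=images_out if run.write_images else None)
            )
        except Exception as exc:  # keep going; report per-mass failures
            failures[entry.mass_id] = f"{type(exc).__name__}: {exc}"

    table = pd.DataFrame.from_records(all_rows)
    confusion = summarize_confusion(table) if len(table) else pd.DataFrame()
    table_path = out / "mass_metrics.csv"
    confusion_path = out / "confusion.csv"
    float_fmt = "%.10g"
    table.to_csv(table_path, index=False, float_format=float_fmt)
    confusion.to_csv(confusion_path, index=False, float_format=float_fmt)

    manifest_csv = out / "cohort_manifest.csv"
    pd.DataFrame.from_records(
        [
            {
                "mass_id": e.mass_id,
                "truth": e.label,
                "mass_kind": e.config.mass_kind,
                "internal_coherence": e.config.internal_coherence,
                "echogenicity_contrast_db": e.config.echogenicity_contrast_db,
                "clutter_level_db": e.config.clutter_level_db,
                "harmonic_distortion": e.config.harmonic_distortion,
                "seed": e.config.seed,
            }
            for e in cohort
        ]
    ).to_csv(manifest_csv, index=False, float_format=float_fmt)

    if run.write_images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for (mass_id, band), images in images_out.items():
            for mode, img in images.items():
                name = f"mass{mass_id:03d}_{band}_{mode.replace('-', '')}.png"
                _export_image(img, img_dir / name, run.dynamic_range_db)

    manifest = {
        "software": "slscbf",
        "version": __version__,
        "seed": run.seed,
        "config_hash": _config_digest(run),
        "n_masses": len(cohort),
        "failures": failures,
        "parameters": {
            "M_slsc": run.effective_M_slsc(),
            "M_weighted": run.effective_M_weighted(),
            "kernel_length": run.kernel_length,
            "sparsity_lambda": run.rpca.sparsity_lambda,
            "thresholds": run.thresholds,
            "dynamic_range_db": run.dynamic_range_db,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "table": table,
        "confusion": confusion,
        "failures": failures,
        "manifest": manifest,
        "cohort": cohort,
    }
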