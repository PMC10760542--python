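"""End-to-end analysis: sample sheet -> per-punctum and per-animal tables.

Each sample-sheet row names an image (TIFF Z-stack or single page) or a
pre-extracted profile CSV, the animal's ID and genotype, the session's
calibration-bead intensity, an optional cord-path file, and an optional
pixel size. Calibration precedence is: explicit config override, then the
sample-sheet column, then TIFF resolution tags; if none is available the
animal fails — there is no silent default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from punctakit.config import RunConfig
from punctakit.detection import detect_puncta
from punctakit.image_io import (
    CalibratedImage,
    IntensityProfile,
    extract_profile,
    max_project,
    read_cord_path,
    read_profile_csv,
    read_tiff_stack,
)
from punctakit.metrics import AnimalRecord, aggregate_animal, measure_puncta

__all__ = ["analyze_profile", "analyze_animal", "analyze_study", "StudyResult"]

logger = logging.getLogger(__name__)

SHEET_REQUIRED = ("file", "animal_id", "genotype", "bead_intensity")


@dataclass
class StudyResult:
    per_punctum: pd.DataFrame
    per_animal: pd.DataFrame
    failures: list[tuple[str, str]]  # (animal_id, reason)


def analyze_profile(
    profile: IntensityProfile,
    bead_intensity: float,
    config: RunConfig | None = None,
    animal_id: str = "",
    genotype: str = "",
) -> AnimalRecord:
    """Detect and measure puncta on one linescan profile."""
    config = config or RunConfig()
    smoothed, mask, segments = detect_puncta(profile, config.detection)
    puncta = measure_puncta(
        smoothed, mask, segments, bead_intensity, config.baseline_method
    )
    return aggregate_animal(
        smoothed, puncta, bead_intensity, animal_id=animal_id, genotype=genotype
    )


def _load_profile(row: pd.Series, base_dir: Path, config: RunConfig) -> IntensityProfile:
    file_path = base_dir / str(row["file"])
    if not file_path.exists():
        raise FileNotFoundError(f"input file not found: {file_path}")
    try:
        sheet_cal = float(row.get("um_per_px"))
        if not np.isfinite(sheet_cal):
            sheet_cal = None
    except (TypeError, ValueError):
        sheet_cal = None

    if file_path.suffix.lower() == ".csv":
        return read_profile_csv(file_path, um_per_px=config.um_per_px or sheet_cal)

    pages, tag_cal = read_tiff_stack(file_path)
    um_per_px = config.um_per_px or sheet_cal or tag_cal
    if um_per_px is None:
        raise ValueError(
            f"no spatial calibration for {file_path}: supply um_per_px in the "
            "config or sample sheet, or a TIFF resolution tag"
        )
    image = CalibratedImage(
        pixels=max_project(pages), um_per_px=um_per_px, source_id=str(row["animal_id"])
    )
    cord_file = row.get("cord_path_file")
    if cord_file is None or (isinstance(cord_file, float) and np.isnan(cord_file)) or cord_file == "":
        raise ValueError(f"image input {file_path} requires a cord_path_file")
    cord_path_file = base_dir / str(cord_file)
    dialect = "imagej_roi" if cord_path_file.suffix.lower() == ".roi" else "csv"
    path = read_cord_path(cord_path_file, dialect=dialect, line_width_px=config.line_width_px)
    return extract_profile(image, path)


def analyze_study(
    sample_sheet: str | Path,
    config: RunConfig | None = None,
) -> StudyResult:
    """Analyze every animal in a sample sheet.

    Per-animal failures (missing files, bad calibration) are logged and
    reported in ``failures``; the remaining animals still complete.
    """
    config = config or RunConfig()
    sheet_path = Path(sample_sheet)
    sheet = pd.read_csv(sheet_path)
    missing_cols = [c for c in SHEET_REQUIRED if c not in sheet.columns]
    if missing_cols:
        raise ValueError(f"sample sheet missing columns: {missing_cols}")
    base_dir = sheet_path.parent

    punctum_rows = []
    animal_rows = []
    failures: list[tuple[str, str]] = []
    for _, row in sheet.iterrows():
        animal_id = str(row["animal_id"])
        try:
            bead = float(row["bead_intensity"])
            profile = _load_profile(row, base_dir, config)
            record = analyze_profile(
                profile, bead, config, animal_id=animal_id, genotype=str(row["genotype"])
            )
        except (ValueError, FileNotFoundError, OSError) as exc:
            logger.error("animal %s failed: %s", animal_id, exc)
            failures.append((animal_id, str(exc)))
            continue
        logger.info("animal %s: %d puncta", animal_id, len(record.puncta))
        for p in record.puncta:
            punctum_rows.append(
                {
                    "animal_id": animal_id,
                    "genotype": record.genotype,
                    "peak_pos_um": p.peak_pos_um,
                    "peak_intensity": p.peak_intensity,
                    "baseline": p.baseline,
                    "fwhm_um": p.fwhm_um if p.fwhm_um is not None else np.nan,
                    "peak_to_bead": p.peak_to_bead,
                    "at_edge": p.at_edge,
                }
            )
        animal_rows.append(
            {
                "animal_id": animal_id,
                "genotype": record.genotype,
                "n_puncta": len(record.puncta),
                "cord_length_um": record.cord_length_um,
                "mean_peak_to_bead": record.mean_peak_to_bead,
                "mean_fwhm_um": record.mean_fwhm_um,
                "density_per_10um": record.density_per_10um,
                "bead_intensity": record.bead_intensity,
            }
        )
    punctum_cols = [
        "animal_id", "genotype", "peak_pos_um", "peak_intensity",
        "baseline", "fwhm_um", "peak_to_bead", "at_edge",
    ]
    animal_cols = [
        "animal_id", "genotype", "n_puncta", "cord_length_um",
        "mean_peak_to_bead", "mean_fwhm_um", "density_per_10um", "bead_intensity",
    ]
    return StudyResult(
        per_punctum=pd.DataFrame(punctum_rows, columns=punctum_cols),
        per_animal=pd.DataFrame(animal_rows, columns=animal_cols),
        failures=failures,
    )


def analyze_animal(
    row: dict | pd.Series,
    base_dir: str | Path = ".",
    config: RunConfig | None = None,
) -> AnimalRecord:
    """Analyze a single sample-sheet row (mapping with the sheet's columns)."""
    config = config or RunConfig()
    row = pd.Series(row)
    profile = _load_profile(row, Path(base_dir), config)
    return analyze_profile(
        profile,
        float(row["bead_intensity"]),
        config,
        animal_id=str(row["animal_id"]),
        genotype=str(row["genotype"]),
    )


def records_from_per_animal(df: pd.DataFrame) -> list[AnimalRecord]:
    """Rebuild lightweight AnimalRecords from a per-animal table.

    Used by the comparison stage, which only needs the aggregate metrics.
    """
    needed = ["animal_id", "genotype", "mean_peak_to_bead", "mean_fwhm_um", "density_per_10um"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"per-animal table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            AnimalRecord(
                animal_id=str(row["animal_id"]),
                genotype=str(row["genotype"]),
                bead_intensity=float(row.get("bead_intensity", 1.0)),
                puncta=[],
                cord_length_um=float(row.get("cord_length_um", np.nan)),
                mean_peak_to_bead=float(row["mean_peak_to_bead"]),
                mean_fwhm_um=float(row["mean_fwhm_um"]),
                density_per_10um=float(row["density_per_10um"]),
            )
        )
    return records
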