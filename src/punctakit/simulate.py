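"""Synthetic cord images and profiles with known ground truth.

No raw micrographs are deposited for the protocol this package implements,
so every stage is validated against a generator that plants puncta with
known position, amplitude and FWHM along a synthetic nerve cord.

The generator emulates the study's conditions: a bright punctate signal on
a noisy background along a roughly linear cord, a scalar calibration-bead
intensity per session, 13 wild-type-like and 28 mutant-like animals, and a
mutant contrast of wider (x1.5), brighter (x1.4), sparser (x0.6) puncta —
the direction of the daf-7 phenotype. Puncta are Gaussian bumps by default
(FWHM ground truth is then closed-form: FWHM = 2*sqrt(2*ln 2)*sigma);
Lorentzian and boxcar shapes are available for robustness checks. Puncta
are placed by a Poisson process at the planted density, optionally with a
minimum-separation rejection step to probe the merged-puncta failure mode.
Noise is additive Gaussian (detector-dominated regime) by default, with a
Poisson shot-noise mode behind a flag.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from punctakit.image_io import (
    CalibratedImage,
    CordPath,
    IntensityProfile,
    write_profile_csv,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_animal",
    "generate_study",
    "match_puncta",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

GROUP_CODES = {"wt": 0, "mut": 1}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic two-genotype puncta study.

    Width/amplitude pairs are (mean, sd) of per-punctum draws; the planted
    density is in puncta per 10 um of cord. ``group_effects`` multiplies
    width, amplitude and density for the mutant-like group. Defaults mirror
    the study conditions the package targets: 13 vs 28 animals, ~100 um of
    analyzed cord, 0.108 um/px (63x objective with a CCD), ~2 um puncta at
    5:1 amplitude-to-noise, and a wider/brighter/sparser mutant.
    """

    n_wt: int = 13
    n_mut: int = 28
    cord_length_um: float = 100.0
    um_per_px: float = 0.108
    punctum_width_um: tuple[float, float] = (2.0, 0.2)
    punctum_amplitude: tuple[float, float] = (100.0, 10.0)
    density_per_10um: float = 1.5
    background_level: float = 20.0
    noise_sd: float = 20.0
    bead_intensity: float = 200.0
    group_effects: dict = field(
        default_factory=lambda: {"width": 1.5, "amplitude": 1.4, "density": 0.6}
    )
    shape: str = "gaussian"
    noise_model: str = "gaussian"
    linescan_width_px: int = 3
    min_separation_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.punctum_width_um[0] <= 2 * self.um_per_px:
            raise ValueError(
                "unresolvable width: planted FWHM must exceed 2 pixels"
            )
        for name in ("cord_length_um", "um_per_px", "bead_intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.group_effects.values()):
            raise ValueError("group effect multipliers must be > 0")
        if self.shape not in ("gaussian", "lorentzian", "boxcar"):
            raise ValueError(f"unknown punctum shape {self.shape!r}")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted puncta of one synthetic animal."""

    animal_id: str
    group: str
    positions_um: np.ndarray
    fwhm_um: np.ndarray
    amplitude: np.ndarray
    planted_density_per_10um: float
    bead_intensity: float
    seed: int

    @property
    def n_puncta(self) -> int:
        return int(len(self.positions_um))

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "group": self.group,
            "positions_um": [float(x) for x in self.positions_um],
            "fwhm_um": [float(x) for x in self.fwhm_um],
            "amplitude": [float(x) for x in self.amplitude],
            "planted_density_per_10um": self.planted_density_per_10um,
            "bead_intensity": self.bead_intensity,
            "seed": self.seed,
        }


def _group_params(spec: SyntheticSpec, group: str):
    if group not in GROUP_CODES:
        raise ValueError(f"group must be one of {tuple(GROUP_CODES)}, got {group!r}")
    eff = spec.group_effects if group == "mut" else {}
    width_mu = spec.punctum_width_um[0] * eff.get("width", 1.0)
    width_sd = spec.punctum_width_um[1] * eff.get("width", 1.0)
    amp_mu = spec.punctum_amplitude[0] * eff.get("amplitude", 1.0)
    amp_sd = spec.punctum_amplitude[1] * eff.get("amplitude", 1.0)
    density = spec.density_per_10um * eff.get("density", 1.0)
    return (width_mu, width_sd), (amp_mu, amp_sd), density


def _place_puncta(
    rng: np.random.Generator, spec: SyntheticSpec, density: float
) -> np.ndarray:
    """Poisson placement along the cord, optional minimum separation.

    With ``min_separation_um`` set, positions follow the uniform distribution
    conditioned on all gaps >= s, sampled exactly by drawing sorted uniforms
    on the shrunken interval [0, L - (n-1)s] and re-inserting the fixed gaps.
    A Poisson count too large to fit is truncated to the densest feasible
    packing.
    """
    L = spec.cord_length_um
    n = int(rng.poisson(density * L / 10.0))
    s = spec.min_separation_um
    if s is None or n < 2:
        return np.sort(rng.uniform(0.0, L, size=n))
    n = min(n, int(L // s) + 1)
    slack = L - (n - 1) * s
    base = np.sort(rng.uniform(0.0, slack, size=n))
    return base + s * np.arange(n)


def _bump(shape: str, x_um: np.ndarray, pos: float, fwhm: float) -> np.ndarray:
    """Unit-amplitude punctum profile of the requested shape."""
    if shape == "gaussian":
        sigma = fwhm / FWHM_PER_SIGMA
        return np.exp(-0.5 * ((x_um - pos) / sigma) ** 2)
    if shape == "lorentzian":
        gamma = fwhm / 2.0
        return 1.0 / (1.0 + ((x_um - pos) / gamma) ** 2)
    # boxcar
    return (np.abs(x_um - pos) <= fwhm / 2.0).astype(float)


def _render_signal(spec: SyntheticSpec, truth: GroundTruth, x_um: np.ndarray) -> np.ndarray:
    signal = np.full_like(x_um, spec.background_level, dtype=float)
    for pos, fw, amp in zip(truth.positions_um, truth.fwhm_um, truth.amplitude):
        signal += amp * _bump(spec.shape, x_um, pos, fw)
    return signal


def _add_noise(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    signal: np.ndarray,
    n_averaged_px: int = 1,
) -> np.ndarray:
    """Add detector noise; ``noise_sd`` is the per-pixel camera noise.

    A directly emitted 1D profile stands for a linescan averaged over
    ``n_averaged_px`` perpendicular pixels, so its additive noise is reduced
    by sqrt(n) — keeping the profile and image render modes statistically
    consistent with each other.
    """
    if spec.noise_model == "poisson":
        lam = np.maximum(signal, 0.0) * n_averaged_px
        return rng.poisson(lam).astype(float) / n_averaged_px
    if spec.noise_sd > 0:
        sd = spec.noise_sd / np.sqrt(n_averaged_px)
        return signal + rng.normal(0.0, sd, size=signal.shape)
    return signal.copy()


def generate_animal(
    spec: SyntheticSpec,
    group: str,
    seed: int,
    render: str = "profile",
    animal_id: str = "",
) -> tuple[IntensityProfile | CalibratedImage, CordPath, GroundTruth]:
    """Generate one synthetic animal, fully reproducible from (spec, group, seed).

    ``render="profile"`` emits the 1D linescan directly; ``render="image"``
    renders a straight horizontal cord of fixed transverse width into a 2D
    image whose linescan recovers the same signal.
    """
    (w_mu, w_sd), (a_mu, a_sd), density = _group_params(spec, group)
    rng = np.random.default_rng([seed, GROUP_CODES[group]])
    positions = _place_puncta(rng, spec, density)
    n = len(positions)
    widths = np.maximum(rng.normal(w_mu, w_sd, n), 2.5 * spec.um_per_px)
    amps = np.maximum(rng.normal(a_mu, a_sd, n), 0.0)
    truth = GroundTruth(
        animal_id=animal_id or f"{group}-{seed}",
        group=group,
        positions_um=positions,
        fwhm_um=widths,
        amplitude=amps,
        planted_density_per_10um=density,
        bead_intensity=spec.bead_intensity,
        seed=seed,
    )

    n_px = int(round(spec.cord_length_um / spec.um_per_px)) + 1
    x_um = np.arange(n_px) * spec.um_per_px

    if render == "profile":
        intensities = _add_noise(
            rng, spec, _render_signal(spec, truth, x_um),
            n_averaged_px=spec.linescan_width_px,
        )
        profile = IntensityProfile(
            positions=x_um, intensities=intensities, um_per_px=spec.um_per_px
        )
        y_mid = 2.0
        path = CordPath(vertices=np.array([[0.0, y_mid], [n_px - 1.0, y_mid]]))
        return profile, path, truth
    if render == "image":
        height = 25
        y_mid = (height - 1) / 2.0
        transverse_sigma_px = 2.0
        rows = np.arange(height, dtype=float)
        transverse = np.exp(-0.5 * ((rows - y_mid) / transverse_sigma_px) ** 2)
        signal_1d = _render_signal(spec, truth, x_um) - spec.background_level
        pixels = spec.background_level + transverse[:, None] * signal_1d[None, :]
        pixels = np.maximum(_add_noise(rng, spec, pixels), 0.0)
        image = CalibratedImage(
            pixels=pixels, um_per_px=spec.um_per_px, source_id=truth.animal_id
        )
        path = CordPath(vertices=np.array([[0.0, y_mid], [n_px - 1.0, y_mid]]))
        return image, path, truth
    raise ValueError(f"unknown render mode {render!r}")


def generate_study(
    spec: SyntheticSpec,
    out_dir: str | Path,
    out_format: str = "profile_csv",
) -> Path:
    """Write a full two-genotype study matching the analyze input contract.

    Emits one file per animal (profile CSV or single-page TIFF plus a cord
    path CSV), a sample sheet, and a ground-truth JSON. Returns the sample
    sheet path.
    """
    if out_format not in ("profile_csv", "tiff"):
        raise ValueError(f"unknown out_format {out_format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truths = []
    animal_index = 0
    for group, count in (("wt", spec.n_wt), ("mut", spec.n_mut)):
        for i in range(count):
            animal_index += 1
            animal_id = f"{group}{i + 1:03d}"
            animal_seed = (spec.seed * 100_003 + animal_index) % (2**31 - 1)
            render = "profile" if out_format == "profile_csv" else "image"
            data, path, truth = generate_animal(
                spec, group, animal_seed, render=render, animal_id=animal_id
            )
            truths.append(truth)
            if out_format == "profile_csv":
                fname = f"{animal_id}.csv"
                write_profile_csv(data, out_dir / fname)
                cord_file = ""
            else:
                fname = f"{animal_id}.tif"
                px_per_um = 1.0 / spec.um_per_px
                tifffile.imwrite(
                    out_dir / fname,
                    data.pixels.astype(np.float32),
                    resolution=(px_per_um, px_per_um),
                    resolutionunit="NONE",  # pixels per micron, ImageJ-style
                )
                cord_file = f"{animal_id}_cord.csv"
                pd.DataFrame(path.vertices, columns=["x", "y"]).to_csv(
                    out_dir / cord_file, index=False
                )
            rows.append(
                {
                    "file": fname,
                    "animal_id": animal_id,
                    "genotype": group,
                    "bead_intensity": spec.bead_intensity,
                    "cord_path_file": cord_file,
                    "um_per_px": spec.um_per_px,
                }
            )
    sheet_path = out_dir / "sample_sheet.csv"
    pd.DataFrame(rows).to_csv(sheet_path, index=False)
    payload = {
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(spec).items()
        },
        "animals": [t.to_dict() for t in truths],
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(payload, indent=1))
    return sheet_path


def match_puncta(
    planted_pos_um: np.ndarray,
    detected_pos_um: np.ndarray,
    tol_um: float,
) -> tuple[int, float, float]:
    """Greedy one-to-one matching of detected to planted puncta.

    Pairs within ``tol_um`` are matched closest-first. Returns
    ``(n_matched, recall, false_discovery_rate)``; recall is over planted
    puncta, FDR over detections.
    """
    planted = np.asarray(planted_pos_um, dtype=float)
    detected = np.asarray(detected_pos_um, dtype=float)
    if planted.size == 0:
        return 0, 1.0, 0.0 if detected.size == 0 else 1.0
    if detected.size == 0:
        return 0, 0.0, 0.0
    dist = np.abs(planted[:, None] - detected[None, :])
    pairs = np.argwhere(dist <= tol_um)
    order = np.argsort(dist[pairs[:, 0], pairs[:, 1]])
    used_p: set[int] = set()
    used_d: set[int] = set()
    matched = 0
    for pi, di in pairs[order]:
        if pi in used_p or di in used_d:
            continue
        used_p.add(int(pi))
        used_d.add(int(di))
        matched += 1
    recall = matched / planted.size
    fdr = (detected.size - matched) / detected.size
    return matched, recall, fdr
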