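"""Synthetic dSTORM localization scenes with known ground truth.

Real dSTORM imaging of the presynaptic scaffold Brp produces, per image,
a 20 x 20 µm field containing dozens of active zones (AZs).  Each AZ is a
~100-300 nm footprint composed of a handful of nanoscale subclusters
(SCs); each labelled epitope (here "molecule") photoswitches and is
re-localized over several bursts of consecutive camera frames with a
per-dye localization precision.  This module generates point patterns
with exactly that hierarchy — AZ > SC > molecule > blink burst >
localization — plus uniform background, and returns a per-localization
ground-truth table so that every downstream stage (precision estimation,
clustering, morphometry, Ripley statistics) can be tested against truth.

Per-dye presets (:func:`dye_preset`) freeze the measured characteristics
of the three dyes compared in the study conditions: localization
precision sigma, median brightness, inclusion threshold, localization
yield per AZ, SC radius and SC count per AZ.

The blink model is deliberately minimal: blinks per molecule and burst
length are geometric, burst starts uniform over the movie.  It produces
the two features the analysis relies on — same-molecule re-localizations
in consecutive frames (for NeNA) and realistic per-AZ localization
counts — without modelling dye photochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .loc_io import LocalizationTable

__all__ = [
    "DyePreset",
    "SceneConfig",
    "Scene",
    "GroundTruth",
    "dye_preset",
    "DYE_PRESETS",
    "make_scene",
    "simulate_blinking",
    "simulate_table",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping AZ placement fails within the retry budget."""


@dataclass(frozen=True)
class DyePreset:
    """Generative parameters for one fluorophore.

    sigma_loc : localization precision (nm, per axis)
    median_adc : median fitted intensity (camera A/D counts)
    min_adc : inclusion threshold applied downstream (A/D counts)
    locs_per_az : target median localization count per AZ
    sc_radius : subcluster radius (nm)
    sc_per_az : mean number of subclusters per AZ
    """

    name: str
    sigma_loc: float
    median_adc: float
    min_adc: float
    locs_per_az: float
    sc_radius: float
    sc_per_az: float

    def __post_init__(self) -> None:
        for f in ("sigma_loc", "median_adc", "min_adc", "locs_per_az",
                  "sc_radius", "sc_per_az"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


DYE_PRESETS: dict[str, DyePreset] = {
    "AF647": DyePreset("AF647", sigma_loc=8.0, median_adc=8228.0, min_adc=3000.0,
                       locs_per_az=1085.0, sc_radius=25.0, sc_per_az=12.0),
    "CF568": DyePreset("CF568", sigma_loc=11.0, median_adc=4144.0, min_adc=1000.0,
                       locs_per_az=1481.0, sc_radius=34.0, sc_per_az=6.0),
    "CF583R": DyePreset("CF583R", sigma_loc=10.0, median_adc=3879.0, min_adc=1000.0,
                        locs_per_az=547.0, sc_radius=26.0, sc_per_az=10.0),
}


def dye_preset(name: str) -> DyePreset:
    """Look up a frozen per-dye preset (AF647, CF568 or CF583R)."""
    try:
        return DYE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown dye {name!r}; available presets: {sorted(DYE_PRESETS)}"
        ) from None


@dataclass
class SceneConfig:
    """Geometry, movie and blink-model parameters of one synthetic image.

    Defaults reproduce the acquisition conditions: a ~20 x 20 µm
    illuminated field recorded over 15000 frames.  ``background_rate`` is
    in localizations per µm² over the whole movie.  Blinks per molecule
    and burst length (frames) are geometric with the given means; burst
    starts are uniform over the movie.  ``az_min_separation`` defaults to
    twice the AZ footprint radius (no overlap).
    """

    field_size: tuple[float, float] = (20000.0, 20000.0)  # nm
    n_frames: int = 15000
    n_az: int = 30
    az_footprint_radius: float = 170.0  # nm
    az_inner_radius: float = 0.0  # annulus inner radius for SC placement
    az_min_separation: Optional[float] = None  # nm; None -> 2 * footprint radius
    background_rate: float = 5.0  # localizations / µm² over the movie
    diffuse_fraction: float = 0.5  # fraction of AZ molecules outside SCs
    mean_blinks_per_molecule: float = 3.0
    mean_burst_length: float = 2.0  # frames
    intensity_sigma: float = 0.45  # lognormal shape parameter
    seed: int = 0
    max_placement_tries: int = 10000

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.n_az < 0:
            raise ValueError("n_az must be >= 0")
        if self.mean_burst_length < 1:
            raise ValueError("mean burst length must be >= 1 frame")
        if not 0.0 <= self.diffuse_fraction < 1.0:
            raise ValueError("diffuse_fraction must be in [0, 1)")
        if self.az_min_separation is None:
            self.az_min_separation = 2.0 * self.az_footprint_radius


@dataclass
class Scene:
    """Molecule positions plus the AZ/SC skeleton they were drawn from."""

    az_centers: np.ndarray          # (n_az, 2) nm
    subclusters: pd.DataFrame       # sc_id, az_id, cx, cy, radius
    molecules: pd.DataFrame         # molecule_id, sc_id, az_id, x, y
    config: SceneConfig
    preset: DyePreset


@dataclass
class GroundTruth:
    """Per-localization labels aligned 1:1 with an emitted LocalizationTable.

    ``labels`` has one row per localization: localization_id, az_id,
    sc_id, molecule_id (all -1 for background) and is_background.
    """

    labels: pd.DataFrame
    scene: Scene

    def __len__(self) -> int:
        return len(self.labels)


def _place_az_centers(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    margin = config.az_footprint_radius + 50.0
    lo = np.array([margin, margin])
    hi = np.array(config.field_size) - margin
    if np.any(hi <= lo) and config.n_az > 0:
        raise PlacementError("field too small for the AZ footprint margin")
    centers: list[np.ndarray] = []
    tries = 0
    min_sep2 = config.az_min_separation**2
    while len(centers) < config.n_az:
        if tries >= config.max_placement_tries:
            raise PlacementError(
                f"could not place {config.n_az} AZs with separation "
                f"{config.az_min_separation} nm in {tries} tries"
            )
        tries += 1
        cand = rng.uniform(lo, hi)
        if all(np.sum((cand - c) ** 2) > min_sep2 for c in centers):
            centers.append(cand)
    return np.array(centers).reshape(config.n_az, 2)


def make_scene(config: SceneConfig, preset: DyePreset,
               rng: np.random.Generator | None = None) -> Scene:
    """Draw the static geometry: AZ centers, SC centers, molecule positions.

    SC centers are uniform in an annulus of the AZ footprint; the number
    of SCs per AZ is Poisson with mean ``preset.sc_per_az``; molecules are
    uniform in a disc of radius ``preset.sc_radius`` around each SC
    center.  A fraction ``config.diffuse_fraction`` of each AZ's
    molecules is instead spread uniformly over the whole footprint
    (``sc_id = -1`` in the ground truth) — the diffuse scaffold signal
    that makes a real AZ one contiguous cluster rather than an
    archipelago of SC islands.  Expected molecule numbers are derived
    from the preset so that the mean localization yield per AZ matches
    ``preset.locs_per_az`` under the blink model.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    az_centers = _place_az_centers(config, rng)

    locs_per_molecule = config.mean_blinks_per_molecule * config.mean_burst_length
    mol_per_az = preset.locs_per_az / locs_per_molecule
    mol_per_sc = (1.0 - config.diffuse_fraction) * mol_per_az / preset.sc_per_az

    sc_rows, mol_rows = [], []
    sc_id = mol_id = 0
    for az_id in range(config.n_az):
        # diffuse scaffold molecules spread over the whole AZ footprint
        n_diff = rng.poisson(config.diffuse_fraction * mol_per_az)
        if n_diff:
            rr = config.az_footprint_radius * np.sqrt(rng.uniform(size=n_diff))
            tt = rng.uniform(0, 2 * np.pi, size=n_diff)
            for dx, dy in zip(rr * np.cos(tt), rr * np.sin(tt)):
                mol_rows.append((mol_id, -1, az_id,
                                 az_centers[az_id, 0] + dx,
                                 az_centers[az_id, 1] + dy))
                mol_id += 1
        n_sc = rng.poisson(preset.sc_per_az)
        for _ in range(n_sc):
            # uniform in annulus [inner, outer]
            r2 = rng.uniform(config.az_inner_radius**2, config.az_footprint_radius**2)
            theta = rng.uniform(0, 2 * np.pi)
            cx, cy = az_centers[az_id] + np.sqrt(r2) * np.array(
                [np.cos(theta), np.sin(theta)])
            sc_rows.append((sc_id, az_id, cx, cy, preset.sc_radius))
            n_mol = rng.poisson(mol_per_sc)
            if n_mol:
                rr = preset.sc_radius * np.sqrt(rng.uniform(size=n_mol))
                tt = rng.uniform(0, 2 * np.pi, size=n_mol)
                for dx, dy in zip(rr * np.cos(tt), rr * np.sin(tt)):
                    mol_rows.append((mol_id, sc_id, az_id, cx + dx, cy + dy))
                    mol_id += 1
            sc_id += 1

    subclusters = pd.DataFrame(sc_rows, columns=["sc_id", "az_id", "cx", "cy", "radius"])
    molecules = pd.DataFrame(mol_rows, columns=["molecule_id", "sc_id", "az_id", "x", "y"])
    return Scene(az_centers, subclusters, molecules, config, preset)


def simulate_blinking(scene: Scene, config: SceneConfig | None = None,
                      preset: DyePreset | None = None,
                      rng: np.random.Generator | None = None
                      ) -> tuple[LocalizationTable, GroundTruth]:
    """Emit localizations from a scene under the blink model.

    Each molecule blinks ``Geometric(mean_blinks)`` times (>= 1); each
    blink is a run of consecutive frames of geometric length clipped at
    the end of the movie; every frame of a burst yields one localization
    at the molecule position plus isotropic Gaussian noise with per-axis
    sd ``sigma_loc``.  Intensities are lognormal with median
    ``median_adc`` and shape ``intensity_sigma``.  Background
    localizations are uniform in the field and in frames.  The output
    table is frame-sorted; ground-truth labels are row-aligned with it.
    """
    config = config or scene.config
    preset = preset or scene.preset
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    mol = scene.molecules
    xs, ys, frames = [], [], []
    lab_az, lab_sc, lab_mol = [], [], []
    for row in mol.itertuples(index=False):
        n_blinks = rng.geometric(1.0 / config.mean_blinks_per_molecule)
        for _ in range(n_blinks):
            start = rng.integers(0, config.n_frames)
            length = rng.geometric(1.0 / config.mean_burst_length)
            stop = min(start + length, config.n_frames)
            for t in range(start, stop):
                frames.append(t)
                lab_az.append(row.az_id)
                lab_sc.append(row.sc_id)
                lab_mol.append(row.molecule_id)
                xs.append(row.x)
                ys.append(row.y)
    n_signal = len(xs)
    xs = np.asarray(xs, float) + rng.normal(0.0, preset.sigma_loc, size=n_signal)
    ys = np.asarray(ys, float) + rng.normal(0.0, preset.sigma_loc, size=n_signal)

    area_um2 = (config.field_size[0] / 1000.0) * (config.field_size[1] / 1000.0)
    n_bg = rng.poisson(config.background_rate * area_um2)
    bg_x = rng.uniform(0, config.field_size[0], size=n_bg)
    bg_y = rng.uniform(0, config.field_size[1], size=n_bg)
    bg_frames = rng.integers(0, config.n_frames, size=n_bg)

    n_total = n_signal + n_bg
    intensity = rng.lognormal(np.log(preset.median_adc), config.intensity_sigma,
                              size=n_total)

    df = pd.DataFrame({
        "x": np.concatenate([xs, bg_x]),
        "y": np.concatenate([ys, bg_y]),
        "frame": np.concatenate([np.asarray(frames, int), bg_frames]),
        "intensity": intensity,
    })
    labels = pd.DataFrame({
        "az_id": np.concatenate([np.asarray(lab_az, int), np.full(n_bg, -1)]),
        "sc_id": np.concatenate([np.asarray(lab_sc, int), np.full(n_bg, -1)]),
        "molecule_id": np.concatenate([np.asarray(lab_mol, int), np.full(n_bg, -1)]),
        "is_background": np.concatenate([np.zeros(n_signal, bool), np.ones(n_bg, bool)]),
    })

    # clip stray coordinates (Gaussian tails) into the field
    df["x"] = df["x"].clip(0.0, config.field_size[0])
    df["y"] = df["y"].clip(0.0, config.field_size[1])

    order = np.argsort(df["frame"].to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    labels = labels.iloc[order].reset_index(drop=True)
    labels.insert(0, "localization_id", np.arange(len(labels)))

    table = LocalizationTable(df, n_frames=config.n_frames,
                              source_id=f"sim-{preset.name}-seed{config.seed}")
    return table, GroundTruth(labels, scene)


def simulate_table(config: SceneConfig, preset: DyePreset | str,
                   ) -> tuple[LocalizationTable, GroundTruth]:
    """Convenience wrapper: make a scene and emit its localizations."""
    if isinstance(preset, str):
        preset = dye_preset(preset)
    rng = np.random.default_rng(config.seed)
    scene = make_scene(config, preset, rng)
    return simulate_blinking(scene, config, preset, rng)
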