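"""Configuration dataclasses shared across the pipeline.

Tabular data flows through the pipeline as pandas DataFrames with documented
column dictionaries (see each module's docstring); these dataclasses hold the
knobs that control simulation and analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

# Mean deployment point of the tagging campaign on the pack ice NW of Jan Mayen.
DEPLOYMENT_CENTER = (13.50, 73.86)  # lon, lat

#: Argos location classes from best to worst; Z is invalid.
LOCATION_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")

#: Plausible published one-sigma position errors (km) per location class.
DEFAULT_ARGOS_ERROR_SD_KM = {"3": 0.25, "2": 0.5, "1": 1.5, "0": 5.0, "A": 8.0, "B": 15.0}

#: Draw probabilities for location classes on transmitted fixes.
DEFAULT_LC_PROBS = {"3": 0.08, "2": 0.14, "1": 0.20, "0": 0.24, "A": 0.15, "B": 0.16, "Z": 0.03}

ANIMAL_CLASSES = ("pup", "female", "male")


def default_condition_trajectory(day: float) -> float:
    """True drift rate (m/s, negative = sinking) as a function of days since start.

    Piecewise linear: the animal leaves the ice lean (strongly negative rate)
    and fattens while foraging, so the rate rises toward neutral buoyancy.
    """
    return float(-0.35 + 0.005 * min(max(day, 0.0), 30.0))


@dataclass
class SimConfig:
    """Knobs for the synthetic SRDL generator."""

    n_animals: int = 3
    class_mix: tuple[float, float, float] = (0.4, 0.45, 0.15)  # pup, female, male
    deployment_center: tuple[float, float] = DEPLOYMENT_CENTER
    duration_days: float = 60.0
    fix_interval_hr: float = 2.0
    dive_interval_min: float = 40.0
    patch_centers: Sequence[tuple[float, float]] = ((20.0, 71.5), (8.0, 66.0))
    patch_radius_km: float = 30.0
    patch_dwell_factor: float = 5.0
    argos_error_sd_by_lc: dict = field(default_factory=lambda: dict(DEFAULT_ARGOS_ERROR_SD_KM))
    lc_probs: dict = field(default_factory=lambda: dict(DEFAULT_LC_PROBS))
    drift_dive_prob: float = 0.15
    condition_trajectory: Callable[[float], float] = default_condition_trajectory
    drift_rate_noise_sd: float = 0.02  # m/s around the trajectory
    transit_speed_ms: float = 1.1     # mean swimming speed in transit mode
    in_patch_rate_elevation_sd: float = 1.0  # descent/ascent elevation inside patches, in SDs
    haulout_days: float = 1.5         # haul-out dwell between trips
    n_spike_fixes: int = 0            # deliberate >vmax spikes injected for filter tests
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        if self.fix_interval_hr <= 0:
            raise ValueError("fix_interval_hr must be positive")
        if not np.isclose(sum(self.class_mix), 1.0):
            raise ValueError("class_mix proportions must sum to 1")
        if not 5.0 <= self.patch_radius_km <= 100.0:
            raise ValueError("patch_radius_km must lie in [5, 100]")
        if not 0.0 <= self.drift_dive_prob <= 1.0:
            raise ValueError("drift_dive_prob must lie in [0, 1]")
        if self.patch_dwell_factor <= 1.0:
            raise ValueError("patch_dwell_factor must exceed 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["condition_trajectory"] = getattr(self.condition_trajectory, "__name__", "custom")
        return d


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    latent_track: "object"                     # DataFrame: animal_id, time, lon, lat, mode
    patches: list                              # [(lon, lat, radius_km, dwell_factor)]
    drift_rate_by_day: dict                    # animal_id -> {day_index: m/s}
    haulouts: "object"                         # DataFrame: animal_id, start, end
    animal_classes: dict                       # animal_id -> class
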