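"""Synthetic reference data: segmented-zone stand-ins and sensor curves.

Real validation data for this workflow — a radiologist's segmentation of the
post-ablation zone and fiber-optic probe recordings — is not redistributable,
so these generators emulate its structure: an ellipsoidal ablation zone with
an optional cylindrical vessel-shaped defect (the heat-sink imprint of a
vessel crossing the zone) and saturating exponential temperature rises with
sensor noise.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .zones import ZoneVolume

__all__ = [
    "SyntheticZoneSpec",
    "SyntheticSensorSpec",
    "generate_reference_zone",
    "generate_sensor_series",
]


@dataclass(frozen=True)
class SyntheticZoneSpec:
    """Ellipsoidal synthetic segmentation, optionally pierced by a cylinder.

    Lengths in mm (segmentations live in image space).  The defect cylinder
    is subtracted from the ellipsoid; ``jitter_amplitude`` perturbs the
    boundary with a smooth seeded random field to emulate manual-segmentation
    roughness.
    """

    half_axes: tuple[float, float, float] = (10.0, 10.0, 12.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    vessel_defect: "tuple[float, str, float] | None" = None  # (radius mm, axis 'x'|'y'|'z', offset mm)
    voxel_spacing: float = 0.5  # mm
    jitter_amplitude: float = 0.0  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.half_axes) <= 0:
            raise ValueError("half-axes must be > 0")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel spacing must be > 0")
        if self.voxel_spacing > min(self.half_axes):
            raise ValueError("voxel spacing larger than the smallest half-axis")


@dataclass(frozen=True)
class SyntheticSensorSpec:
    """Saturating-rise probe curve T(t) = Tinf - (Tinf - T0) exp(-t/tau)."""

    asymptotic_temperature: float = 75.0  # degC
    initial_temperature: float = 17.0  # degC
    time_constant: float = 180.0  # s
    noise_std: float = 0.0  # degC
    sample_interval: float = 1.0  # s
    duration: float = 600.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.time_constant <= 0:
            raise ValueError("time constant must be > 0")
        if self.noise_std < 0:
            raise ValueError("noise must be >= 0")


def generate_reference_zone(spec: SyntheticZoneSpec) -> ZoneVolume:
    """Voxelized ellipsoid minus the optional vessel cylinder, with jitter.

    Deterministic for a fixed seed; spacing and origin are stored in meters
    to match simulated zone volumes.
    """
    sp = spec.voxel_spacing
    a, b, c = spec.half_axes
    pad = 2.0 + spec.jitter_amplitude
    n = [int(np.ceil(2 * (h + pad) / sp)) + 1 for h in (a, b, c)]
    origin_mm = np.array(spec.center) - (np.array(n) - 1) / 2 * sp
    xs = [origin_mm[i] + np.arange(n[i]) * sp - spec.center[i] for i in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    # implicit function < 0 inside; scaled to approximate signed distance (mm)
    level = (np.sqrt((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2) - 1.0) * min(a, b, c)
    if spec.jitter_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.standard_normal(level.shape)
        noise = ndimage.gaussian_filter(noise, sigma=4.0 / sp)
        noise *= spec.jitter_amplitude / max(noise.std(), 1e-12)
        level = level + noise
    mask = level < 0.0

    if spec.vessel_defect is not None:
        radius, axis, offset = spec.vessel_defect
        coords = {"x": (Y, Z), "y": (X, Z), "z": (X, Y)}[axis]
        dist = np.hypot(coords[0] - offset, coords[1])
        mask &= dist > radius

    return ZoneVolume(mask=mask, spacing=sp * 1e-3, origin=origin_mm * 1e-3)


def generate_sensor_series(spec: SyntheticSensorSpec) -> pd.DataFrame:
    """Probe table with columns time_s, temperature_C (seeded noise)."""
    t = np.arange(0.0, spec.duration + spec.sample_interval / 2, spec.sample_interval)
    temp = spec.asymptotic_temperature - (
        spec.asymptotic_temperature - spec.initial_temperature
    ) * np.exp(-t / spec.time_constant)
    if spec.noise_std > 0:
        rng = np.random.default_rng(spec.seed)
        temp = temp + rng.normal(0.0, spec.noise_std, size=t.shape)
    return pd.DataFrame({"time_s": t, "temperature_C": temp})
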