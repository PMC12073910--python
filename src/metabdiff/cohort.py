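"""Shared data containers: decay curves and per-subject records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

METABOLITES = ("tNAA", "tCho", "tCr")
REGIONS = ("cerebellum", "PCC")


def canonical_region(label: str) -> str:
    """Fold region spellings onto {cerebellum, PCC}."""
    low = label.strip().lower()
    if low == "cerebellum":
        return "cerebellum"
    if low == "pcc":
        return "PCC"
    raise ValueError(f"unknown region label: {label!r}")


def canonical_metabolite(label: str) -> str:
    """Fold metabolite spellings onto {tNAA, tCho, tCr}."""
    low = label.strip().lower()
    for m in METABOLITES:
        if low == m.lower():
            return m
    raise ValueError(f"unknown metabolite label: {label!r}")


@dataclass
class DecayCurve:
    """One metabolite's direction-averaged signal decay vs b.

    Amplitudes are in arbitrary units (LCModel-style peak areas); the
    fitting layer estimates the scale S0 jointly with the model
    parameters, so no prior normalization is required.
    """

    metabolite: str
    region: str
    b: np.ndarray
    amplitude: np.ndarray
    amplitude_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.b.shape != self.amplitude.shape:
            raise ValueError("b and amplitude must have the same length")
        if np.any(self.amplitude <= 0):
            raise ValueError("amplitudes must be positive")
        if self.amplitude_sd is not None:
            self.amplitude_sd = np.asarray(self.amplitude_sd, dtype=float)
            if self.amplitude_sd.shape != self.b.shape:
                raise ValueError("amplitude_sd length mismatch")

    @property
    def n_points(self) -> int:
        return self.b.size


@dataclass
class SubjectRecord:
    """One subject in one spectroscopic region.

    Holds demographics, voxel tissue composition and the per-metabolite
    decay curves; synthetic records additionally retain the ground-truth
    parameters they were generated from, for recovery scoring.
    """

    subject_id: str
    age: float
    sex: str
    region: str
    fgm: float
    fwm: float
    fcsf: float
    curves: dict = field(default_factory=dict)
    transients: dict | None = None
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        fr = np.array([self.fgm, self.fwm, self.fcsf])
        if np.any(fr < 0) or np.any(fr > 1):
            raise ValueError("tissue fractions must lie in [0, 1]")
        if abs(fr.sum() - 1.0) > 1e-6:
            raise ValueError("tissue fractions must sum to 1")

    @property
    def fgm_fwm(self) -> float:
        """GM/WM volume-fraction ratio, the trajectory covariate."""
        return self.fgm / self.fwm
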