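"""Shared domain containers used across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: category levels of the discretised clinicopathological variables
AGE_LEVELS = ("le50", "gt50")
SIZE_LEVELS = ("le20", "gt20")
GRADE_LEVELS = ("low", "intermediate", "high")
GAN_LEVELS = ("low", "high")
TILS_RISK_LEVELS = ("low", "high")
LYMPHOCYTE_LEVELS = ("0-5", "gt5")
TOUCHING_LEVELS = ("0", "gt0")
CIRCUMFERENTIAL_LEVELS = ("no", "yes")
HOTSPOT_LEVELS = ("no", "dense")
BCE_LEVELS = (0, 1)

#: columns of a cohort table, in canonical order
COHORT_COLUMNS = (
    "patient_id", "age_group", "size_group", "grade", "lymphocyte",
    "touching_tils", "circumferential", "hotspot", "bce", "followup_years",
)


@dataclass
class CoreImage:
    """One RGB TMA core (H x W x 3, uint8) with provenance identifiers."""

    pixels: np.ndarray
    patient_id: str
    core_id: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("CoreImage requires an H x W x 3 array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("CoreImage pixels must be 8-bit")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class TissueMask:
    """Boolean tissue mask aligned with its core image."""

    mask: np.ndarray
    degenerate: bool = False

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("TissueMask requires an H x W boolean array")

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


@dataclass
class Patch:
    """Fixed-size RGB tile with tissue fraction, provenance and weak label.

    ``origin`` is (core_id, row, col) with 0-based top-left corner; the patch
    covers the half-open window [row, row+S) x [col, col+S).
    """

    pixels: np.ndarray
    tissue_fraction: float
    core_id: str
    row: int
    col: int
    patient_id: str = ""
    weak_label: str = "unlabeled"  # {aggressive, non-aggressive, unlabeled}

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("Patch requires a square S x S x 3 array")
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise ValueError("tissue_fraction outside [0, 1]")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def origin(self):
        return (self.core_id, self.row, self.col)


@dataclass
class PatientScore:
    """Patient-level aggressiveness summary from patch voting."""

    patient_id: str
    n_aggressive: int
    n_total: int

    def __post_init__(self):
        if not 0 <= self.n_aggressive <= self.n_total:
            raise ValueError("need 0 <= n_aggressive <= n_total")

    @property
    def aggressive_fraction(self) -> float:
        return self.n_aggressive / self.n_total if self.n_total else 0.0
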