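"""Containers for protein sequences, measured R2 profiles, and predictions."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .params import AMINO_ACIDS


def default_mask(sequence: str, measured_r2: Optional[np.ndarray] = None) -> np.ndarray:
    """Scoring mask for a sequence: True where a residue participates in
    fitting and error metrics.

    Pro positions are always masked out (no backbone amide proton), as are
    positions with missing (NaN) measurements.
    """
    mask = np.array([aa != "P" for aa in sequence], dtype=bool)
    if measured_r2 is not None:
        mask &= np.isfinite(np.asarray(measured_r2, dtype=float))
    return mask


@dataclass
class R2Profile:
    """Per-residue transverse relaxation rates (s^-1), 1-based alignment to
    the source sequence, with a mask flagging positions excluded from scoring
    (Pro, unobserved)."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values and mask length mismatch: {self.values.shape} vs {self.mask.shape}"
            )
        if np.any(self.values[np.isfinite(self.values)] < 0):
            raise ValueError("R2 values must be non-negative where defined")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ProteinRecord:
    """One protein: identifier, sequence, and optional measured data tracks.

    ``scale`` is the per-protein uniform factor (upsilon, s^-1) absorbing
    temperature, magnetic field and viscosity effects; ``helix_scores`` is a
    per-residue helix-propensity track (e.g. parsed from a PsiPred ss2 file).
    """

    id: str
    sequence: str
    measured_r2: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    scale: Optional[float] = None
    helix_scores: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        n = len(self.sequence)
        if self.measured_r2 is not None:
            self.measured_r2 = np.asarray(self.measured_r2, dtype=float)
            if self.measured_r2.shape != (n,):
                raise ValueError(
                    f"{self.id}: measured_r2 length {self.measured_r2.size} != sequence length {n}"
                )
        if self.mask is None and self.measured_r2 is not None:
            self.mask = default_mask(self.sequence, self.measured_r2)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise ValueError(
                    f"{self.id}: mask length {self.mask.size} != sequence length {n}"
                )
            # Pro and missing measurements can never be masked in
            pro = np.array([aa == "P" for aa in self.sequence])
            self.mask = self.mask & ~pro
            if self.measured_r2 is not None:
                self.mask = self.mask & np.isfinite(self.measured_r2)
                observed = self.measured_r2[self.mask]
                if np.any(observed <= 0):
                    bad = int(np.flatnonzero(self.mask)[observed <= 0][0]) + 1
                    raise ValueError(
                        f"{self.id}: masked-in measured R2 must be positive "
                        f"(first offence at position {bad})"
                    )
        if self.scale is not None and not self.scale > 0:
            raise ValueError(f"{self.id}: scale must be > 0, got {self.scale}")
        if self.helix_scores is not None:
            self.helix_scores = np.asarray(self.helix_scores, dtype=float)
            if self.helix_scores.shape != (n,):
                raise ValueError(
                    f"{self.id}: helix_scores length {self.helix_scores.size} != sequence length {n}"
                )
            if np.any((self.helix_scores < 0) | (self.helix_scores > 1)):
                raise ValueError(f"{self.id}: helix scores must lie in [0, 1]")

    @property
    def n_scored(self) -> int:
        if self.mask is None:
            return 0
        return int(self.mask.sum())

    def with_measurements(self, values: np.ndarray, mask: Optional[np.ndarray] = None) -> "ProteinRecord":
        return replace(self, measured_r2=np.asarray(values, dtype=float), mask=mask)


@dataclass(frozen=True)
class HelixSegment:
    """A contiguous helical stretch, 1-based inclusive residue indices."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid helix segment [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1
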