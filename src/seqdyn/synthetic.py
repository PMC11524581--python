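"""Synthetic IDP-like datasets with known ground truth.

Every pipeline stage (I/O, training, cross-validation, sweeps) is exercised
on data generated from the forward model itself with known parameters, so
parameter-recovery is a well-posed oracle: the generator is the ground
truth.  The default spec mirrors the statistical shape of a typical R2
compilation — a couple dozen unrelated disordered sequences of roughly
80-150 residues, per-protein scale factors in the 0.8-2.0 s^-1 range, and
additive measurement noise of a few tenths of s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .model import predict_unscaled
from .params import AMINO_ACIDS, ModelParameters
from .records import ProteinRecord, default_mask

__all__ = [
    "SyntheticSpec",
    "default_true_params",
    "disorder_biased_composition",
    "generate_sequence",
    "generate_dataset",
    "apply_uniform_scaling",
]

#: Floor applied after adding noise; measured R2 can never be <= 0.
NOISE_CLIP = 0.05

#: Ground-truth q values for the generator: package constants chosen to
#: mirror the empirically observed ordering (aromatics, Arg, and long
#: branched aliphatics highest; Gly and short-polar residues lowest).
_TRUE_Q = {
    "W": 1.30, "I": 1.2174, "Y": 1.19, "R": 1.18, "H": 1.16, "F": 1.1552,
    "L": 1.1447, "M": 1.08, "K": 1.04, "Q": 1.02, "E": 1.00, "A": 0.99,
    "P": 0.97, "C": 0.96, "T": 0.95, "V": 0.94, "D": 0.93, "S": 0.92,
    "N": 0.90, "G": 0.86,
}

#: Disorder-biased amino-acid frequencies: disordered regions are enriched
#: in Gly, Ser, Pro, Glu, Lys and depleted in aromatics and Cys.  A
#: documented package constant, not an empirical claim.
_DISORDER_COMPOSITION = {
    "A": 0.080, "R": 0.050, "N": 0.040, "D": 0.055, "C": 0.010,
    "Q": 0.050, "E": 0.110, "G": 0.100, "H": 0.020, "I": 0.030,
    "L": 0.050, "K": 0.070, "M": 0.020, "F": 0.020, "P": 0.080,
    "S": 0.100, "T": 0.050, "W": 0.005, "Y": 0.015, "V": 0.045,
}


def default_true_params(b: float = 3.164e-2) -> ModelParameters:
    """Ground-truth parameters for synthetic data (correlation length ~5.6
    residues by default)."""
    return ModelParameters(q=dict(_TRUE_Q), b=b)


def disorder_biased_composition() -> np.ndarray:
    """Amino-acid frequency vector (ordered by one-letter code) enriched in
    disorder-promoting residues."""
    return np.array([_DISORDER_COMPOSITION[aa] for aa in AMINO_ACIDS])


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic dataset.

    Defaults give 20 proteins of 80-150 residues with uniform composition,
    scale factors drawn uniformly from 0.8-2.0 s^-1, and additive Gaussian
    noise of sd 0.3 s^-1 clipped to stay positive.
    """

    n_proteins: int = 20
    length_range: tuple[int, int] = (80, 150)
    composition: Optional[np.ndarray] = None
    true_params: ModelParameters = field(default_factory=default_true_params)
    scale_range: tuple[float, float] = (0.8, 2.0)
    noise_sd: float = 0.3
    pro_frequency: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (20 <= lo <= hi <= 500):
            raise ValueError(f"length_range must lie within [20, 500], got {self.length_range}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.scale_range[0] <= 0 or self.scale_range[1] < self.scale_range[0]:
            raise ValueError(f"invalid scale_range {self.scale_range}")
        if self.composition is not None:
            self.composition = _validate_composition(np.asarray(self.composition, float))
        if self.pro_frequency is not None and not 0 <= self.pro_frequency < 1:
            raise ValueError(f"pro_frequency must be in [0, 1), got {self.pro_frequency}")

    def effective_composition(self) -> np.ndarray:
        comp = (
            self.composition
            if self.composition is not None
            else np.full(20, 1.0 / 20.0)
        )
        if self.pro_frequency is not None:
            comp = comp.copy()
            p = AMINO_ACIDS.index("P")
            others = np.delete(np.arange(20), p)
            comp[others] *= (1.0 - self.pro_frequency) / comp[others].sum()
            comp[p] = self.pro_frequency
        return comp


def _validate_composition(comp: np.ndarray) -> np.ndarray:
    if comp.shape != (20,):
        raise ValueError(f"composition must have 20 entries, got shape {comp.shape}")
    if np.any(comp < 0):
        raise ValueError("composition weights must be >= 0")
    total = comp.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"composition must sum to 1, got {total}")
    return comp / total


def generate_sequence(
    length: int,
    composition: Optional[np.ndarray] = None,
    seed: Optional[int | np.random.Generator] = None,
) -> str:
    """Random one-letter sequence of i.i.d. draws from a composition vector
    (uniform over the 20 amino acids by default)."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    comp = (
        _validate_composition(np.asarray(composition, float))
        if composition is not None
        else np.full(20, 0.05)
    )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    letters = rng.choice(list(AMINO_ACIDS), size=length, p=comp)
    return "".join(letters)


def generate_dataset(spec: SyntheticSpec) -> list[ProteinRecord]:
    """Dataset of protein records with model-generated measurements.

    Each record carries its ground-truth scale in ``record.scale``; the
    generating global parameters live in ``spec.true_params``.  Pro
    positions are masked out of scoring exactly as for real data.
    """
    rng = np.random.default_rng(spec.seed)
    comp = spec.effective_composition()
    lo, hi = spec.length_range
    records = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        sequence = generate_sequence(length, comp, rng)
        scale = float(rng.uniform(*spec.scale_range))
        clean = scale * predict_unscaled(sequence, spec.true_params)
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=length) if spec.noise_sd > 0 else clean
        measured = np.maximum(noisy, NOISE_CLIP)
        records.append(
            ProteinRecord(
                id=f"synth{i+1:03d}",
                sequence=sequence,
                measured_r2=measured,
                mask=default_mask(sequence, measured),
                scale=scale,
            )
        )
    return records


def apply_uniform_scaling(record: ProteinRecord, factor: float) -> ProteinRecord:
    """Multiply a record's measurements by a uniform factor.

    Emulates changing temperature, field strength, or viscosity, which to a
    good approximation rescale R2 uniformly along the sequence.  The mask is
    unchanged; the ground-truth scale (if any) is multiplied accordingly, so
    scaled data remain model-consistent."""
    if not factor > 0:
        raise ValueError(f"scaling factor must be > 0, got {factor}")
    return replace(
        record,
        measured_r2=None if record.measured_r2 is None else record.measured_r2 * factor,
        mask=None if record.mask is None else record.mask.copy(),
        scale=None if record.scale is None else record.scale * factor,
    )
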