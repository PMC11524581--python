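"""Global model parameters: the 20 amino-acid q factors and the distance coefficient b.

The model assigns each amino acid a dimensionless propensity ``q`` for slowing
local backbone dynamics (q > 1 raises the R2 of nearby residues, q < 1 lowers
it) and a single distance coefficient ``b`` that sets how quickly a residue's
influence decays with sequence separation.  The derived correlation length
``Lcorr = b**-0.5`` is the separation at which the influence has decayed
halfway between its contact value and 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def correlation_length(b: float) -> float:
    """Correlation length (residues) implied by the distance coefficient.

    Lcorr = b**(-1/2): the sequence separation at which a neighbour's
    contributing factor sits midway between its value at s=0 and its
    asymptote of 1.

    Raises
    ------
    ValueError
        If ``b`` is not strictly positive.
    """
    if b <= 0:
        raise ValueError(f"distance coefficient b must be > 0, got {b}")
    return float(b) ** -0.5


@dataclass(frozen=True)
class ModelParameters:
    """The 21 global parameters: one q per standard amino acid, plus b.

    Parameters
    ----------
    q : mapping of one-letter amino acid to positive float
        Multiplicative propensity of each amino acid for slowing local
        dynamics.  Exactly the 20 standard amino acids must be present
        (Pro included — Pro contributes to its neighbours even though Pro
        positions themselves carry no amide proton).
    b : positive float
        Dimensionless coefficient of the Lorentzian distance attenuation.
    """

    q: Mapping[str, float]
    b: float

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.q)
        extra = set(self.q) - set(AMINO_ACIDS)
        if missing or extra:
            raise ValueError(
                f"q must have exactly one entry per standard amino acid; "
                f"missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        for aa, value in self.q.items():
            if not value > 0:
                raise ValueError(f"q[{aa}] must be > 0, got {value}")
        if not self.b > 0:
            raise ValueError(f"b must be > 0, got {self.b}")
        # freeze an ordered copy so mutation of the caller's dict cannot leak in
        object.__setattr__(self, "q", {aa: float(self.q[aa]) for aa in AMINO_ACIDS})
        object.__setattr__(self, "b", float(self.b))

    @property
    def q_array(self) -> np.ndarray:
        """q values as a length-20 array ordered by :data:`AMINO_ACIDS`."""
        return np.array([self.q[aa] for aa in AMINO_ACIDS], dtype=float)

    @property
    def lcorr(self) -> float:
        """Correlation length in residues, ``b**-0.5``."""
        return correlation_length(self.b)

    @classmethod
    def flat(cls, b: float = 0.04) -> "ModelParameters":
        """All-q=1 parameters (the flat model): every profile is constant."""
        return cls(q={aa: 1.0 for aa in AMINO_ACIDS}, b=b)

    @classmethod
    def from_arrays(cls, q: np.ndarray, b: float) -> "ModelParameters":
        q = np.asarray(q, dtype=float)
        if q.shape != (20,):
            raise ValueError(f"expected 20 q values, got shape {q.shape}")
        return cls(q=dict(zip(AMINO_ACIDS, q.tolist())), b=b)

    def replace_b(self, b: float) -> "ModelParameters":
        return ModelParameters(q=dict(self.q), b=b)
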