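"""Per-protein and dataset statistics: mean/sd of measured R2, RMSE, scaled
R2 (sR2), and amino-acid mean scaled R2 (msR2).

All statistics run over masked-in positions only (Pro and unobserved residues
never contribute).  Standard deviations are population-style (divide by n),
which makes the null-model identity exact: the RMSE of the constant-mean
predictor equals the per-protein sd of the measured rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .params import AMINO_ACIDS
from .records import ProteinRecord, R2Profile

__all__ = [
    "ProteinStats",
    "AminoAcidProfile",
    "protein_stats",
    "rmse",
    "scaled_r2",
    "pooled_msr2",
    "table1_aggregates",
]


@dataclass(frozen=True)
class ProteinStats:
    """Mean and standard deviation of a protein's measured R2 (s^-1), over
    scored residues."""

    mean_r2: float
    sd_r2: float
    n_scored: int


@dataclass(frozen=True)
class AminoAcidProfile:
    """Amino-acid mean scaled R2 pooled over a dataset, with residue counts."""

    msr2: Mapping[str, float]
    counts: Mapping[str, int]

    @property
    def grand_mean(self) -> float:
        """Count-weighted mean msR2 over all amino acids present (i.e. the
        mean of the pooled sR2 values)."""
        total = sum(self.counts.values())
        return sum(self.msr2[aa] * self.counts[aa] for aa in self.msr2) / total


def _observed(record: ProteinRecord) -> np.ndarray:
    if record.measured_r2 is None or record.mask is None:
        raise ValueError(f"{record.id}: no measured R2 data")
    values = record.measured_r2[record.mask]
    if values.size == 0:
        raise ValueError(f"{record.id}: no masked-in measurements")
    return values


def protein_stats(record: ProteinRecord) -> ProteinStats:
    """Mean and (population) standard deviation of measured R2 over scored
    residues."""
    values = _observed(record)
    return ProteinStats(
        mean_r2=float(values.mean()),
        sd_r2=float(values.std(ddof=0)),
        n_scored=int(values.size),
    )


def rmse(
    predicted: R2Profile | np.ndarray,
    measured: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Root-mean-square error over masked-in positions (s^-1)."""
    pred = predicted.values if isinstance(predicted, R2Profile) else np.asarray(predicted, float)
    meas = np.asarray(measured, dtype=float)
    if pred.shape != meas.shape:
        raise ValueError(f"length mismatch: predicted {pred.shape} vs measured {meas.shape}")
    if mask is None:
        mask = np.isfinite(meas)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != meas.shape:
            raise ValueError(f"mask length {mask.shape} != data length {meas.shape}")
    if not mask.any():
        raise ValueError("no masked-in positions to score")
    resid = pred[mask] - meas[mask]
    return float(np.sqrt(np.mean(resid**2)))


def scaled_r2(record: ProteinRecord) -> np.ndarray:
    """Measured R2 divided by the protein's mean R2 (sR2, dimensionless).

    Scaling each protein by its own mean removes uniform external factors
    (temperature, field strength, viscosity), so profiles acquired under
    different conditions become comparable.  The mean of the masked-in
    scaled values is 1 by construction.  Returned at every position
    (NaN where unmeasured); use the record mask to select scored entries.
    """
    stats = protein_stats(record)
    if stats.mean_r2 <= 0:
        raise ValueError(f"{record.id}: mean R2 must be positive to scale")
    return record.measured_r2 / stats.mean_r2


def pooled_msr2(dataset: Sequence[ProteinRecord]) -> AminoAcidProfile:
    """Amino-acid type-specific mean scaled R2 (msR2) pooled across a dataset.

    Pooling is over residues, not over per-protein means: every masked-in
    occurrence of an amino acid contributes one sR2 value.  Amino acids with
    no scored occurrence are absent from the map.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for record in dataset:
        sr2 = scaled_r2(record)
        for pos in np.flatnonzero(record.mask):
            aa = record.sequence[pos]
            sums[aa] = sums.get(aa, 0.0) + float(sr2[pos])
            counts[aa] = counts.get(aa, 0) + 1
    order = [aa for aa in AMINO_ACIDS if aa in counts]
    return AminoAcidProfile(
        msr2={aa: sums[aa] / counts[aa] for aa in order},
        counts={aa: counts[aa] for aa in order},
    )


def table1_aggregates(fixture: pd.DataFrame, named_row: str = "Pdx1") -> dict:
    """Summary statistics over the bundled benchmark table.

    The fixture lists, per protein, the dataset split, number of residues,
    experimental conditions, mean and sd of measured R2, and the prediction
    RMSE (leave-one-out for training rows; a second helix-boosted RMSE where
    one was reported).  Test-set means prefer the boosted value where present.
    """
    required = {"name", "set", "mean_r2", "sd_r2", "rmse"}
    if not required.issubset(fixture.columns):
        raise ValueError(f"fixture missing columns {sorted(required - set(fixture.columns))}")
    train = fixture[fixture["set"] == "train"]
    test = fixture[fixture["set"] == "test"]
    if train.empty or test.empty:
        raise ValueError("fixture must contain both train and test rows")

    def effective_rmse(rows: pd.DataFrame) -> pd.Series:
        if "rmse_boosted" in rows.columns:
            return rows["rmse_boosted"].fillna(rows["rmse"])
        return rows["rmse"]

    named = fixture[fixture["name"] == named_row]
    if named.empty:
        raise ValueError(f"named row {named_row!r} not in fixture")
    named = named.iloc[0]

    return {
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "mean_train_sd_r2": float(train["sd_r2"].mean()),
        "n_train_mean_r2_mid": int(train["mean_r2"].between(2.5, 5.5).sum()),
        "n_train_mean_r2_high": int((train["mean_r2"] > 6.4).sum()),
        "n_train_rmse_below_sd": int((train["rmse"] < train["sd_r2"]).sum()),
        "mean_test_rmse": float(effective_rmse(test).mean()),
        "n_test_rmse_below_sd": int((effective_rmse(test) < test["sd_r2"]).sum()),
        "named_row_rmse_minus_sd": float(named["rmse"] - named["sd_r2"]),
    }
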