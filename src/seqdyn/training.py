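"""Training, baselines, and cross-validation over datasets of proteins.

Thin functional wrappers over :class:`~seqdyn.estimators.SeqDynRegressor`;
the estimator owns the optimization, these functions own dataset-level
workflows (leave-one-out, k-fold with parameter spread and t-tests, the
fixed-correlation-length sweep, and the null/one-residue baselines).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as scipy_stats

from ._optimize import fit_scale
from .estimators import OneResidueRegressor, SeqDynRegressor
from .metrics import protein_stats, rmse
from .model import predict_unscaled
from .params import AA_INDEX, AMINO_ACIDS, ModelParameters
from .records import ProteinRecord

__all__ = [
    "FitResult",
    "CrossValReport",
    "objective",
    "fit_scale",
    "train",
    "null_model_eval",
    "one_residue_model",
    "loocv",
    "kfold_cv",
    "sweep_fixed_lcorr",
]


@dataclass
class FitResult:
    """Outcome of a training run: global parameters, per-protein scales and
    in-sample RMSEs, and optimizer diagnostics."""

    params: Optional[ModelParameters]
    scales: dict[str, float]
    per_protein_rmse: dict[str, float]
    cost: float
    converged: bool
    n_iter: int

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "q": None if self.params is None else dict(self.params.q),
            "b": None if self.params is None else self.params.b,
            "scales": self.scales,
            "per_protein_rmse": self.per_protein_rmse,
            "cost": self.cost,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        payload = json.loads(text)
        params = None
        if payload["q"] is not None:
            params = ModelParameters(q=payload["q"], b=payload["b"])
        return cls(
            params=params,
            scales=payload["scales"],
            per_protein_rmse=payload["per_protein_rmse"],
            cost=payload["cost"],
            converged=payload["converged"],
            n_iter=payload["n_iter"],
        )

    def summary(self) -> str:
        lines = [f"cost {self.cost:.6g}  converged {self.converged}  n_iter {self.n_iter}"]
        if self.params is not None:
            lines.append(f"b {self.params.b:.6g}  Lcorr {self.params.lcorr:.3f} residues")
            qtxt = "  ".join(f"{aa} {self.params.q[aa]:.4f}" for aa in AMINO_ACIDS)
            lines.append(f"q: {qtxt}")
        for pid in sorted(self.per_protein_rmse):
            lines.append(
                f"  {pid}: scale {self.scales[pid]:.4f} s^-1, RMSE {self.per_protein_rmse[pid]:.4f} s^-1"
            )
        return "\n".join(lines)


@dataclass
class CrossValReport:
    """Held-out RMSE per protein, plus (k-fold) per-fold parameter sets,
    their mean +/- sd, and any requested q-pair t-tests."""

    per_protein_rmse_heldout: dict[str, float]
    mean_rmse_heldout: float
    fold_params: list[ModelParameters] = field(default_factory=list)
    param_mean_sd: dict[str, tuple[float, float]] = field(default_factory=dict)
    t_tests: dict[str, tuple[float, float]] = field(default_factory=dict)
    diagnostics: dict[str, bool] = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "per_protein_rmse_heldout": self.per_protein_rmse_heldout,
            "mean_rmse_heldout": self.mean_rmse_heldout,
            "fold_params": [
                {"q": dict(p.q), "b": p.b} for p in self.fold_params
            ],
            "param_mean_sd": {k: list(v) for k, v in self.param_mean_sd.items()},
            "t_tests": {k: list(v) for k, v in self.t_tests.items()},
            "diagnostics": self.diagnostics,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)


def objective(
    params: ModelParameters,
    scales: Mapping[str, float],
    dataset: Sequence[ProteinRecord],
    kernel: str = "lorentzian",
) -> float:
    """Sum over proteins of the mean squared prediction error over scored
    residues — the quantity the trainer minimizes."""
    total = 0.0
    for record in dataset:
        if record.measured_r2 is None or record.mask is None or not record.mask.any():
            raise ValueError(f"{record.id}: no masked-in measurements")
        pred = scales[record.id] * predict_unscaled(record.sequence, params, kernel)
        resid = (pred - record.measured_r2)[record.mask]
        total += float(np.mean(resid**2))
    return total


def train(
    dataset: Sequence[ProteinRecord],
    init_params: Optional[ModelParameters] = None,
    init_scales: Optional[Mapping[str, float]] = None,
    lcorr: Optional[float] = None,
    kernel: str = "lorentzian",
    floor: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> FitResult:
    """Fit the 21 global parameters plus per-protein scales; see
    :class:`~seqdyn.estimators.SeqDynRegressor` for the parameter meanings."""
    est = SeqDynRegressor(
        kernel=kernel, lcorr=lcorr, floor=floor, tol=tol, max_iter=max_iter
    )
    est.fit(dataset, init_params=init_params, init_scales=init_scales)
    return FitResult(
        params=est.params_,
        scales=est.scales_,
        per_protein_rmse=est.training_rmse_,
        cost=est.cost_,
        converged=est.converged_,
        n_iter=est.n_iter_,
    )


def null_model_eval(dataset: Sequence[ProteinRecord]) -> tuple[dict[str, float], float]:
    """RMSE of the uniform-R2 (constant per-protein mean) predictor.

    Identically equal to each protein's standard deviation of measured R2,
    so the dataset mean sets the upper bound any sequence-aware predictor
    must beat."""
    per = {r.id: protein_stats(r).sd_r2 for r in dataset}
    return per, float(np.mean(list(per.values())))


def one_residue_model(
    dataset_train: Sequence[ProteinRecord],
    dataset_eval: Sequence[ProteinRecord],
) -> dict[str, float]:
    """Held-out RMSE of the one-residue baseline (per-residue msR2 learned
    on the training proteins, per-protein scale refit on each eval protein)."""
    est = OneResidueRegressor().fit(dataset_train)
    return {r.id: est.heldout_rmse(r) for r in dataset_eval}


def loocv(
    dataset: Sequence[ProteinRecord],
    **trainer_kwargs,
) -> CrossValReport:
    """Leave-one-out cross-validation: each protein in turn is held out, the
    model is trained on the rest, the held-out scale is refit in closed form,
    and the held-out RMSE is recorded."""
    if len(dataset) < 2:
        raise ValueError("leave-one-out needs at least 2 proteins")
    per: dict[str, float] = {}
    folds: list[ModelParameters] = []
    diagnostics: dict[str, bool] = {}
    for i, heldout in enumerate(dataset):
        rest = [r for j, r in enumerate(dataset) if j != i]
        est = SeqDynRegressor(**trainer_kwargs).fit(rest)
        per[heldout.id] = est.heldout_rmse(heldout)
        diagnostics[heldout.id] = est.converged_
        if est.params_ is not None:
            folds.append(est.params_)
    return CrossValReport(
        per_protein_rmse_heldout=per,
        mean_rmse_heldout=float(np.mean(list(per.values()))),
        fold_params=folds,
        param_mean_sd=_param_spread(folds),
        diagnostics=diagnostics,
    )


def _param_spread(folds: Sequence[ModelParameters]) -> dict[str, tuple[float, float]]:
    if not folds:
        return {}
    out: dict[str, tuple[float, float]] = {}
    for aa in AMINO_ACIDS:
        vals = np.array([p.q[aa] for p in folds])
        out[aa] = (float(vals.mean()), float(vals.std(ddof=1)) if len(folds) > 1 else 0.0)
    bvals = np.array([p.b for p in folds])
    out["b"] = (float(bvals.mean()), float(bvals.std(ddof=1)) if len(folds) > 1 else 0.0)
    return out


def q_pair_ttest(
    folds: Sequence[ModelParameters], aa1: str, aa2: str
) -> tuple[float, float]:
    """Welch two-sample t-test on per-fold q estimates for two amino acids.

    Returns (t statistic, two-sided p-value).  A small p suggests the two
    amino acids genuinely differ in their propensity to slow local dynamics,
    rather than the difference being training noise."""
    if aa1 not in AA_INDEX or aa2 not in AA_INDEX:
        raise ValueError(f"unknown amino acid in pair ({aa1}, {aa2})")
    a = np.array([p.q[aa1] for p in folds])
    b = np.array([p.q[aa2] for p in folds])
    t, p = scipy_stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def kfold_cv(
    dataset: Sequence[ProteinRecord],
    k: int,
    seed: int = 0,
    q_pairs: Optional[Sequence[tuple[str, str]]] = None,
    **trainer_kwargs,
) -> CrossValReport:
    """k-fold cross-validation: k independent parameter estimates from
    training on each (k-1)/k split, per-parameter mean +/- sd, held-out
    RMSEs, and Welch t-tests for requested q pairs."""
    n = len(dataset)
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for rank, idx in enumerate(order):
        fold_of[idx] = rank % k
    per: dict[str, float] = {}
    folds: list[ModelParameters] = []
    diagnostics: dict[str, bool] = {}
    for fold in range(k):
        train_set = [r for i, r in enumerate(dataset) if fold_of[i] != fold]
        test_set = [r for i, r in enumerate(dataset) if fold_of[i] == fold]
        est = SeqDynRegressor(**trainer_kwargs).fit(train_set)
        if est.params_ is not None:
            folds.append(est.params_)
        for record in test_set:
            per[record.id] = est.heldout_rmse(record)
            diagnostics[record.id] = est.converged_
    tests = {}
    for aa1, aa2 in q_pairs or []:
        tests[f"{aa1}-{aa2}"] = q_pair_ttest(folds, aa1, aa2)
    return CrossValReport(
        per_protein_rmse_heldout=per,
        mean_rmse_heldout=float(np.mean(list(per.values()))),
        fold_params=folds,
        param_mean_sd=_param_spread(folds),
        t_tests=tests,
        diagnostics=diagnostics,
    )


def sweep_fixed_lcorr(
    dataset: Sequence[ProteinRecord],
    lcorr_values: Sequence[float],
    **trainer_kwargs,
) -> dict[float, float]:
    """Retrain with the correlation length pinned at each grid value and
    report the mean in-sample RMSE.

    Lcorr = 0 is the exact self-factor-only model (each residue coupled only
    to itself); large Lcorr flattens every profile toward the null model.
    The minimum of the curve estimates the characteristic coupling range of
    the data."""
    out: dict[float, float] = {}
    for lcorr in lcorr_values:
        if lcorr < 0:
            raise ValueError(f"correlation length must be >= 0, got {lcorr}")
        est = SeqDynRegressor(lcorr=float(lcorr), **trainer_kwargs).fit(dataset)
        out[float(lcorr)] = float(np.mean(list(est.training_rmse_.values())))
    return out
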