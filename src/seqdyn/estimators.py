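"""Scikit-learn style estimators.

:class:`SeqDynRegressor` learns the 20 amino-acid propensities q, the
distance coefficient b, and one scale factor per training protein from
measured R2 profiles.  :class:`OneResidueRegressor` is the one-residue
baseline: each residue takes its amino-acid mean scaled R2 (msR2) learned
from the training set, then a per-protein scale is applied.

Both estimators follow sklearn conventions — constructor parameters are
stored verbatim, fitted state lives in trailing-underscore attributes, and
``get_params``/``set_params``/``clone`` work as usual — but samples are whole
proteins: X is a list of :class:`~seqdyn.records.ProteinRecord` (or raw
sequences with y as a list of per-residue arrays), and ``predict`` returns
one profile per protein.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import _optimize
from .metrics import pooled_msr2, rmse
from .model import encode_sequence, _profile_from_indices
from .params import AA_INDEX, ModelParameters
from .records import ProteinRecord

__all__ = ["SeqDynRegressor", "OneResidueRegressor", "as_records"]


def as_records(
    X: Sequence[ProteinRecord] | Sequence[str],
    y: Optional[Sequence[np.ndarray]] = None,
    mask: Optional[Sequence[np.ndarray]] = None,
) -> list[ProteinRecord]:
    """Normalize estimator input to a list of protein records.

    X may already be records (y ignored), or raw one-letter sequences with
    y giving the per-residue measured R2 arrays (NaN = unobserved) and mask
    optionally overriding the default Pro/missing mask.
    """
    if len(X) == 0:
        raise ValueError("empty dataset")
    if isinstance(X[0], ProteinRecord):
        return list(X)
    if y is None:
        return [ProteinRecord(id=f"seq{i+1}", sequence=s) for i, s in enumerate(X)]
    if len(y) != len(X):
        raise ValueError(f"X has {len(X)} sequences but y has {len(y)} profiles")
    records = []
    for i, (seq, values) in enumerate(zip(X, y)):
        m = None if mask is None else mask[i]
        records.append(
            ProteinRecord(id=f"seq{i+1}", sequence=seq, measured_r2=np.asarray(values, float), mask=m)
        )
    return records


class SeqDynRegressor(BaseEstimator):
    """Sequence-based predictor of per-residue backbone amide R2.

    The model multiplies, over every residue i of the chain, a factor
    ``1 + (q_i - 1)/(1 + b s^2)`` (s = sequence separation from the residue
    being predicted) and scales the product by a per-protein factor.
    Fitting minimizes the sum over training proteins of the mean squared
    error over scored residues, with all parameters bounded positive
    (trust-region reflective least squares).

    Parameters
    ----------
    kernel : {"lorentzian", "gaussian"}
        Distance-attenuation form.  The Lorentzian is the reference model;
        the Gaussian decays faster and is provided for comparison only.
    lcorr : float or None
        None (default) trains b freely.  A positive value pins the
        correlation length (b = lcorr**-2).  Zero selects the exact
        self-factor-only limit, where the prediction at a residue is just
        its own q times the protein scale.
    b_init : float
        Starting value for b when free (default 0.04, i.e. Lcorr = 5).
    q_init : float
        Starting q for every amino acid (default 1, the flat model).
    floor : float
        Positive lower bound applied to every parameter.
    tol : float
        Termination tolerance on cost, step, and gradient.
    max_iter : int
        Cap on objective evaluations; exceeding it flags
        ``converged_ = False`` rather than raising.
    strict : bool
        If False, nonstandard letters are resolved through ``aliases``.
    aliases : mapping or None
        Letter-to-standard-amino-acid alias table for permissive parsing.

    Attributes
    ----------
    q_ : ndarray of shape (20,)
        Fitted propensities, ordered alphabetically by one-letter code.
    b_ : float or None
        Fitted (or pinned) distance coefficient; None in the
        self-factor-only limit.
    params_ : ModelParameters or None
        Convenience bundle of q_ and b_ (None when b_ is None).
    scales_ : dict mapping protein id to fitted scale (s^-1).
    cost_ : float
        Final objective: sum over proteins of mean squared error.
    converged_ : bool
    n_iter_ : int
        Number of objective evaluations used.
    """

    def __init__(
        self,
        kernel: str = "lorentzian",
        lcorr: Optional[float] = None,
        b_init: float = 0.04,
        q_init: float = 1.0,
        floor: float = 1e-6,
        tol: float = 1e-8,
        max_iter: int = 2000,
        strict: bool = True,
        aliases: Optional[Mapping[str, str]] = None,
    ):
        self.kernel = kernel
        self.lcorr = lcorr
        self.b_init = b_init
        self.q_init = q_init
        self.floor = floor
        self.tol = tol
        self.max_iter = max_iter
        self.strict = strict
        self.aliases = aliases

    # -- helpers -----------------------------------------------------------

    def _encode(self, sequence: str) -> np.ndarray:
        return encode_sequence(sequence, strict=self.strict, aliases=self.aliases)

    def _unscaled(self, sequence: str, q: np.ndarray, b: Optional[float]) -> np.ndarray:
        idx = self._encode(sequence)
        if b is None:
            return q[idx]
        return _profile_from_indices(idx, q, b, self.kernel)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None, mask=None, init_params: Optional[ModelParameters] = None,
            init_scales: Optional[Mapping[str, float]] = None):
        """Fit q, b and per-protein scales to measured R2 profiles.

        ``init_params``/``init_scales`` override the default start (flat q,
        b_init, each protein's mean measured R2 as its scale).
        """
        records = as_records(X, y, mask)
        if len(records) < 2:
            warnings.warn(
                "fitting on a single protein only biases the parameters to that "
                "profile and has little predictive value",
                stacklevel=2,
            )
        if init_params is not None:
            q0 = init_params.q_array
            b0 = init_params.b
        else:
            q0 = np.full(20, float(self.q_init))
            b0 = float(self.b_init)
        scales0 = np.array(
            [
                (init_scales or {}).get(r.id) or float(r.measured_r2[r.mask].mean())
                for r in records
            ]
        )
        q, b, scales, result = _optimize.fit_global(
            records,
            self._encode,
            q0=q0,
            b0=b0,
            scales0=scales0,
            kernel=self.kernel,
            lcorr_fixed=self.lcorr,
            floor=self.floor,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.q_ = q
        self.b_ = None if b is None else float(b)
        self.params_ = None if b is None else ModelParameters.from_arrays(q, b)
        self.scales_ = {r.id: float(s) for r, s in zip(records, scales)}
        self.cost_ = 2.0 * float(result.cost)
        self.converged_ = bool(result.status > 0)
        self.n_iter_ = int(result.nfev)
        self.optimizer_result_ = result
        self.training_rmse_ = {
            r.id: rmse(s * self._unscaled(r.sequence, q, b), r.measured_r2, r.mask)
            for r, s in zip(records, scales)
        }
        return self

    def predict(self, X, scales: Optional[Sequence[float]] = None) -> list[np.ndarray]:
        """Predicted profiles for a list of records or sequences.

        Without ``scales`` the profiles are unscaled (dimensionless shape);
        supply per-protein factors (s^-1) to obtain rates.
        """
        self._check_fitted()
        records = as_records(X)
        out = []
        for i, record in enumerate(records):
            profile = self._unscaled(record.sequence, self.q_, self.b_)
            if scales is not None:
                profile = scales[i] * profile
            out.append(profile)
        return out

    def heldout_rmse(self, record: ProteinRecord) -> float:
        """RMSE for a protein outside the training set.

        The protein's scale is unknown, so it is refit by closed-form least
        squares against the measurements before scoring — the scale carries
        no sequence information, only experimental conditions.
        """
        self._check_fitted()
        unscaled = self._unscaled(record.sequence, self.q_, self.b_)
        scale = _optimize.fit_scale(unscaled, record.measured_r2, record.mask)
        return rmse(scale * unscaled, record.measured_r2, record.mask)

    def score(self, X, y=None) -> float:
        """Negative mean held-out RMSE (s^-1); higher is better, as sklearn
        model selection expects."""
        records = as_records(X, y)
        return -float(np.mean([self.heldout_rmse(r) for r in records]))

    def _check_fitted(self) -> None:
        if not hasattr(self, "q_"):
            raise AttributeError("estimator is not fitted; call fit() first")


class OneResidueRegressor(BaseEstimator):
    """Baseline ignoring neighbours: each residue predicts its amino-acid
    mean scaled R2 (msR2) learned from the training set, times a per-protein
    scale.  Equivalent to the full model in the zero-correlation-length
    limit with q pinned at msR2."""

    def fit(self, X, y=None):
        records = as_records(X, y)
        profile = pooled_msr2(records)
        self.msr2_ = dict(profile.msr2)
        self.counts_ = dict(profile.counts)
        self.grand_mean_ = profile.grand_mean
        return self

    def predict(self, X, scales: Optional[Sequence[float]] = None) -> list[np.ndarray]:
        if not hasattr(self, "msr2_"):
            raise AttributeError("estimator is not fitted; call fit() first")
        records = as_records(X)
        out = []
        for i, record in enumerate(records):
            values = np.empty(len(record.sequence))
            for pos, aa in enumerate(record.sequence):
                if aa not in AA_INDEX:
                    raise ValueError(f"{record.id}: nonstandard residue {aa!r} at {pos + 1}")
                if aa in self.msr2_:
                    values[pos] = self.msr2_[aa]
                else:
                    # Pro is always masked out of pooling (no amide proton),
                    # so a silent fallback there is expected, not noteworthy
                    if aa != "P":
                        warnings.warn(
                            f"{record.id}: amino acid {aa!r} absent from training msR2; "
                            "using the global mean",
                            stacklevel=2,
                        )
                    values[pos] = self.grand_mean_
            if scales is not None:
                values = scales[i] * values
            out.append(values)
        return out

    def heldout_rmse(self, record: ProteinRecord) -> float:
        unscaled = self.predict([record])[0]
        scale = _optimize.fit_scale(unscaled, record.measured_r2, record.mask)
        return rmse(scale * unscaled, record.measured_r2, record.mask)

    def score(self, X, y=None) -> float:
        records = as_records(X, y)
        return -float(np.mean([self.heldout_rmse(r) for r in records]))
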