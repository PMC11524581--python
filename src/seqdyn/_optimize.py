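"""Nonlinear least-squares machinery shared by the estimators.

The trained objective is the sum over proteins of the mean squared error over
scored residues, minimized jointly over the 20 amino-acid q values, the
distance coefficient b, and one scale factor per protein, all bounded below
by a small positive floor.  Residuals are weighted by 1/sqrt(n_p) per protein
so that the optimizer's sum of squares equals the sum of per-protein MSEs
(each protein counts equally regardless of length).

The Jacobian is analytic.  With P(n) = prod_i F(n, i), F = 1 + (q_i - 1) W,

    dP/dq_a = P * sum_{i: aa_i = a} W(n, i) / F(n, i)
    dP/db   = P * sum_i (q_i - 1) dW/db / F(n, i)

where dW/db = -s^2 W^2 for the Lorentzian kernel and -s^2 W for the Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .records import ProteinRecord


@dataclass
class _Encoded:
    """Per-protein precomputation for the optimizer."""

    idx: np.ndarray       # (N,) amino-acid indices
    d2: np.ndarray        # (N, N) squared sequence separations
    onehot: np.ndarray    # (N, 20) residue-type indicator
    measured: np.ndarray  # (M,) masked-in measurements
    mask: np.ndarray      # (N,) boolean
    weight: float         # 1/sqrt(M)


def encode_dataset(dataset: Sequence[ProteinRecord], encode) -> list[_Encoded]:
    encoded = []
    for record in dataset:
        if record.measured_r2 is None or record.mask is None:
            raise ValueError(f"{record.id}: training requires measured R2 data")
        if not record.mask.any():
            raise ValueError(f"{record.id}: no masked-in residues")
        idx = encode(record.sequence)
        n = idx.size
        pos = np.arange(n)
        d2 = ((pos[:, None] - pos[None, :]) ** 2).astype(float)
        onehot = np.zeros((n, 20))
        onehot[pos, idx] = 1.0
        m = int(record.mask.sum())
        encoded.append(
            _Encoded(
                idx=idx,
                d2=d2,
                onehot=onehot,
                measured=record.measured_r2[record.mask],
                mask=record.mask,
                weight=m**-0.5,
            )
        )
    return encoded


def _weights_and_grad(d2: np.ndarray, b: float, kernel: str):
    if kernel == "lorentzian":
        w = 1.0 / (1.0 + b * d2)
        dw = -d2 * w**2
    elif kernel == "gaussian":
        w = np.exp(-b * d2)
        dw = -d2 * w
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return w, dw


def _profile_and_grads(enc: _Encoded, q: np.ndarray, b: Optional[float], kernel: str, need_jac: bool):
    """Unscaled profile P (masked) and, if requested, dP/dq (M, 20), dP/db (M,).

    ``b is None`` selects the self-factor-only limit (Lcorr = 0): the profile
    is just q at each residue, dP/dq is the residue indicator, dP/db is zero.
    """
    if b is None:
        p = q[enc.idx]
        if not need_jac:
            return p[enc.mask], None, None
        return p[enc.mask], enc.onehot[enc.mask], np.zeros(int(enc.mask.sum()))
    w, dw = _weights_and_grad(enc.d2, b, kernel)
    qi = q[enc.idx]
    f = 1.0 + (qi[None, :] - 1.0) * w
    p = np.exp(np.log(f).sum(axis=1))
    if not need_jac:
        return p[enc.mask], None, None
    g = w / f                                        # dlogF/dq_{aa_i}
    dp_dq = p[:, None] * (g @ enc.onehot)
    dlog_db = ((qi[None, :] - 1.0) * dw / f).sum(axis=1)
    dp_db = p * dlog_db
    return p[enc.mask], dp_dq[enc.mask], dp_db[enc.mask]


def fit_global(
    dataset: Sequence[ProteinRecord],
    encode,
    q0: np.ndarray,
    b0: Optional[float],
    scales0: np.ndarray,
    kernel: str = "lorentzian",
    lcorr_fixed: Optional[float] = None,
    floor: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 2000,
):
    """Joint TRF fit of q, b (unless fixed), and per-protein scales.

    ``lcorr_fixed``: None leaves b free; a positive value pins b = lcorr**-2;
    0 selects the exact self-factor-only model (no b at all).

    Returns (q, b, scales, result) where ``result`` is the scipy optimize
    result (``result.cost`` is half the sum of squares).
    """
    encoded = encode_dataset(dataset, encode)
    n_prot = len(encoded)
    self_only = lcorr_fixed is not None and lcorr_fixed == 0
    b_free = lcorr_fixed is None
    b_fixed_value: Optional[float] = None
    if lcorr_fixed is not None and not self_only:
        if lcorr_fixed < 0:
            raise ValueError("fixed correlation length must be >= 0")
        b_fixed_value = float(lcorr_fixed) ** -2

    def unpack(theta):
        q = theta[:20]
        off = 20
        if b_free:
            b = theta[off]
            off += 1
        else:
            b = None if self_only else b_fixed_value
        scales = theta[off:]
        return q, b, scales

    def residuals(theta):
        q, b, scales = unpack(theta)
        out = []
        for enc, ups in zip(encoded, scales):
            p, _, _ = _profile_and_grads(enc, q, b, kernel, need_jac=False)
            out.append(enc.weight * (ups * p - enc.measured))
        return np.concatenate(out)

    def jacobian(theta):
        q, b, scales = unpack(theta)
        n_theta = theta.size
        blocks = []
        off_scale = 21 if b_free else 20
        for k, (enc, ups) in enumerate(zip(encoded, scales)):
            p, dp_dq, dp_db = _profile_and_grads(enc, q, b, kernel, need_jac=True)
            block = np.zeros((p.size, n_theta))
            block[:, :20] = ups * dp_dq
            if b_free:
                block[:, 20] = ups * dp_db
            block[:, off_scale + k] = p
            blocks.append(enc.weight * block)
        return np.vstack(blocks)

    theta0 = [np.asarray(q0, dtype=float)]
    if b_free:
        theta0.append([float(b0)])
    theta0.append(np.asarray(scales0, dtype=float))
    theta0 = np.concatenate(theta0)
    theta0 = np.maximum(theta0, floor)

    result = least_squares(
        residuals,
        theta0,
        jac=jacobian,
        bounds=(floor, np.inf),
        method="trf",
        ftol=tol,
        xtol=tol,
        gtol=tol,
        max_nfev=max_iter,
    )
    q, b, scales = unpack(result.x)
    return np.array(q), b, np.array(scales), result


def fit_scale(unscaled: np.ndarray, measured: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Closed-form least-squares scale: sum(m*u) / sum(u^2) over masked-in
    positions.  Minimizes the squared error of scale*unscaled against the
    measurements for a fixed profile shape."""
    u = np.asarray(unscaled, dtype=float)
    m = np.asarray(measured, dtype=float)
    if u.shape != m.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {m.shape}")
    if mask is None:
        mask = np.isfinite(m)
    else:
        mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no masked-in positions")
    u, m = u[mask], m[mask]
    denom = float(np.dot(u, u))
    if denom == 0.0:
        raise ValueError("unscaled profile is all zero on masked-in positions")
    return float(np.dot(m, u) / denom)
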