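"""Forward model: per-residue R2 from sequence.

The predicted rate at residue n is a product over every residue i of the
chain (the self term i = n included),

    R2(n) = upsilon * prod_i f(i; n),      f(i; n) = 1 + (q_i - 1) / (1 + b s^2)

with s = |i - n| the sequence separation.  Each amino acid contributes a
Lorentzian-attenuated factor: q_i at contact, decaying to 1 far away, halfway
decayed at the correlation length Lcorr = b**-0.5.  No distance cutoff is
applied — distant residues contribute factors ~1 and the full product is cheap
at disordered-protein lengths.  Terminal residues have fewer near neighbours,
which produces the characteristic falloff of R2 at the N- and C-termini.

Stable long helices tumble more slowly than the short correlation length
implies, so a multiplicative helix boost 1 + alpha * pHlx is applied inside
predicted helical segments that survive a strict filter (per-residue helix
propensity >= 0.99 over at least 12 consecutive residues).
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .params import AA_INDEX, AMINO_ACIDS, ModelParameters, correlation_length
from .records import HelixSegment, R2Profile, default_mask

__all__ = [
    "contributing_factor",
    "predict_unscaled",
    "predict",
    "correlation_length",
    "find_helix_segments",
    "apply_helix_boost",
    "encode_sequence",
    "distance_weights",
]

#: Default alias table for permissive sequence parsing: chemically modified
#: residues mapped to the standard amino acid they are treated as.
#: Methylated cysteine behaves like alanine for backbone-dynamics purposes.
DEFAULT_ALIASES: dict[str, str] = {"c": "A"}


def encode_sequence(
    sequence: str,
    strict: bool = True,
    aliases: Optional[Mapping[str, str]] = None,
) -> np.ndarray:
    """Map a one-letter sequence to amino-acid indices into AMINO_ACIDS.

    In strict mode any letter outside the 20 standard amino acids raises.
    In permissive mode letters are first looked up in ``aliases`` (default:
    :data:`DEFAULT_ALIASES`).  ``X`` is rejected in both modes: an unknown
    residue has no q value and silently guessing one would corrupt the
    product.
    """
    if aliases is None:
        aliases = DEFAULT_ALIASES
    idx = np.empty(len(sequence), dtype=np.intp)
    for pos, aa in enumerate(sequence):
        if aa in AA_INDEX:
            idx[pos] = AA_INDEX[aa]
            continue
        if aa == "X":
            raise ValueError(
                f"unresolvable residue 'X' at position {pos + 1}: no q value exists"
            )
        if not strict and aa in aliases:
            idx[pos] = AA_INDEX[aliases[aa]]
            continue
        raise ValueError(
            f"nonstandard residue letter {aa!r} at position {pos + 1}"
            + ("" if strict else " (no alias defined)")
        )
    return idx


def contributing_factor(q_i, s, b, kernel: str = "lorentzian"):
    """Factor contributed by a residue of propensity ``q_i`` at sequence
    separation ``s`` to the R2 of the central residue.

    Returns ``1 + (q_i - 1) / (1 + b s^2)`` (Lorentzian, the default) or
    ``1 + (q_i - 1) exp(-b s^2)`` (Gaussian alternative).  Equals ``q_i`` at
    s = 0, tends to 1 as s grows, and at s = Lcorr the Lorentzian factor is
    exactly midway, ``(q_i + 1) / 2``.
    """
    q_i = np.asarray(q_i, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(q_i <= 0):
        raise ValueError("q must be > 0")
    if b <= 0:
        raise ValueError("b must be > 0")
    if np.any(s < 0):
        raise ValueError("sequence distance must be >= 0")
    w = _kernel_weight(b * s**2, kernel)
    out = 1.0 + (q_i - 1.0) * w
    return out if out.ndim else float(out)


def _kernel_weight(bs2: np.ndarray, kernel: str) -> np.ndarray:
    if kernel == "lorentzian":
        return 1.0 / (1.0 + bs2)
    if kernel == "gaussian":
        return np.exp(-bs2)
    raise ValueError(f"unknown kernel {kernel!r}")


def distance_weights(n: int, b: float, kernel: str = "lorentzian") -> np.ndarray:
    """(n, n) matrix W[n, i] of distance attenuations for a chain of length n."""
    pos = np.arange(n)
    d2 = (pos[:, None] - pos[None, :]) ** 2
    return _kernel_weight(b * d2.astype(float), kernel)


def predict_unscaled(
    sequence: str,
    params: ModelParameters,
    kernel: str = "lorentzian",
    strict: bool = True,
    aliases: Optional[Mapping[str, str]] = None,
) -> np.ndarray:
    """Dimensionless per-residue profile: the product of contributing factors
    over all residues of the chain, self term included."""
    idx = encode_sequence(sequence, strict=strict, aliases=aliases)
    return _profile_from_indices(idx, params.q_array, params.b, kernel)


def _profile_from_indices(
    idx: np.ndarray, q: np.ndarray, b: float, kernel: str = "lorentzian"
) -> np.ndarray:
    n = idx.size
    w = distance_weights(n, b, kernel)
    factors = 1.0 + (q[idx][None, :] - 1.0) * w
    return np.exp(np.log(factors).sum(axis=1))


def predict(
    sequence: str,
    params: ModelParameters,
    scale: float,
    kernel: str = "lorentzian",
    strict: bool = True,
    aliases: Optional[Mapping[str, str]] = None,
) -> R2Profile:
    """Scaled prediction in s^-1.  Values are emitted at every position,
    including Pro, but the profile mask flags Pro as excluded from scoring."""
    if not scale > 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    values = scale * predict_unscaled(sequence, params, kernel, strict, aliases)
    return R2Profile(values=values, mask=default_mask(sequence))


def find_helix_segments(
    helix_scores: np.ndarray,
    cutoff: float = 0.99,
    min_length: int = 12,
) -> list[HelixSegment]:
    """Maximal runs of positions with helix propensity >= cutoff and length
    >= min_length, as sorted non-overlapping 1-based inclusive segments.

    The strict default cutoff counters the tendency of secondary-structure
    predictors (trained on folded proteins) to over-call helices in
    disordered sequences; only strongly predicted stretches survive.
    """
    scores = np.asarray(helix_scores, dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("helix scores must lie in [0, 1]")
    above = scores >= cutoff
    segments: list[HelixSegment] = []
    start = None
    for pos, flag in enumerate(above):
        if flag and start is None:
            start = pos
        elif not flag and start is not None:
            if pos - start >= min_length:
                segments.append(HelixSegment(start + 1, pos))
            start = None
    if start is not None and above.size - start >= min_length:
        segments.append(HelixSegment(start + 1, int(above.size)))
    return segments


def apply_helix_boost(
    profile: R2Profile,
    helix_scores: np.ndarray,
    segments: Sequence[HelixSegment],
    alpha: float = 0.5,
) -> R2Profile:
    """Multiply values inside qualifying helical segments by 1 + alpha*pHlx.

    Outside the segments the step function is zero and values are returned
    unchanged.  ``alpha`` is the boost amplitude (default 0.5, i.e. a
    fully-confident helix residue is boosted by 50%).
    """
    if alpha < 0:
        raise ValueError(f"boost amplitude alpha must be >= 0, got {alpha}")
    scores = np.asarray(helix_scores, dtype=float)
    if scores.size != profile.values.size:
        raise ValueError(
            f"helix scores length {scores.size} != profile length {profile.values.size}"
        )
    values = profile.values.copy()
    for seg in segments:
        if seg.start < 1 or seg.end > values.size:
            raise ValueError(
                f"helix segment [{seg.start}, {seg.end}] out of range for length {values.size}"
            )
        sl = slice(seg.start - 1, seg.end)
        values[sl] *= 1.0 + alpha * scores[sl]
    return R2Profile(values=values, mask=profile.mask.copy())
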