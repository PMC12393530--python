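"""Evaluate and apply the distance penalty P(s) = Σᵢ πᵢ βᵢ s^−αᵢ.

Scale anchoring: Hi-C fits carry an arbitrary depth-dependent overall scale,
so by default the penalty is normalized to a maximum of 1 over the fit range
("max_one_on_fit_range").  Penalization then only down-weights and the raw
score's units are preserved.  The raw ("none") mode is kept for profile
reconstruction.

The Cicero-style heuristic β·(1 − s^−α) with α = 0.75 is provided as a
comparator baseline only.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .errors import ValidationError
from .types import PenaltyParams, ScoreTable

ArrayLike = Union[float, np.ndarray]

_SCALE_GRID_SIZE = 2049


def _raw_penalty(params: PenaltyParams, s: np.ndarray) -> np.ndarray:
    total = np.zeros_like(s, dtype=float)
    for c in params.components:
        total += c.pi * c.beta * np.power(s, -c.alpha)
    return total


def penalty_scale(params: PenaltyParams) -> float:
    """Maximum of the un-normalized penalty over the fit range.

    Evaluated on a dense log grid; with all αᵢ ≥ 0 the maximum sits at
    s_min, but the grid also covers mixtures containing negative exponents.
    """
    lo, hi = params.fit_range_bp
    grid = np.geomspace(lo, hi, _SCALE_GRID_SIZE)
    return float(_raw_penalty(params, grid).max())


def evaluate_penalty(params: PenaltyParams, s: ArrayLike) -> ArrayLike:
    """Evaluate P(s) at distance(s) ``s`` (bp); scalar in, scalar out.

    Honors ``params.normalization``: in ``max_one_on_fit_range`` mode the
    value is divided by the maximum of P over the fit range, so P ≤ 1 there.
    """
    arr = np.asarray(s, dtype=float)
    if np.any(~(arr > 0)):
        raise ValidationError("penalty is defined for distances s > 0 only")
    out = _raw_penalty(params, arr)
    if params.normalization == "max_one_on_fit_range":
        out = out / penalty_scale(params)
    return float(out) if np.isscalar(s) or arr.ndim == 0 else out


def apply_penalty(table: ScoreTable, params: PenaltyParams,
                  clamp_below_range: bool = False,
                  positive_only: bool = False) -> ScoreTable:
    """Multiply each raw score by P(s) at the pair's genomic distance.

    The raw column is untouched; ``penalized_score`` is added (replaced if
    present).  Rows whose distance falls outside the fit range are penalized
    by the extrapolated formula and flagged ``extrapolated=True``; with
    ``clamp_below_range`` distances short of s_min use P(s_min) instead
    (distal extrapolation is always by formula).  ``positive_only`` drops
    rows with non-positive raw scores first, mirroring analyses restricted
    to positive co-accessibility values.
    """
    df = table.df.copy()
    if positive_only:
        df = df.loc[df["raw_score"] > 0].reset_index(drop=True)
    s = df["distance_bp"].to_numpy(dtype=float)
    lo, hi = params.fit_range_bp
    s_eval = np.maximum(s, lo) if clamp_below_range else s
    pen = evaluate_penalty(params, s_eval) if len(df) else np.array([])
    df["penalized_score"] = df["raw_score"].to_numpy(dtype=float) * pen
    df["extrapolated"] = (s < lo) | (s > hi)
    return ScoreTable(df, score_kind=table.score_kind)


def cicero_baseline_penalty(s: ArrayLike, alpha: float = 0.75,
                            beta: float = 1.0,
                            cutoff_bp: float = 250_000.0) -> ArrayLike:
    """Cicero's heuristic distance term β·(1 − s^−α), as a comparator.

    Cicero assumes a single universal exponent α = 0.75 and tunes β to
    suppress most interactions beyond a user-defined distance (default
    250 kb).  ``cutoff_bp`` is retained for interface parity with that
    convention; it does not enter the formula itself.  Note this term
    *grows* toward β with distance — in Cicero it acts as a subtractive
    regularization strength, not a multiplicative down-weight.
    """
    del cutoff_bp  # documentation-only parameter, see docstring
    arr = np.asarray(s, dtype=float)
    if np.any(~(arr > 0)):
        raise ValidationError("baseline penalty is defined for distances s > 0 only")
    out = beta * (1.0 - np.power(arr, -alpha))
    return float(out) if np.isscalar(s) or arr.ndim == 0 else out
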