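"""Synthetic data with known ground truth.

Contact distances are drawn i.i.d. from the density ∝ Σᵢ πᵢ βᵢ s^−αᵢ
truncated to a bounded range, by choosing a component proportional to its
truncated mass and then inverting the closed-form CDF of the truncated
single power law (with a dedicated α = 1 log branch).  Exact inversion
beats rejection sampling for heavy tails.

Flat proxy score tables emulate distance-independent co-accessibility /
deep-learning outputs: uniform pair distances and multiplicative log-normal
score noise (keeping scores positive).

Anchors are synthesized as fixed-width 2 kb intervals on one synthetic
chromosome; anchor geometry is irrelevant to the math but keeps the BEDPE
round trip exercised.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .binning import bin_grid
from .errors import SimulationError
from .types import (
    ContactRecord,
    ContactSet,
    GenomicInterval,
    NormalizedProfile,
    PowerLawComponent,
    ScoreTable,
    SimulationConfig,
)

ANCHOR_WIDTH_BP = 2_000
_CHROM = "chrS"
_ORIGIN = 1_000_000


def _truncated_mass(alpha: float, lo: float, hi: float) -> float:
    """∫_lo^hi s^−α ds (the unnormalized truncated component mass)."""
    if alpha == 1.0:
        return math.log(hi / lo)
    p = 1.0 - alpha
    return (hi ** p - lo ** p) / p


def _sample_truncated_powerlaw(rng: np.random.Generator, n: int,
                               alpha: float, lo: float, hi: float) -> np.ndarray:
    """Inverse-CDF draws from density ∝ s^−α on [lo, hi]."""
    u = rng.random(n)
    if alpha == 1.0:
        return lo * (hi / lo) ** u
    p = 1.0 - alpha
    return (lo ** p + u * (hi ** p - lo ** p)) ** (1.0 / p)


def simulate_contacts(config: SimulationConfig) -> ContactSet:
    """Draw a ContactSet from the configured truncated power-law mixture."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.range_bp
    masses = []
    for i, c in enumerate(config.components):
        peak = c.beta * lo ** (-c.alpha) if c.alpha >= 0 else c.beta * hi ** (-c.alpha)
        if not (math.isfinite(peak) and peak > 0):
            raise SimulationError(
                f"component {i} (alpha={c.alpha}, beta={c.beta}) over/underflows "
                f"at the range boundary"
            )
        masses.append(c.pi * c.beta * _truncated_mass(c.alpha, lo, hi))
    masses = np.asarray(masses)
    if not (np.all(np.isfinite(masses)) and masses.sum() > 0):
        raise SimulationError("mixture masses are not finite and positive")
    counts = rng.multinomial(config.n_records, masses / masses.sum())
    draws = [
        _sample_truncated_powerlaw(rng, k, c.alpha, lo, hi)
        for c, k in zip(config.components, counts)
    ]
    d = np.concatenate(draws)
    rng.shuffle(d)
    d = np.maximum(np.rint(d).astype(np.int64), 1)
    starts = _ORIGIN + np.arange(config.n_records, dtype=np.int64) * 10
    records = [
        ContactRecord(
            GenomicInterval(_CHROM, int(s1), int(s1) + ANCHOR_WIDTH_BP),
            GenomicInterval(_CHROM, int(s1 + di), int(s1 + di) + ANCHOR_WIDTH_BP),
            count=1.0,
        )
        for s1, di in zip(starts, d)
    ]
    return ContactSet(records, source_label=f"simulated(seed={config.seed})")


def simulate_flat_scores(config: SimulationConfig) -> ScoreTable:
    """Distance-independent raw proxy scores with log-normal noise.

    Pair distances are uniform over the range; raw_score =
    score_level · exp(N(0, noise_sd²)), independent of distance, so the
    distance–score Spearman correlation is ~0 by construction.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.range_bp
    d = np.maximum(np.rint(rng.uniform(lo, hi, config.n_records)).astype(np.int64), 1)
    scores = config.score_level * np.exp(rng.normal(0.0, config.noise_sd, config.n_records))
    starts = _ORIGIN + np.arange(config.n_records, dtype=np.int64) * 10
    df = pd.DataFrame({
        "chrom1": _CHROM,
        "start1": starts,
        "end1": starts + ANCHOR_WIDTH_BP,
        "chrom2": _CHROM,
        "start2": starts + d,
        "end2": starts + d + ANCHOR_WIDTH_BP,
        "distance_bp": d.astype(float),
        "raw_score": scores,
    })
    return ScoreTable(df, score_kind="coaccessibility")


def make_reference_profile(config: SimulationConfig, n_bins: int = 30,
                           range_bp: Optional[tuple[float, float]] = None,
                           spacing: str = "log") -> NormalizedProfile:
    """Ground-truth decay curve: Σπᵢβᵢs^−αᵢ at bin mids, max scaled to 1.

    Uses the same bin-grid construction as profile standardization so that
    reference and standardized proxy profiles share a grid for equal
    ``range_bp``/``n_bins``.
    """
    rng_bp = range_bp if range_bp is not None else config.range_bp
    _, mids = bin_grid(rng_bp, n_bins, spacing)
    values = np.zeros_like(mids)
    for c in config.components:
        values += c.pi * c.beta * np.power(mids, -c.alpha)
    peak = values.max()
    if not (peak > 0 and math.isfinite(peak)):
        raise SimulationError("reference profile is not finite and positive")
    return NormalizedProfile(mids, values / peak, source_label="reference")


def mixture_from_regimes(alphas: Sequence[float],
                         boundaries_bp: Sequence[float],
                         range_bp: tuple[float, float],
                         pis: Optional[Sequence[float]] = None) -> tuple[PowerLawComponent, ...]:
    """Build mixture components whose adjacent terms cross at given boundaries.

    Scales βᵢ so that πᵢβᵢs^−αᵢ = πᵢ₊₁βᵢ₊₁s^−αᵢ₊₁ at each boundary (the
    regimes hand over exactly there) and so the total density is 1 at s_min.
    """
    n = len(alphas)
    if len(boundaries_bp) != n - 1:
        raise SimulationError(f"{n} regimes need {n - 1} boundaries")
    pis = tuple(pis) if pis is not None else tuple(1.0 / n for _ in alphas)
    betas = [1.0]
    for i, b in enumerate(boundaries_bp):
        ratio = (pis[i] / pis[i + 1]) * b ** (alphas[i + 1] - alphas[i])
        betas.append(betas[i] * ratio)
    lo = range_bp[0]
    total_at_lo = sum(p * be * lo ** (-a) for p, be, a in zip(pis, betas, alphas))
    betas = [be / total_at_lo for be in betas]
    return tuple(
        PowerLawComponent(alpha=float(a), beta=float(be), pi=float(p))
        for a, be, p in zip(alphas, betas, pis)
    )


# ---------------------------------------------------------------------------
# Study-condition presets
# ---------------------------------------------------------------------------

def preset_config(name: str, n_records: int = 100_000, seed: int = 42,
                  noise_sd: float = 0.2, score_level: float = 1.0) -> SimulationConfig:
    """Named ground-truth configurations.

    * ``maize-like``  — single regime, α = 2.34, over 35–500 kb (fluid
      architecture without sharp domain boundaries).
    * ``two-regime``  — steep α = 6.0 handing over to shallow α = 0.5 at
      100 kb over 35 kb–2 Mb; equal weights.  A minimal, well-separated
      loop-to-TAD-scale transition (short steep regime, long shallow
      regime) for recovery checks.
    * ``three-regime`` — α = (6.6, 0.31, 1.5) with transitions at 61 kb and
      1 Mb over 20 kb–2 Mb, echoing the rice/soybean-style regime structure
      (steep packed loops, shallow collapsed-globule TAD scale, then a
      faster distal decay).
    * ``flat-scores`` — distance-independent proxy over 2–500 kb (the
      co-accessibility pair range), log-normal score noise.
    """
    lo_hic, hi_hic = 35_000.0, 500_000.0
    if name == "maize-like":
        comps = mixture_from_regimes([2.34], [], (lo_hic, hi_hic))
        rng = (lo_hic, hi_hic)
    elif name == "two-regime":
        comps = mixture_from_regimes([6.0, 0.5], [100_000.0], (lo_hic, 2_000_000.0))
        rng = (lo_hic, 2_000_000.0)
    elif name == "three-regime":
        comps = mixture_from_regimes([6.6, 0.31, 1.5], [61_000.0, 1_000_000.0],
                                     (20_000.0, 2_000_000.0))
        rng = (20_000.0, 2_000_000.0)
    elif name == "flat-scores":
        comps = mixture_from_regimes([2.34], [], (lo_hic, hi_hic))
        rng = (2_000.0, hi_hic)
    else:
        raise SimulationError(f"unknown preset {name!r}")
    return SimulationConfig(components=comps, range_bp=rng, n_records=n_records,
                            seed=seed, noise_sd=noise_sd, score_level=score_level)
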