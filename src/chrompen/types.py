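"""Core domain containers.

Distances are carried internally in base pairs everywhere; kilobase values
appear only in display formatting.  Genomic intervals follow the BED
convention: 0-based, half-open ``[start, end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import MetricError, ValidationError

#: Columns identifying the two anchors of a pair in a score table.
ANCHOR_COLUMNS = ("chrom1", "start1", "end1", "chrom2", "start2", "end2")

#: Weight-sum tolerance for mixture components.
PI_SUM_TOL = 1e-6


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open (BED convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class ContactRecord:
    """One cis locus pair with its linear separation ``s`` (bp) and a weight.

    ``distance_bp`` defaults to the midpoint-to-midpoint separation of the two
    anchors, which is robust to anchor-width differences.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    distance_bp: Optional[float] = None
    count: float = 1.0

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValidationError(
                "contact records are cis-only: "
                f"{self.anchor1.chrom!r} != {self.anchor2.chrom!r}"
            )
        if self.distance_bp is None:
            object.__setattr__(
                self, "distance_bp", abs(self.anchor2.midpoint - self.anchor1.midpoint)
            )
        if not (self.distance_bp > 0 and math.isfinite(self.distance_bp)):
            raise ValidationError(
                f"contact distance must be finite and > 0, got {self.distance_bp}"
            )
        if not (self.count >= 0 and math.isfinite(self.count)):
            raise ValidationError(f"contact count must be finite and >= 0, got {self.count}")


@dataclass
class ContactSet:
    """An ordered collection of cis contacts (e.g. a parsed loop list)."""

    records: list[ContactRecord]
    source_label: str = ""
    #: inter-chromosomal rows dropped while reading (logged, not stored)
    n_trans_dropped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    @property
    def distances(self) -> np.ndarray:
        return np.array([r.distance_bp for r in self.records], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([r.count for r in self.records], dtype=float)

    @property
    def total_count(self) -> float:
        return float(self.counts.sum()) if self.records else 0.0

    def filtered(self, min_distance_bp: Optional[float] = None,
                 max_distance_bp: Optional[float] = None) -> "ContactSet":
        """Restrict to records with distance in the closed interval [min, max]."""
        lo = -math.inf if min_distance_bp is None else min_distance_bp
        hi = math.inf if max_distance_bp is None else max_distance_bp
        kept = [r for r in self.records if lo <= r.distance_bp <= hi]
        return ContactSet(kept, source_label=self.source_label,
                          n_trans_dropped=self.n_trans_dropped)


@dataclass
class ScoreTable:
    """Pairwise interaction scores (co-accessibility, DL predictions, ...).

    Wraps a DataFrame with at least ``distance_bp`` and ``raw_score`` columns;
    anchor columns and any extra columns are preserved and passed through.
    """

    df: pd.DataFrame
    score_kind: str = "other"

    def __post_init__(self) -> None:
        for col in ("distance_bp", "raw_score"):
            if col not in self.df.columns:
                raise ValidationError(f"score table is missing required column {col!r}")
        d = np.asarray(self.df["distance_bp"], dtype=float)
        if len(d) and not np.all(d > 0):
            bad = int(np.flatnonzero(~(d > 0))[0])
            raise ValidationError(
                f"score table row {bad + 1}: distance_bp must be > 0, got {d[bad]}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def distances(self) -> np.ndarray:
        return np.asarray(self.df["distance_bp"], dtype=float)

    @property
    def raw_scores(self) -> np.ndarray:
        return np.asarray(self.df["raw_score"], dtype=float)

    @property
    def penalized_scores(self) -> Optional[np.ndarray]:
        if "penalized_score" not in self.df.columns:
            return None
        return np.asarray(self.df["penalized_score"], dtype=float)


@dataclass(frozen=True)
class PowerLawComponent:
    """One regime of the decay mixture: value(s) = pi * beta * s**(-alpha).

    ``alpha`` is the decay exponent (α = 3v with Flory exponent v); ``beta``
    the scale on the bp axis; ``pi`` the mixture weight.  ``x_range`` records
    the log10-distance span of the points hard-assigned to the regime.
    """

    alpha: float
    beta: float
    pi: float
    x_range: Optional[tuple[float, float]] = None
    r_squared: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha):
            raise ValidationError(f"alpha must be finite, got {self.alpha}")
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ValidationError(f"beta must be finite and > 0, got {self.beta}")
        if not (0 < self.pi <= 1):
            raise ValidationError(f"pi must lie in (0, 1], got {self.pi}")
        if self.x_range is not None:
            lo, hi = self.x_range
            if lo > hi:
                raise ValidationError(f"x_range must be ordered, got {self.x_range}")
            object.__setattr__(self, "x_range", (float(lo), float(hi)))


def _check_pi_sum(components: Sequence[PowerLawComponent]) -> None:
    total = sum(c.pi for c in components)
    if abs(total - 1.0) > PI_SUM_TOL:
        raise ValidationError(f"component weights must sum to 1, got {total!r}")


@dataclass
class PenaltyParams:
    """The fitted penalty P(s) = sum_i pi_i * beta_i * s**(-alpha_i) plus metadata."""

    species_label: str
    components: tuple[PowerLawComponent, ...]
    fit_range_bp: tuple[float, float]
    normalization: str = "max_one_on_fit_range"
    selection_table: tuple[dict, ...] = ()
    transitions_bp: tuple[float, ...] = ()
    seed: Optional[int] = None
    generated_by: Optional[dict] = None
    distance_units: str = "bp"

    def __post_init__(self) -> None:
        self.components = tuple(self.components)
        if not self.components:
            raise ValidationError("penalty needs at least one component")
        _check_pi_sum(self.components)
        lo, hi = self.fit_range_bp
        if not (0 < lo < hi):
            raise ValidationError(f"fit range must satisfy 0 < s_min < s_max, got {self.fit_range_bp}")
        self.fit_range_bp = (float(lo), float(hi))
        if self.normalization not in ("none", "max_one_on_fit_range"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        if self.distance_units != "bp":
            raise ValidationError("distances are always carried in bp")
        self.selection_table = tuple(dict(r) for r in self.selection_table)
        self.transitions_bp = tuple(float(t) for t in self.transitions_bp)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def alphas(self) -> tuple[float, ...]:
        return tuple(c.alpha for c in self.components)


@dataclass
class DecayProfile:
    """Distance-binned aggregate signal (summed counts or mean scores)."""

    bin_edges_bp: np.ndarray
    bin_mid_bp: np.ndarray
    values: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.bin_edges_bp = np.asarray(self.bin_edges_bp, dtype=float)
        self.bin_mid_bp = np.asarray(self.bin_mid_bp, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.bin_mid_bp) != len(self.values):
            raise ValidationError("profile mids and values must have equal length")
        if len(self.values) == 0:
            if len(self.bin_edges_bp) > 1:
                raise ValidationError("empty profile cannot carry bin edges")
        elif len(self.bin_edges_bp) != len(self.values) + 1:
            raise ValidationError("profile needs len(values) + 1 bin edges")
        if len(self.bin_edges_bp) and np.any(np.diff(self.bin_edges_bp) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if np.any(self.values < 0):
            raise ValidationError("profile values must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def bin_widths_bp(self) -> np.ndarray:
        return np.diff(self.bin_edges_bp)


@dataclass
class LogPointSet:
    """2D points (log10 distance, log10 value) feeding the GMM and regressions."""

    x: np.ndarray
    y: np.ndarray
    bin_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValidationError("log point x and y must have equal shape")
        if len(self.bin_index) == 0:
            self.bin_index = np.arange(len(self.x))
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError("log points must be finite (exclude zero bins first)")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class GmmFit:
    """A fitted 2D Gaussian mixture over log-log points."""

    n_components: int
    means: np.ndarray          # (n, 2)
    covariances: np.ndarray    # (n, 2, 2)
    weights: np.ndarray        # (n,)
    responsibilities: np.ndarray  # (n_points, n)
    bic: float
    aic: float
    seed: int
    converged: bool = True


@dataclass
class NormalizedProfile:
    """A binned profile scaled so its maximum value is exactly 1.0."""

    bin_mid_bp: np.ndarray
    values: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.bin_mid_bp = np.asarray(self.bin_mid_bp, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_mid_bp.shape != self.values.shape:
            raise ValidationError("profile mids and values must have equal shape")
        if np.any(self.values < 0):
            raise ValidationError("normalized profile values must be non-negative")
        if len(self.values) and abs(self.values.max() - 1.0) > 1e-9:
            raise ValidationError("normalized profile must have max value 1.0")

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass
class ComparisonReport:
    """Concordance and error metrics for a proxy-vs-reference profile pair.

    ``spearman_rho`` is ``None`` when either profile has zero variance (the
    rank correlation is undefined there).
    """

    spearman_rho: Optional[float]
    wasserstein_bp: float
    fpr: float
    fnr: float
    f1: float
    n_bins: int
    range_bp: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("fpr", "fnr", "f1"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise MetricError(f"{name} must lie in [0, 1], got {v}")
        if not (self.wasserstein_bp >= 0 and math.isfinite(self.wasserstein_bp)):
            raise MetricError(f"wasserstein must be finite and >= 0, got {self.wasserstein_bp}")

    @property
    def wasserstein_kb(self) -> float:
        return self.wasserstein_bp / 1000.0

    def to_dict(self) -> dict:
        return {
            "spearman_rho": self.spearman_rho,
            "wasserstein_bp": self.wasserstein_bp,
            "wasserstein_kb": self.wasserstein_kb,
            "fpr": self.fpr,
            "fnr": self.fnr,
            "f1": self.f1,
            "n_bins": self.n_bins,
            "range_bp": list(self.range_bp),
        }


@dataclass
class SimulationConfig:
    """Ground-truth mixture and sampling sizes for the synthetic generators."""

    components: tuple[PowerLawComponent, ...]
    range_bp: tuple[float, float]
    n_records: int = 100_000
    seed: int = 42
    noise_sd: float = 0.2       # log-normal sd of multiplicative score noise
    score_level: float = 1.0    # baseline raw score of flat proxies

    def __post_init__(self) -> None:
        self.components = tuple(self.components)
        _check_pi_sum(self.components)
        lo, hi = self.range_bp
        if not (0 < lo < hi):
            raise ValidationError(f"range must satisfy 0 < s_min < s_max, got {self.range_bp}")
        self.range_bp = (float(lo), float(hi))
        if self.n_records <= 0:
            raise ValidationError("n_records must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
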