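"""Multi-regime power-law decay fitting.

The contact probability P(s) of two loci separated by linear distance s
behaves like a power law, P(s) ∝ s^−α with α = 3v (Flory exponent v).
Empirical Hi-C decay curves are only piecewise linear in log-log space, so
the pipeline here

1. bins contact distances,
2. converts bin counts to densities (count per bp) so the log-log slope
   estimates −α regardless of the binning scheme,
3. transforms to (log10 s, log10 density) points,
4. decomposes the 2D point cloud with a Gaussian mixture, choosing the
   number of regimes by a parsimonious BIC rule,
5. fits an ordinary least-squares line per regime (αᵢ = −slope, βᵢ = 10^intercept),
6. by default refines all exponents jointly with a nonlinear fit of the full
   mixture curve log10 Σᵢ 10^cᵢ s^−αᵢ (see :func:`refine_mixture_fit`) — near
   a regime handover the observed curve is the *sum* of adjacent power laws,
   which biases any per-cluster line fit,
7. reports the distances at which the dominant regime changes.

The result is a :class:`~chrompen.types.PenaltyParams` object defining
P(s) = Σᵢ πᵢ βᵢ s^−αᵢ with πᵢ taken from the mixture weights.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

from .binning import bin_grid
from .errors import ChromPenError, FitInfeasibleError, ValidationError
from .types import (
    ContactSet,
    DecayProfile,
    GmmFit,
    LogPointSet,
    PenaltyParams,
    PowerLawComponent,
)

DEFAULT_FIT_RANGE_BP = (35_000.0, 500_000.0)
DEFAULT_N_BINS = 50
DEFAULT_SEED = 42
DEFAULT_N_INIT = 10
DEFAULT_PARSIMONY_DELTA = 10.0

# Covariance floor in log10² units (~0.03-decade noise floor).  Binned log
# counts carry Poisson noise; without the floor, BIC rewards splitting one
# straight regime into sub-noise-tight fragments and over-selects n.
DEFAULT_REG_COVAR = 1e-3

# EM settings: full 2x2 covariances (the regimes are elongated diagonal
# clouds), k-means init.
_GMM_KWARGS = dict(
    covariance_type="full",
    tol=1e-6,
    max_iter=500,
    init_params="kmeans",
)


def bin_contacts(contacts: ContactSet,
                 fit_range_bp: tuple[float, float] = DEFAULT_FIT_RANGE_BP,
                 n_bins: int = DEFAULT_N_BINS,
                 spacing: str = "log") -> DecayProfile:
    """Bin contact counts by genomic distance.

    Bins are half-open ``[edge_b, edge_{b+1})`` except the final bin, which
    also includes its right edge (so total in-range count is conserved).
    Fit feasibility (>= 3 positive bins) is enforced downstream by
    :func:`to_log_points`, keeping this a pure aggregation.
    """
    if len(contacts) == 0:
        raise FitInfeasibleError("contact set is empty")
    edges, mids = bin_grid(fit_range_bp, n_bins, spacing)
    d = contacts.distances
    c = contacts.counts
    in_range = (d >= fit_range_bp[0]) & (d <= fit_range_bp[1])
    if not np.any(in_range):
        raise FitInfeasibleError(
            f"no contacts inside fit range {fit_range_bp!r}"
        )
    values, _ = np.histogram(d[in_range], bins=edges, weights=c[in_range])
    return DecayProfile(edges, mids, values, source_label=contacts.source_label)


def to_density(profile: DecayProfile) -> DecayProfile:
    """Convert binned counts to densities (count per bp of bin width).

    Under log-spaced bins raw counts scale like s^(1-α); dividing by the bin
    width restores the s^−α scaling that the per-regime regression targets.
    """
    return DecayProfile(profile.bin_edges_bp, profile.bin_mid_bp,
                        profile.values / profile.bin_widths_bp,
                        source_label=profile.source_label)


def to_log_points(profile: DecayProfile) -> LogPointSet:
    """Transform positive bins to (log10 distance, log10 value) points.

    Zero-valued bins are skipped (and counted in ``n_skipped``); fewer than
    3 positive bins is infeasible.
    """
    positive = profile.values > 0
    n_pos = int(np.count_nonzero(positive))
    if n_pos < 3:
        raise FitInfeasibleError(f"only {n_pos} positive bins; need >= 3")
    idx = np.flatnonzero(positive)
    return LogPointSet(
        x=np.log10(profile.bin_mid_bp[idx]),
        y=np.log10(profile.values[idx]),
        bin_index=idx,
        n_skipped=profile.n_bins - n_pos,
    )


def fit_gmm(points: LogPointSet, n_components: int,
            seed: int = DEFAULT_SEED, n_init: int = DEFAULT_N_INIT,
            reg_covar: float = DEFAULT_REG_COVAR) -> GmmFit:
    """Fit a full-covariance 2D Gaussian mixture to the log-log points."""
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    if len(points) < 3 * n_components:
        raise FitInfeasibleError(
            f"{len(points)} points cannot support {n_components} components "
            "(need >= 3 per component)"
        )
    X = points.xy
    gm = GaussianMixture(n_components=n_components, n_init=n_init,
                         random_state=seed, reg_covar=reg_covar, **_GMM_KWARGS)
    gm.fit(X)
    if not gm.converged_:
        warnings.warn(
            f"EM did not converge for n={n_components}; keeping best-so-far fit",
            stacklevel=2,
        )
    return GmmFit(
        n_components=n_components,
        means=gm.means_,
        covariances=gm.covariances_,
        weights=gm.weights_,
        responsibilities=gm.predict_proba(X),
        bic=float(gm.bic(X)),
        aic=float(gm.aic(X)),
        seed=seed,
        converged=bool(gm.converged_),
    )


def select_n_components(points: LogPointSet,
                        n_min: int = 1, n_max: int = 5,
                        seed: int = DEFAULT_SEED,
                        parsimony_delta: float = DEFAULT_PARSIMONY_DELTA,
                        n_init: int = DEFAULT_N_INIT,
                        reg_covar: float = DEFAULT_REG_COVAR) -> tuple[int, tuple[dict, ...]]:
    """Choose the number of regimes by a parsimonious BIC plateau rule.

    Every candidate n in ``[n_min, n_max]`` is fitted and scored; the chosen
    n is the *smallest* whose BIC lies within ``parsimony_delta`` of the
    minimum over the scan (near-flat BIC curves resolve to the simpler
    model).  Infeasible candidates are recorded as failed and excluded.
    """
    if n_min < 1 or n_max < n_min:
        raise ValidationError(f"need 1 <= n_min <= n_max, got ({n_min}, {n_max})")
    table: list[dict] = []
    for n in range(n_min, n_max + 1):
        try:
            fit = fit_gmm(points, n, seed=seed, n_init=n_init, reg_covar=reg_covar)
        except ChromPenError as exc:
            table.append({"n": n, "bic": None, "aic": None,
                          "converged": False, "failed": str(exc)})
            continue
        table.append({"n": n, "bic": fit.bic, "aic": fit.aic,
                      "converged": fit.converged})
    feasible = [row for row in table if row["bic"] is not None]
    if not feasible:
        raise FitInfeasibleError("no candidate component count could be fitted")
    bic_min = min(row["bic"] for row in feasible)
    chosen = min(row["n"] for row in feasible
                 if row["bic"] <= bic_min + parsimony_delta)
    return chosen, tuple(table)


def fit_component_powerlaws(points: LogPointSet, gmm: GmmFit) -> list[PowerLawComponent]:
    """Per-regime OLS in log-log space.

    Each point is hard-assigned to its maximum-responsibility component
    (ties resolve toward the lower-distance component); a line y = a + b·x
    is fitted per component, giving αᵢ = −b and βᵢ = 10^a.  πᵢ comes from
    the mixture weights.  Components with fewer than 2 assigned points are
    dropped with a warning and the remaining weights renormalized.
    Components are returned sorted by ascending distance.
    """
    order = np.argsort(gmm.means[:, 0], kind="stable")
    resp = gmm.responsibilities[:, order]
    weights = gmm.weights[order]
    labels = np.argmax(resp, axis=1)  # argmax takes the first (= lower-x) on ties
    fitted: list[tuple[float, PowerLawComponent]] = []
    kept_weight = 0.0
    for k in range(gmm.n_components):
        mask = labels == k
        if int(mask.sum()) < 2:
            warnings.warn(
                f"component {k} has {int(mask.sum())} assigned points; dropped",
                stacklevel=2,
            )
            continue
        x, y = points.x[mask], points.y[mask]
        slope, intercept = np.polyfit(x, y, 1)
        residual = y - (intercept + slope * x)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(residual ** 2)) / ss_tot
        fitted.append((weights[k], PowerLawComponent(
            alpha=float(-slope),
            beta=float(10.0 ** intercept),
            pi=float(weights[k]),  # placeholder, renormalized below
            x_range=(float(x.min()), float(x.max())),
            r_squared=r2,
        )))
        kept_weight += float(weights[k])
    if not fitted:
        raise FitInfeasibleError("every mixture component had < 2 assigned points")
    components = [
        PowerLawComponent(alpha=c.alpha, beta=c.beta, pi=float(w / kept_weight),
                          x_range=c.x_range, r_squared=c.r_squared)
        for w, c in fitted
    ]
    components.sort(key=lambda c: c.x_range)
    return components


def refine_mixture_fit(points: LogPointSet,
                       components: Sequence[PowerLawComponent]
                       ) -> tuple[list[PowerLawComponent], list[float]]:
    """Jointly refine all regimes against the full mixture curve.

    Per-cluster line fits are biased near regime handovers, where the
    observed curve is the *sum* of adjacent power laws.  This stage fits

        y(x) ≈ log10 Σᵢ 10^(cᵢ − αᵢ·x),   cᵢ = log10(πᵢ βᵢ)

    over *all* points by least squares, initialized at the per-cluster
    estimates.  Mixture weights πᵢ stay frozen at the GMM values (only the
    products 10^cᵢ are identifiable from the curve), so βᵢ = 10^cᵢ/πᵢ.
    Transition points are re-derived as the exact crossovers of adjacent
    refined terms, 10^((cᵢ−cⱼ)/(αᵢ−αⱼ)).

    Returns ``(refined components, crossover transitions in bp)``.  Falls
    back to the inputs (with assignment-gap transitions) when the problem
    is under-determined or the solver fails.
    """
    comps = sorted(components, key=lambda c: c.x_range)
    n = len(comps)
    if len(points) < 2 * n + 1:
        return list(comps), transition_points(comps) if n > 1 else []
    ln10 = np.log(10.0)
    x, y = points.x, points.y

    def model(a, c):
        return logsumexp(ln10 * (c[:, None] - a[:, None] * x), axis=0) / ln10

    def residuals(p):
        return model(p[:n], p[n:]) - y

    a0 = np.array([c.alpha for c in comps])
    c0 = np.array([np.log10(c.pi * c.beta) for c in comps])
    sol = least_squares(residuals, np.concatenate([a0, c0]),
                        method="lm", xtol=1e-12, ftol=1e-12, max_nfev=10_000)
    if not sol.success or not np.all(np.isfinite(sol.x)):
        warnings.warn("mixture refinement failed; keeping per-cluster estimates",
                      stacklevel=2)
        return list(comps), transition_points(comps) if n > 1 else []
    a_ref, c_ref = sol.x[:n], sol.x[n:]
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(sol.fun ** 2)) / ss_tot
    refined = [
        PowerLawComponent(alpha=float(a), beta=float(10.0 ** c / comp.pi),
                          pi=comp.pi, x_range=comp.x_range, r_squared=r2)
        for a, c, comp in zip(a_ref, c_ref, comps)
    ]
    transitions: list[float] = []
    for i in range(n - 1):
        da = a_ref[i] - a_ref[i + 1]
        if abs(da) < 1e-9:   # parallel terms never cross; use the gap midpoint
            transitions.append(transition_points(refined[i:i + 2])[0])
        else:
            transitions.append(float(10.0 ** ((c_ref[i] - c_ref[i + 1]) / da)))
    return refined, transitions


def transition_points(components: Sequence[PowerLawComponent]) -> list[float]:
    """Distances (bp) at which the dominant regime changes.

    For each adjacent pair of components (ascending distance) the boundary
    is the geometric mean of the gap between their assigned log-distance
    ranges, 10^((x_hi_lower + x_lo_upper)/2).  Overlapping ranges yield the
    midpoint of the overlap and a warning.
    """
    comps = sorted(components, key=lambda c: c.x_range)
    boundaries: list[float] = []
    for lower, upper in zip(comps[:-1], comps[1:]):
        x_hi = lower.x_range[1]
        x_lo = upper.x_range[0]
        if x_lo < x_hi:
            warnings.warn(
                f"overlapping regimes: [{lower.x_range}] vs [{upper.x_range}]",
                stacklevel=2,
            )
        boundaries.append(float(10.0 ** (0.5 * (x_hi + x_lo))))
    return boundaries


def fit_decay_model(contacts: ContactSet,
                    fit_range_bp: tuple[float, float] = DEFAULT_FIT_RANGE_BP,
                    n_bins: int = DEFAULT_N_BINS,
                    n_range: tuple[int, int] = (1, 5),
                    seed: int = DEFAULT_SEED,
                    parsimony_delta: float = DEFAULT_PARSIMONY_DELTA,
                    spacing: str = "log",
                    n_init: int = DEFAULT_N_INIT,
                    reg_covar: float = DEFAULT_REG_COVAR,
                    density: bool = True,
                    refine: Optional[str] = "mixture",
                    species_label: Optional[str] = None,
                    normalization: str = "max_one_on_fit_range") -> PenaltyParams:
    """Full pipeline: bin → density → log points → select n → GMM → per-regime
    OLS → joint mixture refinement.

    ``density=True`` (default) regresses on count densities so the fitted
    slope is −α for any bin spacing; with ``density=False`` raw bin values
    are used as-is (appropriate for pre-normalized profiles).
    ``refine="mixture"`` (default) runs :func:`refine_mixture_fit` as the
    final stage; ``refine=None`` keeps the pure per-cluster OLS estimates.
    Deterministic for fixed inputs and seed.
    """
    if refine not in (None, "mixture"):
        raise ValidationError(f"refine must be None or 'mixture', got {refine!r}")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ChromPenError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    profile = stage("bin_contacts", bin_contacts, contacts, fit_range_bp, n_bins, spacing)
    if density:
        profile = to_density(profile)
    points = stage("to_log_points", to_log_points, profile)
    n, selection = stage("select_n_components", select_n_components, points,
                         n_range[0], n_range[1], seed, parsimony_delta, n_init,
                         reg_covar)
    gmm = stage("fit_gmm", fit_gmm, points, n, seed, n_init, reg_covar)
    components = stage("fit_component_powerlaws", fit_component_powerlaws, points, gmm)
    if refine == "mixture":
        components, transitions = stage("refine_mixture_fit", refine_mixture_fit,
                                        points, components)
    else:
        transitions = transition_points(components) if len(components) > 1 else []
    return PenaltyParams(
        species_label=species_label or contacts.source_label or "unknown",
        components=tuple(components),
        fit_range_bp=(float(fit_range_bp[0]), float(fit_range_bp[1])),
        normalization=normalization,
        selection_table=selection,
        transitions_bp=tuple(transitions),
        seed=seed,
    )
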