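"""Free-energy surfaces reconstructed from sampled vertical energy gaps.

Under linear response, the Boltzmann distribution of a vertical energy gap
``dE`` sampled along an equilibrium trajectory is Gaussian,
``P(dE) ∝ exp(-((dE-mu)/sigma)^2 / 2)``, which implies a quadratic
free-energy surface in the gap coordinate::

    V(dE) = (kT/2) * ((dE - mu) / sigma)^2

Three constructions give the surfaces of the donor/acceptor pair:

* **sampled** — Gaussian fit of the gap histogram on the trajectory of the
  state itself (available for GS and CS, which have forcefields);
* **companion** — the partner state on the same axis follows for free,
  ``V_ES(dE) = V_CS(dE) + dE`` when the axis is ``dE = E_ES - E_CS``;
* **crossfit** — the excited-state surface is anchored to ground-state
  sampling: on the GS trajectory the gap ``y = E_ES - E_CS`` is linear in
  ``x = E_CS - E_GS``, so ``V_ES(x) = V_CS(x) + a x + b`` with (a, b) from
  ordinary least squares.

From an (ES, CS) surface pair the Marcus parameters follow:
``dA = V_CS(min CS) - V_ES(min ES)`` (positive when the CS minimum lies above
the ES minimum, i.e. uphill charge separation) and
``lambda = V_CS(at ES min) - V_CS(at CS min)``.  Statistical uncertainty in
the fitted (mu, sigma, a, b) is propagated to any derived quantity as the
min/max envelope over the Cartesian product of confidence-interval endpoints.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .constants import thermal_energy

__all__ = [
    "Axis",
    "GapDistributionFit",
    "QuadraticFES",
    "LinearGapRelation",
    "SurfacePairSummary",
    "CrossfitResult",
    "fit_gap_distribution",
    "build_sampled_fes",
    "companion_surface",
    "fit_gap_relation",
    "crossfit_es_surface",
    "summarize_surface_pair",
    "propagate_uncertainty",
]


class Axis:
    """Tags naming which vertical gap a surface is a function of."""

    ES_MINUS_CS = "ES_minus_CS"
    CS_MINUS_GS = "CS_minus_GS"
    ES_MINUS_GS = "ES_minus_GS"


@dataclass(frozen=True)
class GapDistributionFit:
    """Normal fit of a vertical-gap sample with confidence intervals.

    ``mu`` is the sample mean and ``sigma`` the sample SD (ddof=1, the
    normal-fit scale); ``mu_ci`` is the exact t interval and ``sigma_ci`` the
    exact chi-square interval at the stated confidence level.
    """

    mu: float
    sigma: float
    n: int
    mu_ci: tuple[float, float]
    sigma_ci: tuple[float, float]
    confidence: float = 0.95
    axis: str = Axis.ES_MINUS_CS
    trajectory: str = "CS"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (self.mu_ci[0] <= self.mu <= self.mu_ci[1]):
            raise ValueError("mu_ci must bracket mu")
        if not (self.sigma_ci[0] <= self.sigma <= self.sigma_ci[1]):
            raise ValueError("sigma_ci must bracket sigma")


@dataclass(frozen=True)
class QuadraticFES:
    """One-dimensional parabolic surface V(x) = c2 (x-x0)^2 + c1 (x-x0) + c0.

    ``x0`` (``x_ref``) is the reference point of the canonical form; for a
    *sampled* surface it is the distribution mean and c1 = c0 = 0, so the
    minimum sits at ``x_ref`` with V = 0.  Energies in eV, ``x`` in eV (a
    vertical gap is an energy), curvature c2 in eV^-1.
    """

    c2: float
    c1: float
    c0: float
    x_ref: float
    axis: str
    provenance: str = "sampled"
    sampled_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.c2 <= 0:
            raise ValueError("curvature c2 must be positive")
        if self.provenance == "sampled" and (self.c1 != 0 or self.c0 != 0):
            raise ValueError("a sampled surface has c1 = c0 = 0")

    def __call__(self, x):
        d = np.asarray(x, dtype=float) - self.x_ref
        out = self.c2 * d * d + self.c1 * d + self.c0
        return float(out) if np.isscalar(x) else out

    @property
    def argmin(self) -> float:
        """Location of the minimum."""
        return self.x_ref - self.c1 / (2.0 * self.c2)

    @property
    def min_value(self) -> float:
        """Value at the minimum."""
        return self.c0 - self.c1 * self.c1 / (4.0 * self.c2)

    def shifted(self, **changes) -> "QuadraticFES":
        return replace(self, **changes)

    def poly_coefficients(self) -> tuple[float, float, float]:
        """Coefficients (A, B, C) of V(x) = A x^2 + B x + C in the raw axis."""
        a = self.c2
        b = self.c1 - 2.0 * self.c2 * self.x_ref
        c = (
            self.c2 * self.x_ref**2
            - self.c1 * self.x_ref
            + self.c0
        )
        return a, b, c

    def minimum_outside_sampled_range(self) -> bool | None:
        """Extrapolation flag: does the reported minimum lie outside the
        sampled gap range?  None when no range was recorded."""
        if self.sampled_range is None:
            return None
        lo, hi = self.sampled_range
        return not (lo <= self.argmin <= hi)


@dataclass(frozen=True)
class LinearGapRelation:
    """OLS fit y = a*x + b between two vertical gaps, with parameter CIs."""

    slope_a: float
    intercept_b: float
    residual_sd: float
    r_value: float
    a_ci: tuple[float, float]
    b_ci: tuple[float, float]
    n: int
    confidence: float = 0.95

    def __post_init__(self) -> None:
        for name in ("slope_a", "intercept_b", "residual_sd", "r_value"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (self.a_ci[0] <= self.slope_a <= self.a_ci[1]):
            raise ValueError("a_ci must bracket slope_a")
        if not (self.b_ci[0] <= self.intercept_b <= self.b_ci[1]):
            raise ValueError("b_ci must bracket intercept_b")


@dataclass(frozen=True)
class SurfacePairSummary:
    """Marcus parameters extracted from an (ES, CS) surface pair.

    ``delta_a`` > 0 means the CS minimum lies above the ES minimum (uphill
    charge separation).  ``crossing_energy_above_es_min`` is the height of
    the surface crossing over the ES minimum, or None when the surfaces do
    not cross on the real line.  The reverse (CS->ES) process is in the
    Marcus inverted region iff -delta_a > lambda.
    """

    delta_a: float
    lambda_reorg: float
    crossing_energy_above_es_min: float | None
    marcus_region: str
    delta_a_bounds: tuple[float, float] | None = None
    lambda_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.delta_a_bounds is not None and not (
            self.delta_a_bounds[0] - 1e-12
            <= self.delta_a
            <= self.delta_a_bounds[1] + 1e-12
        ):
            raise ValueError("delta_a_bounds must bracket delta_a")
        if self.lambda_bounds is not None and not (
            self.lambda_bounds[0] - 1e-12
            <= self.lambda_reorg
            <= self.lambda_bounds[1] + 1e-12
        ):
            raise ValueError("lambda_bounds must bracket lambda_reorg")


def fit_gap_distribution(
    samples: Sequence[float],
    confidence: float = 0.95,
    axis: str = Axis.ES_MINUS_CS,
    trajectory: str = "CS",
) -> GapDistributionFit:
    """Fit a vertical-gap sample to a normal distribution with exact CIs.

    mu is the sample mean with a t-distribution CI; sigma is the ddof=1
    sample SD with a chi-square CI.  Requires n >= 3 finite values and a
    non-degenerate sample.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError(f"need at least 3 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    n = x.size
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=1))
    if sigma == 0.0:
        raise ValueError("zero-variance sample: cannot fit a gap distribution")
    alpha = 1.0 - confidence
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 1)
    half = tcrit * sigma / math.sqrt(n)
    chi_lo = stats.chi2.ppf(alpha / 2.0, df=n - 1)
    chi_hi = stats.chi2.ppf(1.0 - alpha / 2.0, df=n - 1)
    sigma_ci = (
        sigma * math.sqrt((n - 1) / chi_hi),
        sigma * math.sqrt((n - 1) / chi_lo),
    )
    return GapDistributionFit(
        mu=mu,
        sigma=sigma,
        n=n,
        mu_ci=(mu - half, mu + half),
        sigma_ci=sigma_ci,
        confidence=confidence,
        axis=axis,
        trajectory=trajectory,
    )


def build_sampled_fes(
    fit: GapDistributionFit,
    temperature: float = 300.0,
    sampled_range: tuple[float, float] | None = None,
) -> QuadraticFES:
    """Quadratic surface V(x) = (kT/2)((x-mu)/sigma)^2 implied by a Gaussian gap fit.

    The minimum sits at the distribution mean with V = 0; the curvature is
    kT/sigma^2 (second derivative), i.e. c2 = kT/(2 sigma^2).
    """
    kt = thermal_energy(temperature)
    return QuadraticFES(
        c2=kt / (2.0 * fit.sigma**2),
        c1=0.0,
        c0=0.0,
        x_ref=fit.mu,
        axis=fit.axis,
        provenance="sampled",
        sampled_range=sampled_range,
    )


def companion_surface(fes: QuadraticFES) -> QuadraticFES:
    """Partner-state surface on the same gap axis: V_ES(x) = V_CS(x) + x.

    Valid only on the ES-CS axis, where adding the gap to the CS surface
    yields the ES surface identically.  For a sampled CS surface
    (mu, sigma) the companion minimum sits at mu - sigma^2/kT, giving the
    closed forms lambda = sigma^2/(2kT) and dA = sigma^2/(2kT) - mu.
    """
    if fes.axis != Axis.ES_MINUS_CS:
        raise ValueError(
            "companion construction requires the ES_minus_CS axis, "
            f"got {fes.axis}"
        )
    # V(x) + x = c2 (x-x0)^2 + (c1+1)(x-x0) + c0 + x0
    return QuadraticFES(
        c2=fes.c2,
        c1=fes.c1 + 1.0,
        c0=fes.c0 + fes.x_ref,
        x_ref=fes.x_ref,
        axis=fes.axis,
        provenance="companion",
        sampled_range=fes.sampled_range,
    )


def fit_gap_relation(
    x_samples: Sequence[float],
    y_samples: Sequence[float],
    confidence: float = 0.95,
) -> LinearGapRelation:
    """Ordinary least squares y = a*x + b between two gap samples, with CIs."""
    x = np.asarray(x_samples, dtype=float)
    y = np.asarray(y_samples, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.std(x) == 0.0:
        raise ValueError("degenerate x sample (zero variance)")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    res = stats.linregress(x, y)
    n = x.size
    resid = y - (res.slope * x + res.intercept)
    residual_sd = (
        float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    )
    tcrit = stats.t.ppf(1.0 - (1.0 - confidence) / 2.0, df=n - 2)
    a_half = tcrit * res.stderr
    b_half = tcrit * res.intercept_stderr
    return LinearGapRelation(
        slope_a=float(res.slope),
        intercept_b=float(res.intercept),
        residual_sd=residual_sd,
        r_value=float(res.rvalue),
        a_ci=(res.slope - a_half, res.slope + a_half),
        b_ci=(res.intercept - b_half, res.intercept + b_half),
        n=n,
        confidence=confidence,
    )


@dataclass(frozen=True)
class CrossfitResult:
    """Excited-state surface anchored to ground-state sampling.

    ``surface`` lives on the CS-GS axis (V_ES(x) = V_CS(x) + a x + b); when
    the linear map dE = a x + b is invertible (a != 0) ``surface_es_axis``
    is the same parabola re-expressed as a function of dE = E_ES - E_CS,
    otherwise it is None and ``reexpressed`` is False.
    """

    surface: QuadraticFES
    surface_es_axis: QuadraticFES | None
    reexpressed: bool


def crossfit_es_surface(
    cs_fes_on_gs_axis: QuadraticFES,
    relation: LinearGapRelation,
) -> CrossfitResult:
    """ES surface from the linear gap relation: V_ES(x) = V_CS(x) + a x + b.

    ``cs_fes_on_gs_axis`` must be the CS surface as a function of
    x = E_CS - E_GS.  The returned primary surface shares its axis; when the
    relation slope is nonzero the surface is also re-expressed on the
    dE = E_ES - E_CS axis via the substitution x = (dE - b)/a.

    Closed forms for a sampled CS surface (mu_x, sigma_x): ES minimum at
    mu_x - a sigma_x^2/kT, lambda = a^2 sigma_x^2/(2kT) and
    dA = a^2 sigma_x^2/(2kT) - a mu_x - b.
    """
    fes = cs_fes_on_gs_axis
    if fes.axis != Axis.CS_MINUS_GS:
        raise ValueError(
            f"crossfit requires the CS_minus_GS axis, got {fes.axis}"
        )
    a, b = relation.slope_a, relation.intercept_b
    # V(x) + a x + b about x0: add a(x-x0) + a x0 + b
    es_gs_axis = QuadraticFES(
        c2=fes.c2,
        c1=fes.c1 + a,
        c0=fes.c0 + a * fes.x_ref + b,
        x_ref=fes.x_ref,
        axis=fes.axis,
        provenance="crossfit",
        sampled_range=fes.sampled_range,
    )
    if a == 0.0:
        return CrossfitResult(surface=es_gs_axis, surface_es_axis=None,
                              reexpressed=False)
    # substitute x = (u - b)/a with u = a x + b: x - x0 = (u - u0)/a
    u0 = a * es_gs_axis.x_ref + b
    srange = None
    if es_gs_axis.sampled_range is not None:
        lo, hi = (a * v + b for v in es_gs_axis.sampled_range)
        srange = (min(lo, hi), max(lo, hi))
    es_es_axis = QuadraticFES(
        c2=es_gs_axis.c2 / a**2,
        c1=es_gs_axis.c1 / a,
        c0=es_gs_axis.c0,
        x_ref=u0,
        axis=Axis.ES_MINUS_CS,
        provenance="crossfit",
        sampled_range=srange,
    )
    return CrossfitResult(surface=es_gs_axis, surface_es_axis=es_es_axis,
                          reexpressed=True)


def _crossing_points(es: QuadraticFES, cs: QuadraticFES) -> np.ndarray:
    """Real roots of V_ES(x) - V_CS(x) = 0, ascending; may be empty."""
    a1, b1, c1 = es.poly_coefficients()
    a2, b2, c2 = cs.poly_coefficients()
    da, db, dc = a1 - a2, b1 - b2, c1 - c2
    if abs(da) < 1e-300:
        if db == 0.0:
            return np.array([])  # identical or parallel-offset surfaces
        return np.array([-dc / db])
    disc = db * db - 4.0 * da * dc
    if disc < 0.0:
        return np.array([])
    sq = math.sqrt(disc)
    return np.sort(np.array([(-db - sq) / (2 * da), (-db + sq) / (2 * da)]))


def summarize_surface_pair(
    es: QuadraticFES, cs: QuadraticFES
) -> SurfacePairSummary:
    """Extract dA, lambda, the crossing height and the Marcus region.

    Both surfaces must share a gap axis.  The crossing reported is the real
    root of V_ES - V_CS between the two minima when one exists (the
    thermally relevant crossing), else the root with the lower energy; its
    height is measured above the ES minimum.  Identical surfaces cross
    everywhere and report a height of 0.
    """
    if es.axis != cs.axis:
        raise ValueError(
            f"surfaces on different axes: {es.axis} vs {cs.axis}"
        )
    delta_a = cs.min_value - es.min_value
    lam = cs(es.argmin) - cs.min_value
    roots = _crossing_points(es, cs)
    es_a, es_b, es_c = es.poly_coefficients()
    cs_a, cs_b, cs_c = cs.poly_coefficients()
    identical = (
        math.isclose(es_a, cs_a, rel_tol=0, abs_tol=1e-14)
        and math.isclose(es_b, cs_b, rel_tol=0, abs_tol=1e-14)
        and math.isclose(es_c, cs_c, rel_tol=0, abs_tol=1e-14)
    )
    if identical:
        crossing = 0.0
    elif roots.size == 0:
        crossing = None
    else:
        lo, hi = sorted((es.argmin, cs.argmin))
        between = roots[(roots >= lo - 1e-12) & (roots <= hi + 1e-12)]
        if between.size:
            root = between[np.argmin(es(between))]
        else:
            root = roots[np.argmin(es(roots))]
        crossing = float(es(root) - es.min_value)
    region = "inverted" if -delta_a > lam else "normal"
    return SurfacePairSummary(
        delta_a=delta_a,
        lambda_reorg=lam,
        crossing_energy_above_es_min=crossing,
        marcus_region=region,
    )


def propagate_uncertainty(
    params: Mapping[str, tuple[float, tuple[float, float]]],
    evaluator: Callable[..., float],
) -> tuple[float, float, list[dict]]:
    """Min/max envelope of a derived quantity over CI-endpoint corners.

    ``params`` maps parameter names to (point_estimate, (lower, upper)).
    The evaluator is called with keyword arguments at every point of the
    Cartesian product of {lower, point, upper} per parameter.  Corners where
    the evaluator raises are recorded (name -> values plus the error) and
    excluded from the envelope rather than silently dropped.

    Returns (lower, upper, failed_corners).
    """
    names = list(params)
    grids = []
    for name in names:
        point, (lo, hi) = params[name]
        if not (lo <= point <= hi):
            raise ValueError(f"CI for {name} must bracket its point estimate")
        grids.append(sorted({lo, point, hi}))
    values: list[float] = []
    failures: list[dict] = []
    for corner in itertools.product(*grids):
        kwargs = dict(zip(names, corner))
        try:
            values.append(float(evaluator(**kwargs)))
        except Exception as exc:  # noqa: BLE001 - flagged, not dropped
            failures.append({**kwargs, "error": repr(exc)})
    if not values:
        raise ValueError("evaluator failed at every corner")
    return min(values), max(values), failures
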