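"""Reaction-diffusion analysis of FCS autocorrelation curves.

Chromatin binding of a fluorescent protein is modelled as exchange
between a freely diffusing state (diffusion coefficient ``Df``) and an
immobile chromatin-bound state, with pseudo-first-order association rate
``k*on`` and dissociation rate ``koff``.  The module provides:

* the closed-form pure-diffusion autocorrelation for a 3-D Gaussian
  observation volume,
* the full reaction-diffusion autocorrelation, evaluated by quadrature
  over the Gaussian-filtered relaxation spectrum of the linearized
  two-state system,
* outlier screening and averaging of replicate curves,
* weighted nonlinear least-squares fits with multi-start initialization,
* derived quantities: bound fraction ``k*on/(k*on+koff)`` and residence
  time ``1/koff``,
* observation-volume calibration from a fluorescein dilution series
  (fixed Df = 425 um^2/s; V = n/(NA*c)),
* one-way ANOVA with Dunnett's many-to-one post-test across lines.

Derivation sketch for the full model: concentration fluctuations of the
free (F) and bound (C) species relax, per spatial mode q, under
``M(q) = [[-Df q^2 - k*on, koff], [k*on, -koff]]``.  Both species are
equally fluorescent and initial cross-correlations vanish for ideal
solutions, so ``G(tau)`` is proportional to the observation-volume
filtered sum ``sum_ij [exp(M q tau)]_ij f_j`` with equilibrium fractions
``f = (koff, k*on)/(k*on+koff)``.  The Gaussian filter separates into a
lateral part (Gauss-Laguerre quadrature) and an axial part
(Gauss-Hermite quadrature); normalizing by the same quadrature at
``tau = 0`` makes ``G(0) = 1/n`` exact by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.constants import Avogadro

__all__ = [
    "AcfCurve",
    "ObservationVolume",
    "KineticFit",
    "CalibrationSeries",
    "acf_pure_diffusion",
    "acf_full_model",
    "screen_outliers",
    "average_curves",
    "fit_kinetics",
    "derive_binding",
    "calibrate_volume",
    "compare_groups",
    "FLUORESCEIN_DF",
]

FLUORESCEIN_DF = 425.0  # um^2/s, fixed during volume calibration


@dataclass
class AcfCurve:
    """One autocorrelation curve: log-spaced lags (s) and G values."""

    lags: np.ndarray
    g: np.ndarray
    se: np.ndarray | None = None
    nucleus_id: str = ""
    curve_id: str = ""

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.ndim != 1 or self.lags.shape != self.g.shape:
            raise ValueError("lags and g must be 1-D arrays of equal length")
        if (self.lags <= 0).any() or (np.diff(self.lags) <= 0).any():
            raise ValueError("lags must be positive and strictly increasing")
        if not np.isfinite(self.g).all():
            raise ValueError("non-finite correlation values")

    @property
    def n_points(self) -> int:
        return self.lags.size


@dataclass(frozen=True)
class ObservationVolume:
    """3-D Gaussian observation volume.

    ``beam_waist_w`` is the lateral 1/e^2 radius in um and
    ``structural_parameter_s`` the axial-to-lateral aspect ratio; the
    effective volume is ``pi^{3/2} w^3 s``.
    """

    beam_waist_w: float
    structural_parameter_s: float = 5.0

    def __post_init__(self) -> None:
        if self.beam_waist_w <= 0:
            raise ValueError("beam waist must be positive")
        if self.structural_parameter_s < 1:
            raise ValueError("structural parameter must be >= 1")

    @property
    def volume_um3(self) -> float:
        return float(np.pi**1.5 * self.beam_waist_w**3 * self.structural_parameter_s)

    @property
    def volume_litres(self) -> float:
        return self.volume_um3 * 1e-15  # 1 um^3 = 1e-15 L

    @classmethod
    def from_volume(cls, volume_litres: float, structural_parameter_s: float = 5.0):
        w = (volume_litres / 1e-15 / (np.pi**1.5 * structural_parameter_s)) ** (1.0 / 3.0)
        return cls(beam_waist_w=w, structural_parameter_s=structural_parameter_s)


@dataclass
class KineticFit:
    """Fitted kinetic parameters of one averaged curve."""

    model: str  # "pure_diffusion" | "full_model"
    n: float
    Df: float
    kstar_on: float = 0.0
    koff: float = np.inf
    fit_rss: float = np.nan
    se: dict = field(default_factory=dict)
    nucleus_id: str = ""

    @property
    def bound_fraction(self) -> float:
        return derive_binding(self.kstar_on, self.koff)[0]

    @property
    def residence_time(self) -> float:
        return derive_binding(self.kstar_on, self.koff)[1]


@dataclass
class CalibrationSeries:
    """Fluorescein dilution-series calibration of the observation volume."""

    points: list  # (concentration mol/L, fitted n)
    fixed_Df: float
    fitted_volume_litres: float
    structural_parameter_s: float = 5.0

    @property
    def beam_waist_w(self) -> float:
        return ObservationVolume.from_volume(
            self.fitted_volume_litres, self.structural_parameter_s
        ).beam_waist_w


# ---------------------------------------------------------------------------
# Model evaluation


def acf_pure_diffusion(
    lags: np.ndarray, n: float, Df: float, volume: ObservationVolume
) -> np.ndarray:
    """Closed-form 3-D diffusion ACF: (1/n) (1+t/tD)^-1 (1+t/(s^2 tD))^-1/2."""
    if n <= 0 or Df <= 0:
        raise ValueError("n and Df must be positive")
    tau = np.asarray(lags, dtype=float)
    tau_d = volume.beam_waist_w**2 / (4.0 * Df)
    s2 = volume.structural_parameter_s**2
    return (1.0 / n) / ((1.0 + tau / tau_d) * np.sqrt(1.0 + tau / (s2 * tau_d)))


def _quad_nodes(volume: ObservationVolume, n_panels: int = 48, n_points: int = 5):
    """Spectral quadrature grid for the Gaussian observation-volume filter.

    The 3-D mode integral with the anisotropic Gaussian filter reduces
    to one dimension: integrating the direction cosine analytically
    gives, up to a constant that cancels in the normalization,

        I = int_0^inf dq q^2 exp(-q^2 w^2/4) * E(q) * F(q^2),
        E(q) = sqrt(pi) erf(q sqrt(b)) / (2 q sqrt(b)),  b = (wz^2 - w^2)/4,

    with ``E -> 1`` for an isotropic volume.  The radial integral is
    evaluated on a composite Gauss-Legendre grid uniform in log q, which
    resolves relaxation exponentials of any stiffness.  Returns
    (q^2 nodes, weights).
    """
    w = volume.beam_waist_w
    wz = w * volume.structural_parameter_s
    q_min = 2e-4 / w
    q_max = 13.0 / w
    x, gw = np.polynomial.legendre.leggauss(n_points)
    edges = np.linspace(np.log(q_min), np.log(q_max), n_panels + 1)
    mid = (edges[1:] + edges[:-1]) / 2.0
    half = (edges[1:] - edges[:-1]) / 2.0
    v = (mid[:, None] + half[:, None] * x[None, :]).ravel()
    wt = (half[:, None] * gw[None, :]).ravel()
    q = np.exp(v)
    b = (wz**2 - w**2) / 4.0
    if b > 0:
        arg = q * np.sqrt(b)
        from scipy.special import erf

        aniso = np.where(arg < 1e-6, 1.0 - arg**2 / 3.0, np.sqrt(np.pi) * erf(arg) / (2.0 * arg))
    else:
        aniso = np.ones_like(q)
    # q^3: q^2 from the volume element, one q from dq = q dlogq
    weight = wt * q**3 * np.exp(-(q**2) * w**2 / 4.0) * aniso
    return q**2, weight


def acf_full_model(
    lags: np.ndarray,
    n: float,
    Df: float,
    kstar_on: float,
    koff: float,
    volume: ObservationVolume,
    n_quad: tuple[int, int] = (64, 5),
) -> np.ndarray:
    """Reaction-diffusion ACF for free diffusion exchanging with an
    immobile bound state inside a 3-D Gaussian volume.

    Limits: ``kstar_on -> 0`` recovers the pure-diffusion form; in the
    fast-exchange regime the curve is pure diffusion with
    ``D_eff = Df/(1 + kstar_on/koff)``; in the reaction-dominant regime
    (``koff << 1/tau_D``) it is the diffusing fraction's shape plus a
    bound-fraction exponential ``exp(-koff tau)``.
    """
    if kstar_on < 0 or koff < 0:
        raise ValueError("rates must be non-negative")
    if kstar_on == 0 or (kstar_on + koff) == 0:
        return acf_pure_diffusion(lags, n, Df, volume)
    tau = np.atleast_1d(np.asarray(lags, dtype=float))
    q2, wt = _quad_nodes(volume, *n_quad)
    a = Df * q2  # per-mode diffusive rate
    ktot = kstar_on + koff
    f_free = koff / ktot
    f_bound = kstar_on / ktot
    # 2x2 relaxation matrix M = [[-(a+kon), koff], [kon, -koff]]
    s_half = -(a + ktot) / 2.0
    disc = np.sqrt(np.maximum(s_half**2 - a * koff, 0.0))
    # column sums of exp(M tau): free column and bound column
    m11 = -(a + kstar_on)
    m22 = -koff
    tau_q = tau[:, None]
    ep = np.exp((s_half + disc) * tau_q)  # exponents <= 0: no overflow
    em = np.exp((s_half - disc) * tau_q)
    cosh_t = 0.5 * (ep + em)
    small = disc * np.abs(tau_q) < 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        sinh_over_d = np.where(small, tau_q * np.exp(s_half * tau_q), 0.5 * (ep - em) / disc)
    col_free = cosh_t + sinh_over_d * (m11 - s_half + kstar_on)
    col_bound = cosh_t + sinh_over_d * (koff + m22 - s_half)
    phi = f_free * col_free + f_bound * col_bound
    num = phi @ wt
    norm = wt.sum()  # phi(tau=0) = 1 exactly
    out = num / norm / n
    return out if np.ndim(lags) else float(out[0])


# ---------------------------------------------------------------------------
# Curve screening and averaging


def screen_outliers(
    curves: list[AcfCurve], mad_multiplier: float = 3.0
) -> tuple[list[AcfCurve], list[bool]]:
    """Discard replicate curves far from the pointwise median curve.

    A curve's distance is the median absolute difference from the
    pointwise median curve; curves whose distance exceeds the cohort
    median distance plus ``mad_multiplier`` times the MAD of the
    distances are discarded.  At least one curve is always retained;
    with only two mutually distant curves both are kept with a warning.
    Returns (kept curves, per-curve keep flags).
    """
    if not curves:
        raise ValueError("no curves supplied")
    if len(curves) == 1:
        return list(curves), [True]
    g = np.stack([c.g for c in curves])
    med = np.median(g, axis=0)
    dist = np.median(np.abs(g - med), axis=1)
    if len(curves) == 2:
        if not np.allclose(g[0], g[1], rtol=1e-3, atol=1e-12):
            warnings.warn("only two curves and no majority: keeping both")
        return list(curves), [True, True]
    m = np.median(dist)
    mad = np.median(np.abs(dist - m))
    keep = dist <= m + mad_multiplier * mad
    if not keep.any():
        keep[np.argmin(dist)] = True
    return [c for c, k in zip(curves, keep) if k], keep.tolist()


def average_curves(curves: list[AcfCurve]) -> AcfCurve:
    """Pointwise mean of replicate curves sharing one lag grid."""
    if not curves:
        raise ValueError("no curves supplied")
    lags = curves[0].lags
    for c in curves[1:]:
        if not np.array_equal(c.lags, lags):
            raise ValueError("curves must share a common lag grid")
    g = np.stack([c.g for c in curves])
    se = g.std(axis=0, ddof=1) / np.sqrt(len(curves)) if len(curves) > 1 else None
    return AcfCurve(lags=lags, g=g.mean(axis=0), se=se, nucleus_id=curves[0].nucleus_id)


# ---------------------------------------------------------------------------
# Fitting


def _model_g(theta_log: np.ndarray, lags: np.ndarray, model: str, volume: ObservationVolume):
    p = np.exp(theta_log)
    if model == "pure_diffusion":
        return acf_pure_diffusion(lags, p[0], p[1], volume)
    return acf_full_model(lags, p[0], p[1], p[2], p[3], volume)


def fit_kinetics(
    curve: AcfCurve,
    model: str,
    volume: ObservationVolume,
    weights: np.ndarray | None = None,
    min_lag: float = 1e-5,
    fixed_Df: float | None = None,
    n_best_starts: int = 2,
) -> KineticFit:
    """Weighted nonlinear least-squares fit of one averaged curve.

    Parameters are fitted in log space (positivity by construction) with
    a grid of starting points; the ``n_best_starts`` starts with lowest
    initial RSS are refined and the best refined fit returned.  Lags
    below ``min_lag`` (default 10 us, the afterpulsing region) are
    excluded.  Standard errors come from the Jacobian at the optimum,
    mapped back to the linear scale.
    """
    if model not in ("pure_diffusion", "full_model"):
        raise ValueError(f"unknown model {model!r}")
    sel = curve.lags >= min_lag
    lags, g = curve.lags[sel], curve.g[sel]
    if lags.size < 4 or lags[-1] / lags[0] < 100:
        raise ValueError("curve must cover at least two decades of lag")
    if weights is None:
        if curve.se is not None and np.all(np.asarray(curve.se)[sel] > 0):
            weights = 1.0 / np.asarray(curve.se)[sel]
        else:
            weights = np.ones_like(g)
    else:
        weights = np.asarray(weights, dtype=float)[sel]

    n0 = max(1.0 / max(g[0], 1e-12), 1e-6)
    tau_mid = float(lags[np.argmin(np.abs(g - g[0] / 2.0))])  # half-amplitude lag
    df_grid = [1.0, 5.0, 20.0, 80.0] if fixed_Df is None else [fixed_Df]
    starts: list[np.ndarray] = []
    if model == "pure_diffusion":
        for df in df_grid:
            starts.append(np.log([n0, df]))
        # tau_D-based guess from the half-amplitude lag
        df_half = volume.beam_waist_w**2 / (4.0 * max(tau_mid, 1e-9))
        starts.append(np.log([n0, max(df_half, 1e-3)]))
    else:
        rate_grid = [(0.1, 0.1), (1.0, 0.3), (2.0, 2.0), (5.0, 1.0), (0.5, 5.0)]
        for df in df_grid:
            for kon, koff in rate_grid:
                starts.append(np.log([n0, df, kon, koff]))

    def resid(theta: np.ndarray) -> np.ndarray:
        if fixed_Df is not None:
            theta = np.insert(theta, 1, np.log(fixed_Df))
        return weights * (_model_g(theta, lags, model, volume) - g)

    def strip(theta: np.ndarray) -> np.ndarray:
        return np.delete(theta, 1) if fixed_Df is not None else theta

    rss0 = [float(np.sum(resid(strip(t)) ** 2)) for t in starts]
    order = np.argsort(rss0)[:n_best_starts]
    best = None
    for i in order:
        try:
            sol = optimize.least_squares(
                resid, strip(starts[i]), xtol=1e-12, ftol=1e-12, gtol=1e-12
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.isfinite(best.cost):
        raise RuntimeError(f"{model} fit failed to converge from all starts")

    theta = best.x if fixed_Df is None else np.insert(best.x, 1, np.log(fixed_Df))
    p = np.exp(theta)
    names = ["n", "Df"] if model == "pure_diffusion" else ["n", "Df", "kstar_on", "koff"]
    # delta-method SEs: cov(log p) ~ (J^T J)^-1 * 2 cost / dof
    se: dict[str, float] = {}
    dof = max(lags.size - best.x.size, 1)
    try:
        jtj = best.jac.T @ best.jac
        cov_log = np.linalg.pinv(jtj) * (2.0 * best.cost / dof)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
        free_names = [nm for nm in names if not (fixed_Df is not None and nm == "Df")]
        se = {nm: float(s * np.exp(th)) for nm, s, th in zip(free_names, se_log, best.x)}
    except np.linalg.LinAlgError:
        pass
    fit = KineticFit(
        model=model,
        n=float(p[0]),
        Df=float(p[1]),
        kstar_on=float(p[2]) if model == "full_model" else 0.0,
        koff=float(p[3]) if model == "full_model" else np.inf,
        fit_rss=float(2.0 * best.cost),
        se=se,
        nucleus_id=curve.nucleus_id,
    )
    return fit


def derive_binding(kstar_on: float, koff: float) -> tuple[float, float]:
    """Bound fraction k*on/(k*on+koff) and residence time 1/koff.

    ``koff = 0`` yields an infinite residence time (permanent binding).
    """
    if kstar_on < 0 or koff < 0:
        raise ValueError("rates must be non-negative")
    total = kstar_on + koff
    bf = kstar_on / total if total > 0 else 0.0
    rt = 1.0 / koff if koff > 0 else np.inf
    return bf, rt


# ---------------------------------------------------------------------------
# Volume calibration


def calibrate_volume(
    series: list[tuple[float, AcfCurve]],
    structural_parameter_s: float = 5.0,
    fixed_Df: float = FLUORESCEIN_DF,
    volume_guess_litres: float = 1e-16,
) -> CalibrationSeries:
    """Observation-volume calibration from a fluorescein dilution series.

    Each curve is fitted with the pure-diffusion model at the fixed
    literature diffusion coefficient of fluorescein; ordinary least
    squares of fitted molecule number ``n`` on the known molar
    concentration, through the origin, gives ``V = slope / NA`` litres.
    """
    if len(series) < 1:
        raise ValueError("empty calibration series")
    points = []
    for conc, curve in series:
        if conc <= 0:
            raise ValueError("concentrations must be positive")
        vol0 = ObservationVolume.from_volume(volume_guess_litres, structural_parameter_s)
        fit = fit_kinetics(curve, "pure_diffusion", vol0, fixed_Df=None)
        # With Df free the fitted tau_D re-expresses the true waist in units
        # of the guess volume's waist; re-anchor via the fixed Df instead:
        # refit n with the waist implied by tau_D = w^2/(4 Df_fixed).
        tau_d = vol0.beam_waist_w**2 / (4.0 * fit.Df)
        w = float(np.sqrt(4.0 * fixed_Df * tau_d))
        vol = ObservationVolume(w, structural_parameter_s)
        fit = fit_kinetics(curve, "pure_diffusion", vol, fixed_Df=fixed_Df)
        points.append((conc, fit.n))
    c = np.array([p[0] for p in points])
    n = np.array([p[1] for p in points])
    slope = float(np.sum(n * c) / np.sum(c * c))  # OLS through the origin
    if slope <= 0:
        raise ValueError("non-positive calibration slope")
    return CalibrationSeries(
        points=points,
        fixed_Df=fixed_Df,
        fitted_volume_litres=slope / Avogadro,
        structural_parameter_s=structural_parameter_s,
    )


# ---------------------------------------------------------------------------
# Group comparison


def compare_groups(
    groups: dict[str, np.ndarray], reference: str, alpha: float = 0.05
) -> dict:
    """One-way ANOVA plus Dunnett's many-to-one post-test.

    Compares every line against the reference line on the supplied
    per-nucleus parameter values (residence time or bound fraction).
    Stars follow the figure-legend thresholds: * p < 0.01, *** p < 0.001.
    """
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} missing")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than two observations")
    if all(np.ptp(v) == 0 for v in arrays.values()):
        return {"anova_p": np.nan, "comparisons": {}, "degenerate": True}
    ref = arrays[reference]
    others = [k for k in arrays if k != reference]
    _, anova_p = stats.f_oneway(*arrays.values())
    res = stats.dunnett(*(arrays[k] for k in others), control=ref)
    comparisons = {}
    for k, p in zip(others, np.atleast_1d(res.pvalue)):
        stars = "***" if p < 0.001 else ("*" if p < 0.01 else "")
        comparisons[k] = {"p_adjusted": float(p), "significant": bool(p < alpha), "stars": stars}
    return {"anova_p": float(anova_p), "comparisons": comparisons, "degenerate": False}
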