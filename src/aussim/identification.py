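"""Inverse identification of Ogden parameters from uniaxial tensile curves.

The tissue parameters of the model (shear-like modulus ``mu`` per layer and
a stiffening exponent ``alpha`` shared by both layers) are identified from
near-equilibrium nominal stress--stretch curves by nonlinear least squares.
A synthetic-curve generator stands in for the experimental median curves:
it evaluates the closed-form uniaxial Ogden response on a uniform stretch
grid and optionally applies multiplicative Gaussian noise with a given
coefficient of variation.

The fit exploits the structure of the model: for a fixed ``alpha`` the
nominal stress is linear in ``mu``, so the optimal ``mu`` has a closed form
(variable projection).  The search therefore reduces to one dimension in
``alpha``, run from multiple starts to avoid the mu/alpha trade-off valley,
followed by a bounded two-parameter least-squares polish.  Misfit is
measured on nominal stress, the quantity a tensile test reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize

from .constitutive import NeoHookeanMaterial, OgdenMaterial, uniaxial_nominal_stress

__all__ = [
    "StressStretchCurve",
    "FitResult",
    "generate_curve",
    "fit_ogden",
    "fit_ogden_shared",
]

DEFAULT_BOUNDS = ((0.1, 100.0), (1.0, 12.0))


@dataclass
class StressStretchCurve:
    """Uniaxial nominal stress--stretch data.

    ``stretch`` must be strictly increasing and positive; ``nominal_stress``
    is the first Piola stress in kPa.
    """

    stretch: np.ndarray
    nominal_stress: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.stretch = np.asarray(self.stretch, dtype=float)
        self.nominal_stress = np.asarray(self.nominal_stress, dtype=float)
        if self.stretch.ndim != 1 or self.stretch.shape != self.nominal_stress.shape:
            raise ValueError("stretch and nominal_stress must be 1-D of equal length")
        if self.stretch.size < 2:
            raise ValueError("a curve needs at least two points")
        if np.any(self.stretch <= 0.0):
            raise ValueError("stretches must be positive")
        if np.any(np.diff(self.stretch) <= 0.0):
            raise ValueError("stretches must be strictly increasing")
        if not (np.all(np.isfinite(self.stretch)) and np.all(np.isfinite(self.nominal_stress))):
            raise ValueError("curve values must be finite")

    def save(self, path) -> None:
        """Write the curve as two-column delimited text."""

        header = "stretch,nominal_stress_kPa"
        data = np.column_stack([self.stretch, self.nominal_stress])
        np.savetxt(path, data, delimiter=",", header=header, comments="")

    @classmethod
    def load(cls, path, label: str | None = None) -> "StressStretchCurve":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError(f"expected two columns in {path}")
        return cls(data[:, 0], data[:, 1], label=label or Path(str(path)).stem)


@dataclass
class FitResult:
    """Outcome of an Ogden fit: parameters, RMS misfit (kPa) and status."""

    mu: float
    alpha: float
    residual: float
    converged: bool
    n_iter: int = 0

    def material(self, name: str = "") -> OgdenMaterial:
        return OgdenMaterial(self.mu, self.alpha, name=name)


def generate_curve(
    material,
    lam_max: float,
    n_points: int = 50,
    noise_cv: float = 0.0,
    seed: int | None = None,
    label: str = "",
) -> StressStretchCurve:
    """Synthetic uniaxial nominal-stress curve on a uniform grid [1, lam_max].

    With ``noise_cv > 0`` each stress value is multiplied by an independent
    Gaussian factor N(1, noise_cv); a fixed ``seed`` makes the draw
    reproducible.  ``noise_cv = 0`` returns the exact closed-form response.
    """

    if not lam_max > 1.0:
        raise ValueError("lam_max must exceed 1")
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    if noise_cv < 0.0:
        raise ValueError("noise_cv must be non-negative")
    lam = np.linspace(1.0, lam_max, n_points)
    P = uniaxial_nominal_stress(material, lam)
    if noise_cv > 0.0:
        rng = np.random.default_rng(seed)
        P = P * rng.normal(1.0, noise_cv, size=P.shape)
    return StressStretchCurve(lam, P, label=label)


def _model(lam: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    return (2.0 * mu / alpha) * (lam ** (alpha - 1.0) - lam ** (-alpha / 2.0 - 1.0))


def _projected_mu(lam, P, alpha, mu_bounds):
    """Least-squares optimal mu for fixed alpha, clipped to bounds."""

    g = _model(lam, 1.0, alpha)
    denom = float(g @ g)
    if denom <= 0.0:
        return mu_bounds[0]
    mu = float(g @ P) / denom
    return float(np.clip(mu, *mu_bounds))


def _check_curve(curve: StressStretchCurve) -> None:
    if np.unique(curve.stretch).size < 2:
        raise ValueError("underdetermined fit: fewer than two distinct stretches")


def fit_ogden(
    curve: StressStretchCurve,
    initial: OgdenMaterial | None = None,
    bounds=DEFAULT_BOUNDS,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Identify (mu, alpha) from a nominal stress--stretch curve.

    Multi-start search: ``n_starts`` alpha values drawn log-uniformly within
    bounds plus the supplied initial guess, each solved by variable
    projection in mu and a bounded 1-D minimisation in alpha; the candidate
    with the lowest residual is polished by bounded 2-D least squares.
    The result is independent of the ordering of the curve points.
    """

    _check_curve(curve)
    (mu_lo, mu_hi), (a_lo, a_hi) = bounds
    lam = curve.stretch
    P = curve.nominal_stress

    def rss(alpha: float) -> float:
        mu = _projected_mu(lam, P, alpha, (mu_lo, mu_hi))
        r = _model(lam, mu, alpha) - P
        return float(r @ r)

    rng = np.random.default_rng(seed)
    starts = list(np.exp(rng.uniform(np.log(a_lo), np.log(a_hi), size=n_starts)))
    if initial is not None:
        if not (mu_lo <= initial.mu <= mu_hi and a_lo <= initial.alpha <= a_hi):
            raise ValueError("initial guess outside bounds")
        starts.append(float(initial.alpha))

    best_alpha, best_val = None, np.inf
    n_iter = 0
    for a0 in starts:
        lo = max(a_lo, a0 / 2.0)
        hi = min(a_hi, a0 * 2.0)
        res = optimize.minimize_scalar(rss, bounds=(lo, hi), method="bounded")
        n_iter += int(res.nfev)
        for a_cand in (float(res.x), a0):
            v = rss(a_cand)
            if v < best_val:
                best_alpha, best_val = a_cand, v
    # widen once around the best candidate over the full alpha range
    res = optimize.minimize_scalar(rss, bounds=(a_lo, a_hi), method="bounded")
    n_iter += int(res.nfev)
    if res.fun < best_val:
        best_alpha, best_val = float(res.x), float(res.fun)

    mu0 = _projected_mu(lam, P, best_alpha, (mu_lo, mu_hi))

    def resid(x):
        return _model(lam, x[0], x[1]) - P

    polish = optimize.least_squares(
        resid,
        x0=[mu0, best_alpha],
        bounds=([mu_lo, a_lo], [mu_hi, a_hi]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    n_iter += int(polish.nfev)
    mu_hat, alpha_hat = (float(v) for v in polish.x)
    rms = float(np.sqrt(np.mean(polish.fun**2)))
    converged = bool(polish.success) and np.isfinite(rms)
    return FitResult(mu=mu_hat, alpha=alpha_hat, residual=rms, converged=converged, n_iter=n_iter)


def fit_ogden_shared(
    curves: list[StressStretchCurve],
    bounds=DEFAULT_BOUNDS,
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[list[float], float, float]:
    """Joint fit of several curves with a shared alpha exponent.

    Returns (mu per curve, alpha, total RMS residual).  Mirrors the
    shared-exponent reading of a two-layer identification in which both
    tissue layers exhibit the same stiffening exponent.
    """

    if not curves:
        raise ValueError("need at least one curve")
    for c in curves:
        _check_curve(c)
    (mu_lo, mu_hi), (a_lo, a_hi) = bounds

    def rss(alpha: float) -> float:
        total = 0.0
        for c in curves:
            mu = _projected_mu(c.stretch, c.nominal_stress, alpha, (mu_lo, mu_hi))
            r = _model(c.stretch, mu, alpha) - c.nominal_stress
            total += float(r @ r)
        return total

    rng = np.random.default_rng(seed)
    starts = np.exp(rng.uniform(np.log(a_lo), np.log(a_hi), size=n_starts))
    best_alpha, best_val = a_lo, np.inf
    for a0 in starts:
        res = optimize.minimize_scalar(
            rss, bounds=(max(a_lo, a0 / 2), min(a_hi, a0 * 2)), method="bounded"
        )
        if res.fun < best_val:
            best_alpha, best_val = float(res.x), float(res.fun)
    res = optimize.minimize_scalar(rss, bounds=(a_lo, a_hi), method="bounded")
    if res.fun < best_val:
        best_alpha, best_val = float(res.x), float(res.fun)

    mus = [
        _projected_mu(c.stretch, c.nominal_stress, best_alpha, (mu_lo, mu_hi)) for c in curves
    ]
    n_total = sum(c.stretch.size for c in curves)
    return mus, best_alpha, float(np.sqrt(best_val / n_total))
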