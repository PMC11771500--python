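"""Stimulation metrics: principal strain/stress measures and box-plot summaries.

The device-comparison metrics follow the mechanobiological reading of the
fields: hydrostatic pressure (positive in compression) as a
vasoconstriction-relevant stimulus, and the extreme principal logarithmic
strains and Cauchy stresses split into compressive and tensile measures:

* compressive strain  = |min principal log strain| * 100  (percent)
* tensile strain      = max(0, max principal log strain) * 100
* compressive stress  = |min(0, min principal Cauchy stress)|  (kPa)
* tensile stress      = max(0, max principal Cauchy stress)

Summaries are area-weighted five-number statistics (median, quartiles,
1.5 IQR whiskers clipped to the data range) over a region of interest,
weighted by the reference area attached to each integration point; the
quantile rule reduces to the common linear-interpolation ("type 7") rule
for equal weights.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .geometry import Mesh
from .solver import SolutionState

__all__ = [
    "FieldSummary",
    "StimulationReport",
    "hydrostatic_pressure",
    "principal_measures",
    "weighted_quantile",
    "summarise",
    "lumen_closure",
    "stimulation_report",
]


@dataclass
class FieldSummary:
    """Five-number summary with box-plot whiskers (units of the field)."""

    median: float
    q1: float
    q3: float
    min: float
    max: float
    whisker_low: float
    whisker_high: float

    def __post_init__(self) -> None:
        seq = (self.min, self.whisker_low, self.q1, self.median,
               self.q3, self.whisker_high, self.max)
        if any(b < a - 1e-9 * (1 + abs(a)) for a, b in zip(seq, seq[1:])):
            raise ValueError(f"inconsistent summary ordering: {seq}")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class StimulationReport:
    """Per-scenario tissue stimulation summary over a region of interest."""

    compressive_strain: FieldSummary   # percent
    compressive_stress: FieldSummary   # kPa
    hydrostatic_pressure: FieldSummary  # kPa
    tensile_strain: FieldSummary       # percent
    tensile_stress: FieldSummary       # kPa
    lumen_closure_fraction: float
    region: str = "all"

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.lumen_closure_fraction <= 1.0 + 1e-9):
            raise ValueError("closure fraction outside [0, 1]")

    def as_dict(self) -> dict:
        out = {"region": self.region,
               "lumen_closure_fraction": self.lumen_closure_fraction}
        for name in ("compressive_strain", "compressive_stress",
                     "hydrostatic_pressure", "tensile_strain", "tensile_stress"):
            out[name] = getattr(self, name).as_dict()
        return out


def hydrostatic_pressure(stress) -> np.ndarray | float:
    """Hydrostatic pressure p = -tr(sigma)/3, positive in compression (kPa).

    ``stress`` is a symmetric 3x3 tensor or an (..., 3, 3) stack.
    """

    s = np.asarray(stress, dtype=float)
    if s.shape[-2:] != (3, 3):
        raise ValueError("stress must be (..., 3, 3)")
    if not np.all(np.isfinite(s)):
        raise ValueError("stress has non-finite entries")
    if not np.allclose(s, np.swapaxes(s, -1, -2), atol=1e-8 * (1 + np.abs(s).max())):
        raise ValueError("stress tensor must be symmetric")
    p = -np.trace(s, axis1=-2, axis2=-1) / 3.0
    return float(p) if p.ndim == 0 else p


def _state_tensors(state: SolutionState):
    """Per-point 3x3 stress and in-plane stretch data from a solution state."""

    s = state.stress  # (m, 4, 4): s11, s22, s12, s33
    m, g = s.shape[:2]
    sig = np.zeros((m, g, 3, 3))
    sig[..., 0, 0] = s[..., 0]
    sig[..., 1, 1] = s[..., 1]
    sig[..., 0, 1] = sig[..., 1, 0] = s[..., 2]
    sig[..., 2, 2] = s[..., 3]
    return sig


def principal_measures(state: SolutionState) -> dict:
    """Per-integration-point stimulation measures of a converged state.

    Returns arrays of shape (n_elem, n_gp) for keys ``compressive_strain``,
    ``tensile_strain`` (percent), ``compressive_stress``, ``tensile_stress``
    and ``hydrostatic_pressure`` (kPa).
    """

    F = state.F  # (m, g, 2, 2)
    b11 = F[..., 0, 0] ** 2 + F[..., 0, 1] ** 2
    b22 = F[..., 1, 0] ** 2 + F[..., 1, 1] ** 2
    b12 = F[..., 0, 0] * F[..., 1, 0] + F[..., 0, 1] * F[..., 1, 1]
    tr2 = 0.5 * (b11 + b22)
    disc = np.sqrt(np.maximum(0.25 * (b11 - b22) ** 2 + b12**2, 0.0))
    lam1 = np.sqrt(np.maximum(tr2 + disc, 1e-18))
    lam2 = np.sqrt(np.maximum(tr2 - disc, 1e-18))
    eps = np.stack([np.log(lam1), np.log(lam2), np.zeros_like(lam1)], axis=-1)
    eps_min = eps.min(axis=-1)
    eps_max = eps.max(axis=-1)

    sig = _state_tensors(state)
    w = np.linalg.eigvalsh(sig)  # ascending principal stresses
    s_min = w[..., 0]
    s_max = w[..., -1]

    return {
        "compressive_strain": np.abs(eps_min) * 100.0,
        "tensile_strain": np.maximum(0.0, eps_max) * 100.0,
        "compressive_stress": np.abs(np.minimum(0.0, s_min)),
        "tensile_stress": np.maximum(0.0, s_max),
        "hydrostatic_pressure": hydrostatic_pressure(sig),
    }


def weighted_quantile(values, q, weights=None) -> np.ndarray:
    """Weighted quantile with linear interpolation between closest ranks.

    For equal weights this reduces to the standard "type 7" rule
    (numpy's default): positions p_i = cumw_{i-1} / (W - w_n) on the
    sorted sample.  Weights are normalisation-invariant.
    """

    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty sample")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if weights is None:
        out = np.quantile(values, q)
        return out if out.size > 1 else float(out[0])
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.shape != values.shape:
        raise ValueError("weights must match values")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cw = np.concatenate([[0.0], np.cumsum(w)])
    denom = cw[-1] - w[-1]
    if denom <= 0:  # single effective point
        out = np.full_like(q, v[-1])
        return out if out.size > 1 else float(out[0])
    p = cw[:-1] / denom
    out = np.interp(q, p, v)
    return out if out.size > 1 else float(out[0])


def summarise(values, weights=None) -> FieldSummary:
    """Area-weighted five-number summary with 1.5 IQR whiskers."""

    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot summarise an empty region")
    q1, med, q3 = np.atleast_1d(weighted_quantile(values, [0.25, 0.5, 0.75], weights))
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    vmin = float(values.min())
    vmax = float(values.max())
    inside_lo = values[values >= lo_fence]
    inside_hi = values[values <= hi_fence]
    wl = float(inside_lo.min()) if inside_lo.size else vmin
    wh = float(inside_hi.max()) if inside_hi.size else vmax
    return FieldSummary(median=float(med), q1=float(q1), q3=float(q3),
                        min=vmin, max=vmax, whisker_low=wl, whisker_high=wh)


def plot_report(reports: dict, path) -> None:
    """Box-plot figure of stimulation summaries, one group per scenario.

    ``reports`` maps scenario labels to :class:`StimulationReport`.
    Requires matplotlib (optional dependency).
    """

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = [("compressive_strain", "compressive strain (%)"),
               ("compressive_stress", "compressive stress (kPa)"),
               ("hydrostatic_pressure", "hydrostatic pressure (kPa)"),
               ("tensile_stress", "tensile stress (kPa)")]
    fig, axes = plt.subplots(1, len(metrics), figsize=(3.2 * len(metrics), 3.4))
    for ax, (key, label) in zip(axes, metrics):
        stats = []
        for name, rep in reports.items():
            s = getattr(rep, key)
            stats.append({"label": name, "med": s.median, "q1": s.q1, "q3": s.q3,
                          "whislo": s.whisker_low, "whishi": s.whisker_high,
                          "fliers": []})
        ax.bxp(stats, showfliers=False)
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def lumen_closure(state: SolutionState, mesh: Mesh) -> float:
    """Fraction of the initial lumen area closed at a state, in [0, 1]."""

    if "lumen_boundary" not in mesh.loops:
        raise ValueError("mesh has no lumen boundary")
    a0 = mesh.lumen_polygon_area()
    a = mesh.lumen_polygon_area(state.u)
    return float(np.clip(1.0 - a / a0, 0.0, 1.0))


def stimulation_report(state: SolutionState, mesh: Mesh,
                       region: str = "all") -> StimulationReport:
    """Assemble the five stimulation summaries for a region of the section.

    ``region`` selects elements by label ('lining', 'spongiosum') or 'all'.
    Quantiles are weighted by the reference area of each integration point.
    """

    measures = principal_measures(state)
    if region == "all":
        mask = np.ones(mesh.n_elems, dtype=bool)
    else:
        mask = mesh.regions == region
        if not mask.any():
            raise ValueError(f"empty region {region!r}")
    w = state.gp_weight[mask].ravel()
    summaries = {k: summarise(v[mask].ravel(), w) for k, v in measures.items()}
    return StimulationReport(
        compressive_strain=summaries["compressive_strain"],
        compressive_stress=summaries["compressive_stress"],
        hydrostatic_pressure=summaries["hydrostatic_pressure"],
        tensile_strain=summaries["tensile_strain"],
        tensile_stress=summaries["tensile_stress"],
        lumen_closure_fraction=lumen_closure(state, mesh),
        region=region,
    )
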