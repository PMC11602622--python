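"""Hill-model dose-response fitting and curve normalization.

The response to a ligand dose d (μg on filter paper) is modelled by the
four-parameter logistic ("variable slope" Hill equation) on log dose:

    y(d) = bottom + (top − bottom) / (1 + (EC50 / d)^h)

with EC50 the half-maximal dose, h the Hill coefficient (curve steepness),
and bottom/top the asymptotes.  Solvent (0 μg) replicates enter the loss as
direct observations of the bottom asymptote rather than at a fake position
on the log-dose axis.  Fitting is bounded least squares with a
deterministic multi-start over the EC50 initialization; standard errors
come from the Jacobian at the optimum.

Two usage modes: a pooled fit over all replicates, or per-animal fits
(one EC50/Hill per animal) whose spread supports between-receptor
rank-based comparisons.  Per-animal is the default for group comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseSeries",
    "DoseResponseFit",
    "FlatCurveError",
    "fit_hill",
    "fit_hill_per_animal",
    "normalize_dose_curve",
    "cross_ligand_normalization",
]


class FlatCurveError(ValueError):
    """The responses carry no dose dependence; EC50 is unidentifiable."""


@dataclass
class DoseSeries:
    """Replicate response amplitudes per dose for one receptor × ligand.

    ``data`` is long-format with columns (animal, dose, amplitude); dose 0
    denotes the solvent control.  At least 4 distinct nonzero doses are
    required for a 4-parameter fit.
    """

    data: pd.DataFrame
    ligand: str = ""
    receptor: str = ""

    def __post_init__(self) -> None:
        missing = {"dose", "amplitude"} - set(self.data.columns)
        if missing:
            raise ValueError(f"dose series missing columns {sorted(missing)}")
        if "animal" not in self.data.columns:
            self.data = self.data.assign(animal="pooled")
        if (self.data["dose"] < 0).any():
            raise ValueError("doses must be >= 0")
        self.data = self.data.sort_values("dose", kind="stable").reset_index(drop=True)

    @property
    def nonzero_doses(self) -> np.ndarray:
        d = np.unique(self.data.loc[self.data["dose"] > 0, "dose"].to_numpy(dtype=float))
        return d

    def dose_means(self) -> pd.Series:
        return self.data.groupby("dose")["amplitude"].mean()


@dataclass
class DoseResponseFit:
    ec50: float  # μg
    ec50_se: float
    hill: float
    hill_se: float
    top: float
    bottom: float
    residual_ss: float
    n_points: int
    converged: bool
    extrapolated: bool = False  # EC50 outside the tested dose range
    message: str = ""
    covariance: np.ndarray | None = field(default=None, repr=False)


def _hill(d: np.ndarray, bottom: float, top: float, log_ec50: float, h: float) -> np.ndarray:
    out = np.full(d.shape, bottom, dtype=float)
    pos = d > 0
    out[pos] = bottom + (top - bottom) / (1.0 + 10.0 ** (h * (log_ec50 - np.log10(d[pos]))))
    return out


def _hill_jac(d: np.ndarray, bottom: float, top: float, log_ec50: float, h: float) -> np.ndarray:
    """Analytic Jacobian of the 4PL w.r.t. (bottom, top, log_ec50, h)."""
    jac = np.zeros((d.size, 4))
    pos = d > 0
    x = np.log10(d[pos])
    expo = np.clip(h * (log_ec50 - x), -300, 300)
    u = 10.0**expo
    g = 1.0 / (1.0 + u)
    span = top - bottom
    jac[:, 0] = 1.0
    jac[pos, 0] = 1.0 - g
    jac[pos, 1] = g
    common = -span * np.log(10.0) * u * g**2
    jac[pos, 2] = common * h
    jac[pos, 3] = common * (log_ec50 - x)
    return jac


def fit_hill(series: DoseSeries) -> DoseResponseFit:
    """Fit the four-parameter logistic to a dose series.

    Raises :class:`FlatCurveError` when the responses carry no dose signal,
    and flags (without failing) fits whose EC50 falls outside the tested
    dose range.
    """
    d = series.data["dose"].to_numpy(dtype=float)
    y = series.data["amplitude"].to_numpy(dtype=float)
    doses = series.nonzero_doses
    if doses.size < 4:
        raise ValueError(f"need >= 4 distinct nonzero doses, got {doses.size}")
    means = series.dose_means()
    span = float(means.max() - means.min())
    scale = max(np.abs(y).max(), 1.0)
    if span <= 1e-12 * scale or np.ptp(y) == 0:
        raise FlatCurveError("responses do not vary with dose; cannot estimate EC50")

    lo_d, hi_d = np.log10(doses.min()), np.log10(doses.max())
    # asymptotes may lie far beyond the observed responses when the curve
    # does not plateau within the tested range
    y_span = float(y.max() - y.min())
    bounds = (
        [y.min() - 10 * y_span, y.min() - 10 * y_span, lo_d - 2.0, 1e-3],
        [y.max() + 10 * y_span, y.max() + 10 * y_span, hi_d + 2.0, 50.0],
    )

    def residuals(p):
        return _hill(d, *p) - y

    def jac(p):
        return _hill_jac(d, *p)

    # EC50 start: dose whose mean response is nearest half-max, plus a grid
    nz_means = means[means.index > 0]
    half = (means.min() + means.max()) / 2.0
    crossing = float(np.log10(nz_means.index[np.argmin(np.abs(nz_means.to_numpy() - half))]))
    starts = sorted({crossing, lo_d, (lo_d + hi_d) / 2.0, hi_d})

    best = None
    for s0 in starts:
        p0 = np.clip(
            [float(means.min()), float(means.max()), s0, 1.0],
            bounds[0], bounds[1],
        )
        try:
            res = least_squares(
                residuals, p0, jac=jac, bounds=bounds, method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=500,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.success and best.cost < 1e-20 * max(1.0, float(np.abs(y).max()) ** 2):
            break  # exact fit found; further starts cannot improve
    if best is not None and not best.success:
        # polish an iteration-capped run from its own endpoint
        res = least_squares(
            residuals, best.x, jac=jac, bounds=bounds, method="trf",
            xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=1000,
        )
        if res.cost <= best.cost:
            best = res
    # iteration-capped runs (status 0) count as converged when the gradient
    # has collapsed — the Hill-slope direction can be arbitrarily flat
    converged = best is not None and (
        best.success or best.optimality < 5e-3 * max(2.0 * best.cost, 1e-9)
    )
    if best is None or not converged:
        raise RuntimeError(
            "Hill fit failed to converge"
            + ("" if best is None else f": {best.message} (cost {best.cost:g})")
        )

    bottom, top, log_ec50, h = best.x
    ssr = float(2.0 * best.cost)
    m, p_n = len(y), 4
    dof = max(m - p_n, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * ssr / dof
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        cov = None
        se = np.full(4, np.nan)
    ec50 = 10.0**log_ec50
    ec50_se = ec50 * np.log(10.0) * se[2]  # delta method from log10 EC50
    extrapolated = not (doses.min() <= ec50 <= doses.max())
    if extrapolated:
        warnings.warn(
            f"EC50 {ec50:.3g} lies outside the tested dose range "
            f"[{doses.min():g}, {doses.max():g}]",
            stacklevel=2,
        )
    return DoseResponseFit(
        ec50=float(ec50),
        ec50_se=float(ec50_se),
        hill=float(h),
        hill_se=float(se[3]),
        top=float(top),
        bottom=float(bottom),
        residual_ss=ssr,
        n_points=m,
        converged=True,
        extrapolated=extrapolated,
        message=best.message,
        covariance=cov,
    )


def fit_hill_per_animal(series: DoseSeries) -> pd.DataFrame:
    """One Hill fit per animal; rows = animals, columns = fit parameters.

    The per-animal EC50/Hill values are the inputs for between-receptor
    comparisons (rank tests need one value per animal); their mean ± SEM
    is the conventional summary.
    """
    rows = []
    for animal, sub in series.data.groupby("animal", sort=False):
        fit = fit_hill(DoseSeries(sub.reset_index(drop=True), series.ligand, series.receptor))
        rows.append(
            {
                "animal": animal,
                "ec50": fit.ec50,
                "ec50_se": fit.ec50_se,
                "hill": fit.hill,
                "top": fit.top,
                "bottom": fit.bottom,
                "residual_ss": fit.residual_ss,
                "extrapolated": fit.extrapolated,
            }
        )
    return pd.DataFrame(rows).set_index("animal")


def normalize_dose_curve(series: DoseSeries) -> DoseSeries:
    """Rescale so the solvent mean is 0% and the top-dose mean is 100%.

    The same affine map is applied to every replicate point, preserving
    within-dose scatter shape.  Requires the top-dose mean to exceed the
    solvent mean.
    """
    means = series.dose_means()
    if 0.0 not in means.index:
        raise ValueError("series has no solvent (0 dose) point")
    m0 = float(means.loc[0.0])
    mtop = float(means.loc[means.index.max()])
    if mtop <= m0:
        raise ValueError(f"top-dose mean ({mtop:g}) must exceed solvent mean ({m0:g})")
    data = series.data.copy()
    data["amplitude"] = 100.0 * (data["amplitude"] - m0) / (mtop - m0)
    return DoseSeries(data, ligand=series.ligand, receptor=series.receptor)


def cross_ligand_normalization(secondary: DoseSeries, reference: DoseSeries) -> DoseSeries:
    """Express a secondary ligand's responses as % of the reference maximum.

    The reference is the primary ligand's series for the *same* receptor
    (9-ODA in the study); its mean response at the highest dose defines
    100%.
    """
    if secondary.receptor and reference.receptor and secondary.receptor != reference.receptor:
        raise ValueError(
            f"cross-ligand normalization requires the same receptor "
            f"({secondary.receptor!r} vs {reference.receptor!r})"
        )
    ref_means = reference.dose_means()
    nz = ref_means[ref_means.index > 0]
    if nz.empty:
        raise ValueError("reference series has no nonzero dose")
    ref_top = float(nz.loc[nz.index.max()])
    if ref_top <= 0:
        raise ValueError("reference top-dose mean response must be positive")
    data = secondary.data.copy()
    data["amplitude"] = 100.0 * data["amplitude"] / ref_top
    return DoseSeries(data, ligand=secondary.ligand, receptor=secondary.receptor)
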