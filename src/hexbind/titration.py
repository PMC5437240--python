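"""Hill-slope analysis of chromophore-reported titration curves.

The 4H3N chromophore binds R-state insulin hexamers only, so the
difference absorbance at 444 nm (ligand-bound minus ligand-free) reports
the R-state population induced by a titrated phenolic ligand.  The
curves are fitted with the one-site specific-binding model with a Hill
slope,

    ΔA(c) = B_max · c^h / (K_d^h + c^h)

per replicate, and replicate fits are summarised as mean ± SD.
Concentrations are in mM throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TitrationSeries",
    "HillParameters",
    "ReplicateSummary",
    "hill_model",
    "fit_hill",
    "summarize_replicates",
    "difference_absorbance",
]

#: Optimiser bounds: (K_d mM, B_max AU, h).
FIT_BOUNDS_LOWER = (1e-6, 0.0, 1e-6)
FIT_BOUNDS_UPPER = (100.0, 1.0, 20.0)


@dataclass
class TitrationSeries:
    concentrations: np.ndarray  # mM
    delta_a: np.ndarray  # AU at 444 nm
    replicate_id: int = 0
    ligand_name: str = ""
    background_ligand: str | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.delta_a = np.asarray(self.delta_a, dtype=float)
        if self.concentrations.shape != self.delta_a.shape:
            raise ValueError("concentration and ΔA arrays differ in length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if len(np.unique(self.concentrations)) < 5:
            raise ValueError("need at least 5 distinct concentrations")
        if not np.all(np.isfinite(self.delta_a)):
            raise ValueError("ΔA values must be finite")


@dataclass
class HillParameters:
    kd: float  # mM
    bmax: float  # AU
    h: float
    se_kd: float = math.nan
    se_bmax: float = math.nan
    se_h: float = math.nan
    rss: float = math.nan
    converged: bool = True

    def as_dict(self) -> dict:
        return {
            "Kd_mM": self.kd,
            "Bmax_AU": self.bmax,
            "h": self.h,
            "se_Kd_mM": self.se_kd,
            "se_Bmax_AU": self.se_bmax,
            "se_h": self.se_h,
            "rss": self.rss,
            "converged": self.converged,
        }


@dataclass
class ReplicateSummary:
    kd_mean: float
    kd_sd: float
    bmax_mean: float
    bmax_sd: float
    h_mean: float
    h_sd: float
    n: int


def hill_model(
    c: np.ndarray | float, kd: float, bmax: float, h: float
) -> np.ndarray | float:
    """One-site specific binding with a Hill slope.

    ΔA = B_max c^h / (K_d^h + c^h); returns 0 at c = 0 and B_max/2 at
    c = K_d for any h.
    """
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        ch = np.where(c > 0, np.power(c, h), 0.0)
    out = bmax * ch / (kd**h + ch)
    return float(out) if out.ndim == 0 else out


def _auto_init(series: TitrationSeries) -> tuple[float, float, float]:
    """K_d = concentration at half-max observed ΔA, B_max = max ΔA, h = 1."""
    bmax0 = float(series.delta_a.max())
    order = np.argsort(series.concentrations)
    c = series.concentrations[order]
    y = series.delta_a[order]
    half = bmax0 / 2.0
    above = np.flatnonzero(y >= half)
    if bmax0 > 0 and above.size:
        kd0 = float(c[above[0]])
    else:
        kd0 = float(np.median(c[c > 0])) if np.any(c > 0) else 1.0
    kd0 = min(max(kd0, FIT_BOUNDS_LOWER[0] * 10), FIT_BOUNDS_UPPER[0] * 0.9)
    bmax0 = min(max(bmax0, 1e-4), FIT_BOUNDS_UPPER[1])
    return kd0, bmax0, 1.0


def fit_hill(
    series: TitrationSeries, init: tuple[float, float, float] | None = None
) -> HillParameters:
    """Least-squares Hill fit of one titration curve.

    Standard errors come from the curvature of the residual surface at
    the optimum (Gauss-Newton covariance (JᵀJ)⁻¹ · RSS/(n−p)).  The
    ``converged`` flag reflects the optimiser status and is cleared for
    a degenerate flat curve (B_max indistinguishable from zero).
    """
    n = series.concentrations.size
    if n < 3:
        raise ValueError("need at least as many points as parameters (3)")
    x0 = np.array(init if init is not None else _auto_init(series), dtype=float)
    x0 = np.clip(x0, FIT_BOUNDS_LOWER, FIT_BOUNDS_UPPER)

    def residuals(p: np.ndarray) -> np.ndarray:
        return hill_model(series.concentrations, *p) - series.delta_a

    res = least_squares(
        residuals,
        x0,
        bounds=(FIT_BOUNDS_LOWER, FIT_BOUNDS_UPPER),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    kd, bmax, h = (float(v) for v in res.x)
    rss = float(np.sum(res.fun**2))
    dof = max(n - 3, 1)
    try:
        cov = np.linalg.pinv(res.jac.T @ res.jac) * rss / dof
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(3, math.nan)
    converged = bool(res.status > 0)
    if bmax < 1e-4:  # flat curve: K_d and h are unidentifiable
        converged = False
    return HillParameters(
        kd=kd,
        bmax=bmax,
        h=h,
        se_kd=float(ses[0]),
        se_bmax=float(ses[1]),
        se_h=float(ses[2]),
        rss=rss,
        converged=converged,
    )


def summarize_replicates(fits: list[HillParameters]) -> ReplicateSummary:
    """Mean ± SD (n−1 denominator) of K_d, B_max and h over converged fits."""
    good = [f for f in fits if f.converged]
    if len(good) < 2:
        raise ValueError("need at least 2 converged fits to summarise")
    kd = np.array([f.kd for f in good])
    bmax = np.array([f.bmax for f in good])
    h = np.array([f.h for f in good])
    return ReplicateSummary(
        kd_mean=float(kd.mean()),
        kd_sd=float(kd.std(ddof=1)),
        bmax_mean=float(bmax.mean()),
        bmax_sd=float(bmax.std(ddof=1)),
        h_mean=float(h.mean()),
        h_sd=float(h.std(ddof=1)),
        n=len(good),
    )


def difference_absorbance(
    bound_spectrum: dict[float, float] | tuple[np.ndarray, np.ndarray],
    free_spectrum: dict[float, float] | tuple[np.ndarray, np.ndarray],
    lambda_max: float = 444.0,
) -> float:
    """ΔA = A_bound(λ_max) − A_free(λ_max), linearly interpolated.

    Spectra are wavelength (nm) → absorbance maps, given either as dicts
    or as (wavelengths, absorbances) array pairs; both must cover
    ``lambda_max``.
    """

    def interp(spec) -> float:
        if isinstance(spec, dict):
            wl = np.array(sorted(spec))
            ab = np.array([spec[w] for w in wl], dtype=float)
        else:
            wl = np.asarray(spec[0], dtype=float)
            ab = np.asarray(spec[1], dtype=float)
            order = np.argsort(wl)
            wl, ab = wl[order], ab[order]
        if not (wl[0] <= lambda_max <= wl[-1]):
            raise ValueError(
                f"spectrum ({wl[0]:.0f}-{wl[-1]:.0f} nm) does not cover "
                f"{lambda_max:.0f} nm"
            )
        return float(np.interp(lambda_max, wl, ab))

    return interp(bound_spectrum) - interp(free_spectrum)
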