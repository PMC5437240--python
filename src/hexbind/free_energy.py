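"""Binding free-energy estimation: thermodynamic integration, umbrella
sampling / WHAM, standard-state corrections, and ΔG ↔ K_d conversion.

The site-III binding free energy is decomposed as

    ΔG_b° = W₀ + ΔG_symm + ΔG_vol,        K_d = exp(ΔG_b° / RT)

where W₀ is the well depth of the potential of mean force (bound minimum
relative to the unbound plateau), ΔG_symm accounts for the n equivalent
symmetric sites of the hexamer (default -RT ln n, with a pass-through
override), and ΔG_vol = -RT ln(v_bound / V₀) references the bound-state
volume to the 1 M standard state (V₀ = 1660.539 Å³ per molecule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, V0_STANDARD_STATE, rt

logger = logging.getLogger(__name__)

__all__ = [
    "LambdaSeries",
    "UmbrellaWindow",
    "UmbrellaWindowSet",
    "PMFProfile",
    "BindingDecomposition",
    "ti_integrate",
    "wham_pmf",
    "well_depth",
    "symmetry_correction",
    "volume_correction",
    "bound_volume",
    "combine_binding",
    "dg_to_kd",
    "kd_to_dg",
]


@dataclass
class LambdaSeries:
    """⟨∂U/∂λ⟩ with standard errors on a λ grid in [0, 1]."""

    lambdas: np.ndarray
    dudl_mean: np.ndarray  # kcal/mol
    dudl_sem: np.ndarray  # kcal/mol

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.dudl_mean = np.asarray(self.dudl_mean, dtype=float)
        if self.dudl_sem is None:
            self.dudl_sem = np.zeros_like(self.dudl_mean)
        self.dudl_sem = np.asarray(self.dudl_sem, dtype=float)
        if not (
            len(self.lambdas) == len(self.dudl_mean) == len(self.dudl_sem)
        ):
            raise ValueError("lambda grid and values differ in length")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("lambda values must be strictly increasing")
        if np.any((self.lambdas < 0) | (self.lambdas > 1)):
            raise ValueError("lambda values must lie in [0, 1]")
        if self.lambdas[0] != 0.0 or self.lambdas[-1] != 1.0:
            logger.warning(
                "lambda grid does not span [0, 1] (%.3f..%.3f); the "
                "integral extrapolates nothing beyond the grid",
                self.lambdas[0],
                self.lambdas[-1],
            )


@dataclass
class UmbrellaWindow:
    center: float
    spring_k: float  # kcal/mol per (coordinate unit)^2
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 1:
            raise ValueError("every umbrella window needs at least one sample")
        if self.spring_k < 0:
            raise ValueError("spring constant must be non-negative")

    def bias(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.spring_k * (np.asarray(x, float) - self.center) ** 2


@dataclass
class UmbrellaWindowSet:
    windows: list[UmbrellaWindow]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("no umbrella windows")
        ranges = sorted(
            (w.samples.min(), w.samples.max()) for w in self.windows
        )
        for (lo1, hi1), (lo2, hi2) in zip(ranges, ranges[1:]):
            if lo2 > hi1:
                logger.warning(
                    "umbrella windows do not overlap between %.3f and %.3f; "
                    "the PMF will have a gap",
                    hi1,
                    lo2,
                )


@dataclass
class PMFProfile:
    bin_centers: np.ndarray
    free_energy: np.ndarray  # kcal/mol, plateau-referenced
    uncertainty: np.ndarray | None = None
    window_shifts: np.ndarray | None = None  # converged WHAM f_i, kcal/mol


@dataclass
class BindingDecomposition:
    w0: float  # kcal/mol
    dg_symm: float
    dg_vol: float
    dg_total: float
    kd: float  # mol/L
    temperature: float
    sigma_w0: float = 0.0
    sigma_vol: float = 0.0
    sigma_total: float = 0.0
    sigma_kd: float = 0.0

    def as_dict(self) -> dict:
        return {
            "W0_kcal_mol": self.w0,
            "dG_symm_kcal_mol": self.dg_symm,
            "dG_vol_kcal_mol": self.dg_vol,
            "dG_total_kcal_mol": self.dg_total,
            "Kd_M": self.kd,
            "temperature_K": self.temperature,
            "sigma_dG_kcal_mol": self.sigma_total,
            "sigma_Kd_M": self.sigma_kd,
        }


def ti_integrate(series: LambdaSeries) -> tuple[float, float]:
    """Thermodynamic integration: trapezoidal quadrature of ⟨∂U/∂λ⟩.

    Returns (ΔG, σ) in kcal/mol, with σ from propagating the per-point
    standard errors through the trapezoid weights.
    """
    lam = series.lambdas
    if len(lam) < 2:
        raise ValueError("thermodynamic integration needs at least 2 lambda points")
    dg = float(np.trapezoid(series.dudl_mean, lam))
    weights = np.zeros_like(lam)
    dl = np.diff(lam)
    weights[:-1] += dl / 2.0
    weights[1:] += dl / 2.0
    sigma = float(np.sqrt(np.sum((weights * series.dudl_sem) ** 2)))
    return dg, sigma


def wham_pmf(
    windows: UmbrellaWindowSet,
    n_bins: int = 100,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    plateau_range: tuple[float, float] | None = None,
) -> PMFProfile:
    """Self-consistent WHAM solution for the PMF of biased windows.

    Iterates the window free-energy shifts f_i of the standard WHAM
    equations until the maximum relative change falls below ``tol``,
    then converts the unbiased bin probabilities to a free-energy
    profile.  The PMF zero is the mean over ``plateau_range`` (the
    unbound coordinate range); if no plateau is given, the minimum is
    set to zero.  Empty bins interior to the sampled range are returned
    as NaN and flagged with a warning.
    """
    kt = rt(windows.temperature)
    all_samples = np.concatenate([w.samples for w in windows.windows])
    lo, hi = float(all_samples.min()), float(all_samples.max())
    if hi <= lo:
        hi = lo + 1e-6
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.histogram(all_samples, bins=edges)[0].astype(float)  # M_j
    n_i = np.array([w.samples.size for w in windows.windows], dtype=float)
    bias = np.array(
        [w.bias(centers) for w in windows.windows]
    )  # (n_windows, n_bins)
    boltz = np.exp(-bias / kt)

    f = np.zeros(len(windows.windows))
    residual = np.inf
    for _ in range(max_iter):
        denom = (n_i * np.exp(f / kt)) @ boltz  # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, counts / denom, 0.0)
        z = boltz @ p  # (n_windows,)
        f_new = -kt * np.log(np.where(z > 0, z, np.finfo(float).tiny))
        f_new -= f_new[0]  # gauge: first window at 0
        residual = float(np.max(np.abs(f_new - f) / np.maximum(1.0, np.abs(f_new))))
        f = f_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last residual {residual:.3e}, tol {tol:.3e})"
        )

    denom = (n_i * np.exp(f / kt)) @ boltz
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where((denom > 0) & (counts > 0), counts / denom, np.nan)
        pmf = -kt * np.log(p)

    empty = np.isnan(pmf)
    if empty.any():
        filled = np.flatnonzero(~empty)
        if filled.size and (
            np.any(empty[filled[0] : filled[-1] + 1])
        ):
            logger.warning(
                "%d empty bins interior to the sampled range; PMF has gaps",
                int(empty[filled[0] : filled[-1] + 1].sum()),
            )

    if plateau_range is not None:
        mask = (centers >= plateau_range[0]) & (centers <= plateau_range[1])
        ref_vals = pmf[mask & ~empty]
        if ref_vals.size == 0:
            raise ValueError("plateau range contains no sampled bins")
        pmf = pmf - ref_vals.mean()
    else:
        pmf = pmf - np.nanmin(pmf)

    with np.errstate(divide="ignore"):
        uncertainty = np.where(counts > 0, kt / np.sqrt(counts), np.nan)
    return PMFProfile(
        bin_centers=centers,
        free_energy=pmf,
        uncertainty=uncertainty,
        window_shifts=f,
    )


def well_depth(
    pmf: PMFProfile,
    bound_range: tuple[float, float],
    plateau_range: tuple[float, float],
) -> float:
    """W₀ = min PMF over the bound range − mean PMF over the plateau."""
    x = pmf.bin_centers
    g = pmf.free_energy
    bound = (x >= bound_range[0]) & (x <= bound_range[1]) & ~np.isnan(g)
    plateau = (x >= plateau_range[0]) & (x <= plateau_range[1]) & ~np.isnan(g)
    if not bound.any():
        raise ValueError("bound range does not intersect sampled bins")
    if not plateau.any():
        raise ValueError("plateau range does not intersect sampled bins")
    return float(g[bound].min() - g[plateau].mean())


def symmetry_correction(
    n_sites: int,
    temperature: float = DEFAULT_TEMPERATURE,
    override: float | None = None,
) -> float:
    """Free-energy contribution of n equivalent symmetric sites.

    Default -RT ln(n); an ``override`` value is passed through verbatim
    for workflows whose symmetry term comes from an external estimate.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if override is not None:
        return float(override)
    return -rt(temperature) * math.log(n_sites)


def volume_correction(
    v_bound: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Volume-entropy correction to the 1 M standard state.

    ΔG_vol = -RT ln(v_bound / V₀) with V₀ = 1660.539 Å³ per molecule.
    """
    if v_bound <= 0:
        raise ValueError("bound volume must be positive")
    return -rt(temperature) * math.log(v_bound / V0_STANDARD_STATE)


def bound_volume(positions: np.ndarray) -> float:
    """Effective Gaussian volume of a bound-state position cloud.

    v = (2πe)^{3/2} |Σ|^{1/2} from the 3×3 positional covariance Σ of
    the ligand-centre samples (Å³).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("positions must be an (n, 3) array")
    if pos.shape[0] < 10:
        raise ValueError("need at least 10 positions to estimate a volume")
    cov = np.cov(pos, rowvar=False)
    if np.linalg.matrix_rank(cov, tol=1e-10) < 3:
        raise ValueError("degenerate position covariance (rank < 3)")
    det = float(np.linalg.det(cov))
    if det <= 0:
        raise ValueError("non-positive covariance determinant")
    return float((2.0 * math.pi * math.e) ** 1.5 * math.sqrt(det))


def combine_binding(
    w0: float,
    dg_symm: float,
    dg_vol: float,
    temperature: float = DEFAULT_TEMPERATURE,
    sigma_w0: float = 0.0,
    sigma_vol: float = 0.0,
) -> BindingDecomposition:
    """Assemble ΔG_b° = W₀ + ΔG_symm + ΔG_vol and the implied K_d.

    Component uncertainties combine in quadrature; the K_d uncertainty
    uses the first-order delta method σ_Kd = K_d σ_ΔG / RT.
    """
    for name, v in (("w0", w0), ("dg_symm", dg_symm), ("dg_vol", dg_vol)):
        if not math.isfinite(v):
            raise ValueError(f"{name} is not finite")
    dg_total = w0 + dg_symm + dg_vol
    kd = dg_to_kd(dg_total, temperature)
    sigma_total = math.hypot(sigma_w0, sigma_vol)
    sigma_kd = kd * sigma_total / rt(temperature)
    return BindingDecomposition(
        w0=w0,
        dg_symm=dg_symm,
        dg_vol=dg_vol,
        dg_total=dg_total,
        kd=kd,
        temperature=temperature,
        sigma_w0=sigma_w0,
        sigma_vol=sigma_vol,
        sigma_total=sigma_total,
        sigma_kd=sigma_kd,
    )


def dg_to_kd(dg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Dissociation constant (mol/L) from a binding free energy (kcal/mol)."""
    return math.exp(dg / rt(temperature))


def kd_to_dg(kd: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy (kcal/mol) from a dissociation constant (mol/L)."""
    if kd <= 0:
        raise ValueError("K_d must be positive")
    return rt(temperature) * math.log(kd)
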