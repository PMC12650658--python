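"""Oligomer dissociation equilibria and hydrodynamic cross-checks.

Two schemes are supported: a direct trimer/monomer equilibrium
(``T3M``: Kd = [M]³/[T], units M²) and an extended scheme with a dimer
intermediate (``T3_D2_M``: K1 = [D][M]/[T] and K2 = [M]²/[D], units M).
Species concentrations at a given total subunit concentration come from a
bracketed root solve of the subunit mass balance; the dissociation
constant is fitted to titration data by bounded scalar minimization over
log10(Kd) with case-resampling bootstrap confidence intervals.

Diffusion coefficients are predicted from fitted spheroids via the
Stokes--Einstein relation with Perrin translational friction factors for
prolate/oblate ellipsoids of revolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

KB = 1.380649e-23  # J/K
WATER_VISCOSITY_20C = 1.002e-3  # Pa s


@dataclass(frozen=True)
class EquilibriumModel:
    """Dissociation scheme plus its constants (molar units)."""

    scheme: str  # "T3M" | "T3_D2_M"
    kd: float | None = None  # M², [M]^3/[T]
    k1: float | None = None  # M,  [D][M]/[T]
    k2: float | None = None  # M,  [M]^2/[D]

    def __post_init__(self) -> None:
        if self.scheme == "T3M":
            if self.kd is None or self.kd <= 0:
                raise ValueError("T3M scheme needs kd > 0")
        elif self.scheme == "T3_D2_M":
            if self.k1 is None or self.k2 is None or self.k1 <= 0 or self.k2 <= 0:
                raise ValueError("T3_D2_M scheme needs k1 > 0 and k2 > 0")
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def effective_kd(self) -> float:
        """[M]³/[T] for either scheme (k1·k2 in the extended one)."""
        if self.scheme == "T3M":
            return float(self.kd)  # type: ignore[arg-type]
        return float(self.k1 * self.k2)  # type: ignore[operator]


@dataclass(frozen=True)
class SpeciesFractions:
    m: float  # [M], molar
    d: float  # [D], molar
    t: float  # [T], molar
    f_monomer: float
    f_dimer: float
    f_trimer: float


@dataclass
class TitrationDataset:
    """(total subunit concentration, monomer fraction) observations."""

    c_tot: np.ndarray  # M
    f_m: np.ndarray  # in [0, 1]
    technique: list[str] = field(default_factory=list)
    weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.c_tot = np.asarray(self.c_tot, dtype=float)
        self.f_m = np.asarray(self.f_m, dtype=float)
        if len(self.c_tot) != len(self.f_m):
            raise ValueError("c_tot and f_m must have the same length")
        if np.any(self.c_tot <= 0):
            raise ValueError("all concentrations must be positive")
        if np.any((self.f_m < 0) | (self.f_m > 1)):
            raise ValueError("monomer fractions must lie in [0, 1]")
        if not self.technique:
            self.technique = ["unknown"] * len(self.c_tot)
        if self.weight is None:
            self.weight = np.ones(len(self.c_tot))
        else:
            self.weight = np.asarray(self.weight, dtype=float)
            if np.any(self.weight <= 0):
                raise ValueError("weights must be positive")

    def __len__(self) -> int:
        return len(self.c_tot)

    @classmethod
    def from_csv(cls, path) -> "TitrationDataset":
        df = pd.read_csv(path)
        return cls(
            c_tot=df["c_tot_M"].to_numpy(),
            f_m=df["f_monomer"].to_numpy(),
            technique=df["technique"].tolist() if "technique" in df else [],
            weight=df["weight"].to_numpy() if "weight" in df else None,
        )


def species_fractions(model: EquilibriumModel, c_tot: float) -> SpeciesFractions:
    """Solve the subunit mass balance for the species concentrations.

    T3M:      M + 3M³/Kd = c_tot
    T3_D2_M:  M + 2M²/K2 + 3M³/(K1·K2) = c_tot

    The left side is strictly increasing in M, so the positive root is
    unique; it is bracketed in [0, c_tot] and solved to 1e-14 relative
    tolerance.  Fractions are subunit-mass fractions (M, 2D, 3T over
    c_tot).
    """
    if c_tot <= 0:
        raise ValueError(f"c_tot must be positive, got {c_tot}")

    if model.scheme == "T3M":
        kd = model.kd

        def balance(m: float) -> float:
            return m + 3.0 * m**3 / kd - c_tot

    else:
        k1, k2 = model.k1, model.k2

        def balance(m: float) -> float:
            return m + 2.0 * m**2 / k2 + 3.0 * m**3 / (k1 * k2) - c_tot

    m = optimize.brentq(balance, 0.0, c_tot, xtol=1e-30, rtol=8.9e-16, maxiter=200)
    if model.scheme == "T3M":
        d = 0.0
        t = m**3 / model.kd
    else:
        d = m**2 / model.k2
        t = m**3 / (model.k1 * model.k2)
    return SpeciesFractions(
        m=m,
        d=d,
        t=t,
        f_monomer=m / c_tot,
        f_dimer=2.0 * d / c_tot,
        f_trimer=3.0 * t / c_tot,
    )


def monomer_fraction_curve(model: EquilibriumModel, c_tot: np.ndarray) -> np.ndarray:
    return np.array([species_fractions(model, c).f_monomer for c in np.asarray(c_tot, float)])


@dataclass
class DissociationFit:
    scheme: str
    kd: float  # M² ([M]³/[T]); for T3_D2_M this is k1*k2
    k2: float | None
    log10_kd: float
    ci_low: float
    ci_high: float
    rss: float
    residuals: np.ndarray
    residuals_by_technique: dict[str, float]
    n_bootstrap: int
    seed: int

    def model(self) -> EquilibriumModel:
        if self.scheme == "T3M":
            return EquilibriumModel(scheme="T3M", kd=self.kd)
        return EquilibriumModel(scheme="T3_D2_M", k1=self.kd / self.k2, k2=self.k2)


_LOG10_KD_BOUNDS = (-20.0, -10.0)


def _fit_kd_once(
    c_tot: np.ndarray,
    f_m: np.ndarray,
    w: np.ndarray,
    scheme: str,
    k2: float | None,
) -> tuple[float, float]:
    def loss(log10_kd: float) -> float:
        kd = 10.0**log10_kd
        if scheme == "T3M":
            model = EquilibriumModel(scheme="T3M", kd=kd)
        else:
            model = EquilibriumModel(scheme="T3_D2_M", k1=kd / k2, k2=k2)
        pred = monomer_fraction_curve(model, c_tot)
        return float(np.sum(w * (f_m - pred) ** 2))

    res = optimize.minimize_scalar(
        loss, bounds=_LOG10_KD_BOUNDS, method="bounded", options={"xatol": 1e-10}
    )
    return float(res.x), float(res.fun)


def fit_dissociation(
    data: TitrationDataset,
    scheme: str = "T3M",
    k2: float | None = None,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> DissociationFit:
    """Weighted least-squares fit of the dissociation constant.

    The search runs over log10(Kd) with a bounded scalar minimizer
    (bounds 1e-20 ... 1e-10 M²); for the extended scheme the dimer
    constant ``k2`` is held fixed and only the overall Kd = K1·K2 is
    fitted.  Confidence intervals are percentile bootstrap over case
    resampling with a fixed seed.
    """
    if len(data) < 4:
        raise ValueError("need at least 4 titration points")
    span = np.log10(data.c_tot.max() / data.c_tot.min())
    if span < 2.0:
        raise ValueError(
            f"concentrations must span >= 2 decades (got {span:.2f})"
        )
    if scheme not in ("T3M", "T3_D2_M"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "T3_D2_M" and (k2 is None or k2 <= 0):
        raise ValueError("T3_D2_M fitting requires a fixed k2 > 0")

    log10_kd, rss = _fit_kd_once(data.c_tot, data.f_m, data.weight, scheme, k2)
    kd = 10.0**log10_kd
    if scheme == "T3M":
        best = EquilibriumModel(scheme="T3M", kd=kd)
    else:
        best = EquilibriumModel(scheme="T3_D2_M", k1=kd / k2, k2=k2)
    pred = monomer_fraction_curve(best, data.c_tot)
    residuals = data.f_m - pred
    by_tech: dict[str, float] = {}
    for tech in sorted(set(data.technique)):
        sel = np.array([t == tech for t in data.technique])
        by_tech[tech] = float(np.sqrt(np.mean(residuals[sel] ** 2)))

    rng = np.random.default_rng(seed)
    boot = np.empty(n_bootstrap)
    n = len(data)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        lb, _ = _fit_kd_once(
            data.c_tot[idx], data.f_m[idx], data.weight[idx], scheme, k2
        )
        boot[b] = 10.0**lb
    ci_low, ci_high = (
        (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
        if n_bootstrap > 0
        else (float("nan"), float("nan"))
    )
    return DissociationFit(
        scheme=scheme,
        kd=kd,
        k2=k2,
        log10_kd=log10_kd,
        ci_low=ci_low,
        ci_high=ci_high,
        rss=rss,
        residuals=residuals,
        residuals_by_technique=by_tech,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Hydrodynamics


@dataclass(frozen=True)
class HydroSpheroid:
    r_polar: float  # Å
    r_equatorial: float  # Å
    temperature: float  # K
    viscosity: float  # Pa s
    r_hydro: float  # Å
    d_trans: float  # µm²/s
    shape_class: str


def perrin_hydro(
    r_polar: float,
    r_equatorial: float,
    temperature: float = 293.15,
    viscosity: float = WATER_VISCOSITY_20C,
) -> HydroSpheroid:
    """Translational diffusion of a spheroid via Perrin + Stokes-Einstein.

    Prolate (a = r_polar > b = r_equatorial, p = b/a):
        R_h = a·√(1−p²) / ln((1+√(1−p²))/p)
    Oblate (a = r_polar < b = r_equatorial, p = a/b):
        R_h = b·√(1−p²) / arctan(√(1−p²)/p)
    Sphere limit: R_h = radius.  Then D = kB·T / (6π·η·R_h).
    """
    if r_polar <= 0 or r_equatorial <= 0:
        raise ValueError("radii must be positive")
    if temperature <= 0 or viscosity <= 0:
        raise ValueError("temperature and viscosity must be positive")
    a, b = float(r_polar), float(r_equatorial)
    if np.isclose(a, b, rtol=1e-12):
        r_h = a
        shape = "sphere"
    elif a > b:  # prolate
        p = b / a
        e = np.sqrt(1.0 - p * p)
        r_h = a * e / np.log((1.0 + e) / p)
        shape = "prolate"
    else:  # oblate
        p = a / b
        e = np.sqrt(1.0 - p * p)
        r_h = b * e / np.arctan2(e, p)
        shape = "oblate"
    d = KB * temperature / (6.0 * np.pi * viscosity * r_h * 1e-10)  # m²/s
    return HydroSpheroid(
        r_polar=a,
        r_equatorial=b,
        temperature=temperature,
        viscosity=viscosity,
        r_hydro=float(r_h),
        d_trans=float(d * 1e12),  # µm²/s
        shape_class=shape,
    )
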