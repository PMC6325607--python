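"""Enzyme activity and redox-inactivation kinetics.

GAPDH activity is assayed by following NADH formation at 340 nm
(epsilon = 6220 M-1 cm-1); one unit (U) reduces 1 umol NAD+ per minute.
Incubation with a disulphide reagent (CoASSCoA, GSSG) at fixed excess
inactivates the enzyme by S-thiolation of the active-site cysteine.  At
fixed reagent concentration C the decay of relative activity is
pseudo-first-order, A(t) = A0 * exp(-k_obs * t); across concentrations
k_obs = k2 * C defines the apparent second-order rate constant k2
(M-1 s-1) of the thiol-disulphide exchange.  Substrate turnover follows
Michaelis-Menten kinetics, v = Vmax * S / (Km + S), with kcat derived from
Vmax via the native (tetramer) molar mass.

The fitting API follows the Model -> fit() -> Results convention: each
model is built from data, ``fit()`` returns a results object carrying
estimates, standard errors and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lmfit import Model as _LmfitModel

__all__ = [
    "EPSILON_340",
    "SUBUNIT_MASS_DA",
    "TETRAMER_MASS_DA",
    "activity_from_absorbance",
    "recovery_percent",
    "ActivityTimeCourse",
    "RecoverySummary",
    "InactivationModel",
    "InactivationResults",
    "SecondOrderModel",
    "SecondOrderResults",
    "MichaelisMentenModel",
    "MichaelisMentenResults",
    "fit_inactivation_series",
]

#: NADH molar absorptivity at 340 nm, 1/(M cm).
EPSILON_340 = 6220.0
#: GAPDH subunit mass from linear MALDI (Da).
SUBUNIT_MASS_DA = 35363.0
#: Native homotetramer mass (Da).
TETRAMER_MASS_DA = 4 * SUBUNIT_MASS_DA

LN2 = float(np.log(2.0))


def activity_from_absorbance(
    slope_per_min: float,
    assay_volume_l: float,
    path_cm: float = 1.0,
    epsilon: float = EPSILON_340,
    enzyme_mg: float | None = None,
) -> tuple[float, float | None]:
    """Enzyme units and specific activity from an A340 slope.

    ``slope_per_min`` is dA340/min; the NADH formation rate in the cuvette
    is slope/(epsilon*path) mol/L/min, which times the assay volume gives
    mol/min, expressed in umol/min = U.  Specific activity is U per mg of
    enzyme (None when no mass is supplied).
    """
    if slope_per_min < 0:
        raise ValueError("slope must be >= 0")
    if assay_volume_l <= 0:
        raise ValueError("assay volume must be positive")
    units = slope_per_min / (epsilon * path_cm) * assay_volume_l * 1e6
    if enzyme_mg is None:
        return units, None
    if enzyme_mg <= 0:
        raise ValueError("enzyme mass must be positive for specific activity")
    return units, units / enzyme_mg


def recovery_percent(activity_after: float, initial: float) -> float:
    """Residual/recovered activity as a percentage of the initial activity."""
    if initial <= 0:
        raise ValueError("initial activity must be positive")
    return 100.0 * activity_after / initial


@dataclass(frozen=True)
class RecoverySummary:
    """Residual activity before and recovered activity after a reductant."""

    condition: str
    residual_pct: float
    recovered_pct: float

    def __post_init__(self) -> None:
        if self.residual_pct < 0 or self.recovered_pct < 0:
            raise ValueError("percentages must be >= 0")


@dataclass(frozen=True)
class ActivityTimeCourse:
    """Relative activity (% of initial) over time at one reagent concentration."""

    condition: str
    concentration: float  # mol/L
    times: tuple[float, ...]  # s
    activities: tuple[float, ...]  # %

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.times) != len(self.activities):
            raise ValueError("times and activities differ in length")
        if any(a < 0 for a in self.activities):
            raise ValueError("activities must be >= 0")


def _exp_decay(t, a0, k_obs):
    return a0 * np.exp(-k_obs * t)


class InactivationModel:
    """Pseudo-first-order inactivation model A(t) = A0 exp(-k_obs t).

    Fitted by nonlinear least squares on the linear activity scale (A0 and
    k_obs free), which avoids the heteroscedastic bias of log-linear
    regression on percent-scale noise; a log-linear option is provided for
    comparison.
    """

    def __init__(self, timecourse: ActivityTimeCourse):
        if len(timecourse.times) < 3:
            raise ValueError("need at least 3 time points")
        self.timecourse = timecourse

    def fit(self, log_linear: bool = False) -> "InactivationResults":
        t = np.asarray(self.timecourse.times, dtype=float)
        a = np.asarray(self.timecourse.activities, dtype=float)
        if a[-1] >= a[0]:
            warnings.warn(
                f"{self.timecourse.condition}: activity does not decrease; "
                "reporting k_obs = 0",
                stacklevel=2,
            )
            return InactivationResults(
                model=self, k_obs=0.0, k_obs_se=float("nan"), a0=float(a[0]),
                a0_se=float("nan"),
            )
        if log_linear:
            mask = a > 0
            slope, intercept = np.polyfit(t[mask], np.log(a[mask]), 1)
            k0, a00 = -slope, float(np.exp(intercept))
            return InactivationResults(
                model=self, k_obs=float(max(k0, 0.0)), k_obs_se=float("nan"),
                a0=a00, a0_se=float("nan"),
            )
        # crude initial rate from the first decade of decay
        mask = a > 0
        k_init = max(
            -np.polyfit(t[mask], np.log(a[mask]), 1)[0], 1e-9
        )
        lm = _LmfitModel(_exp_decay)
        out = lm.fit(a, t=t, a0=float(a[0]), k_obs=float(k_init))
        k = out.params["k_obs"]
        a0 = out.params["a0"]
        return InactivationResults(
            model=self,
            k_obs=float(k.value),
            k_obs_se=float(k.stderr) if k.stderr is not None else float("nan"),
            a0=float(a0.value),
            a0_se=float(a0.stderr) if a0.stderr is not None else float("nan"),
        )


@dataclass(frozen=True)
class InactivationResults:
    """Pseudo-first-order fit results."""

    model: InactivationModel
    k_obs: float  # 1/s
    k_obs_se: float
    a0: float  # %
    a0_se: float

    @property
    def t_half(self) -> float:
        """Half-time of inactivation, ln2/k_obs (s); inf when k_obs = 0."""
        return LN2 / self.k_obs if self.k_obs > 0 else float("inf")

    def t_half_interpolated(self) -> float:
        """Half-time read directly off the 50%-crossing of the data.

        Literature half-time tables are often read from the curve rather
        than derived from the fitted constant; this reports that reading
        (linear interpolation between the bracketing samples), inf if the
        course never crosses 50% of its initial value.
        """
        t = np.asarray(self.model.timecourse.times, dtype=float)
        a = np.asarray(self.model.timecourse.activities, dtype=float)
        half = a[0] / 2.0
        below = np.nonzero(a <= half)[0]
        if below.size == 0:
            return float("inf")
        j = below[0]
        if j == 0:
            return float(t[0])
        t0, t1, a0_, a1 = t[j - 1], t[j], a[j - 1], a[j]
        return float(t0 + (a0_ - half) / (a0_ - a1) * (t1 - t0))

    def predict(self, t) -> np.ndarray:
        return _exp_decay(np.asarray(t, dtype=float), self.a0, self.k_obs)

    def summary(self) -> str:
        tc = self.model.timecourse
        lines = [
            "Pseudo-first-order inactivation fit",
            f"  condition:      {tc.condition}",
            f"  concentration:  {tc.concentration:.3g} M",
            f"  n points:       {len(tc.times)}",
            f"  k_obs:          {self.k_obs:.4g} 1/s (SE {self.k_obs_se:.2g})",
            f"  A0:             {self.a0:.4g} % (SE {self.a0_se:.2g})",
            f"  t1/2 (ln2/k):   {self.t_half:.4g} s",
            f"  t1/2 (interp):  {self.t_half_interpolated():.4g} s",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.asarray(self.model.timecourse.times, dtype=float)
        ax.plot(t, self.model.timecourse.activities, "o", label="data")
        grid = np.linspace(t.min(), t.max(), 200)
        ax.plot(grid, self.predict(grid), "-", label="fit")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("relative activity (%)")
        ax.set_title(self.model.timecourse.condition)
        ax.legend()
        return ax


class SecondOrderModel:
    """Apparent second-order rate constant from k_obs vs concentration.

    For a bimolecular thiol-disulphide exchange at excess reagent,
    k_obs = k2 * C; the fit is a least-squares line through the origin
    (controls show no reagent-free inactivation), with an optional
    intercept for diagnostic use.
    """

    def __init__(self, points: Sequence[tuple[float, float]]):
        if len(points) < 2:
            raise ValueError("need at least 2 (concentration, k_obs) points")
        conc = np.asarray([p[0] for p in points], dtype=float)
        kobs = np.asarray([p[1] for p in points], dtype=float)
        if np.all(conc == 0):
            raise ValueError("all concentrations are zero")
        self.concentrations = conc
        self.k_obs = kobs

    def fit(self, intercept: bool = False) -> "SecondOrderResults":
        c, k = self.concentrations, self.k_obs
        if intercept:
            X = np.column_stack([c, np.ones_like(c)])
            coef, *_ = np.linalg.lstsq(X, k, rcond=None)
            slope, b = float(coef[0]), float(coef[1])
            resid = k - X @ coef
            dof = max(len(c) - 2, 1)
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.inv(X.T @ X)
            se = float(np.sqrt(cov[0, 0]))
        else:
            slope = float(np.dot(c, k) / np.dot(c, c))
            b = 0.0
            resid = k - slope * c
            dof = max(len(c) - 1, 1)
            s2 = float(resid @ resid) / dof
            se = float(np.sqrt(s2 / np.dot(c, c)))
        return SecondOrderResults(
            model=self, k2=slope, k2_se=se, intercept=b, with_intercept=intercept
        )


@dataclass(frozen=True)
class SecondOrderResults:
    """Origin-forced regression results: k2 in 1/(M s)."""

    model: SecondOrderModel
    k2: float
    k2_se: float
    intercept: float
    with_intercept: bool

    def summary(self) -> str:
        return "\n".join(
            [
                "Apparent second-order rate constant",
                f"  n concentrations: {len(self.model.concentrations)}",
                f"  k2:               {self.k2:.4g} 1/(M s) (SE {self.k2_se:.2g})",
                f"  intercept:        {self.intercept:.3g}"
                + ("" if self.with_intercept else " (forced through origin)"),
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.concentrations
        ax.plot(c, self.model.k_obs, "o", label="k_obs")
        grid = np.linspace(0, c.max(), 50)
        ax.plot(grid, self.k2 * grid + self.intercept, "-", label="fit")
        ax.set_xlabel("concentration (M)")
        ax.set_ylabel("k_obs (1/s)")
        ax.legend()
        return ax


def fit_inactivation_series(
    timecourses: Sequence[ActivityTimeCourse],
    log_linear: bool = False,
    intercept: bool = False,
) -> tuple[list[InactivationResults], SecondOrderResults]:
    """Two-stage fit: per-concentration k_obs, then k2 through the origin."""
    stage1 = [InactivationModel(tc).fit(log_linear=log_linear) for tc in timecourses]
    points = [
        (tc.concentration, res.k_obs) for tc, res in zip(timecourses, stage1)
    ]
    stage2 = SecondOrderModel(points).fit(intercept=intercept)
    return stage1, stage2


def _mm(s, vmax, km):
    return vmax * s / (km + s)


class MichaelisMentenModel:
    """Michaelis-Menten model v = Vmax S/(Km + S) for initial-rate data.

    Substrate concentrations in mM, rates in U/mg.  ``fit`` converts Vmax
    to kcat through the native molar mass: by default the homotetramer
    (4 x 35 363 g/mol), the convention under which specific activity and
    turnover number are mutually consistent for this enzyme; pass
    ``per_subunit=True`` for the per-subunit convention.
    """

    def __init__(self, substrate_mm: Sequence[float], rates: Sequence[float]):
        s = np.asarray(substrate_mm, dtype=float)
        v = np.asarray(rates, dtype=float)
        if s.size != v.size:
            raise ValueError("substrate and rate arrays differ in length")
        if s.size < 4:
            raise ValueError("need at least 4 substrate concentrations")
        if np.all(v <= 0):
            raise ValueError("no positive rates to fit")
        self.substrate_mm = s
        self.rates = v

    def fit(
        self,
        native_molar_mass: float = TETRAMER_MASS_DA,
        per_subunit: bool = False,
    ) -> "MichaelisMentenResults":
        s, v = self.substrate_mm, self.rates
        km0 = float(np.median(s[s > 0])) if np.any(s > 0) else 1.0
        if not (s.min() < km0 < s.max()):
            warnings.warn(
                "substrate grid may not span Km; fit may be poorly constrained",
                stacklevel=2,
            )
        mass = native_molar_mass / 4.0 if per_subunit else native_molar_mass
        lm = _LmfitModel(_mm)
        out = lm.fit(v, s=s, vmax=float(v.max()), km=km0)
        vmax_p, km_p = out.params["vmax"], out.params["km"]
        return MichaelisMentenResults(
            model=self,
            vmax=float(vmax_p.value),
            vmax_se=float(vmax_p.stderr) if vmax_p.stderr is not None else float("nan"),
            km_mm=float(km_p.value),
            km_se=float(km_p.stderr) if km_p.stderr is not None else float("nan"),
            native_molar_mass=mass,
        )


@dataclass(frozen=True)
class MichaelisMentenResults:
    """Michaelis-Menten fit with derived turnover numbers.

    kcat (1/s) = Vmax [umol/(min mg)] * M [g/mol] * 1e-3 / 60 — one mg of
    enzyme is 1e-3/M mol, so the per-mg rate of 1e-6*Vmax/60 mol/s becomes
    Vmax*M*1e-3/60 per enzyme per second.  kcat/Km in 1/(M s) uses Km
    converted from mM to M.
    """

    model: MichaelisMentenModel
    vmax: float  # U/mg
    vmax_se: float
    km_mm: float  # mmol/L
    km_se: float
    native_molar_mass: float  # g/mol

    @property
    def kcat(self) -> float:
        return self.vmax * self.native_molar_mass * 1e-3 / 60.0

    @property
    def kcat_over_km(self) -> float:
        return self.kcat / (self.km_mm * 1e-3)

    def predict(self, substrate_mm) -> np.ndarray:
        return _mm(np.asarray(substrate_mm, dtype=float), self.vmax, self.km_mm)

    def summary(self) -> str:
        return "\n".join(
            [
                "Michaelis-Menten fit",
                f"  n points:  {self.model.substrate_mm.size}",
                f"  Vmax:      {self.vmax:.4g} U/mg (SE {self.vmax_se:.2g})",
                f"  Km:        {self.km_mm:.4g} mM (SE {self.km_se:.2g})",
                f"  M (native):{self.native_molar_mass:.6g} g/mol",
                f"  kcat:      {self.kcat:.4g} 1/s",
                f"  kcat/Km:   {self.kcat_over_km:.3g} 1/(M s)",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.substrate_mm
        ax.plot(s, self.model.rates, "o", label="data")
        grid = np.linspace(0, s.max(), 200)
        ax.plot(grid, self.predict(grid), "-", label="fit")
        ax.set_xlabel("substrate (mM)")
        ax.set_ylabel("rate (U/mg)")
        ax.legend()
        return ax
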