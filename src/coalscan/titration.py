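"""Active-site cysteine pKa from pH-activity titration; free-thiol counting.

The alkylation-protection titration exploits that only the thiolate form of
a cysteine reacts with iodoacetamide: incubating the enzyme with IAM across
a pH series and then assaying residual activity traces the thiolate
fraction, giving a descending sigmoid

    R(pH) = bottom + (top - bottom) / (1 + 10**(pH - pKa)),

a rearrangement of the Henderson-Hasselbalch relation for a single ionizing
thiol (Hill coefficient fixed at 1).  Free thiols are counted by Ellman's
assay: DTNB releases TNB2- absorbing at 412 nm (epsilon = 14 150 M-1 cm-1),
so thiols per subunit follow from Beer-Lambert at known subunit
concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lmfit import Model as _LmfitModel

__all__ = [
    "EPSILON_412",
    "TitrationPoint",
    "ThiolTitrationModel",
    "PKaResults",
    "thiols_per_subunit",
]

#: TNB2- molar absorptivity at 412 nm, 1/(M cm).
EPSILON_412 = 14150.0


@dataclass(frozen=True)
class TitrationPoint:
    """Residual activity (% of no-IAM maximum) at one pH."""

    ph: float
    residual_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError("pH outside 0..14")
        if self.residual_pct < 0:
            raise ValueError("residual activity must be >= 0")


def _sigmoid(ph, pka, top, bottom):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (ph - pka))


class ThiolTitrationModel:
    """Single-site sigmoid model of an IAM-protection titration.

    ``fit`` defaults to fixing the top plateau at 100% (activities are
    already normalised to the no-IAM maximum) with the bottom free; pass
    ``fix_top=None`` to free it.
    """

    def __init__(self, points: Sequence[TitrationPoint]):
        if len(points) < 5:
            raise ValueError("need at least 5 titration points")
        pts = sorted(points, key=lambda p: p.ph)
        self.ph = np.asarray([p.ph for p in pts], dtype=float)
        self.residual = np.asarray([p.residual_pct for p in pts], dtype=float)

    def fit(self, fix_top: float | None = 100.0) -> "PKaResults":
        ph, r = self.ph, self.residual
        span = r.max() - r.min()
        if span < 5.0:
            raise ValueError(
                "no titration transition in the sampled pH range "
                f"(activity span {span:.1f} points)"
            )
        # initial pKa: pH nearest the half-fall
        half = (r.max() + r.min()) / 2.0
        pka0 = float(ph[np.argmin(np.abs(r - half))])
        lm = _LmfitModel(_sigmoid)
        params = lm.make_params(
            pka=pka0, top=float(r.max()), bottom=float(r.min())
        )
        if fix_top is not None:
            params["top"].set(value=fix_top, vary=False)
        out = lm.fit(r, params, ph=ph)
        p = out.params
        pka = float(p["pka"].value)
        if not ph.min() <= pka <= ph.max():
            warnings.warn(
                f"fitted pKa {pka:.2f} lies outside the sampled pH range",
                stacklevel=2,
            )
        def _se(name):
            s = p[name].stderr
            return float(s) if s is not None else float("nan")

        return PKaResults(
            model=self,
            pka=pka,
            pka_se=_se("pka"),
            top=float(p["top"].value),
            top_se=_se("top") if fix_top is None else 0.0,
            bottom=float(p["bottom"].value),
            bottom_se=_se("bottom"),
        )


@dataclass(frozen=True)
class PKaResults:
    """Sigmoid titration fit: pKa and the two plateaus with SEs."""

    model: ThiolTitrationModel
    pka: float
    pka_se: float
    top: float
    top_se: float
    bottom: float
    bottom_se: float

    def __post_init__(self) -> None:
        if self.top <= self.bottom:
            raise ValueError("top plateau must exceed bottom plateau")

    def predict(self, ph) -> np.ndarray:
        return _sigmoid(np.asarray(ph, dtype=float), self.pka, self.top, self.bottom)

    def summary(self) -> str:
        return "\n".join(
            [
                "Cysteine pKa titration fit (single-site sigmoid)",
                f"  n points: {self.model.ph.size}",
                f"  pKa:      {self.pka:.3f} (SE {self.pka_se:.2g})",
                f"  top:      {self.top:.4g} % (SE {self.top_se:.2g})",
                f"  bottom:   {self.bottom:.4g} % (SE {self.bottom_se:.2g})",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.ph, self.model.residual, "o", label="data")
        grid = np.linspace(self.model.ph.min(), self.model.ph.max(), 200)
        ax.plot(grid, self.predict(grid), "-", label="fit")
        ax.set_xlabel("pH")
        ax.set_ylabel("residual activity (%)")
        ax.legend()
        return ax


def thiols_per_subunit(
    a412: float,
    subunit_conc_m: float,
    epsilon: float = EPSILON_412,
    path_cm: float = 1.0,
) -> float:
    """Free thiols per subunit from DTNB absorbance (Beer-Lambert)."""
    if a412 < 0:
        raise ValueError("absorbance must be >= 0")
    if subunit_conc_m <= 0:
        raise ValueError("subunit concentration must be positive")
    return a412 / (epsilon * path_cm * subunit_conc_m)
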