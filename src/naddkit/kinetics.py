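"""Michaelis–Menten kinetics fitting and catalytic-efficiency reporting.

Unit contract (documented once, applied everywhere):

* substrate concentrations S and the Michaelis constant KM are in mM;
* initial rates v are in µM product per second;
* the enzyme concentration E0 is in µM;

so Vmax is in µM/s, kcat = Vmax / E0 is in 1/s, and the catalytic
efficiency kcat / KM is in 1/(mM*s).

The fit is nonlinear least squares on v = Vmax * S / (KM + S)
(no substrate inhibition or Hill variants), seeded by a Hanes–Woolf
linearisation (S/v regressed on S).  By default residuals carry relative
(1/v) weights — the efficient estimator when the measurement error has a
roughly constant coefficient of variation, as chromatographic peak areas
do; unweighted fitting is available.  Standard errors come from the
covariance matrix of the fit; the efficiency SE uses first-order error
propagation treating KM and kcat as independent.

Report rounding follows enzyme-table convention: KM, kcat and efficiencies
to three significant figures, substrate-preference ratios to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._util import round_half_away, round_sig


@dataclass
class KineticDataset:
    """Initial-rate measurements for one substrate."""

    substrate: str
    concentrations_mM: np.ndarray
    rates: np.ndarray  # µM/s
    enzyme_uM: float
    replicates: Optional[np.ndarray] = None

    def __post_init__(self):
        self.concentrations_mM = np.asarray(self.concentrations_mM, float)
        self.rates = np.asarray(self.rates, float)
        if self.concentrations_mM.shape != self.rates.shape:
            raise ValueError("concentrations and rates differ in length")
        if np.any(self.concentrations_mM <= 0):
            raise ValueError("substrate concentrations must be positive")
        if np.any(self.rates < 0):
            raise ValueError("initial rates must be non-negative")
        if len(np.unique(self.concentrations_mM)) < 4:
            raise ValueError("need at least four distinct substrate concentrations")
        if self.enzyme_uM <= 0:
            raise ValueError("enzyme concentration must be positive")

    @classmethod
    def from_csv(cls, path, enzyme_uM: float, substrate: str = "") -> "KineticDataset":
        """Read a CSV with columns substrate_mM, rate[, replicate]."""
        df = pd.read_csv(path)
        required = {"substrate_mM", "rate"}
        if not required <= set(df.columns):
            raise ValueError("kinetics CSV requires columns substrate_mM and rate")
        reps = df["replicate"].to_numpy() if "replicate" in df.columns else None
        return cls(
            substrate=substrate,
            concentrations_mM=df["substrate_mM"].to_numpy(float),
            rates=df["rate"].to_numpy(float),
            enzyme_uM=enzyme_uM,
            replicates=reps,
        )


@dataclass
class MMFit:
    """Fitted Michaelis–Menten parameters with standard errors."""

    substrate: str
    km_mM: float
    km_se: float
    vmax: float  # µM/s
    vmax_se: float
    kcat: float  # 1/s
    kcat_se: float
    efficiency: float  # 1/(mM*s)
    efficiency_se: float
    enzyme_uM: float

    def as_dict(self) -> dict:
        return {
            "substrate": self.substrate,
            "km_mM": self.km_mM,
            "km_se": self.km_se,
            "vmax_uM_per_s": self.vmax,
            "vmax_se": self.vmax_se,
            "kcat_per_s": self.kcat,
            "kcat_se": self.kcat_se,
            "efficiency_per_mM_s": self.efficiency,
            "efficiency_se": self.efficiency_se,
            "enzyme_uM": self.enzyme_uM,
        }


def initial_rate(
    time_points: Sequence[float],
    signal: Sequence[float],
    window: Optional[tuple] = None,
) -> float:
    """Least-squares slope of signal vs time over the stated linear window."""
    t = np.asarray(time_points, float)
    y = np.asarray(signal, float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, y = t[mask], y[mask]
    if len(t) < 3:
        raise ValueError("need at least three points in the rate window")
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(dataset: KineticDataset, weighting: str = "relative") -> MMFit:
    """Nonlinear least-squares Michaelis–Menten fit.

    Initial values come from a Hanes–Woolf linearisation; raises on
    non-convergence or a non-positive KM estimate.

    `weighting` selects the error model: ``"relative"`` (default) weights
    residuals by 1/v, the efficient choice when measurement error scales
    with the signal (the usual situation for chromatographic peak areas);
    ``"none"`` is ordinary unweighted least squares.
    """
    if weighting not in ("relative", "none"):
        raise ValueError("weighting must be 'relative' or 'none'")
    s = dataset.concentrations_mM
    v = dataset.rates
    if np.all(v == 0):
        raise ValueError("all rates are zero; nothing to fit")

    pos = v > 0
    if pos.sum() >= 2:
        # Hanes: S/v = S/Vmax + KM/Vmax
        slope, intercept = np.polyfit(s[pos], s[pos] / v[pos], 1)
        vmax0 = 1.0 / slope if slope > 0 else float(v.max())
        km0 = intercept * vmax0 if intercept * vmax0 > 0 else float(np.median(s))
    else:
        vmax0, km0 = float(v.max()), float(np.median(s))

    sigma = None
    if weighting == "relative":
        floor = 1e-6 * float(v.max())
        sigma = np.maximum(v, floor)
    try:
        popt, pcov = curve_fit(
            _mm, s, v, p0=(vmax0, km0), sigma=sigma, maxfev=10000,
            bounds=((0.0, 0.0), (np.inf, np.inf)),
        )
    except RuntimeError as exc:
        raise ValueError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    if km <= 0:
        raise ValueError("fitted KM is non-positive")
    vmax_se, km_se = (float(x) for x in np.sqrt(np.diag(pcov)))

    kcat = vmax / dataset.enzyme_uM
    kcat_se = vmax_se / dataset.enzyme_uM
    eff = kcat / km
    eff_se = (
        eff * np.hypot(kcat_se / kcat, km_se / km) if kcat > 0 else float("nan")
    )
    return MMFit(
        substrate=dataset.substrate,
        km_mM=km,
        km_se=km_se,
        vmax=vmax,
        vmax_se=vmax_se,
        kcat=kcat,
        kcat_se=kcat_se,
        efficiency=eff,
        efficiency_se=float(eff_se),
        enzyme_uM=dataset.enzyme_uM,
    )


FitOrValue = Union[MMFit, float]


def catalytic_efficiency(kcat: FitOrValue, km_mM: Optional[float] = None) -> float:
    """kcat/KM in 1/(mM*s), rounded to three significant figures.

    Accepts either an :class:`MMFit` or the (kcat, KM) component values as
    printed in a report table.
    """
    if isinstance(kcat, MMFit):
        value = kcat.kcat / kcat.km_mM
    else:
        if km_mM is None:
            raise ValueError("km_mM required when kcat is a plain number")
        if km_mM == 0:
            raise ZeroDivisionError("KM must be non-zero")
        value = kcat / km_mM
    return round_sig(value, 3)


def efficiency_ratio(fit_or_eff_a: FitOrValue, fit_or_eff_b: FitOrValue) -> float:
    """Ratio of catalytic efficiencies (e.g. NAD+/NADH), two decimals."""
    a = fit_or_eff_a.efficiency if isinstance(fit_or_eff_a, MMFit) else float(fit_or_eff_a)
    b = fit_or_eff_b.efficiency if isinstance(fit_or_eff_b, MMFit) else float(fit_or_eff_b)
    if b == 0:
        raise ZeroDivisionError("denominator efficiency is zero")
    return round_half_away(a / b, 2)
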