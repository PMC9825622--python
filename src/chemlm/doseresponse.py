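"""Hill-model dose-response fitting for equilibrium binding assays.

The response of an 11-point three-fold serial dilution is modelled with
the Hill equation at a fixed slope of -1::

    Response = Background + (Signal - Background) / (1 + Dose/Kd)

so the response passes through the midpoint (Background+Signal)/2 exactly
at Dose = Kd.  Parameters (Kd, Background, Signal) are estimated by
unweighted nonlinear least squares with the Levenberg-Marquardt
algorithm.  Doses are molar internally.

The module follows the model/results split common in statistical
packages: :class:`HillCurveModel` holds the data, ``fit()`` returns a
:class:`HillCurveResults` with estimates, standard errors, residual sum
of squares and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitDiverged, InsufficientData, NonPositiveDose

HILL_SLOPE = -1.0


def hill_response(dose, Kd: float, background: float,
                  signal: float) -> np.ndarray | float:
    """Hill binding curve at slope -1 (note Kd^s/Dose^s = Dose/Kd there)."""
    dose = np.asarray(dose, dtype=np.float64)
    if np.any(dose <= 0):
        raise NonPositiveDose("doses must be > 0")
    if Kd <= 0:
        raise ValueError(f"Kd must be > 0, got {Kd}")
    out = background + (signal - background) / (1.0 + dose / Kd)
    return float(out) if out.ndim == 0 else out


def serial_dilution(top_dose: float, n_points: int = 11,
                    factor: float = 3.0) -> np.ndarray:
    """Descending n-point serial dilution (default 11-point three-fold)."""
    return top_dose / factor ** np.arange(n_points)


def simulate_curve(Kd: float, background: float, signal: float,
                   top_dose: float = 30e-6, n_points: int = 11,
                   factor: float = 3.0, noise_sd: float = 0.0,
                   seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Generate (doses, responses) from the Hill model, optionally noisy.

    The default titration is an 11-point three-fold dilution from 30 uM
    (0.5 nM - 30 uM), the range used by commercial kinase-binding panels
    for sub-micromolar Kd values.  ``noise_sd`` is a proportional Gaussian
    coefficient of variation: each response is perturbed by
    ``N(0, noise_sd * response)``, matching the multiplicative error of
    plate-readout assays.
    """
    doses = serial_dilution(top_dose, n_points, factor)
    resp = hill_response(doses, Kd, background, signal)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp * (1.0 + rng.normal(0.0, noise_sd, size=resp.shape))
    return doses, resp


@dataclass
class HillCurveResults:
    """Fitted Hill curve: estimates, uncertainties and diagnostics."""

    Kd: float
    background: float
    signal: float
    rss: float
    bse: np.ndarray                    # standard errors (Kd, bg, signal)
    doses: np.ndarray = field(repr=False, default=None)
    responses: np.ndarray = field(repr=False, default=None)
    hill_slope: float = HILL_SLOPE

    def predict(self, dose) -> np.ndarray | float:
        return hill_response(dose, self.Kd, self.background, self.signal)

    def to_dict(self) -> dict:
        return {"Kd_M": self.Kd, "Kd_nM": self.Kd * 1e9,
                "background": self.background, "signal": self.signal,
                "hill_slope": self.hill_slope, "rss": self.rss}

    def summary(self) -> str:
        lines = [
            "Hill dose-response fit (slope fixed at -1)",
            "-" * 44,
            f"{'Kd':<12}{self.Kd:>14.6g} M  (se {self.bse[0]:.3g})",
            f"{'background':<12}{self.background:>14.6g}    "
            f"(se {self.bse[1]:.3g})",
            f"{'signal':<12}{self.signal:>14.6g}    (se {self.bse[2]:.3g})",
            f"{'RSS':<12}{self.rss:>14.6g}",
            f"{'n points':<12}{len(self.doses):>14d}",
        ]
        return "\n".join(lines)


class HillCurveModel:
    """Dose-response data plus the fixed-slope Hill model.

    Parameters
    ----------
    doses : positive molar concentrations
    responses : assay signal at each dose
    """

    def __init__(self, doses, responses):
        self.doses = np.asarray(doses, dtype=np.float64)
        self.responses = np.asarray(responses, dtype=np.float64)
        if np.any(self.doses <= 0):
            raise NonPositiveDose("doses must be > 0")
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses differ in length")
        if len(self.doses) < 4:
            raise InsufficientData("need >= 4 dose points")

    @classmethod
    def from_dataframe(cls, df, dose_col: str = "dose_nM",
                       response_col: str = "response") -> "HillCurveModel":
        """Build from a table with doses in nM (converted to molar)."""
        return cls(np.asarray(df[dose_col], dtype=np.float64) * 1e-9,
                   np.asarray(df[response_col], dtype=np.float64))

    def default_init(self) -> tuple[float, float, float]:
        """Robust starting values: background=min, signal=max, Kd at the
        dose nearest the half-range crossing."""
        background = float(self.responses.min())
        signal = float(self.responses.max())
        half = 0.5 * (background + signal)
        kd0 = float(self.doses[np.argmin(np.abs(self.responses - half))])
        return kd0, background, signal

    def fit(self, init: tuple[float, float, float] | None = None
            ) -> HillCurveResults:
        """Levenberg-Marquardt least squares; deterministic given init."""
        if np.ptp(self.responses) == 0:
            raise FitDiverged("constant responses: Kd unidentifiable")
        p0 = np.asarray(init if init is not None else self.default_init(),
                        dtype=np.float64)
        # fit log10(Kd) so the dose scale is unconstrained and positive
        def f(dose, log_kd, background, signal):
            return hill_response(dose, 10.0 ** log_kd, background, signal)

        try:
            popt, pcov = curve_fit(
                f, self.doses, self.responses,
                p0=[np.log10(p0[0]), p0[1], p0[2]],
                method="lm", maxfev=20000)
        except RuntimeError as e:
            raise FitDiverged(str(e)) from None
        kd = float(10.0 ** popt[0])
        resid = self.responses - f(self.doses, *popt)
        rss = float(resid @ resid)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(pcov))
        # delta method: se(Kd) = ln(10) * Kd * se(log10 Kd)
        bse = np.array([np.log(10.0) * kd * se[0], se[1], se[2]])
        if not np.isfinite(kd) or kd <= 0:
            raise FitDiverged("Kd estimate not identifiable")
        return HillCurveResults(
            Kd=kd, background=float(popt[1]), signal=float(popt[2]),
            rss=rss, bse=bse, doses=self.doses, responses=self.responses)


def fit_kd(doses, responses,
           init: tuple[float, float, float] | None = None
           ) -> HillCurveResults:
    """Convenience wrapper around :class:`HillCurveModel`."""
    return HillCurveModel(doses, responses).fit(init=init)
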