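"""Growth-rate drug-sensitivity scoring.

Converts raw luminescence plate readouts (CellTiter-Glo-style ATP assays)
into exponential growth rates, mu/mu.max dose-response curves, fitted-curve
AUC, sensitivity categories, GI75 calls, and caspase fold-inductions.

The central quantity is the growth rate

    mu = ln((Tend - blank) / (T0 - blank)) / time

where T0 and Tend are ATP-normalized signals at the start and end of the
assay and blank is the cell-free background.  mu is divided by the mean
DMSO-control growth rate (mu.max) to give mu/mu.max: 1 means no drug
effect, 0 means complete growth arrest, and negative values mean net cell
loss (cytotoxicity).  A four-parameter log-logistic curve is fit to
mu/mu.max against log10 dose and its integral over the tested dose range
(the AUC, in (mu/mu.max)*decades) summarizes sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize


class CalibrationError(ValueError):
    """Raised when an ATP standard curve cannot be fit."""


@dataclass(frozen=True)
class ATPStandardCurve:
    """Linear luminescence-vs-ATP calibration: signal = slope*atp + intercept."""

    slope: float
    intercept: float

    def to_atp(self, signal: float | np.ndarray) -> float | np.ndarray:
        """Invert the calibration, clamping negative ATP values to 0."""
        atp = (np.asarray(signal, dtype=float) - self.intercept) / self.slope
        if np.any(atp < 0):
            warnings.warn(
                "signal below calibration intercept; ATP clamped to 0",
                stacklevel=2,
            )
        atp = np.clip(atp, 0.0, None)
        return float(atp) if atp.ndim == 0 else atp


@dataclass(frozen=True)
class WellMeasurement:
    """One plate well: signal at a timepoint with its role and treatment.

    role is one of {"sample", "blank", "standard", "dmso_control"};
    timepoint_h is hours from assay start (0 for T0 wells); conc_um is the
    drug concentration in micromolar (0 for DMSO controls and blanks).
    """

    well_id: str
    role: str
    timepoint_h: float
    signal: float
    drug: str | None = None
    conc_um: float = 0.0

    def __post_init__(self):
        if self.signal < 0:
            raise ValueError(f"negative signal in well {self.well_id}")
        if self.conc_um < 0:
            raise ValueError(f"negative concentration in well {self.well_id}")


@dataclass(frozen=True)
class GrowthRate:
    mu: float
    mu_max: float

    @property
    def ratio(self) -> float:
        return self.mu / self.mu_max


@dataclass
class SigmoidFit:
    """Four-parameter log-logistic fit of mu/mu.max against log10 dose.

    r(x) = bottom + (top - bottom) / (1 + 10**(hill * (log_ec50 - x)))

    With hill < 0 the curve falls from `top` at low dose to `bottom` at
    high dose (the usual shape for a growth inhibitor).  When the
    nonlinear fit fails, ``converged`` is False and ``predict`` falls back
    to monotone piecewise-linear interpolation of the dose-averaged
    ratios stored on the fit.
    """

    bottom: float
    top: float
    log_ec50: float
    hill: float
    converged: bool
    residual_rms: float
    log_doses: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_ratios: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, log_dose: float | np.ndarray) -> np.ndarray:
        x = np.asarray(log_dose, dtype=float)
        if self.converged:
            return four_param_logistic(x, self.bottom, self.top, self.log_ec50, self.hill)
        return np.interp(x, self.log_doses, self.mean_ratios)

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50


@dataclass(frozen=True)
class SensitivityResult:
    auc: float
    category: str
    thresholds: tuple[float, float] = (2.0, 9.0)


@dataclass(frozen=True)
class GI75Result:
    """GI75: dose causing a 75% reduction in endpoint signal vs DMSO."""

    gi75: float | None
    sensitive_call: bool
    cutoff_um: float = 2.0


def four_param_logistic(x, bottom, top, log_ec50, hill):
    """Evaluate the 4PL curve at log10 dose x."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - x)))


def fit_atp_standard(points) -> ATPStandardCurve:
    """Least-squares linear calibration from (atp, luminescence) pairs.

    Raises CalibrationError for fewer than two points, degenerate points,
    or a nonpositive slope.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise CalibrationError("ATP standard curve needs >= 2 points")
    atp, lum = pts[:, 0], pts[:, 1]
    if np.ptp(lum) == 0 or np.ptp(atp) == 0:
        raise CalibrationError("degenerate ATP standard points")
    slope, intercept = np.polyfit(atp, lum, 1)
    if slope <= 0:
        raise CalibrationError(f"nonpositive calibration slope {slope:g}")
    return ATPStandardCurve(slope=float(slope), intercept=float(intercept))


def normalize_readout(wells, curve: ATPStandardCurve) -> list[WellMeasurement]:
    """Map sample/blank/control well signals through the inverse calibration.

    Standard wells are passed through untouched; roles and annotations are
    preserved.  Signals below the calibration intercept clamp to 0 ATP with
    a warning.
    """
    out = []
    for w in wells:
        if w.role == "standard":
            out.append(w)
            continue
        out.append(
            WellMeasurement(
                well_id=w.well_id,
                role=w.role,
                timepoint_h=w.timepoint_h,
                signal=curve.to_atp(w.signal),
                drug=w.drug,
                conc_um=w.conc_um,
            )
        )
    return out


def compute_mu(
    t0_signal: float,
    tend_signal: float,
    blank: float,
    time_h: float,
    floor_ratio: float = 0.01,
) -> float:
    """Exponential growth rate mu = ln((Tend-blank)/(T0-blank))/time.

    Negative when the culture shrank.  If the endpoint signal falls at or
    below blank (complete kill), mu is floored at ln(floor_ratio)/time and
    a warning is emitted.  A T0 signal at or below blank is an input error.
    """
    if time_h <= 0:
        raise ValueError("time must be positive")
    net0 = t0_signal - blank
    if net0 <= 0:
        raise ValueError("T0 signal does not exceed blank")
    net_end = tend_signal - blank
    if net_end <= net0 * floor_ratio:
        if net_end <= 0:
            warnings.warn(
                "Tend signal at or below blank; mu floored (complete kill)",
                stacklevel=2,
            )
        return float(np.log(floor_ratio) / time_h)
    return float(np.log(net_end / net0) / time_h)


def mu_ratio(mu_drug: float, mu_dmso_wells) -> GrowthRate:
    """mu/mu.max with mu.max = mean growth rate of the DMSO replicates."""
    mu_max = float(np.mean(np.asarray(mu_dmso_wells, dtype=float)))
    if mu_max <= 0:
        raise ValueError("no growth in DMSO controls (mu.max <= 0)")
    return GrowthRate(mu=float(mu_drug), mu_max=mu_max)


def fit_sigmoid(concentrations_um, ratios) -> SigmoidFit:
    """Fit the 4PL log-logistic to mu/mu.max vs log10([drug]).

    Requires >= 4 distinct nonzero concentrations; replicate ratios are
    allowed and averaged per dose for the non-convergence fallback curve.
    `top` is bounded to [0.5, 1.5]; `bottom` is unconstrained below zero so
    cytotoxic responses (mu/mu.max < 0) are representable.
    """
    conc = np.asarray(concentrations_um, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if conc.shape != y.shape:
        raise ValueError("concentrations and ratios must align")
    mask = conc > 0
    conc, y = conc[mask], y[mask]
    distinct = np.unique(conc)
    if distinct.size < 4:
        raise ValueError("need >= 4 distinct nonzero concentrations")
    x = np.log10(conc)

    # dose-averaged profile, used for initialization and as fallback
    xs = np.log10(distinct)
    means = np.array([y[conc == c].mean() for c in distinct])

    top0 = float(np.clip(means[0], 0.5, 1.5))
    bottom0 = float(means[-1])
    mid0 = float(xs[np.argmin(np.abs(means - (top0 + bottom0) / 2))])
    p0 = [bottom0, top0, mid0, -1.0]
    bounds = ([-10.0, 0.5, xs[0] - 3, -20.0], [1.5, 1.5, xs[-1] + 3, 20.0])

    converged = True
    try:
        popt, _ = optimize.curve_fit(
            four_param_logistic, x, y, p0=p0, bounds=bounds, maxfev=20000
        )
        resid = y - four_param_logistic(x, *popt)
        rms = float(np.sqrt(np.mean(resid**2)))
    except RuntimeError:
        converged = False
        popt = p0
        rms = float("nan")

    # enforce monotone fallback profile (isotonic in the direction of the trend)
    order = np.argsort(xs)
    return SigmoidFit(
        bottom=float(popt[0]),
        top=float(popt[1]),
        log_ec50=float(popt[2]),
        hill=float(popt[3]),
        converged=converged,
        residual_rms=rms,
        log_doses=xs[order],
        mean_ratios=means[order],
    )


def compute_auc(fit: SigmoidFit, log_range: tuple[float, float], n_grid: int = 1001) -> float:
    """Trapezoid integral of the fitted curve over [lo, hi] log10 dose.

    Units: (mu/mu.max) * log10-decades.  The grid is fixed at 1001 points.
    """
    lo, hi = log_range
    if not lo < hi:
        raise ValueError("log_range must satisfy lo < hi")
    grid = np.linspace(lo, hi, n_grid)
    return float(np.trapezoid(fit.predict(grid), grid))


def classify_sensitivity(auc: float, thresholds: tuple[float, float] = (2.0, 9.0)) -> SensitivityResult:
    """Categorize an AUC: < low -> sensitive, > high -> insensitive, else moderate.

    Boundary values land in the moderate band.
    """
    low, high = thresholds
    if not np.isfinite(auc):
        raise ValueError("AUC must be finite")
    if auc < low:
        cat = "sensitive"
    elif auc > high:
        cat = "insensitive"
    else:
        cat = "moderate"
    return SensitivityResult(auc=float(auc), category=cat, thresholds=thresholds)


def classify_panel(aucs, thresholds: tuple[float, float] = (2.0, 9.0)) -> dict[str, int]:
    """Category counts over a panel of AUC values."""
    counts = {"sensitive": 0, "moderate": 0, "insensitive": 0}
    for a in np.asarray(aucs, dtype=float):
        counts[classify_sensitivity(a, thresholds).category] += 1
    return counts


def compute_gi75(concentrations_um, viability_fractions, cutoff_um: float = 2.0) -> GI75Result:
    """Dose at which endpoint viability falls to 25% of the DMSO control.

    Interpolates fraction against log10 concentration piecewise-linearly
    between tested doses; no extrapolation beyond the tested range.  If the
    lowest tested dose is already at or below 0.25, that dose is returned.
    Returns gi75=None when the 0.25 level is never reached.
    """
    conc = np.asarray(concentrations_um, dtype=float)
    frac = np.asarray(viability_fractions, dtype=float)
    if conc.size < 2:
        raise ValueError("need >= 2 doses")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    order = np.argsort(conc)
    conc, frac = conc[order], frac[order]
    target = 0.25

    if frac[0] <= target:
        gi75 = float(conc[0])
        return GI75Result(gi75=gi75, sensitive_call=gi75 < cutoff_um, cutoff_um=cutoff_um)

    logc = np.log10(conc)
    for i in range(len(conc) - 1):
        if frac[i] > target >= frac[i + 1]:
            t = (frac[i] - target) / (frac[i] - frac[i + 1])
            gi75 = float(10.0 ** (logc[i] + t * (logc[i + 1] - logc[i])))
            return GI75Result(gi75=gi75, sensitive_call=gi75 < cutoff_um, cutoff_um=cutoff_um)
    return GI75Result(gi75=None, sensitive_call=False, cutoff_um=cutoff_um)


def normalize_caspase(signal, background, dmso_signal, dmso_background) -> float:
    """Caspase fold-induction over the DMSO control after background subtraction."""
    net_dmso = dmso_signal - dmso_background
    if net_dmso <= 0:
        raise ValueError("nonpositive DMSO net signal")
    return float((signal - background) / net_dmso)


def score_plate(plate, standards=None, floor_ratio: float = 0.01):
    """Score a whole plate table into per-well mu/mu.max ratios.

    Parameters
    ----------
    plate : pandas.DataFrame
        Columns well_id, role, timepoint_h, signal, drug, conc_um.  T0
        wells (timepoint_h == min) are the shared untreated baseline;
        blank wells give the cell-free background; dmso_control wells at
        the endpoint define mu.max.
    standards : pandas.DataFrame, optional
        Columns atp, luminescence.  When given, all signals are mapped to
        ATP units through the fitted standard curve first.

    Returns
    -------
    pandas.DataFrame with one row per treated endpoint well: drug,
    conc_um, mu, ratio; plus attrs {"mu_max": float, "time_h": float}.
    """
    import pandas as pd

    df = plate.copy()
    if standards is not None:
        curve = fit_atp_standard(standards[["atp", "luminescence"]].to_numpy())
        df["signal"] = curve.to_atp(df["signal"].to_numpy())

    t0 = df["timepoint_h"].min()
    tend = df["timepoint_h"].max()
    if not tend > t0:
        raise ValueError("plate needs two timepoints")
    time_h = tend - t0

    blank = df.loc[df.role == "blank", "signal"].mean()
    baseline = df.loc[
        (df.role.isin(["sample", "dmso_control"])) & (df.timepoint_h == t0), "signal"
    ].mean()

    dmso_end = df.loc[(df.role == "dmso_control") & (df.timepoint_h == tend), "signal"]
    if dmso_end.empty:
        raise ValueError("no DMSO endpoint wells")
    mu_dmso = [compute_mu(baseline, s, blank, time_h, floor_ratio) for s in dmso_end]
    mu_max = float(np.mean(mu_dmso))
    if mu_max <= 0:
        raise ValueError("no growth in DMSO controls (mu.max <= 0)")

    treated = df.loc[(df.role == "sample") & (df.timepoint_h == tend)]
    rows = []
    for _, w in treated.iterrows():
        mu = compute_mu(baseline, w.signal, blank, time_h, floor_ratio)
        rows.append(
            {
                "well_id": w.well_id,
                "drug": w.drug,
                "conc_um": w.conc_um,
                "mu": mu,
                "ratio": mu / mu_max,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["mu_max"] = mu_max
    out.attrs["time_h"] = time_h
    return out


def score_dose_response(scored, thresholds: tuple[float, float] = (2.0, 9.0)):
    """Fit, integrate and classify a scored plate's dose-response.

    `scored` is the per-well frame from :func:`score_plate`.  Returns
    (SigmoidFit, SensitivityResult); the AUC domain is the tested log-dose
    range.
    """
    conc = scored["conc_um"].to_numpy(dtype=float)
    ratios = scored["ratio"].to_numpy(dtype=float)
    fit = fit_sigmoid(conc, ratios)
    pos = conc[conc > 0]
    log_range = (float(np.log10(pos.min())), float(np.log10(pos.max())))
    auc = compute_auc(fit, log_range)
    return fit, classify_sensitivity(auc, thresholds)
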