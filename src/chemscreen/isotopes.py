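"""Stable-isotope tracing analytics.

Natural-abundance correction of mass isotopomer distributions (MIDs),
labeled-fraction readouts (e.g. cholesterol m+2 from a 13C2-acetate
trace), labeling-inhibition IC50 fits, and IRMS delta-to-atom-percent
conversion for D2O labeling.

The correction is the standard matrix deconvolution: the observed
intensity vector is modelled as M @ x where column j of M is the mass
shift distribution of a molecule carrying exactly j tracer-labeled
atoms — a binomial over the remaining tracer-element atoms convolved
with the aggregate natural-isotope shift distribution of every other
element in the formula.  x is recovered by nonnegative least squares
and renormalized to a fractional distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyteomics.mass import Composition
from scipy.optimize import nnls

# Per-atom probabilities of heavy-isotope mass shifts (IUPAC natural
# abundances); index = mass shift in Da relative to the monoisotopic atom.
DEFAULT_ABUNDANCES: dict[str, list[float]] = {
    "C": [1 - 0.0107, 0.0107],
    "H": [1 - 0.000156, 0.000156],
    "N": [1 - 0.00364, 0.00364],
    "O": [1 - 0.00038 - 0.00205, 0.00038, 0.00205],
    "S": [0.9499, 0.0075, 0.0425, 0.0, 0.0001],
    "P": [1.0],  # monoisotopic
}

VSMOW_D_TO_H = 155.76e-6


def parse_formula(formula) -> dict[str, int]:
    """Element counts from a Hill-notation formula string (or a dict passthrough)."""
    if isinstance(formula, dict):
        return {k: int(v) for k, v in formula.items() if v}
    return {k: int(v) for k, v in Composition(formula=str(formula)).items()}


@dataclass
class IsotopomerDistribution:
    """m+0 ... m+n intensity or fraction vector for one species.

    kind is "raw_intensity" for instrument output and
    "corrected_fraction" after natural-abundance correction (then the
    values sum to 1).
    """

    values: np.ndarray
    kind: str = "raw_intensity"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("isotopomer vector must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("negative isotopomer values")
        if self.kind == "corrected_fraction" and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("corrected fractions must sum to 1")

    def __len__(self) -> int:
        return len(self.values)


def _element_shift_distribution(element: str, count: int, abundances) -> np.ndarray:
    """Mass-shift distribution of `count` atoms of one element (full support)."""
    per_atom = np.asarray(abundances[element], dtype=float)
    dist = np.array([1.0])
    # exponentiation by squaring on the convolution monoid
    base = per_atom
    k = count
    while k:
        if k & 1:
            dist = np.convolve(dist, base)
        k >>= 1
        if k:
            base = np.convolve(base, base)
    return dist


def _truncate_fold(dist: np.ndarray, n: int) -> np.ndarray:
    """Truncate a shift distribution at m+n, folding heavier mass into the last bin."""
    out = np.zeros(n + 1)
    m = min(len(dist), n + 1)
    out[:m] = dist[:m]
    if len(dist) > n + 1:
        out[n] += dist[n + 1 :].sum()
    return out


def build_correction_matrix(
    formula, tracer: str = "C", abundances: dict | None = None
) -> np.ndarray:
    """(n+1)x(n+1) natural-abundance matrix for a tracer element.

    n is the tracer-atom count of the formula.  Entry (i, j) is the
    probability that a molecule with exactly j tracer-labeled atoms is
    observed at mass m+i: the j labeled atoms contribute a fixed +j
    shift, the remaining n-j tracer atoms a binomial over the tracer
    element's heavy-isotope probability, and every non-tracer atom its
    own natural shift distribution.  Shifts beyond m+n are folded into
    the m+n bin, so columns sum to 1.
    """
    counts = parse_formula(formula)
    abund = dict(DEFAULT_ABUNDANCES)
    if abundances:
        abund.update(abundances)
    if tracer not in abund:
        raise ValueError(f"unknown tracer element {tracer!r}")
    unknown = set(counts) - set(abund)
    if unknown:
        raise ValueError(f"no abundance data for element(s) {sorted(unknown)}")
    n = counts.get(tracer, 0)
    if n < 1:
        raise ValueError(f"formula has no {tracer} atoms to trace")

    # aggregate shift distribution of all non-tracer atoms (shared by columns)
    other = np.array([1.0])
    for el, cnt in counts.items():
        if el == tracer or cnt == 0:
            continue
        other = np.convolve(other, _element_shift_distribution(el, cnt, abund))

    matrix = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        tracer_part = _element_shift_distribution(tracer, n - j, abund)
        col = np.convolve(tracer_part, other)
        col = np.concatenate([np.zeros(j), col])  # the j labeled atoms shift by +j
        matrix[:, j] = _truncate_fold(col, n)
    return matrix


def correct_mid(
    raw: IsotopomerDistribution | np.ndarray, matrix: np.ndarray
) -> IsotopomerDistribution:
    """Deconvolve natural abundance from a raw isotopomer vector.

    Solves matrix @ x = raw by nonnegative least squares, then
    renormalizes x to sum to 1.  NNLS (rather than plain inversion)
    prevents noise from producing negative fractions.
    """
    values = raw.values if isinstance(raw, IsotopomerDistribution) else np.asarray(raw, float)
    if len(values) != matrix.shape[0]:
        raise ValueError(
            f"length {len(values)} does not match matrix dimension {matrix.shape[0]}"
        )
    total = values.sum()
    if total <= 0:
        raise ValueError("all-zero intensity vector")
    x, _ = nnls(matrix, values / total)
    x = np.clip(x, 0.0, None)
    s = x.sum()
    if s <= 0:
        raise ValueError("correction produced an empty distribution")
    return IsotopomerDistribution(values=x / s, kind="corrected_fraction")


def labeled_fraction(mid: IsotopomerDistribution, index: int) -> float:
    """Fraction of molecules at mass m+index in a corrected MID."""
    if not 0 <= index < len(mid):
        raise IndexError(f"isotopomer index {index} out of range 0..{len(mid) - 1}")
    return float(mid.values[index])


def total_labeled_fraction(mid: IsotopomerDistribution) -> float:
    """Fraction of molecules carrying at least one tracer atom: 1 - m+0."""
    return float(1.0 - mid.values[0])


@dataclass
class LabelingIC50Result:
    ic50: float | None
    fit: "object"  # SigmoidFit from chemscreen.growth
    flat: bool = False
    percent_of_vehicle: np.ndarray = field(default_factory=lambda: np.array([]))


def labeling_inhibition_ic50(
    doses, labeled_fractions, vehicle_fraction: float
) -> LabelingIC50Result:
    """Dose-response IC50 of labeling inhibition.

    Labeled fractions are expressed as percent of the vehicle-control
    fraction and fit with the 4-parameter log-logistic used for growth
    scoring; the IC50 is the fitted midpoint concentration, in the units
    the doses were given in.  A flat response (span < 5% of vehicle) is
    flagged and returns ic50=None.
    """
    from .growth import fit_sigmoid

    if vehicle_fraction <= 0:
        raise ValueError("vehicle fraction must be positive")
    doses = np.asarray(doses, dtype=float)
    frac = np.asarray(labeled_fractions, dtype=float)
    percent = 100.0 * frac / vehicle_fraction

    if np.ptp(percent) < 5.0:
        return LabelingIC50Result(ic50=None, fit=None, flat=True, percent_of_vehicle=percent)

    fit = fit_sigmoid(doses, percent / 100.0)
    ic50 = fit.ec50 if fit.converged else None
    return LabelingIC50Result(
        ic50=ic50, fit=fit, flat=False, percent_of_vehicle=percent
    )


@dataclass(frozen=True)
class DeltaMeasurement:
    """IRMS isotope ratio in delta-per-mil notation vs a reference standard."""

    delta: float
    reference_ratio: float = VSMOW_D_TO_H

    def __post_init__(self):
        if self.delta <= -1000:
            raise ValueError("delta must exceed -1000 per mil")
        if self.reference_ratio <= 0:
            raise ValueError("reference ratio must be positive")


def delta_to_atom_percent(m: DeltaMeasurement | float, reference_ratio: float = VSMOW_D_TO_H) -> float:
    """Convert an IRMS delta value (per mil) to atom percent deuterium.

    R = R_ref * (delta/1000 + 1); atom% = 100 * R / (1 + R).
    """
    if not isinstance(m, DeltaMeasurement):
        m = DeltaMeasurement(delta=float(m), reference_ratio=reference_ratio)
    r = m.reference_ratio * (m.delta / 1000.0 + 1.0)
    return 100.0 * r / (1.0 + r)
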