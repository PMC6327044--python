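"""Seeded synthetic-data generators and forward models.

Each generator emulates the statistical structure of one assay so every
pipeline stage can be exercised without external data, and each returns
a machine-readable truth record holding the generating parameters so
recovery tests can compare estimates against ground truth.  All noise is
multiplicative lognormal (standard for positive-valued assay signals)
and every generator is a pure function of its seed: the same seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .growth import four_param_logistic
from .isotopes import build_correction_matrix
from .pk import PKSeries

# constant vector sequence preceding the guide barcode in sequencing reads
DEFAULT_PREFIX = "TTGTGGAAAGGACGAAACACCG"

# ten-point 3-fold dilution from 3 uM, the panel's standard dose series
DEFAULT_DOSES_UM = tuple(3.0 / 3.0**i for i in range(10))


@dataclass(frozen=True)
class FourPL:
    """Four-parameter log-logistic dose-effect curve (truth parameterization)."""

    bottom: float = 0.0
    top: float = 1.0
    log_ec50: float = -1.0  # log10 uM
    hill: float = -1.0

    def __call__(self, conc_um) -> np.ndarray:
        x = np.log10(np.asarray(conc_um, dtype=float))
        return four_param_logistic(x, self.bottom, self.top, self.log_ec50, self.hill)


NEUTRAL_EFFECT = FourPL(bottom=1.0, top=1.0)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    return rng.lognormal(mean=0.0, sigma=cv, size=size)


def simulate_plate(
    true_mu_max: float = np.log(2) / 48,
    drug_effect: FourPL = NEUTRAL_EFFECT,
    doses_um=DEFAULT_DOSES_UM,
    replicates: int = 3,
    cv: float = 0.05,
    seed: int = 0,
    time_h: float = 96.0,
    drug: str = "drugA",
    n0_atp: float = 1000.0,
    background_atp: float = 20.0,
    cal_slope: float = 2.0,
    cal_intercept: float = 100.0,
):
    """Simulate one two-timepoint viability plate with its ATP standards.

    Cells grow exponentially from `n0_atp` ATP units for `time_h` hours
    at rate mu(dose) = true_mu_max * drug_effect(dose); DMSO controls
    grow at true_mu_max.  Every well carries a cell-free background and
    luminescence is the linear calibration of total ATP, with
    multiplicative lognormal noise of coefficient `cv`.

    Returns (plate_df, standards_df, truth) where plate_df has columns
    well_id, role, timepoint_h, signal, drug, conc_um.
    """
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses_um, dtype=float)

    def lum(atp, n):
        return (cal_slope * atp + cal_intercept) * _lognormal_noise(rng, cv, n)

    rows = []

    def add(prefix, role, tp, atp_values, drug_name=None, conc=0.0):
        for i, s in enumerate(lum(np.asarray(atp_values, float), len(atp_values))):
            rows.append(
                {
                    "well_id": f"{prefix}{i + 1}",
                    "role": role,
                    "timepoint_h": tp,
                    "signal": s,
                    "drug": drug_name,
                    "conc_um": conc,
                }
            )

    # untreated baseline wells (collected at treatment start)
    add("T0_", "sample", 0.0, np.full(replicates, n0_atp + background_atp))
    # blanks at both timepoints
    add("BLK0_", "blank", 0.0, np.full(replicates, background_atp))
    add("BLK1_", "blank", time_h, np.full(replicates, background_atp))
    # DMSO controls at endpoint
    dmso_end = n0_atp * np.exp(true_mu_max * time_h) + background_atp
    add("DMSO_", "dmso_control", time_h, np.full(replicates, dmso_end))
    # treated wells at endpoint
    mus = true_mu_max * drug_effect(doses)
    for d, mu in zip(doses, mus):
        atp = n0_atp * np.exp(mu * time_h) + background_atp
        add(f"D{d:.5g}_", "sample", time_h, np.full(replicates, atp), drug, float(d))

    plate = pd.DataFrame(rows)

    std_atp = np.array([0.0, 500.0, 1000.0, 2000.0, 4000.0])
    standards = pd.DataFrame(
        {"atp": std_atp, "luminescence": cal_slope * std_atp + cal_intercept}
    )

    truth = {
        "mu_max": true_mu_max,
        "effect": asdict(drug_effect),
        "doses_um": doses.tolist(),
        "time_h": time_h,
        "cv": cv,
        "seed": seed,
    }
    return plate, standards, truth


@dataclass
class SimulatedScreen:
    """A scaled-down pooled suppressor screen with ground truth.

    `counts` holds the true per-guide read counts drawn for each
    condition; `write_fastq` materializes them as reads (constant prefix
    + barcode + random filler) for the trimming/counting path.
    """

    library: pd.DataFrame  # sgrna_id, gene, barcode
    counts: pd.DataFrame  # index sgrna_id, columns treated/control
    prefix: str
    truth: dict
    read_seed: int
    read_length: int = 50

    def write_fastq(self, treated_path, control_path) -> None:
        rng = np.random.default_rng(self.read_seed)
        barcode = dict(zip(self.library["sgrna_id"], self.library["barcode"]))
        for path, cond in ((treated_path, "treated"), (control_path, "control")):
            with open(path, "w") as fh:
                i = 0
                for sg, n in self.counts[cond].items():
                    core = self.prefix + barcode[sg]
                    pad = self.read_length - len(core)
                    for _ in range(int(n)):
                        filler = "".join(rng.choice(list("ACGT"), size=pad)) if pad > 0 else ""
                        seq = (core + filler)[: self.read_length]
                        fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
                        i += 1


def _random_barcodes(rng: np.random.Generator, n: int, length: int = 22) -> list[str]:
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(bases, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_screen(
    n_genes: int = 500,
    guides_per_gene: int = 8,
    n_suppressors: int = 10,
    effect_log2fc: float = 4.0,
    background_log2fc: float = -2.0,
    background_sd: float = 0.5,
    depth: int = 1_000_000,
    dispersion: float = 0.5,
    seed: int = 0,
    prefix: str = DEFAULT_PREFIX,
) -> SimulatedScreen:
    """Simulate a pooled CRISPR suppressor screen at reduced scale.

    Control guide abundances are lognormal with shape `dispersion`.
    Guides of the `n_suppressors` designated suppressor genes are
    enriched in the treated condition by `effect_log2fc` doublings; all
    other guides deplete by `background_log2fc` on average (killed-
    control design) with per-guide jitter `background_sd`.  Read counts
    are multinomial at `depth` reads per condition.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    suppressors = list(rng.choice(genes, size=n_suppressors, replace=False))

    sgrna_ids, gene_col = [], []
    for g in genes:
        for k in range(guides_per_gene):
            sgrna_ids.append(f"{g}_sg{k + 1}")
            gene_col.append(g)
    n_guides = len(sgrna_ids)
    library = pd.DataFrame(
        {
            "sgrna_id": sgrna_ids,
            "gene": gene_col,
            "barcode": _random_barcodes(rng, n_guides),
        }
    )

    control_abund = rng.lognormal(mean=0.0, sigma=dispersion, size=n_guides)
    is_supp = np.isin(gene_col, suppressors)
    jitter = rng.normal(0.0, background_sd, size=n_guides) if background_sd > 0 else 0.0
    guide_lfc = np.where(is_supp, effect_log2fc, background_log2fc + jitter)
    treated_abund = control_abund * 2.0**guide_lfc

    counts = pd.DataFrame(
        {
            "treated": rng.multinomial(depth, treated_abund / treated_abund.sum()),
            "control": rng.multinomial(depth, control_abund / control_abund.sum()),
        },
        index=pd.Index(sgrna_ids, name="sgrna_id"),
    )

    truth = {
        "suppressor_genes": sorted(suppressors),
        "effect_log2fc": effect_log2fc,
        "background_log2fc": background_log2fc,
        "depth": depth,
        "dispersion": dispersion,
        "seed": seed,
    }
    return SimulatedScreen(
        library=library,
        counts=counts,
        prefix=prefix,
        truth=truth,
        read_seed=int(rng.integers(2**31)),
    )


def forward_convolve(
    mid,
    formula,
    tracer: str = "C",
    abundances: dict | None = None,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Forward model of natural abundance: matrix @ mid, with optional noise.

    Uses the same correction-matrix construction the analysis inverts,
    so a noiseless forward-then-correct round trip is the identity.  The
    `mid` is the true labeling distribution and must sum to 1.
    """
    mid = np.asarray(mid, dtype=float)
    if abs(mid.sum() - 1.0) > 1e-9:
        raise ValueError("true MID must sum to 1")
    matrix = build_correction_matrix(formula, tracer=tracer, abundances=abundances)
    if len(mid) != matrix.shape[1]:
        raise ValueError("MID length does not match tracer atom count + 1")
    raw = matrix @ mid
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        raw = raw * rng.lognormal(0.0, noise_cv, size=len(raw))
    return raw


def simulate_labeling_response(
    ic50_um: float,
    doses_um,
    vehicle_fraction: float = 0.30,
    replicates: int = 3,
    cv: float = 0.05,
    hill: float = -1.0,
    seed: int = 0,
):
    """Simulate a labeled-fraction (e.g. cholesterol m+2) dose-response.

    The true response is a 4PL falling from 100% of the vehicle labeled
    fraction to 0 with midpoint `ic50_um`; fractions get multiplicative
    lognormal noise of coefficient `cv`.  Returns (doses, fractions,
    truth) with doses repeated per replicate.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses_um, dtype=float)
    effect = FourPL(bottom=0.0, top=1.0, log_ec50=np.log10(ic50_um), hill=hill)
    true_frac = vehicle_fraction * effect(doses)
    all_doses = np.repeat(doses, replicates)
    fractions = np.repeat(true_frac, replicates) * _lognormal_noise(
        rng, cv, len(all_doses)
    )
    truth = {
        "ic50_um": ic50_um,
        "hill": hill,
        "vehicle_fraction": vehicle_fraction,
        "cv": cv,
        "seed": seed,
    }
    return all_doses, fractions, truth


def simulate_pk(
    t_half_h: float,
    c0: float = 1000.0,
    times_h=(1, 2, 4, 8, 12, 24, 36, 48),
    cv: float = 0.10,
    seed: int = 0,
) -> tuple[PKSeries, dict]:
    """Mono-exponential plasma decay c(t) = c0 * 2^(-t/t_half) with noise."""
    if t_half_h <= 0:
        raise ValueError("half-life must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(times_h, dtype=float)
    conc = c0 * 2.0 ** (-t / t_half_h) * _lognormal_noise(rng, cv, len(t))
    truth = {"t_half_h": t_half_h, "c0": c0, "cv": cv, "seed": seed}
    return PKSeries(times_h=t, concentrations=conc), truth


def simulate_tumors(
    n_per_group: int = 10,
    baseline_mm3: float = 200.0,
    growth_per_day: float = 0.08,
    inhibition: float = 0.85,
    cv: float = 0.10,
    days=(0, 3, 7, 10, 14, 17, 21),
    seed: int = 0,
    aspect: float = 1.2,
):
    """Simulate vehicle and treated xenograft caliper series.

    Vehicle tumors grow exponentially from the randomization baseline
    (~`baseline_mm3`); the treated group's volume *gain* is scaled by
    (1 - inhibition), so with cv = 0 the realized TGI equals
    100 * inhibition exactly.  Calipers are back-calculated assuming
    L = aspect * W, so volume = 0.5 * W^2 * L holds for every record.

    Returns (treated_df, vehicle_df, truth) with columns animal_id,
    group, day, W_mm, L_mm, volume_mm3.
    """
    rng = np.random.default_rng(seed)
    days = np.asarray(days, dtype=float)

    def build(group, inhib, offset):
        rows = []
        for a in range(n_per_group):
            v0 = baseline_mm3 * _lognormal_noise(rng, cv, 1)[0]
            for d in days:
                gain = v0 * (np.exp(growth_per_day * d) - 1.0)
                v = (v0 + (1.0 - inhib) * gain) * _lognormal_noise(rng, cv, 1)[0]
                w = (v / (0.5 * aspect)) ** (1.0 / 3.0)
                rows.append(
                    {
                        "animal_id": f"{group[0].upper()}{a + offset + 1:03d}",
                        "group": group,
                        "day": float(d),
                        "W_mm": w,
                        "L_mm": aspect * w,
                        "volume_mm3": 0.5 * w**2 * (aspect * w),
                    }
                )
        return pd.DataFrame(rows)

    vehicle = build("vehicle", 0.0, 0)
    treated = build("treated", inhibition, n_per_group)
    truth = {
        "inhibition": inhibition,
        "baseline_mm3": baseline_mm3,
        "growth_per_day": growth_per_day,
        "cv": cv,
        "seed": seed,
    }
    return treated, vehicle, truth
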