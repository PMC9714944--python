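"""Standard-curve QC: efficiency, detection limit, precision, normalization.

A calibration (standard) curve regresses Cq on log10 template copies.
Perfect doubling per cycle gives a slope of -1/log10(2) = -3.3219 and an
amplification efficiency of ``10**(-1/slope) - 1 = 1.0`` (100%).  The
detection limit follows Hubaux & Vos: prediction bands around the
calibration regression, evaluated on a response that is linear in
concentration, give a decision limit (false-positive control at zero
concentration) and the smallest concentration whose signal clears it
with controlled false-negative rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

# Mass-to-copies constants (config-level; see docs/methods.md).
BP_PER_HAPLOID_GENOME = 3.1e9
GRAMS_PER_MOL_BP = 650.0
AVOGADRO = 6.02214076e23
#: grams of DNA in one diploid human genome equivalent
GRAMS_PER_DIPLOID_GENOME = 2 * BP_PER_HAPLOID_GENOME * GRAMS_PER_MOL_BP / AVOGADRO


def copies_from_mass(mass_ng: float, copies_per_diploid_genome: float = 1.0) -> float:
    """Template copies contained in ``mass_ng`` of genomic DNA.

    One diploid genome equivalent weighs 2 x 3.1 Gbp x 650 g/mol / N_A
    ~= 6.69 pg, so 2.5 ng of DNA holds ~374 diploid genomes.
    """
    if mass_ng <= 0:
        raise ValueError("template mass must be positive")
    genomes = mass_ng * 1e-9 / GRAMS_PER_DIPLOID_GENOME
    return genomes * copies_per_diploid_genome


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of Cq on log10(copies) with derived efficiency."""

    assay_id: str
    channel: str
    slope: float
    intercept: float
    r2: float
    residual_sd: float
    n_points: int
    efficiency: float
    degenerate: bool = False
    log10_copies: tuple[float, ...] = ()
    cqs: tuple[float, ...] = ()


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency, E = 10**(-1/slope) - 1 (perfect = 1.0)."""
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_calibration(points: list[tuple[float, float]], assay_id: str = "",
                    channel: str = "target") -> CalibrationFit:
    """Fit a standard curve to (log10 copies, Cq) points.

    Requires >= 3 distinct concentrations.  A non-negative or undefined
    slope yields a fit flagged ``degenerate`` (with a warning) rather
    than an exception, so QC reports can still show the numbers.
    """
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("calibration needs >= 3 distinct concentrations")
    res = stats.linregress(x, y)
    n = len(x)
    resid = y - (res.intercept + res.slope * x)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    degenerate = not (res.slope < 0)
    if degenerate:
        warnings.warn(f"calibration slope {res.slope:.3g} is not negative; "
                      "fit flagged degenerate", stacklevel=2)
        eff = float("nan")
    else:
        eff = efficiency_from_slope(res.slope)
    return CalibrationFit(assay_id=assay_id, channel=channel,
                          slope=float(res.slope), intercept=float(res.intercept),
                          r2=float(res.rvalue**2), residual_sd=residual_sd,
                          n_points=n, efficiency=eff, degenerate=degenerate,
                          log10_copies=tuple(x), cqs=tuple(y))


@dataclass(frozen=True)
class LodEstimate:
    assay_id: str
    lod_copies: float
    alpha: float
    beta: float


def lod_hubaux_vos(fit: CalibrationFit, alpha: float = 0.05,
                   beta: float = 0.05) -> LodEstimate:
    """Detection limit from calibration prediction bands (Hubaux & Vos).

    The construction assumes a response linear in concentration, so the
    exponential Cq scale is first linearized as ``y = 2**(-Cq)`` and the
    calibration is re-fit as y on copies.  The decision limit is the
    upper (1 - alpha) prediction bound of the regression at zero
    concentration; the detection limit is the concentration whose lower
    (1 - beta) prediction bound first exceeds it.
    """
    if not 0 < alpha < 0.5 or not 0 < beta < 0.5:
        raise ValueError("alpha and beta must lie in (0, 0.5)")
    if fit.degenerate or fit.n_points < 3:
        raise ValueError("cannot estimate a detection limit from a degenerate fit")
    x = np.array([10.0 ** lx for lx in fit.log10_copies])
    y = np.array([2.0 ** (-cq) for cq in fit.cqs])
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise ValueError("linearized response is not increasing in concentration")
    resid = y - (intercept + slope * x)
    s = math.sqrt(float(np.sum(resid**2)) / (n - 2))
    xbar = float(np.mean(x))
    sxx = float(np.sum((x - xbar) ** 2))

    def band(x0: float, prob: float, sign: float) -> float:
        t = stats.t.ppf(prob, n - 2)
        half = t * s * math.sqrt(1.0 + 1.0 / n + (x0 - xbar) ** 2 / sxx)
        return intercept + slope * x0 + sign * half

    y_c = band(0.0, 1.0 - alpha, +1.0)  # decision limit

    def gap(x0: float) -> float:
        return band(x0, 1.0 - beta, -1.0) - y_c

    if s == 0.0:
        return LodEstimate(fit.assay_id, 0.0, alpha, beta)
    hi = max(x.max(), 1.0)
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("no detection limit within search range")
    lod = optimize.brentq(gap, 0.0, hi, xtol=1e-10 * hi)
    return LodEstimate(fit.assay_id, float(lod), alpha, beta)


def pooled_cv(groups: list[list[float]]) -> float:
    """Pooled coefficient of variation in percent.

    Per-group CVs (SD/mean) are pooled as a degrees-of-freedom-weighted
    root mean square: ``sqrt(sum (n_g - 1) CV_g^2 / sum (n_g - 1)) * 100``.
    Groups with non-positive mean are excluded with a warning.
    """
    num = den = 0.0
    for g in groups:
        g = np.asarray(g, dtype=float)
        if len(g) < 2:
            continue
        mean = g.mean()
        if mean <= 0:
            warnings.warn("group with non-positive mean excluded from pooled CV",
                          stacklevel=2)
            continue
        cv = g.std(ddof=1) / mean
        num += (len(g) - 1) * cv**2
        den += len(g) - 1
    if den == 0:
        raise ValueError("no usable groups for pooled CV")
    return 100.0 * math.sqrt(num / den)


def nrmse(target_cqs: list[float], reference_cqs: list[float],
          integer_gcn: int, offset: float = 0.0) -> float:
    """Normalized RMSE of target Cqs against the reference-predicted Cqs.

    The duplex model predicts ``Cq_target = Cq_reference + offset + 1 -
    log2(n)`` for integer copy number n; the RMSE of observed minus
    predicted is normalized by the mean observed target Cq.  Measures
    how faithfully the target channel tracks the reference channel.
    """
    if integer_gcn < 1:
        raise ValueError("NRMSE is undefined for 0 copies")
    t = np.asarray(target_cqs, dtype=float)
    r = np.asarray(reference_cqs, dtype=float)
    if t.shape != r.shape or t.size == 0:
        raise ValueError("paired, non-empty Cq vectors required")
    predicted = r + offset + 1.0 - math.log2(integer_gcn)
    rmse = math.sqrt(float(np.mean((t - predicted) ** 2)))
    return rmse / float(np.mean(t))


# ---------------------------------------------------------------------------
# precision report plumbing

def precision_report(replicate_sets: dict[tuple, list[list[float]]]) -> "pd.DataFrame":
    """Pooled CV% per (assay, channel, scope) grouping.

    ``replicate_sets`` maps (assay_id, channel, scope) to a list of
    replicate groups (each a list of Cq or GCN values); scope is e.g.
    "repeatability" (within run) or "reproducibility" (across runs).
    """
    import pandas as pd

    rows = []
    for (assay, channel, scope), groups in sorted(replicate_sets.items()):
        rows.append({"assay_id": assay, "channel": channel, "scope": scope,
                     "pooled_cv_percent": pooled_cv(groups)})
    return pd.DataFrame(rows)
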