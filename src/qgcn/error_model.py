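"""Closed-form normal model of ambiguity and misclassification rates.

The relative error X of a sample's average measured copy number is
modeled as Normal(mu, sigma^2).  At true integer copy number n the
measured value is n(1 + X), and on the measured-GCN axis the windows of
the +-0.3 calling rule translate into windows on X divided by n:

* unambiguous:       |X| <= 0.3/n          (within +-0.3 of the truth)
* ambiguous:         0.3/n < |X| < 0.7/n   (between integer catchments)
* misclassified:     |X| >= 0.7/n          (within +-0.3 of a wrong integer)

The three probabilities sum to one exactly, misclassification grows
with n (the windows shrink as 1/n), and all rates depend on |mu| only.
An inverse fit recovers (|mu|, sigma) from two observed ambiguity rates
at distinct copy numbers, which is how a published rate table can be
checked for internal consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .assays import ASSAYS


@dataclass(frozen=True)
class ErrorModel:
    """Normal relative-error distribution of an assay: X ~ N(mu, sigma^2)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _p_abs_below(model: ErrorModel, c: float) -> float:
    """P(|X| < c) under the model."""
    return float(stats.norm.cdf(c, model.mu, model.sigma)
                 - stats.norm.cdf(-c, model.mu, model.sigma))


def rate_at_gcn(model: ErrorModel, n: int, halfwidth: float = 0.3
                ) -> tuple[float, float]:
    """(ambiguity %, misclassification %) at integer copy number n >= 1.

    With boundary b = 1 - halfwidth: ambiguity = P(halfwidth/n < |X| <
    b/n) and misclassification = P(|X| >= b/n), via the normal CDF.
    """
    if n < 1:
        raise ValueError("rates are defined for copy numbers >= 1")
    b = 1.0 - halfwidth
    p_inner = _p_abs_below(model, halfwidth / n)
    p_outer = _p_abs_below(model, b / n)
    ambiguity = p_outer - p_inner
    misclassification = 1.0 - p_outer
    return 100.0 * ambiguity, 100.0 * misclassification


def sample_rates(model: ErrorModel, n: int, draws: int,
                 rng: np.random.Generator, halfwidth: float = 0.3
                 ) -> tuple[float, float]:
    """Monte-Carlo estimate of the same rates (simulation cross-check)."""
    b = 1.0 - halfwidth
    x = np.abs(rng.normal(model.mu, model.sigma, size=draws))
    amb = np.mean((x > halfwidth / n) & (x < b / n))
    mis = np.mean(x >= b / n)
    return 100.0 * float(amb), 100.0 * float(mis)


def fit_error_model(observed: list[tuple[int, float]], halfwidth: float = 0.3
                    ) -> ErrorModel:
    """Recover (|mu|, sigma) from two observed ambiguity rates.

    ``observed`` holds two (n, ambiguity %) pairs at distinct copy
    numbers.  The 2x2 system is solved by a deterministic coarse grid
    multi-start followed by bounded least squares; the residual must
    vanish to 1e-10 in probability units, otherwise a fit failure is
    raised.  Only |mu| is identifiable (the windows are symmetric).
    """
    if len(observed) != 2 or observed[0][0] == observed[1][0]:
        raise ValueError("need two ambiguity rates at distinct copy numbers")
    for n, rate in observed:
        if n < 1:
            raise ValueError("copy numbers must be >= 1")
        if not 0 < rate < 100:
            raise ValueError("ambiguity rates must lie in (0, 100) percent")
    targets = [(n, rate / 100.0) for n, rate in observed]

    def residuals(p: np.ndarray) -> list[float]:
        model = ErrorModel(mu=p[0], sigma=p[1])
        out = []
        for n, t in targets:
            amb, _ = rate_at_gcn(model, n, halfwidth)
            out.append(amb / 100.0 - t)
        return out

    lo, hi = np.array([0.0, 1e-6]), np.array([0.5, 0.5])
    best = None
    for mu0 in (0.0, 0.02, 0.05, 0.1, 0.2):
        for s0 in (0.02, 0.05, 0.08, 0.12, 0.2, 0.3):
            sol = optimize.least_squares(residuals, [mu0, s0],
                                         bounds=(lo, hi), xtol=1e-15,
                                         ftol=1e-15, gtol=1e-15)
            if best is None or sol.cost < best.cost:
                best = sol
    resid = float(np.max(np.abs(best.fun)))
    if resid > 1e-10:
        raise RuntimeError(
            f"no (|mu|, sigma) in bounds reproduces the observed rates "
            f"(best residual {resid:.3g})")
    return ErrorModel(mu=float(best.x[0]), sigma=float(best.x[1]))


def rate_table(models: dict[str, ErrorModel], ns: range | list[int] = range(1, 5),
               halfwidth: float = 0.3) -> "pd.DataFrame":
    """Ambiguity/misclassification grid: rows metric x n, one column per assay."""
    import pandas as pd

    index = ([f"ambiguity at {n} GCN" for n in ns]
             + [f"misclassification at {n} GCN" for n in ns])
    table = {}
    for assay, model in models.items():
        amb, mis = zip(*(rate_at_gcn(model, n, halfwidth) for n in ns))
        table[assay] = list(amb) + list(mis)
    return pd.DataFrame(table, index=index)


def format_rate_table(table: "pd.DataFrame", sub_threshold: float = 0.005,
                      sub_symbol: str = "<0.01%") -> "pd.DataFrame":
    """Render a rate table to 2 decimals, flooring tiny cells to a symbol.

    Cells below ``sub_threshold`` percent are shown as ``sub_symbol``
    (set ``sub_symbol=">0.01%"`` to mimic the inverted glyph some
    published tables use for the same cells).
    """
    def fmt(v: float) -> str:
        return sub_symbol if v < sub_threshold else f"{v:.2f}%"

    return table.map(fmt)


def fit_models_from_re(average_res: dict[str, list[float]]) -> dict[str, ErrorModel]:
    """Per-assay models from observed per-sample average relative errors."""
    models = {}
    for assay in ASSAYS:
        if assay not in average_res:
            continue
        re = np.asarray(average_res[assay], dtype=float)
        if len(re) < 2:
            raise ValueError(f"{assay}: need >= 2 average relative errors")
        models[assay] = ErrorModel(mu=float(re.mean()),
                                   sigma=float(re.std(ddof=1)))
    return models
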