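"""Cq-to-copy-number conversion, offset calibration and classification.

The duplex relative-quantification relationship is

    Cq_target - Cq_reference = 1 - log2(GCN)

so a copy number of 2 (the reference gene's own dosage) gives a Cq
difference of 0 and each halving of copy number costs one extra cycle.
Inverting, the measured copy number of a well is

    mGCN = 2 ** (1 - (Cq_target - Cq_reference - offset))

where ``offset`` (cycles) absorbs the assay-specific quantification
threshold: it is tuned on a calibration cohort so that the mean relative
error of measured versus integer copy numbers is exactly zero.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .assays import ASSAYS, PARALOG_PAIRS, locus_counts_to_totals
from .io import CqRecord


class MeasurementInvalidError(ValueError):
    """A well cannot be quantified (e.g. the reference channel dropped out)."""


@dataclass(frozen=True)
class MeasuredGcn:
    """Replicate-level and aggregated measured copy number for one
    sample x assay.

    ``per_well`` holds one real-valued copy number per well (0 for a
    dropout well).  ``mean``/``sd`` are computed over non-dropout wells;
    if every well dropped out the mean is 0 and the dispersion fields
    are ``None`` (flagged undefined).
    """

    sample_id: str
    assay_id: str
    per_well: tuple[float, ...]
    mean: float
    sd: float | None
    cv_percent: float | None
    ci95: tuple[float, float] | None
    n_wells: int
    n_dropout: int


def gcn_from_cq(cq_target: float | None, cq_reference: float | None,
                offset: float = 0.0) -> float:
    """Measured copy number of one well from its duplex Cq pair.

    A dropout target (``None``) maps to 0 copies; a dropout reference
    invalidates the well.
    """
    if cq_reference is None:
        raise MeasurementInvalidError("reference channel did not amplify")
    if cq_target is None:
        return 0.0
    return 2.0 ** (1.0 - (cq_target - cq_reference - offset))


def relative_error(measured: float, integer: int) -> float:
    """(measured - integer) / integer; undefined (error) for integer 0."""
    if integer < 1:
        raise ValueError("relative error is undefined for 0 copies")
    return (measured - integer) / integer


def tune_offset(measured: list[float], integers: list[int]) -> float:
    """Calibration offset (cycles) driving the mean relative error to zero.

    Samples with integer copy number 0 are excluded.  The corrected
    measured value is ``m * 2**offset``, so the offset solving
    ``mean(m_i * 2**o / n_i) = 1`` is ``-log2(mean(m_i / n_i))``.
    """
    ratios = [m / n for m, n in zip(measured, integers, strict=True) if n >= 1]
    if not ratios:
        raise ValueError("no measurements with integer copy number >= 1")
    return -math.log2(float(np.mean(ratios)))


def tune_offset_iterative(measured: list[float], max_iter: int = 10
                          ) -> tuple[float, list[int]]:
    """Offset tuning when integer copy numbers are not supplied.

    Rounds measured values to the nearest integer, tunes, re-rounds the
    corrected values and repeats until the assignment is stable (at most
    ``max_iter`` rounds).  Returns the offset and the final integers.
    """
    assigned = [max(0, round(m)) for m in measured]
    offset = 0.0
    for _ in range(max_iter):
        offset = tune_offset(measured, assigned)
        corrected = [m * 2.0 ** offset for m in measured]
        new = [max(0, round(c)) for c in corrected]
        if new == assigned:
            break
        assigned = new
    return offset, assigned


def apply_offset(measured: float, offset: float) -> float:
    """Re-express a measured copy number under a calibration offset."""
    return measured * 2.0 ** offset


def aggregate_replicates(wells: list[float], sample_id: str = "",
                         assay_id: str = "") -> MeasuredGcn:
    """Aggregate per-well copy numbers: mean, SD (n-1), CV%, normal 95% CI.

    Dropout wells (value 0) are excluded from the statistics; an
    all-dropout set yields mean 0 with dispersion flagged undefined.
    """
    wells = list(wells)
    if not wells:
        raise ValueError("no wells to aggregate")
    live = [w for w in wells if w > 0]
    n_drop = len(wells) - len(live)
    if not live:
        return MeasuredGcn(sample_id, assay_id, tuple(wells), mean=0.0,
                           sd=None, cv_percent=None, ci95=None,
                           n_wells=len(wells), n_dropout=n_drop)
    mean = float(np.mean(live))
    if len(live) > 1:
        sd = float(np.std(live, ddof=1))
        tcrit = stats.t.ppf(0.975, len(live) - 1)
        half = tcrit * sd / math.sqrt(len(live))
        ci: tuple[float, float] | None = (mean - half, mean + half)
    else:
        sd, ci = None, None
    cv = 100.0 * sd / mean if sd is not None and mean > 0 else None
    return MeasuredGcn(sample_id, assay_id, tuple(wells), mean=mean, sd=sd,
                       cv_percent=cv, ci95=ci, n_wells=len(wells),
                       n_dropout=n_drop)


def classify_ambiguity(measured: float, halfwidth: float = 0.3
                       ) -> tuple[str, int | None]:
    """Label a measured copy number against the integer grid.

    Returns ``("unambiguous", n)`` when some integer n >= 0 lies within
    ``halfwidth`` (inclusive boundary) of the value, else
    ``("ambiguous", None)``.  Because ``halfwidth < 0.5`` at most one
    integer can qualify.
    """
    if measured < 0:
        raise ValueError("measured copy number must be >= 0")
    nearest = max(0, round(measured))
    # inclusive boundary, robust to binary representation of e.g. 1.7 - 2
    if abs(measured - nearest) <= halfwidth + 1e-12:
        return ("unambiguous", nearest)
    return ("ambiguous", None)


@dataclass(frozen=True)
class ExpectedGcn:
    """Constraint-based expectation for one sample's seven loci.

    The four totals (C4, CYP21, HERV, breakpoints + 2) estimate the same
    segment count; their equal-weight mean is the expected total, and
    each locus expectation splits the total in proportion to the
    measured paralog pair.  A locus deviating from its expectation by
    more than ``deviation_threshold`` is flagged inconsistent.
    """

    sample_id: str
    expected_total: float
    expected: dict[str, float]
    deviation: dict[str, float]
    inconsistent: dict[str, bool]


def expected_gcn(measured: dict[str, float], sample_id: str = "",
                 deviation_threshold: float = 0.4) -> ExpectedGcn:
    """Expected copy numbers from the four-way genomic constraint."""
    totals = locus_counts_to_totals(measured)
    exp_total = float(np.mean(totals))
    expected: dict[str, float] = {}
    for a, b in PARALOG_PAIRS:
        pair_sum = measured[a] + measured[b]
        if pair_sum <= 0:
            expected[a] = expected[b] = 0.0
        else:
            expected[a] = exp_total * measured[a] / pair_sum
            expected[b] = exp_total * measured[b] / pair_sum
    expected["BP"] = max(exp_total - 2.0, 0.0)
    deviation = {k: abs(measured[k] - v) for k, v in expected.items()}
    inconsistent = {}
    for k in ASSAYS:
        pair_zero = any(k in pair and measured[pair[0]] + measured[pair[1]] <= 0
                        for pair in PARALOG_PAIRS)
        inconsistent[k] = (not pair_zero) and deviation[k] > deviation_threshold
    return ExpectedGcn(sample_id, exp_total, expected, deviation, inconsistent)


# ---------------------------------------------------------------------------
# record-level pipeline

def measured_gcns_from_records(
    records: list[CqRecord],
    offsets: dict[str, float] | None = None,
) -> list[MeasuredGcn]:
    """Per-well duplex quantification followed by per-sample aggregation.

    Wells are paired by (sample, assay, run, replicate); each well's
    copy number comes from its own target/reference Cq pair (never from
    averaged Cqs).  ``offsets`` maps assay id to calibration offset.
    """
    offsets = offsets or {}
    pairs: dict[tuple, dict[str, float | None]] = defaultdict(dict)
    for rec in records:
        pairs[(rec.sample_id, rec.assay_id, rec.run, rec.replicate)][rec.channel] = rec.cq
    wells: dict[tuple[str, str], list[float]] = defaultdict(list)
    for (sid, assay, _run, _rep), chans in sorted(pairs.items()):
        if "reference" not in chans:
            raise MeasurementInvalidError(
                f"well {(sid, assay, _run, _rep)} has no reference channel")
        g = gcn_from_cq(chans.get("target"), chans["reference"],
                        offsets.get(assay, 0.0))
        wells[(sid, assay)].append(g)
    return [aggregate_replicates(v, sample_id=sid, assay_id=assay)
            for (sid, assay), v in sorted(wells.items())]


def measured_matrix(measured: list[MeasuredGcn]) -> "pd.DataFrame":
    """Pivot aggregated measurements to a sample x assay mean-GCN matrix."""
    import pandas as pd

    rows: dict[str, dict[str, float]] = defaultdict(dict)
    for m in measured:
        rows[m.sample_id][m.assay_id] = m.mean
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df.reindex(columns=list(ASSAYS))
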