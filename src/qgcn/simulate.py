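"""Synthetic RCCX genotypes and duplex qPCR Cq data.

The generator reproduces the statistical structure the downstream
analysis assumes, so the whole pipeline is testable without instrument
exports:

* diploid genotypes drawn from a haplotype model in which each haplotype
  is an ordered run of 1-4 RCCX segments, so that the four locus totals
  (C4, CYP21, HERV-K(C4), breakpoints + 2) are equal by construction;
* per-well Cq values following the duplex relative-quantification
  relationship ``Cq_target - Cq_reference = 1 - log2(GCN)``;
* a sample-specific "matrix effect" shift of the reference Cq that is
  shared by both channels (and therefore cancels in the difference),
  plus a small channel-asymmetric component that does not cancel;
* replicate structure (wells within runs, runs on separate days),
  between-run shifts, extra noise and bias for degraded-DNA samples,
  and amplification dropout for zero-copy target loci;
* dilution series over a mass range for calibration-curve work.

All randomness flows from a single :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .assays import ASSAYS
from .io import CqRecord

C4_TYPES = ("A", "B")
CYP21_TYPES = ("A1P", "A2")
HERV_TYPES = ("insertion", "deletion")


@dataclass(frozen=True)
class Segment:
    """One RCCX repeat unit: a C4 gene, a CYP21 gene and the HERV state."""

    c4_type: str  # "A" | "B"
    cyp21_type: str  # "A1P" | "A2"
    herv: str  # "insertion" | "deletion"

    def __post_init__(self) -> None:
        if self.c4_type not in C4_TYPES:
            raise ValueError(f"unknown C4 type {self.c4_type!r}")
        if self.cyp21_type not in CYP21_TYPES:
            raise ValueError(f"unknown CYP21 type {self.cyp21_type!r}")
        if self.herv not in HERV_TYPES:
            raise ValueError(f"unknown HERV state {self.herv!r}")


@dataclass(frozen=True)
class Haplotype:
    """Ordered RCCX segments on one chromosome (1-4 tandem repeats)."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.segments) <= 4:
            raise ValueError("a haplotype carries 1-4 RCCX segments")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def breakpoints(self) -> int:
        return len(self.segments) - 1


@dataclass(frozen=True)
class Genotype:
    """Two haplotypes and the integer copy numbers they imply."""

    hap1: Haplotype
    hap2: Haplotype

    def locus_counts(self) -> dict[str, int]:
        """Integer copy number per assay locus for this diploid genotype."""
        counts = dict.fromkeys(ASSAYS, 0)
        for hap in (self.hap1, self.hap2):
            for seg in hap.segments:
                counts["C4A" if seg.c4_type == "A" else "C4B"] += 1
                counts["CYP21A1P" if seg.cyp21_type == "A1P" else "CYP21A2"] += 1
                counts["HERV_ins" if seg.herv == "insertion" else "HERV_del"] += 1
            counts["BP"] += hap.breakpoints
        return counts

    @property
    def total_segments(self) -> int:
        return self.hap1.n_segments + self.hap2.n_segments


def _seg(c4: str, cyp: str, herv: str) -> Segment:
    return Segment(c4_type=c4, cyp21_type=cyp, herv=herv)


#: Default haplotype pool: monomodular, bimodular and trimodular
#: haplotypes at 0.55 / 0.40 / 0.05, each carrying CYP21A2 on exactly one
#: segment.  This skew is typical of European cohorts and produces
#: diploid totals from 2 to 6.
DEFAULT_HAPLOTYPE_FREQS: dict[Haplotype, float] = {
    Haplotype((_seg("B", "A2", "deletion"),)): 0.55,
    Haplotype((_seg("A", "A1P", "insertion"), _seg("B", "A2", "deletion"))): 0.40,
    Haplotype(
        (
            _seg("A", "A1P", "insertion"),
            _seg("A", "A1P", "insertion"),
            _seg("B", "A2", "deletion"),
        )
    ): 0.05,
}


@dataclass(frozen=True)
class NoiseSpec:
    """Cq noise model, all terms in PCR cycles.

    ``matrix_sd`` is the between-sample reference-Cq spread (the genomic
    "matrix effect"); it shifts both duplex channels equally and cancels
    in the Cq difference.  ``asym_matrix_sd`` is the small persistent
    per-sample, per-assay component that hits the target channel only and
    therefore propagates into measured copy numbers.  Degraded ("bad
    quality") samples receive ``degraded_bias`` on target channels plus
    ``degraded_extra_sd`` of extra well noise.
    """

    base_ref_cq: float = 26.07
    matrix_sd: float = 0.5
    well_sd: float = 0.05
    run_sd: float = 0.05
    asym_matrix_sd: float = 0.02
    degraded_extra_sd: float = 0.10
    degraded_bias: float = 0.05
    assay_bias: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("matrix_sd", "well_sd", "run_sd", "asym_matrix_sd",
                     "degraded_extra_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def bias_for(self, assay: str) -> float:
        return self.assay_bias.get(assay, 0.0)


NOISELESS = NoiseSpec(matrix_sd=0.0, well_sd=0.0, run_sd=0.0,
                      asym_matrix_sd=0.0, degraded_extra_sd=0.0,
                      degraded_bias=0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, replicate design and quality-group composition."""

    n_samples: int = 46
    wells_per_run: int = 3
    n_runs: int = 3
    haplotype_freqs: dict[Haplotype, float] | None = None
    # good / population / bad fractions, mirroring a 17/19/10 split.
    quality_fractions: tuple[float, float, float] = (0.37, 0.41, 0.22)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if abs(sum(self.quality_fractions) - 1.0) > 1e-9:
            raise ValueError("quality fractions must sum to 1")

    def freqs(self) -> dict[Haplotype, float]:
        return self.haplotype_freqs or DEFAULT_HAPLOTYPE_FREQS


def sample_genotype(freqs: dict[Haplotype, float], rng: np.random.Generator) -> Genotype:
    """Draw two independent haplotypes from a frequency map.

    Raises ``ValueError`` on an empty map or probabilities that do not
    sum to 1 (within 1e-9).
    """
    if not freqs:
        raise ValueError("haplotype frequency map is empty")
    haps = list(freqs)
    probs = np.array([freqs[h] for h in haps], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"haplotype probabilities sum to {probs.sum()}, not 1")
    i, j = rng.choice(len(haps), size=2, p=probs / probs.sum())
    return Genotype(hap1=haps[i], hap2=haps[j])


def _target_cq_offset(gcn: int) -> float:
    """Ideal target-minus-reference Cq for an integer copy number >= 1."""
    return 1.0 - math.log2(gcn)


def simulate_cq(
    genotype: Genotype,
    noise: NoiseSpec,
    design: CohortSpec,
    rng: np.random.Generator,
    sample_id: str = "S1",
    study_group: str = "good",
) -> list[CqRecord]:
    """Simulate duplex Cq wells for one sample across all seven assays.

    For every well the reference Cq is ``base + matrix + run + eps`` and
    the target Cq adds ``1 - log2(GCN)`` plus assay bias, the asymmetric
    matrix component and its own independent well noise.  Target loci
    with copy number 0 emit a dropout record (absent Cq).  Deterministic
    for a fixed generator state.
    """
    counts = genotype.locus_counts()
    degraded = study_group == "bad"
    matrix_shift = rng.normal(0.0, noise.matrix_sd) if noise.matrix_sd else 0.0
    records: list[CqRecord] = []
    tgt_sd = math.hypot(noise.well_sd, noise.degraded_extra_sd if degraded else 0.0)
    for assay in ASSAYS:
        gcn = counts[assay]
        asym = rng.normal(0.0, noise.asym_matrix_sd) if noise.asym_matrix_sd else 0.0
        for run in range(1, design.n_runs + 1):
            run_shift = rng.normal(0.0, noise.run_sd) if noise.run_sd else 0.0
            for well in range(1, design.wells_per_run + 1):
                base = noise.base_ref_cq + matrix_shift + run_shift
                cq_ref = base + rng.normal(0.0, noise.well_sd) if noise.well_sd else base
                records.append(CqRecord(sample_id=sample_id, assay_id=assay,
                                        channel="reference", replicate=well,
                                        run=run, cq=cq_ref))
                if gcn == 0:
                    records.append(CqRecord(sample_id=sample_id, assay_id=assay,
                                            channel="target", replicate=well,
                                            run=run, cq=None))
                    continue
                cq_tgt = (base + _target_cq_offset(gcn) + noise.bias_for(assay)
                          + asym + (noise.degraded_bias if degraded else 0.0))
                if tgt_sd:
                    cq_tgt += rng.normal(0.0, tgt_sd)
                records.append(CqRecord(sample_id=sample_id, assay_id=assay,
                                        channel="target", replicate=well,
                                        run=run, cq=cq_tgt))
    return records


def simulate_dilution_series(
    genotype: Genotype,
    noise: NoiseSpec,
    masses_ng: list[float],
    rng: np.random.Generator,
    assay: str = "CYP21A2",
    reference_mass_ng: float = 10.0,
    replicates: int = 3,
    sample_id: str = "CAL1",
) -> list[CqRecord]:
    """Simulate a calibration dilution series for one assay.

    ``base_ref_cq`` is anchored at ``reference_mass_ng`` of template;
    halving the mass raises both channels by one cycle (perfect
    amplification efficiency).  Each mass level is measured in
    ``replicates`` wells.
    """
    if any(m <= 0 for m in masses_ng):
        raise ValueError("template masses must be positive")
    counts = genotype.locus_counts()
    gcn = counts[assay]
    matrix_shift = rng.normal(0.0, noise.matrix_sd) if noise.matrix_sd else 0.0
    records: list[CqRecord] = []
    for level, mass in enumerate(masses_ng, start=1):
        mass_shift = -math.log2(mass / reference_mass_ng)
        for well in range(1, replicates + 1):
            base = noise.base_ref_cq + matrix_shift + mass_shift
            cq_ref = base + (rng.normal(0.0, noise.well_sd) if noise.well_sd else 0.0)
            records.append(CqRecord(sample_id=sample_id, assay_id=assay,
                                    channel="reference", replicate=well,
                                    run=level, cq=cq_ref, template_mass=mass))
            if gcn == 0:
                records.append(CqRecord(sample_id=sample_id, assay_id=assay,
                                        channel="target", replicate=well,
                                        run=level, cq=None, template_mass=mass))
                continue
            cq_tgt = base + _target_cq_offset(gcn) + noise.bias_for(assay)
            if noise.well_sd:
                cq_tgt += rng.normal(0.0, noise.well_sd)
            records.append(CqRecord(sample_id=sample_id, assay_id=assay,
                                    channel="target", replicate=well,
                                    run=level, cq=cq_tgt, template_mass=mass))
    return records


def simulate_cohort(
    design: CohortSpec,
    noise: NoiseSpec,
    seed: int,
) -> tuple[list[CqRecord], "pd.DataFrame"]:
    """Simulate a full cohort; returns Cq records and a truth table.

    The truth table (one row per sample) holds the study group, the seven
    integer copy numbers and the segment total, and is the ground truth
    against which calls are scored.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    freqs = design.freqs()
    n = design.n_samples
    fr = design.quality_fractions
    n_good = round(n * fr[0])
    n_pop = round(n * fr[1])
    groups = (["good"] * n_good + ["population"] * n_pop
              + ["bad"] * (n - n_good - n_pop))
    records: list[CqRecord] = []
    truth_rows = []
    for i, group in enumerate(groups, start=1):
        sid = f"S{i:03d}"
        gt = sample_genotype(freqs, rng)
        records.extend(simulate_cq(gt, noise, design, rng,
                                   sample_id=sid, study_group=group))
        row = {"sample_id": sid, "study_group": group}
        row.update(gt.locus_counts())
        row["total"] = gt.total_segments
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    return records, truth
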