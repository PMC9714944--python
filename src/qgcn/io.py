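"""Reading and writing Cq tables, sample metadata, configuration and results.

The canonical on-disk form is a long (tidy) CSV/TSV with one row per
well and channel:

    sample_id,assay_id,channel,replicate,run,cq[,template_mass]

Dropouts (no amplification, e.g. a zero-copy target locus) are encoded
as an empty Cq cell or the instrument literal ``Undetermined``; on
output they are always written as ``NA``.  A converter from wide 96-well
plate exports is provided for convenience.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .assays import ASSAYS, CHANNELS, REFERENCE_GENE, STUDY_GROUPS

_DROPOUT_LITERALS = {"", "na", "nan", "undetermined"}


@dataclass(frozen=True)
class CqRecord:
    """One well/channel quantification-cycle measurement.

    ``cq`` is ``None`` for a dropout well (target did not amplify, e.g.
    zero template copies).  ``template_mass`` (ng) is set only on
    calibration-series rows.
    """

    sample_id: str
    assay_id: str
    channel: str
    replicate: int
    run: int
    cq: float | None
    template_mass: float | None = None

    def __post_init__(self) -> None:
        if self.assay_id not in ASSAYS:
            raise ValueError(f"unknown assay_id {self.assay_id!r}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.cq is not None and not 0 < self.cq < 45:
            raise ValueError(f"Cq {self.cq} outside (0, 45)")

    @property
    def is_dropout(self) -> bool:
        return self.cq is None

    def key(self) -> tuple:
        return (self.sample_id, self.assay_id, self.run, self.replicate,
                self.channel)


@dataclass(frozen=True)
class SampleMeta:
    """Study-group label and, optionally, known integer copy numbers."""

    sample_id: str
    study_group: str = "population"
    known_gcns: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.study_group not in STUDY_GROUPS:
            raise ValueError(f"unknown study group {self.study_group!r}")
        if self.known_gcns is not None:
            for assay, n in self.known_gcns.items():
                if assay not in ASSAYS:
                    raise ValueError(f"unknown assay {assay!r} in known GCNs")
                if n != int(n) or n < 0:
                    raise ValueError(f"known GCN for {assay} must be a "
                                     f"non-negative integer, got {n}")


@dataclass(frozen=True)
class AssayConfig:
    """Per-assay calibration offset and classification windows.

    A measured copy number within ``ambiguity_halfwidth`` of an integer
    is unambiguous; beyond ``misclass_boundary`` (= 1 - halfwidth) from
    the true integer it falls into the catchment of a wrong integer.
    """

    assay_id: str
    calibration_offset: float = 0.0
    ambiguity_halfwidth: float = 0.3
    reference_gene: str = REFERENCE_GENE

    def __post_init__(self) -> None:
        if not 0 < self.ambiguity_halfwidth < 0.5:
            raise ValueError("ambiguity halfwidth must lie in (0, 0.5)")

    @property
    def misclass_boundary(self) -> float:
        return 1.0 - self.ambiguity_halfwidth


def _parse_cq(raw) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip().lower()
    if text in _DROPOUT_LITERALS:
        return None
    return float(raw)


def read_cq_table(path: str | Path, dialect: str = "csv") -> list[CqRecord]:
    """Read a long-format Cq table, validating keys and ranges.

    Duplicate (sample, assay, run, replicate, channel) keys and Cq
    values outside (0, 45) are hard errors naming the offending rows.
    """
    sep = "\t" if dialect in ("tsv", "tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"cq": str})
    required = {"sample_id", "assay_id", "channel", "replicate", "run", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records: list[CqRecord] = []
    seen: dict[tuple, int] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        mass = getattr(row, "template_mass", None)
        if mass is not None and (isinstance(mass, float) and math.isnan(mass)):
            mass = None
        try:
            rec = CqRecord(sample_id=str(row.sample_id), assay_id=row.assay_id,
                           channel=row.channel, replicate=int(row.replicate),
                           run=int(row.run), cq=_parse_cq(row.cq),
                           template_mass=None if mass is None else float(mass))
        except ValueError as exc:
            raise ValueError(f"{path} line {idx}: {exc}") from exc
        key = rec.key()
        if key in seen:
            raise ValueError(
                f"{path}: duplicate well key {key} on lines {seen[key]} and {idx}")
        seen[key] = idx
        records.append(rec)
    return records


def write_cq_table(records: list[CqRecord], path: str | Path) -> None:
    """Write Cq records in the canonical long format (dropouts as NA)."""
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id, "assay_id": r.assay_id,
            "channel": r.channel, "replicate": r.replicate, "run": r.run,
            "cq": "NA" if r.cq is None else f"{r.cq:.6g}",
            "template_mass": "" if r.template_mass is None else r.template_mass,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata: sample_id, study_group, optional GCN columns."""
    df = pd.read_csv(path)
    metas = []
    gcn_cols = [a for a in ASSAYS if a in df.columns]
    for _, row in df.iterrows():
        known = None
        if gcn_cols:
            vals = {a: row[a] for a in gcn_cols if pd.notna(row[a])}
            if vals:
                known = {a: int(v) for a, v in vals.items()}
        metas.append(SampleMeta(sample_id=str(row["sample_id"]),
                                study_group=row.get("study_group", "population"),
                                known_gcns=known))
    return metas


def read_gcn_table(path: str | Path) -> pd.DataFrame:
    """Read a per-sample measured-GCN matrix (sample_id + 7 assay columns).

    This is the layout of a detailed copy-number results sheet exported
    from a workbook: one row per sample, one column of average measured
    copy number per assay.  Returns a DataFrame indexed by sample_id.
    """
    df = pd.read_csv(path)
    missing = [a for a in ASSAYS if a not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing assay columns {missing}")
    return df.set_index("sample_id")


def wide_plate_to_records(
    df: pd.DataFrame,
    sample_id: str,
    assay_id: str,
    channel: str,
    run: int = 1,
) -> list[CqRecord]:
    """Convert a wide 96-well plate export (wells as columns) to records."""
    values = df.to_numpy().ravel()
    records = []
    for i, raw in enumerate(values, start=1):
        records.append(CqRecord(sample_id=sample_id, assay_id=assay_id,
                                channel=channel, replicate=i, run=run,
                                cq=_parse_cq(raw)))
    return records


# ---------------------------------------------------------------------------
# results

def write_results(calls, measured, metrics, out_dir: str | Path) -> dict[str, Path]:
    """Write the three result CSVs: measured GCNs, integer calls, QC metrics.

    ``measured`` is a list of :class:`qgcn.core.MeasuredGcn`, ``calls`` a
    list of :class:`qgcn.caller.IntegerGcnCall`, ``metrics`` a DataFrame
    (may be empty).  Numeric fields are written with 6 significant
    digits so that a read/write round trip is idempotent.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def fmt(x):
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return "NA"
        return f"{x:.6g}"

    mrows = [{
        "sample_id": m.sample_id, "assay_id": m.assay_id,
        "mean": fmt(m.mean), "sd": fmt(m.sd), "cv_percent": fmt(m.cv_percent),
        "ci95_low": fmt(m.ci95[0] if m.ci95 else None),
        "ci95_high": fmt(m.ci95[1] if m.ci95 else None),
        "n_wells": m.n_wells, "n_dropout": m.n_dropout,
    } for m in measured]
    mcols = ["sample_id", "assay_id", "mean", "sd", "cv_percent",
             "ci95_low", "ci95_high", "n_wells", "n_dropout"]
    measured_path = out_dir / "measured_gcns.csv"
    pd.DataFrame(mrows, columns=mcols).to_csv(measured_path, index=False)

    crows = [{
        "sample_id": c.sample_id, "total": c.total,
        **{a: c.gcns[a] for a in ASSAYS},
        "posterior": fmt(c.posterior),
        "cv_pass": c.cv_pass, "ambiguous": c.ambiguous,
        "consistency_pass": c.consistency_pass,
    } for c in calls]
    ccols = (["sample_id", "total"] + list(ASSAYS)
             + ["posterior", "cv_pass", "ambiguous", "consistency_pass"])
    calls_path = out_dir / "integer_calls.csv"
    pd.DataFrame(crows, columns=ccols).to_csv(calls_path, index=False)

    metrics_path = out_dir / "qc_metrics.csv"
    (metrics if metrics is not None else pd.DataFrame()).to_csv(
        metrics_path, index=False)
    return {"measured": measured_path, "calls": calls_path,
            "metrics": metrics_path}


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Structured configuration: per-assay settings plus caller thresholds."""

    assays: dict[str, AssayConfig] = field(default_factory=dict)
    posterior_threshold: float = 0.95
    deviation_threshold: float = 0.4
    lda_regularization: float = 1e-6

    def __post_init__(self) -> None:
        for a in ASSAYS:
            self.assays.setdefault(a, AssayConfig(assay_id=a))


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    assays = {}
    for a, cfg in (raw.get("assays") or {}).items():
        assays[a] = AssayConfig(assay_id=a, **(cfg or {}))
    return PipelineConfig(
        assays=assays,
        posterior_threshold=raw.get("posterior_threshold", 0.95),
        deviation_threshold=raw.get("deviation_threshold", 0.4),
        lda_regularization=raw.get("lda_regularization", 1e-6),
    )


def save_config(config: PipelineConfig, path: str | Path) -> None:
    raw = {
        "posterior_threshold": config.posterior_threshold,
        "deviation_threshold": config.deviation_threshold,
        "lda_regularization": config.lda_regularization,
        "assays": {
            a: {"calibration_offset": c.calibration_offset,
                "ambiguity_halfwidth": c.ambiguity_halfwidth,
                "reference_gene": c.reference_gene}
            for a, c in config.assays.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
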