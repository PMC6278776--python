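"""Sized-allele tables, patient metadata and run configuration.

The unit of data is one *sample*: the list of individually sized expanded
alleles (in CTG-repeat units) obtained by single-molecule small-pool PCR
from one patient, tissue and time point.  Tables are plain TSV:

``alleles.tsv``
    columns ``patient_id, tissue, timepoint, age_at_sampling, size`` —
    one row per sized molecule.
``patients.tsv``
    columns ``patient_id, sex, group, age_at_onset, pattern,
    interrupted_block_override`` — one row per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .patterns import InterruptionPattern, parse_interruption_pattern

__all__ = [
    "MIN_ALLELES_QC",
    "AlleleSample",
    "PatientRecord",
    "read_allele_table",
    "write_allele_table",
    "read_patient_table",
    "write_summary_table",
    "load_config",
]

#: Minimum number of sized alleles per sample required by the sizing QC.
MIN_ALLELES_QC = 200

ALLELE_COLUMNS = ["patient_id", "tissue", "timepoint", "age_at_sampling", "size"]

TISSUES = ("blood", "buccal")
TIMEPOINTS = ("t1", "t2")


@dataclass
class AlleleSample:
    """Sized alleles for one patient/tissue/timepoint.

    ``sizes`` are allele lengths in trinucleotide repeat units; gel sizing is
    continuous, so they are stored as floats and only integerised when a
    modal length is taken.
    """

    patient_id: str
    tissue: str
    timepoint: str
    age_at_sampling: float
    sizes: np.ndarray
    is_five_prime_view: bool = False

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.sizes.size == 0:
            raise ValueError(
                f"{self.patient_id}/{self.tissue}/{self.timepoint}: "
                "sample has no sized alleles"
            )
        if not np.all(self.sizes > 0):
            raise ValueError(
                f"{self.patient_id}/{self.tissue}/{self.timepoint}: "
                "allele sizes must be positive"
            )
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")

    @property
    def n_alleles(self) -> int:
        return int(self.sizes.size)

    @property
    def low_count_flag(self) -> bool:
        """True when fewer than 200 alleles were sized (QC flag, not a
        rejection)."""
        return self.n_alleles < MIN_ALLELES_QC

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.patient_id, self.tissue, self.timepoint)


@dataclass
class PatientRecord:
    """Per-patient metadata plus the patient's allele samples."""

    patient_id: str
    sex: str
    group: str  # interrupted | control | reference
    age_at_onset: float | None
    pattern: InterruptionPattern | None
    interrupted_block_override: int | None = None
    samples: list[AlleleSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_at_onset is not None and self.age_at_onset < 0:
            raise ValueError(f"{self.patient_id}: age_at_onset must be >= 0")
        keys = [s.key for s in self.samples]
        if len(keys) != len(set(keys)):
            raise ValueError(
                f"{self.patient_id}: duplicate (tissue, timepoint) sample"
            )

    def sample(self, tissue: str, timepoint: str) -> AlleleSample | None:
        for s in self.samples:
            if s.tissue == tissue and s.timepoint == timepoint:
                return s
        return None


def _samples_from_frame(df: pd.DataFrame) -> list[AlleleSample]:
    samples = []
    for (pid, tissue, tp), grp in df.groupby(
        ["patient_id", "tissue", "timepoint"], sort=True
    ):
        ages = grp["age_at_sampling"].unique()
        if len(ages) > 1:
            raise ValueError(
                f"{pid}/{tissue}/{tp}: conflicting age_at_sampling values "
                f"{sorted(ages)}"
            )
        samples.append(
            AlleleSample(
                patient_id=str(pid),
                tissue=str(tissue),
                timepoint=str(tp),
                age_at_sampling=float(ages[0]),
                sizes=grp["size"].to_numpy(dtype=float),
            )
        )
    return samples


def read_allele_table(path: str | Path) -> list[AlleleSample]:
    """Read a sized-allele TSV into one :class:`AlleleSample` per
    (patient, tissue, timepoint) group.

    Raises
    ------
    ValueError
        On missing columns, non-numeric sizes, or duplicate groups with
        conflicting ages.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ALLELE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("age_at_sampling", "size"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            bad = df.index[df[col].isna()].tolist()[:5]
            raise ValueError(f"{path}: non-numeric {col} at rows {bad}")
    return _samples_from_frame(df)


def allele_frame(samples: Iterable[AlleleSample]) -> pd.DataFrame:
    """Long-format allele table (inverse of :func:`read_allele_table`)."""
    rows = []
    for s in samples:
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "tissue": s.tissue,
                    "timepoint": s.timepoint,
                    "age_at_sampling": s.age_at_sampling,
                    "size": s.sizes,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=ALLELE_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def write_allele_table(samples: Iterable[AlleleSample], path: str | Path) -> None:
    allele_frame(samples).to_csv(path, sep="\t", index=False)


def read_patient_table(path: str | Path) -> dict[str, PatientRecord]:
    """Read patient metadata TSV into records keyed by patient id."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = ["patient_id", "sex", "group", "age_at_onset", "pattern"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records: dict[str, PatientRecord] = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        if pid in records:
            raise ValueError(f"{path}: duplicate patient_id {pid}")
        ao = row["age_at_onset"]
        ao = None if pd.isna(ao) else float(ao)
        pat_text = row["pattern"]
        pattern = (
            None
            if pd.isna(pat_text) or not str(pat_text).strip()
            else parse_interruption_pattern(str(pat_text))
        )
        override = row.get("interrupted_block_override")
        override = None if pd.isna(override) else int(override)
        records[pid] = PatientRecord(
            patient_id=pid,
            sex=str(row["sex"]),
            group=str(row["group"]),
            age_at_onset=ao,
            pattern=pattern,
            interrupted_block_override=override,
        )
    return records


def attach_samples(
    records: dict[str, PatientRecord], samples: Sequence[AlleleSample]
) -> dict[str, PatientRecord]:
    """Attach allele samples to their patient records (in place)."""
    for s in samples:
        if s.patient_id not in records:
            raise ValueError(f"sample for unknown patient {s.patient_id!r}")
        records[s.patient_id].samples.append(s)
    for rec in records.values():
        keys = [s.key for s in rec.samples]
        if len(keys) != len(set(keys)):
            raise ValueError(
                f"{rec.patient_id}: duplicate (tissue, timepoint) sample"
            )
    return records


def write_summary_table(summaries, path: str | Path) -> None:
    """Write MosaicismSummary records (or any dataclass sequence) as TSV."""
    from dataclasses import asdict, is_dataclass

    rows = [asdict(s) if is_dataclass(s) else dict(s) for s in summaries]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (model forms, coefficients, seeds)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
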