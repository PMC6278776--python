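"""End-to-end orchestration: data -> metrics -> models -> comparisons.

Produces a report bundle shaped like the analysis' published tables:

* ``table1`` — per patient: sex, interruption pattern, age at onset, and
  per-time-point age at sampling and 10th-percentile (ePAL) estimates;
* ``table2`` — per patient with two blood samplings: whole-repeat and
  5'-end modal lengths, the between-time-point AFD test, the sampling
  interval and observed/expected modal increments;
* ``tests`` — every comparison of the matrix, with skipped comparisons
  and their reasons logged alongside;
* ``figure_data`` — density-curve and residual-scatter coordinates for
  AFD and residual plots.

Numbers in the TSV tables are printed at table precision (percentiles to
0.5 repeat, p-values to two significant figures); ``bundle.json`` keeps
full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import ComparisonMatrix, run_comparison_matrix
from .io import AlleleSample, PatientRecord
from .metrics import density_curve, five_prime_view, summarize_sample
from .models import expected_increment
from .patterns import PatternError, interrupted_block_length

logger = logging.getLogger("somamosaic")

__all__ = ["ReportBundle", "run_full_analysis", "write_bundle",
           "read_reference_table"]

REFERENCE_COLUMNS = [
    "patient_id", "timepoint", "epal", "age_at_sampling", "si", "mode",
    "age_at_onset", "interval",
]


def read_reference_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format reference-cohort table (one row per subject and
    time point)."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


@dataclass
class ReportBundle:
    """All tables and plot data of one full analysis run."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    tests: pd.DataFrame
    skipped: pd.DataFrame
    fits: dict[str, dict]
    figure_data: dict[str, pd.DataFrame] = field(default_factory=dict)


def _round_half(x: float) -> float:
    return round(x * 2) / 2


def _interrupted_len(rec: PatientRecord) -> int | None:
    """Subtraction constant for the 5'-end view, or None if unavailable."""
    if rec.pattern is None and rec.interrupted_block_override is None:
        return None
    try:
        return interrupted_block_length(
            rec.pattern, rec.interrupted_block_override
        ) if rec.pattern is not None else rec.interrupted_block_override
    except PatternError:
        return None


def _build_table1(records: dict[str, PatientRecord]) -> pd.DataFrame:
    rows = []
    for pid, rec in sorted(records.items()):
        row = {
            "patient_id": pid,
            "sex": rec.sex,
            "group": rec.group,
            "pattern": rec.pattern.format() if rec.pattern else "",
            "age_at_onset": rec.age_at_onset,
        }
        for tp in ("t1", "t2"):
            s = rec.sample("blood", tp)
            if s is not None:
                summ = summarize_sample(s)
                row[f"age_at_sampling_{tp}"] = s.age_at_sampling
                row[f"p10_{tp}"] = _round_half(summ.p10)
                row[f"si_{tp}"] = _round_half(summ.si)
            else:
                row[f"age_at_sampling_{tp}"] = None
                row[f"p10_{tp}"] = None
                row[f"si_{tp}"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def _build_table2(
    records: dict[str, PatientRecord],
    matrix: ComparisonMatrix,
    bandwidth: float | None,
) -> pd.DataFrame:
    afd_time = {r.label: r for r in matrix.family("afd_time")}
    incr_fit = matrix.fits.get("INCR")
    rows = []
    for pid, rec in sorted(records.items()):
        s1, s2 = rec.sample("blood", "t1"), rec.sample("blood", "t2")
        if s1 is None or s2 is None:
            continue
        m1 = summarize_sample(s1, bandwidth=bandwidth)
        m2 = summarize_sample(s2, bandwidth=bandwidth)
        c = _interrupted_len(rec) or 0
        try:
            m1_5 = summarize_sample(five_prime_view(s1, c), bandwidth=bandwidth)
            m2_5 = summarize_sample(five_prime_view(s2, c), bandwidth=bandwidth)
            mode5_t1, mode5_t2 = m1_5.mode, m2_5.mode
        except ValueError:
            mode5_t1 = mode5_t2 = None
        interval = s2.age_at_sampling - s1.age_at_sampling
        test = afd_time.get(pid)
        expected = (
            expected_increment(incr_fit, m1.mode, interval)
            if incr_fit is not None else None
        )
        expected5 = (
            expected_increment(incr_fit, mode5_t1, interval)
            if incr_fit is not None and mode5_t1 is not None else None
        )
        rows.append(
            {
                "patient_id": pid,
                "mode_t1": m1.mode,
                "mode_t2": m2.mode,
                "mode_5prime_t1": mode5_t1,
                "mode_5prime_t2": mode5_t2,
                "W": test.statistic if test else None,
                "p_value": float(f"{test.p_two_tailed:.2g}") if test else None,
                "interval": interval,
                "observed_increment": m2.mode - m1.mode,
                "expected_increment": expected,
                "expected_increment_5prime": expected5,
            }
        )
    return pd.DataFrame(rows)


def _figure_data(
    records: dict[str, PatientRecord], matrix: ComparisonMatrix
) -> dict[str, pd.DataFrame]:
    dens_rows = []
    for pid, rec in sorted(records.items()):
        for s in rec.samples:
            grid, dens = density_curve(s)
            dens_rows.append(
                pd.DataFrame(
                    {
                        "patient_id": pid,
                        "tissue": s.tissue,
                        "timepoint": s.timepoint,
                        "size": grid,
                        "density": dens,
                    }
                )
            )
    scatter_rows = []
    for key, fit in matrix.fits.items():
        if fit.model is None:
            continue
        data = fit.model.data
        for subj, resid in fit.std_residuals.items():
            scatter_rows.append(
                {
                    "fit": key,
                    "patient_id": subj,
                    "predictor": float(
                        data.loc[subj, fit.spec.predictors[0][0]]
                    ),
                    "std_residual": float(resid),
                }
            )
    out = {}
    if dens_rows:
        out["density_curves"] = pd.concat(dens_rows, ignore_index=True)
    if scatter_rows:
        out["residual_scatter"] = pd.DataFrame(scatter_rows)
    return out


def run_full_analysis(
    records: dict[str, PatientRecord],
    reference: pd.DataFrame,
    *,
    bandwidth: float | None = None,
    figure_data: bool = True,
) -> ReportBundle:
    """Run the whole pipeline on study records plus a reference cohort.

    Deterministic given its inputs.  Comparisons whose inputs are missing
    are skipped and logged, never silently dropped.
    """
    matrix = run_comparison_matrix(records, reference, bandwidth=bandwidth)
    for family, label, reason in matrix.skipped:
        logger.info("skipped %s/%s: %s", family, label, reason)
    fits = {
        key: {
            "model": fit.spec.name,
            "params": [float(v) for v in fit.params],
            "param_names": fit.spec.param_names,
            "r_squared": fit.r_squared,
            "n": fit.n,
        }
        for key, fit in matrix.fits.items()
    }
    return ReportBundle(
        table1=_build_table1(records),
        table2=_build_table2(records, matrix, bandwidth),
        tests=matrix.frame(),
        skipped=pd.DataFrame(
            matrix.skipped, columns=["family", "label", "reason"]
        ),
        fits=fits,
        figure_data=_figure_data(records, matrix) if figure_data else {},
    )


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write the bundle as TSV tables plus a full-precision JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.table1.to_csv(out / "table1.tsv", sep="\t", index=False)
    bundle.table2.to_csv(out / "table2.tsv", sep="\t", index=False)
    tests = bundle.tests.copy()
    if not tests.empty:
        tests["p_two_tailed"] = tests["p_two_tailed"].map(
            lambda p: float(f"{p:.3g}")
        )
    tests.to_csv(out / "tests.tsv", sep="\t", index=False)
    bundle.skipped.to_csv(out / "skipped.tsv", sep="\t", index=False)
    for name, frame in bundle.figure_data.items():
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    sidecar = {
        "fits": bundle.fits,
        "tests": bundle.tests.to_dict(orient="records"),
        "table2": bundle.table2.to_dict(orient="records"),
    }
    with open(out / "bundle.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if obj is pd.NA or (isinstance(obj, float) and np.isnan(obj)):
        return None
    raise TypeError(f"not JSON serialisable: {type(obj)}")
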