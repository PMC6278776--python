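"""Nonparametric comparison harness for allele distributions and residuals.

Implements the full comparison matrix of the analysis:

(a) per-patient blood-vs-buccal AFD rank-sum tests (tissue specificity);
(b) per-patient first-vs-second time point AFD rank-sum tests (progression);
(c) per-group observed-vs-expected somatic instability, paired signed-rank;
(d) per-group observed-vs-expected modal-size increments, paired signed-rank;
(e) interrupted-vs-reference and control-vs-reference comparisons of
    standardised model residuals (M8/M10/M11), rank-sum;
(f) within-group M11-vs-M10 standardised-residual paired signed-rank.

The rank-sum statistic ``W`` is the Mann–Whitney count of the first sample
(pairs won plus half-ties); the signed-rank statistic ``V`` is the sum of
positive-difference ranks.  Exact two-sided p-values are computed by
enumeration of the null distribution (count-based dynamic programming) for
small samples, and by a normal approximation with tie and continuity
corrections otherwise — deliberately in-house, because the exactness
conventions (two-sided doubling, midranks, zero-dropping) are part of the
analysis contract.  Normality is recorded via a Shapiro–Wilk gate but, as
throughout this analysis, the nonparametric test is used regardless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import PatientRecord
from .metrics import instability_range, percentile_length, summarize_sample
from .models import (
    DEFAULT_SPECS,
    RegressionFit,
    RepeatRegression,
    attach_si_residual,
)

__all__ = [
    "TestResult",
    "rank_sum_test",
    "signed_rank_test",
    "shapiro_wilk_gate",
    "ComparisonMatrix",
    "run_comparison_matrix",
    "ALPHA",
]

#: Two-tailed significance level used throughout (no multiplicity correction).
ALPHA = 0.05

#: Exact rank-sum enumeration is used when n1*n2 <= this and there are no ties.
EXACT_RANKSUM_LIMIT = 400
#: Exact signed-rank enumeration is used when n (nonzero differences) <= this.
EXACT_SIGNEDRANK_LIMIT = 25


@dataclass(frozen=True)
class TestResult:
    """Outcome of one comparison.

    ``statistic`` is W for rank-sum (Mann–Whitney count of the first
    sample), V for signed-rank (sum of positive ranks) and the W-statistic
    for Shapiro–Wilk.  ``orientation`` records which sample came first so
    the reflection identity W -> n1*n2 - W keeps reports unambiguous.
    """

    method: str  # rank_sum | signed_rank | shapiro_wilk
    statistic: float
    p_two_tailed: float
    n1: int
    n2: int = 0
    exact: bool = False
    orientation: str = ""
    family: str = ""
    label: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_tailed <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_two_tailed < ALPHA


def _ranksum_exact_counts(n1: int, n2: int) -> np.ndarray:
    """Exact U-distribution counts via generating-function convolution.

    The number of assignments with rank configuration giving U equals the
    coefficient of q^U in the Gaussian binomial [n1+n2 choose n1]_q.
    Computed by multiplying (1-q^{n2+j})/(1-q^j) iteratively in integer
    coefficient arrays — O(n1 * n1 * n2) and exact in floating point for
    the sizes used here.
    """
    max_u = n1 * n2
    coef = np.zeros(max_u + 1, dtype=float)
    coef[0] = 1.0
    for j in range(1, n1 + 1):
        # multiply by (1 - q^{n2+j}), then divide by (1 - q^j)
        nxt = coef.copy()
        if n2 + j <= max_u:
            nxt[n2 + j:] -= coef[: max_u + 1 - (n2 + j)]
        # divide by (1 - q^j): prefix recurrence
        for u in range(j, max_u + 1):
            nxt[u] += nxt[u - j]
        coef = nxt
    return coef


def _two_sided_from_counts(counts: np.ndarray, obs: float) -> float:
    total = counts.sum()
    cdf = counts.cumsum()
    k = int(np.floor(obs + 1e-9))
    p_le = cdf[k] / total if k >= 0 else 0.0
    p_ge = (total - (cdf[k - 1] if k >= 1 else 0.0)) / total
    # half-integer statistics (ties) fall between lattice points
    if abs(obs - round(obs)) > 1e-9:
        p_le = cdf[int(np.floor(obs))] / total
        p_ge = (total - cdf[int(np.floor(obs))]) / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def rank_sum_test(
    x,
    y,
    *,
    orientation: str = "x_first",
    exact_limit: int = EXACT_RANKSUM_LIMIT,
    continuity: bool = True,
    **labels,
) -> TestResult:
    """Wilcoxon–Mann–Whitney test of two independent samples.

    W is the Mann–Whitney count of the first sample: the number of (x, y)
    pairs with x > y plus half the tied pairs.  Exact enumeration is used
    when ``n1*n2 <= exact_limit`` and the pooled data are tie-free;
    otherwise a normal approximation with tie correction and (optional)
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires two non-empty samples")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    w = r1 - n1 * (n1 + 1) / 2.0  # Mann–Whitney count of x

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if not has_ties and n1 * n2 <= exact_limit:
        counts = _ranksum_exact_counts(n1, n2)
        p = _two_sided_from_counts(counts, w)
        exact = True
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            diff = w - mu
            cc = 0.5 if continuity else 0.0
            adj = max(abs(diff) - cc, 0.0)
            z = adj / np.sqrt(var)
            p = float(min(1.0, 2.0 * stats.norm.sf(z)))
        exact = False
    return TestResult(
        method="rank_sum", statistic=float(w), p_two_tailed=p,
        n1=n1, n2=n2, exact=exact, orientation=orientation, **labels,
    )


def _signed_rank_exact_p(ranks2: np.ndarray, v2: int) -> float:
    """Exact two-sided p for the signed-rank statistic.

    ``ranks2`` are doubled (mid)ranks so the lattice is integer; the null
    assigns +rank or 0 to each with probability 1/2.  Distribution built by
    subset-sum convolution: exact conditional on the observed tie pattern.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return _two_sided_from_counts(counts, v2)


def signed_rank_test(
    differences,
    *,
    exact_limit: int = EXACT_SIGNEDRANK_LIMIT,
    continuity: bool = True,
    **labels,
) -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking; ties get midranks.  V is
    the sum of ranks of positive differences.  Exact enumeration of all
    2^n sign patterns (via subset-sum counting) when n <= ``exact_limit``,
    else normal approximation with tie and continuity corrections.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("signed_rank_test: all differences are zero")
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())

    if n <= exact_limit:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _signed_rank_exact_p(ranks2, int(round(2 * v)))
        exact = True
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
            (tie_counts**3 - tie_counts).sum()
        ) / 48.0
        if var <= 0:
            p = 1.0
        else:
            cc = 0.5 if continuity else 0.0
            adj = max(abs(v - mu) - cc, 0.0)
            p = float(min(1.0, 2.0 * stats.norm.sf(adj / np.sqrt(var))))
        exact = False
    return TestResult(
        method="signed_rank", statistic=v, p_two_tailed=p,
        n1=n, n2=n, exact=exact, orientation="positive_ranks", **labels,
    )


def shapiro_wilk_gate(x, **labels) -> TestResult:
    """Shapiro–Wilk normality gate at alpha = 0.05.

    The harness records the gate outcome but proceeds with the
    nonparametric test either way.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("shapiro_wilk_gate requires n >= 3")
    if x.size > 5000:
        raise ValueError("shapiro_wilk_gate requires n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("shapiro_wilk_gate: sample has zero variance")
    w, p = stats.shapiro(x)
    return TestResult(
        method="shapiro_wilk", statistic=float(w), p_two_tailed=float(p),
        n1=int(x.size), exact=False, orientation="", **labels,
    )


# ---------------------------------------------------------------------------
# full comparison matrix
# ---------------------------------------------------------------------------

STUDY_GROUPS = ("interrupted", "control")


@dataclass
class ComparisonMatrix:
    """All comparison results plus the model fits behind them."""

    results: list[TestResult] = field(default_factory=list)
    skipped: list[tuple[str, str, str]] = field(default_factory=list)
    fits: dict[str, RegressionFit] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        from dataclasses import asdict

        return pd.DataFrame([asdict(r) for r in self.results])

    def skip(self, family: str, label: str, reason: str) -> None:
        self.skipped.append((family, label, reason))

    def family(self, name: str) -> list[TestResult]:
        return [r for r in self.results if r.family == name]


def study_rows(
    records: dict[str, PatientRecord], timepoint: str, tissue: str = "blood"
) -> pd.DataFrame:
    """Per-subject model rows for study patients at one time point."""
    rows = {}
    for pid, rec in records.items():
        s = rec.sample(tissue, timepoint)
        if s is None:
            continue
        rows[pid] = {
            "group": rec.group,
            "epal": percentile_length(s, 10),
            "age_at_sampling": s.age_at_sampling,
            "si": instability_range(s),
            "mode": summarize_sample(s).mode,
            "age_at_onset": rec.age_at_onset,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def run_comparison_matrix(
    records: dict[str, PatientRecord],
    reference: pd.DataFrame,
    *,
    timepoints: tuple[str, ...] = ("t1", "t2"),
    bandwidth: float | None = None,
) -> ComparisonMatrix:
    """Run the full comparison matrix of the analysis.

    Parameters
    ----------
    records : dict
        Study patients (groups ``interrupted``/``control``) with attached
        allele samples.
    reference : pandas.DataFrame
        Reference-cohort rows, one per subject and time point, with columns
        ``patient_id, timepoint, epal, age_at_sampling, si, mode,
        age_at_onset, interval`` (``age_at_onset`` may be missing for
        asymptomatic subjects).

    Any comparison whose inputs are unavailable is skipped with a logged
    reason rather than failing the run.
    """
    mx = ComparisonMatrix()

    # (a) tissue specificity: blood vs buccal per patient, matched timepoint
    for pid, rec in sorted(records.items()):
        done = False
        for tp in reversed(timepoints):  # prefer the later sampling
            blood, buccal = rec.sample("blood", tp), rec.sample("buccal", tp)
            if blood is not None and buccal is not None:
                mx.results.append(
                    rank_sum_test(
                        blood.sizes, buccal.sizes,
                        orientation="blood_first",
                        family="afd_tissue", label=pid, timepoint=tp,
                    )
                )
                done = True
                break
        if not done:
            mx.skip("afd_tissue", pid, "no matched blood/buccal samples")

    # (b) progression: blood t1 vs t2 per patient
    for pid, rec in sorted(records.items()):
        s1, s2 = rec.sample("blood", "t1"), rec.sample("blood", "t2")
        if s1 is None or s2 is None:
            mx.skip("afd_time", pid, "missing blood sample at one time point")
            continue
        mx.results.append(
            rank_sum_test(
                s1.sizes, s2.sizes, orientation="t1_first",
                family="afd_time", label=pid,
            )
        )

    ref_by_tp = {tp: grp.set_index("patient_id")
                 for tp, grp in reference.groupby("timepoint")}

    for tp in timepoints:
        if tp not in ref_by_tp:
            mx.skip("models", tp, "no reference rows at this time point")
            continue
        ref = ref_by_tp[tp]
        study = study_rows(records, tp)
        combined = pd.concat(
            [ref.assign(group="reference")[
                ["group", "epal", "age_at_sampling", "si", "mode",
                 "age_at_onset"]],
             study],
        )

        # M8 fit on the combined cohort
        try:
            fit8 = RepeatRegression(DEFAULT_SPECS["M8"], combined).fit()
        except ValueError as exc:
            mx.skip("models", f"M8/{tp}", str(exc))
            continue
        mx.fits[f"M8/{tp}"] = fit8

        # (c) observed vs expected SI per group
        expected_si = fit8.predict(combined)
        for grp in STUDY_GROUPS + ("reference",):
            idx = combined.index[
                (combined["group"] == grp) & combined["si"].notna()
            ]
            idx = idx.intersection(expected_si.index)
            diffs = combined.loc[idx, "si"] - expected_si.loc[idx]
            if len(diffs) < 2 or (diffs == 0).all():
                mx.skip("si_obs_vs_exp", f"{grp}/{tp}", "too few paired values")
                continue
            mx.results.append(
                signed_rank_test(
                    diffs.to_numpy(), family="si_obs_vs_exp",
                    label=grp, timepoint=tp,
                )
            )

        # (e) standardized residual comparisons vs reference, model M8
        _residual_family(mx, fit8, combined, "M8", tp)

        # AO models M10, M11 on symptomatic subjects
        ao_rows = attach_si_residual(
            combined.loc[fit8.std_residuals.index], fit8
        )
        ao_rows = ao_rows[ao_rows["age_at_onset"].notna()]
        fit10 = fit11 = None
        try:
            fit10 = RepeatRegression(DEFAULT_SPECS["M10"], ao_rows).fit()
            mx.fits[f"M10/{tp}"] = fit10
            _residual_family(mx, fit10, combined, "M10", tp)
        except ValueError as exc:
            mx.skip("residual_vs_reference", f"M10/{tp}", str(exc))
        try:
            fit11 = RepeatRegression(DEFAULT_SPECS["M11"], ao_rows).fit()
            mx.fits[f"M11/{tp}"] = fit11
            _residual_family(mx, fit11, combined, "M11", tp)
        except ValueError as exc:
            mx.skip("residual_vs_reference", f"M11/{tp}", str(exc))

        # (f) M11 vs M10 standardized residuals within each group
        if fit10 is not None and fit11 is not None:
            for grp in STUDY_GROUPS + ("reference",):
                idx = combined.index[combined["group"] == grp]
                idx = idx.intersection(fit10.std_residuals.index).intersection(
                    fit11.std_residuals.index
                )
                d = (
                    fit11.std_residuals.loc[idx] - fit10.std_residuals.loc[idx]
                ).to_numpy()
                if len(d) < 2 or np.all(d == 0):
                    mx.skip("m11_vs_m10", f"{grp}/{tp}", "too few paired values")
                    continue
                mx.results.append(
                    signed_rank_test(
                        d, family="m11_vs_m10", label=grp, timepoint=tp,
                    )
                )

    # (d) observed vs expected increments per group
    _increment_family(mx, records, ref_by_tp)
    return mx


def _residual_family(
    mx: ComparisonMatrix,
    fit: RegressionFit,
    combined: pd.DataFrame,
    model_name: str,
    tp: str,
) -> None:
    resid = fit.std_residuals
    groups = combined.loc[resid.index, "group"]
    ref_vals = resid[groups == "reference"].to_numpy()
    if ref_vals.size == 0:
        mx.skip("residual_vs_reference", f"{model_name}/{tp}", "no reference residuals")
        return
    try:
        mx.results.append(
            shapiro_wilk_gate(
                ref_vals, family="normality_gate",
                label=f"{model_name}/reference", timepoint=tp,
            )
        )
    except ValueError:
        pass
    for grp in STUDY_GROUPS:
        vals = resid[groups == grp].to_numpy()
        if vals.size == 0:
            mx.skip(
                "residual_vs_reference", f"{model_name}/{grp}/{tp}",
                "no residuals for group",
            )
            continue
        mx.results.append(
            rank_sum_test(
                vals, ref_vals, orientation=f"{grp}_first",
                family="residual_vs_reference",
                label=f"{model_name}/{grp}", timepoint=tp,
            )
        )


def _increment_family(mx, records, ref_by_tp) -> None:
    from .metrics import observed_increment

    if "t1" not in ref_by_tp or "t2" not in ref_by_tp:
        mx.skip("incr_obs_vs_exp", "all", "reference lacks two time points")
        return
    r1, r2 = ref_by_tp["t1"], ref_by_tp["t2"]
    shared = r1.index.intersection(r2.index)
    incr = pd.DataFrame(
        {
            "observed_increment": r2.loc[shared, "mode"] - r1.loc[shared, "mode"],
            "mode": r1.loc[shared, "mode"],
            "interval": r1.loc[shared, "interval"],
        }
    ).dropna()
    if len(incr) < 4:
        mx.skip("incr_obs_vs_exp", "all", "too few reference increments")
        return
    fit_incr = RepeatRegression(DEFAULT_SPECS["INCR"], incr).fit()
    mx.fits["INCR"] = fit_incr

    groups: dict[str, list[float]] = {g: [] for g in STUDY_GROUPS}
    for pid, rec in sorted(records.items()):
        if rec.group not in groups:
            continue
        s1, s2 = rec.sample("blood", "t1"), rec.sample("blood", "t2")
        if s1 is None or s2 is None:
            mx.skip("incr_obs_vs_exp", pid, "missing a blood time point")
            continue
        rec_incr = observed_increment(summarize_sample(s1), summarize_sample(s2))
        expected = fit_incr.predict(
            pd.DataFrame(
                {"mode": [rec_incr.mode_t1], "interval": [rec_incr.interval]}
            )
        ).iloc[0]
        groups[rec.group].append(rec_incr.observed_increment - expected)
    for grp, diffs in groups.items():
        if len(diffs) < 2:
            mx.skip("incr_obs_vs_exp", grp, "too few paired increments")
            continue
        mx.results.append(
            signed_rank_test(np.array(diffs), family="incr_obs_vs_exp", label=grp)
        )
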