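"""Allele-frequency-distribution statistics for somatic mosaicism.

For each sample the pipeline reports:

* **ePAL** — the estimated progenitor allele length, taken as the 10th
  percentile of the allele frequency distribution (AFD).  Somatic mutation
  is expansion-biased, so the inherited length sits near the lower edge of
  the distribution.
* **SI** — the observed level of somatic instability, the 90th − 10th
  percentile range of the AFD.
* **mode** — the modal expansion size in whole repeats, used for
  size-increment comparisons between time points.

A *5'-end view* of an interrupted expansion is obtained by subtracting the
(constant) interrupted 3'-block length from every sized allele; SI is
invariant under this shift while ePAL and the mode move down by the
constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import AlleleSample

__all__ = [
    "MosaicismSummary",
    "IncrementRecord",
    "percentile_length",
    "instability_range",
    "modal_length",
    "five_prime_view",
    "summarize_sample",
    "observed_increment",
    "density_curve",
]


@dataclass(frozen=True)
class MosaicismSummary:
    """Per-sample AFD statistics (one patient/tissue/timepoint)."""

    patient_id: str
    tissue: str
    timepoint: str
    age_at_sampling: float
    n_alleles: int
    p10: float
    p90: float
    si: float
    mode: int
    is_five_prime_view: bool = False
    low_count_flag: bool = False

    def __post_init__(self) -> None:
        if self.p10 > self.p90:
            raise ValueError("p10 must not exceed p90")
        if self.n_alleles < 1:
            raise ValueError("n_alleles must be >= 1")


@dataclass(frozen=True)
class IncrementRecord:
    """Modal expansion-size change for one patient/tissue between samplings."""

    patient_id: str
    tissue: str
    mode_t1: int
    mode_t2: int
    interval: float
    observed_increment: int
    expected_increment: float | None = None

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("sampling interval must be positive")
        if self.observed_increment != self.mode_t2 - self.mode_t1:
            raise ValueError("observed_increment must equal mode_t2 - mode_t1")


def percentile_length(sample: AlleleSample, q: float) -> float:
    """Order-statistic percentile of the AFD with linear interpolation.

    Uses the rank convention h = (n−1)·q/100 + 1 (numpy's default
    ``linear`` method), which yields the half-integer percentiles seen in
    sized-allele tables.
    """
    if not 0 < q < 100:
        raise ValueError(f"percentile q={q} must be in (0, 100)")
    return float(np.percentile(sample.sizes, q, method="linear"))


def instability_range(sample: AlleleSample) -> float:
    """SI: the 90th − 10th percentile range of the AFD (>= 0)."""
    return percentile_length(sample, 90) - percentile_length(sample, 10)


def modal_length(sample: AlleleSample, bandwidth: float | None = None) -> int:
    """Modal allele length in whole repeats.

    Sizes are rounded to the nearest integer repeat and tallied into an
    integer histogram.  The histogram is optionally smoothed with a Gaussian
    kernel before taking the argmax; ``bandwidth=None`` applies Silverman's
    rule-of-thumb computed on the raw sizes, ``bandwidth=0`` disables
    smoothing.  Ties break toward the smallest length.
    """
    sizes = np.round(sample.sizes).astype(int)
    lo, hi = sizes.min(), sizes.max()
    counts = np.bincount(sizes - lo, minlength=hi - lo + 1).astype(float)
    if bandwidth is None:
        n = sizes.size
        sd = float(np.std(sample.sizes, ddof=1)) if n > 1 else 0.0
        iqr = float(np.subtract(*np.percentile(sample.sizes, [75, 25])))
        spread = min(sd, iqr / 1.349) if iqr > 0 else sd
        bandwidth = 0.9 * spread * n ** (-1 / 5) if spread > 0 else 0.0
    if bandwidth and bandwidth > 0 and counts.size > 1:
        counts = ndimage.gaussian_filter1d(counts, sigma=bandwidth, mode="constant")
    # argmax returns the first (smallest) index on ties
    return int(lo + int(np.argmax(counts)))


def five_prime_view(sample: AlleleSample, interrupted_len: float) -> AlleleSample:
    """Shift every allele down by the interrupted 3'-block length.

    The result is flagged ``is_five_prime_view``; its SI equals the SI of
    the original sample (shift invariance).
    """
    if interrupted_len < 0:
        raise ValueError("interrupted_len must be >= 0")
    if interrupted_len >= sample.sizes.min():
        raise ValueError(
            f"interrupted_len={interrupted_len} >= smallest allele "
            f"({sample.sizes.min():g}); would produce non-positive lengths"
        )
    return AlleleSample(
        patient_id=sample.patient_id,
        tissue=sample.tissue,
        timepoint=sample.timepoint,
        age_at_sampling=sample.age_at_sampling,
        sizes=sample.sizes - interrupted_len,
        is_five_prime_view=True,
    )


def summarize_sample(
    sample: AlleleSample, bandwidth: float | None = None
) -> MosaicismSummary:
    """All AFD statistics for one sample."""
    p10 = percentile_length(sample, 10)
    p90 = percentile_length(sample, 90)
    return MosaicismSummary(
        patient_id=sample.patient_id,
        tissue=sample.tissue,
        timepoint=sample.timepoint,
        age_at_sampling=sample.age_at_sampling,
        n_alleles=sample.n_alleles,
        p10=p10,
        p90=p90,
        si=p90 - p10,
        mode=modal_length(sample, bandwidth=bandwidth),
        is_five_prime_view=sample.is_five_prime_view,
        low_count_flag=sample.low_count_flag,
    )


def observed_increment(
    summary_t1: MosaicismSummary,
    summary_t2: MosaicismSummary,
    interval: float | None = None,
) -> IncrementRecord:
    """Signed change of the modal expansion size between two time points."""
    if summary_t1.patient_id != summary_t2.patient_id:
        raise ValueError(
            f"patient mismatch: {summary_t1.patient_id} vs {summary_t2.patient_id}"
        )
    if summary_t1.tissue != summary_t2.tissue:
        raise ValueError(
            f"tissue mismatch: {summary_t1.tissue} vs {summary_t2.tissue}"
        )
    if (summary_t1.timepoint, summary_t2.timepoint) != ("t1", "t2"):
        raise ValueError("summaries must be ordered (t1, t2)")
    if interval is None:
        interval = summary_t2.age_at_sampling - summary_t1.age_at_sampling
    return IncrementRecord(
        patient_id=summary_t1.patient_id,
        tissue=summary_t1.tissue,
        mode_t1=summary_t1.mode,
        mode_t2=summary_t2.mode,
        interval=float(interval),
        observed_increment=summary_t2.mode - summary_t1.mode,
    )


def density_curve(
    sample: AlleleSample, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of the AFD for density-plot exports."""
    from scipy.stats import gaussian_kde

    sizes = sample.sizes
    if grid is None:
        pad = 0.1 * (sizes.max() - sizes.min() + 1)
        grid = np.linspace(sizes.min() - pad, sizes.max() + pad, 512)
    if np.ptp(sizes) == 0:
        dens = np.zeros_like(grid)
        dens[np.argmin(np.abs(grid - sizes[0]))] = 1.0
        return grid, dens
    kde = gaussian_kde(sizes)
    return grid, kde(grid)
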