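"""Population statistics: per-chamber summaries, repeatability, distributions.

One chamber sample (two pooled video tracks) is summarized into vesicle
quantity, mean/std effective diameter, and mean/std IPQ.  Chambers filled
from the same vesicle population are then aggregated: for each metric the
mean and sample (n-1) standard deviation across chamber means give the
relative standard deviation RSD = 100*std/mean, the repeatability figure of
merit for the whole method (reported as integer percent, round half-up).
Population diameter/IPQ are summarized as means of chamber means, because
the RSD explicitly measures variation *between chambers*, not between
pooled vesicles.

Also provides distribution tools: lognormal ML fitting of diameters,
half-open histograms, and five-number box statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import AggregationError, DataError, ParameterError
from .morphometry import VesicleRecord

__all__ = [
    "SampleSummary",
    "PopulationSummary",
    "BoxStats",
    "rsd_percent",
    "summarize_sample",
    "summarize_population",
    "compare_over_time",
    "fit_lognormal",
    "histogram",
    "boxplot_stats",
]

#: records carrying any of these flags are excluded from sample statistics
EXCLUDED_FLAGS = frozenset({"clump", "unreliable"})


def _round_half_up(x: float, ndigits: int = 0) -> float:
    factor = 10.0**ndigits
    return math.floor(x * factor + 0.5) / factor


def rsd_percent(mean: float, std: float) -> int:
    """Relative standard deviation as integer percent, round half-up."""
    if mean == 0:
        raise DataError("RSD undefined for zero mean")
    return int(_round_half_up(100.0 * std / mean))


@dataclass(frozen=True)
class SampleSummary:
    """Per-chamber aggregate: quantity and diameter/IPQ moments."""

    sample_id: str
    time_min: float
    quantity: int
    diameter_mean_um: float
    diameter_std_um: float
    ipq_mean: float
    ipq_std: float


@dataclass(frozen=True)
class PopulationSummary:
    """Across-chamber aggregate at one incubation time, with RSDs."""

    time_min: float
    n_chambers: int
    quantity_mean: float
    quantity_std: float
    quantity_rsd_pct: int
    diameter_mean_um: float
    diameter_std_um: float
    diameter_rsd_pct: int
    ipq_mean: float
    ipq_std: float
    ipq_rsd_pct: int


@dataclass(frozen=True)
class BoxStats:
    min: float
    q25: float
    median: float
    q75: float
    max: float
    mean: float


def summarize_sample(
    records: list[VesicleRecord], time_min: float, sample_id: str = "sample"
) -> SampleSummary:
    """Summarize one chamber sample from its vesicle records.

    Quantity counts the accepted, non-flagged records ('clump' and
    'unreliable' objects await expert review and are excluded); diameter and
    IPQ moments use the sample (n-1) standard deviation.  An empty sample
    reports quantity 0 and missing (NaN) moments.
    """
    good = [r for r in records if not (set(r.flags) & EXCLUDED_FLAGS)]
    if not good:
        return SampleSummary(sample_id, time_min, 0, math.nan, math.nan, math.nan, math.nan)
    d = np.array([r.diameter_um for r in good])
    q = np.array([r.ipq for r in good])
    d_std = float(d.std(ddof=1)) if d.size > 1 else 0.0
    q_std = float(q.std(ddof=1)) if q.size > 1 else 0.0
    return SampleSummary(
        sample_id, time_min, len(good), float(d.mean()), d_std, float(q.mean()), q_std
    )


def summarize_population(samples: list[SampleSummary]) -> PopulationSummary:
    """Aggregate >= 2 chamber summaries recorded at the same incubation time.

    Each metric gets the mean and sample std across chamber means, and the
    RSD as integer percent (round half-up).
    """
    if len(samples) < 2:
        raise AggregationError("population statistics need >= 2 chamber samples")
    times = {s.time_min for s in samples}
    if len(times) > 1:
        raise AggregationError(f"samples span multiple incubation times: {sorted(times)}")

    def agg(values):
        v = np.asarray(values, dtype=float)
        mean = float(v.mean())
        std = float(v.std(ddof=1))
        return mean, std, rsd_percent(mean, std)

    q_mean, q_std, q_rsd = agg([s.quantity for s in samples])
    d_mean, d_std, d_rsd = agg([s.diameter_mean_um for s in samples])
    i_mean, i_std, i_rsd = agg([s.ipq_mean for s in samples])
    return PopulationSummary(
        time_min=samples[0].time_min,
        n_chambers=len(samples),
        quantity_mean=q_mean,
        quantity_std=q_std,
        quantity_rsd_pct=q_rsd,
        diameter_mean_um=d_mean,
        diameter_std_um=d_std,
        diameter_rsd_pct=d_rsd,
        ipq_mean=i_mean,
        ipq_std=i_std,
        ipq_rsd_pct=i_rsd,
    )


def compare_over_time(population_summaries: list[PopulationSummary]):
    """Trend table over consecutive time points: quantity ratios and deltas.

    Ratios (later/earlier) are reported to 1 decimal, matching how settling
    dynamics are usually quoted (e.g. "a factor of 1.3").
    """
    import pandas as pd

    if len(population_summaries) < 2:
        raise ParameterError("compare_over_time needs >= 2 time points")
    summaries = sorted(population_summaries, key=lambda s: s.time_min)
    rows = []
    for earlier, later in zip(summaries[:-1], summaries[1:]):
        rows.append(
            {
                "time_from_min": earlier.time_min,
                "time_to_min": later.time_min,
                "quantity_ratio": _round_half_up(later.quantity_mean / earlier.quantity_mean, 1),
                "diameter_delta_um": later.diameter_mean_um - earlier.diameter_mean_um,
                "ipq_delta": later.ipq_mean - earlier.ipq_mean,
            }
        )
    return pd.DataFrame(rows)


def fit_lognormal(diameters_um) -> tuple[float, float]:
    """Maximum-likelihood lognormal fit: (mean, std) of the log-diameters."""
    d = np.asarray(diameters_um, dtype=float)
    if np.any(d <= 0):
        raise DataError("diameters must be > 0 for a lognormal fit")
    if d.size < 10:
        raise DataError("lognormal fit needs n >= 10")
    logs = np.log(d)
    return float(logs.mean()), float(logs.std(ddof=0))


def histogram(records, field: str | None = None, bin_edges=None) -> np.ndarray:
    """Counts per half-open bin [e_i, e_{i+1}) over records or raw values.

    ``records`` may be a list of :class:`VesicleRecord` (then ``field`` must
    be 'diameter_um' or 'ipq') or an array of values.  Counts sum to the
    number of in-range records.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ParameterError("bin_edges must be strictly increasing with >= 2 entries")
    if isinstance(records, (list, tuple)) and records and isinstance(records[0], VesicleRecord):
        if field not in ("diameter_um", "ipq"):
            raise ParameterError("field must be 'diameter_um' or 'ipq'")
        values = np.array([getattr(r, field) for r in records], dtype=float)
    else:
        values = np.asarray(records, dtype=float)
    if values.size == 0:
        return np.zeros(edges.size - 1, dtype=int)
    idx = np.searchsorted(edges, values, side="right") - 1
    in_range = (idx >= 0) & (idx < edges.size - 1) & (values >= edges[0]) & (values < edges[-1])
    return np.bincount(idx[in_range], minlength=edges.size - 1).astype(int)


def boxplot_stats(values) -> BoxStats:
    """Five-number box statistics plus the mean (quartiles by linear interpolation)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("boxplot_stats needs at least one value")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return BoxStats(float(v.min()), float(q25), float(q50), float(q75), float(v.max()), float(v.mean()))
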