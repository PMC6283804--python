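"""Scan-sparsification study: TIACs from reduced imaging protocols.

The three-point schedule {3 h, 24 h, 48 h} is the reference.  Two-point
subsets ({3,24}, {3,48}, {24,48}) refit the mono-exponential on the subset
and attach the physical-decay tail at the subset's last time.  Single-point
protocols skip the planar data entirely: the SPECT activity at t1 is
combined with an assumed half-life (the physical half-life, or a
population effective half-life), which then applies from t1 to infinity.
Percent differences against the reference are summarized with box-plot
statistics and compared with the Mann-Whitney-Wilcoxon rank-sum test
(exact by enumeration for small samples).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import RE188, NuclideConstants, RegionLabel
from .dosimetry import TIACResult, piecewise_time_integrated_activity, tiac
from .kinetics import fit_monoexponential, rescale_to_absolute
from .planar import RelativeTAC
from .spect import AbsoluteActivityMeasurement

# ---------------------------------------------------------------------------
# protocol specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolSpec:
    """Either a time-point subset or a single-scan rule."""

    name: str
    subset_times_h: tuple[float, ...] | None = None
    assumed_half_life_h: float | None = None

    def __post_init__(self) -> None:
        if (self.subset_times_h is None) == (self.assumed_half_life_h is None):
            raise ValueError("specify exactly one of subset times or assumed half-life")
        if self.subset_times_h is not None and len(self.subset_times_h) < 2:
            raise ValueError("subsets need >= 2 time points")
        if self.assumed_half_life_h is not None and self.assumed_half_life_h <= 0:
            raise ValueError("assumed half-life must be positive")

    @property
    def is_single_point(self) -> bool:
        return self.assumed_half_life_h is not None

    @classmethod
    def subset(cls, times_h, name: str | None = None) -> "ProtocolSpec":
        times = tuple(float(t) for t in times_h)
        return cls(name or "{%s}" % ",".join(f"{t:g}h" for t in times), subset_times_h=times)

    @classmethod
    def single_point(cls, assumed_half_life_h: float, name: str | None = None) -> "ProtocolSpec":
        return cls(
            name or f"{{3h}}+T({assumed_half_life_h:g}h)",
            assumed_half_life_h=float(assumed_half_life_h),
        )


def percent_difference(value, reference) -> float:
    """100 (x - ref) / ref."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (value - reference) / reference


# ---------------------------------------------------------------------------
# TIACs under a protocol
# ---------------------------------------------------------------------------


def _select_subset(tac: RelativeTAC, times_h, tolerance_h: float = 6.0) -> RelativeTAC:
    samples = []
    for target in times_h:
        deltas = np.abs(tac.times - target)
        k = int(np.argmin(deltas))
        if deltas[k] > tolerance_h:
            raise ValueError(f"no scan within {tolerance_h} h of requested {target} h")
        samples.append(tac.samples[k])
    if len({s[0] for s in samples}) != len(samples):
        raise ValueError("subset selects the same scan twice")
    return RelativeTAC(region=tac.region, samples=tuple(samples))


def tiac_under_protocol(
    tac: RelativeTAC | None,
    spect: AbsoluteActivityMeasurement,
    protocol: ProtocolSpec,
    injected_activity_MBq: float,
    constants: NuclideConstants = RE188,
    include_rise: bool = True,
) -> TIACResult:
    """TIAC of one region under a reduced imaging protocol.

    Subset protocols refit the mono-exponential on the selected planar
    samples, rescale to the SPECT activity at the SPECT time, and attach
    the physical-decay tail at the subset's last scan.  Single-point
    protocols take the SPECT activity directly (no planar refit) and apply
    the assumed half-life from t1 onwards; the linear-rise segment before
    t1 is included by default (``include_rise=False`` is the variant).
    """
    t_spect = spect.time_h
    if protocol.is_single_point:
        segments = piecewise_time_integrated_activity(
            spect.activity_MBq,
            protocol.assumed_half_life_h,
            t_spect if include_rise else 0.0,
            t_spect if include_rise else 0.0,
            constants,
            tail_half_life_h=protocol.assumed_half_life_h,
        )
    else:
        if tac is None:
            raise ValueError("subset protocols require planar data")
        sub = _select_subset(tac, protocol.subset_times_h)
        fit = fit_monoexponential(sub.times, sub.rates, sub.sigmas)
        abs_tac = rescale_to_absolute(fit, float(fit.predict(t_spect)), spect)
        segments = piecewise_time_integrated_activity(
            float(abs_tac.activity_MBq(t_spect)),
            fit.half_life_h,
            t_spect if include_rise else 0.0,
            float(sub.times[-1]),
            constants,
        )
    total = sum(segments)
    return TIACResult(
        region=spect.region,
        tia_MBq_h=total,
        segments=segments,
        tiac_h=tiac(total, injected_activity_MBq),
    )


REFERENCE_PROTOCOL = ProtocolSpec.subset((3.0, 24.0, 48.0), name="{3h,24h,48h}")

STANDARD_PROTOCOLS = (
    ProtocolSpec.subset((3.0, 24.0), name="{3h,24h}"),
    ProtocolSpec.subset((3.0, 48.0), name="{3h,48h}"),
    ProtocolSpec.subset((24.0, 48.0), name="{24h,48h}"),
)


def compare_protocols(
    patients: list[dict],
    protocols: tuple[ProtocolSpec, ...] = STANDARD_PROTOCOLS,
    reference: ProtocolSpec = REFERENCE_PROTOCOL,
    regions: tuple[RegionLabel, ...] = (RegionLabel.TUMOR, RegionLabel.LIVER, RegionLabel.LUNGS),
    constants: NuclideConstants = RE188,
) -> pd.DataFrame:
    """Tidy per-(patient, region, protocol) comparison table.

    Each patient entry is a dict with keys ``id``, ``tacs`` (region ->
    RelativeTAC), ``measurements`` (region -> AbsoluteActivityMeasurement)
    and ``A0``.  Single-point protocols carry their assumed half-life on
    the :class:`ProtocolSpec` itself.  Patients lacking a required scan
    time for a subset are skipped for that subset.
    """
    rows = []
    for patient in patients:
        for region in regions:
            tac = patient["tacs"].get(region)
            spect = patient["measurements"].get(region)
            if tac is None or spect is None:
                continue
            try:
                ref = tiac_under_protocol(tac, spect, reference, patient["A0"], constants)
            except ValueError:
                continue
            for protocol in protocols:
                try:
                    res = tiac_under_protocol(tac, spect, protocol, patient["A0"], constants)
                except ValueError:
                    continue
                rows.append(
                    {
                        "patient": patient["id"],
                        "region": region.region_name,
                        "protocol": protocol.name,
                        "tiac_h": res.tiac_h,
                        "tiac_ref_h": ref.tiac_h,
                        "pct_diff": percent_difference(res.tiac_h, ref.tiac_h),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float
    p_value: float
    method: str


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    greater = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(greater) + 0.5 * float(ties)


def ranksum_test(sample_x, sample_y, exact_threshold: int = 12) -> RankSumResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test.

    U counts pairs with x > y plus half the ties.  For combined sample
    sizes up to ``exact_threshold`` the p-value is exact: all C(n+m, n)
    assignments of the pooled values to the x-group are enumerated and the
    two-sided p is the probability of a U at least as far from nm/2 as the
    observed one.  Larger samples use the normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(list(sample_x), dtype=float)
    y = np.asarray(list(sample_y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    u_obs = _u_statistic(x, y)
    center = n * m / 2.0
    if n + m <= exact_threshold:
        pooled = np.concatenate([x, y])
        dev_obs = abs(u_obs - center)
        hits = total = 0
        for idx in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - center) >= dev_obs - 1e-12:
                hits += 1
        return RankSumResult(u_obs, hits / total, "exact")
    pooled = np.concatenate([x, y])
    big_n = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (big_n * (big_n - 1.0))
    var = n * m / 12.0 * ((big_n + 1.0) - tie_term)
    if var <= 0:
        return RankSumResult(u_obs, 1.0, "normal")
    dev = abs(u_obs - center)
    z = max(dev - 0.5, 0.0) / math.sqrt(var)
    return RankSumResult(u_obs, min(1.0, 2.0 * float(norm.sf(z))), "normal")


@dataclass(frozen=True)
class BoxplotSummary:
    """Median/quartiles with 1.5-IQR whiskers and outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def boxplot_summary(values) -> BoxplotSummary:
    """Box-plot statistics: quartiles by linear interpolation between order
    statistics; whiskers extend to the most extreme points within 1.5 IQR
    beyond the quartiles; everything beyond is an outlier."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 1:
        raise ValueError("at least one value required")
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_bound) & (v <= hi_bound)]
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(sorted(v[(v < lo_bound) | (v > hi_bound)])),
    )
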