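"""Kinetic analysis: depolymerization traces, single-molecule dwells, ATPase.

Rates live in a :class:`RateTable` keyed by condition label; the comparison
layer (fold changes, percent comparisons, tubulins-per-ATP coupling) operates
on those entries with uncertainties propagated in quadrature on the log
scale, s.e.m. = s.d./sqrt(n).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DataError

#: single-molecule acquisition frame rate used throughout the fixtures (Hz)
DEFAULT_FRAME_RATE = 8.7
#: length below which a shrinking microtubule is no longer resolvable (um)
RESOLUTION_FLOOR = 0.5
#: NADH extinction coefficient at 340 nm (M^-1 cm^-1); standard constant
NADH_EXTINCTION = 6220.0


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LengthTrace:
    """Length-vs-time record for one microtubule."""

    mt_id: str
    times_s: tuple[float, ...]
    lengths_um: tuple[float, ...]
    addition_time_s: float = 0.0
    interval_s: float = 5.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s)
        if len(t) != len(self.lengths_um):
            raise DataError(f"trace {self.mt_id}: times/lengths length mismatch")
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise DataError(f"trace {self.mt_id}: times not strictly increasing")
        if any(l < 0 for l in self.lengths_um):
            raise DataError(f"trace {self.mt_id}: negative length")
        if not (t[0] <= self.addition_time_s <= t[-1]):
            raise DataError(
                f"trace {self.mt_id}: addition time outside record span"
            )


@dataclass(frozen=True)
class DwellEvent:
    duration_s: float
    location: str  # 'end' or 'lattice'
    censored: bool = False


@dataclass(frozen=True)
class DwellTimeSet:
    """Single-molecule residence events plus movie metadata."""

    events: tuple[DwellEvent, ...]
    movie_length_s: float
    frame_interval_s: float = 1.0 / DEFAULT_FRAME_RATE
    mt_length_um: float = 0.0
    concentration_nM: float = 0.0
    observation_time_s: float = 0.0

    def __post_init__(self) -> None:
        for e in self.events:
            if e.location not in ("end", "lattice"):
                raise DataError(f"unknown event location {e.location!r}")
            if self.frame_interval_s > 0 and (
                e.duration_s < self.frame_interval_s - 1e-9
            ):
                raise DataError(
                    "event duration below one frame interval: "
                    f"{e.duration_s} < {self.frame_interval_s}"
                )

    def at(self, location: str) -> tuple[DwellEvent, ...]:
        return tuple(e for e in self.events if e.location == location)


@dataclass(frozen=True)
class ATPaseAssay:
    """Progress-curve measurement, HPLC [ADP] or NADH-coupled absorbance."""

    mode: str  # 'hplc_adp' | 'nadh_coupled'
    times_s: tuple[float, ...]
    signal: tuple[float, ...]  # uM ADP (hplc) or absorbance (coupled)
    motor_uM: float
    extinction_M_cm: float = NADH_EXTINCTION
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("hplc_adp", "nadh_coupled"):
            raise DataError(f"unknown assay mode {self.mode!r}")
        if self.motor_uM <= 0:
            raise DataError("motor concentration must be positive")
        if len(self.times_s) < 3:
            raise DataError("ATPase assay needs at least 3 time points")
        if len(self.times_s) != len(self.signal):
            raise DataError("times/signal length mismatch")


@dataclass(frozen=True)
class GeometryConstants:
    """Microtubule lattice geometry for absolute stoichiometry."""

    dimer_rise_nm: float = 8.0
    protofilaments: int = 13

    @property
    def dimers_per_um(self) -> float:
        return 1000.0 / self.dimer_rise_nm * self.protofilaments


@dataclass(frozen=True)
class RateEntry:
    label: str
    value: float
    sd: float = 0.0
    n: int = 1
    units: str = ""

    def __post_init__(self) -> None:
        if self.value < 0:
            raise DataError(f"rate {self.label!r} is negative")
        if self.n < 1:
            raise DataError(f"rate {self.label!r} has n < 1")

    @property
    def sem(self) -> float:
        return self.sd / math.sqrt(self.n)


class RateTable:
    """Named kinetic rates with uncertainty and n (the Tables 1-3 surface)."""

    def __init__(self, entries: Iterable[RateEntry] = ()):
        self._entries: dict[str, RateEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: RateEntry) -> None:
        if entry.label in self._entries:
            raise DataError(f"duplicate rate label {entry.label!r}")
        self._entries[entry.label] = entry

    def __getitem__(self, label: str) -> RateEntry:
        try:
            return self._entries[label]
        except KeyError:
            raise DataError(f"no rate labelled {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._entries

    def labels(self) -> list[str]:
        return list(self._entries)

    @classmethod
    def from_tsv(cls, path) -> "RateTable":
        table = cls()
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                table.add(
                    RateEntry(
                        row["condition"],
                        float(row["rate"]),
                        float(row.get("sd") or 0.0),
                        int(row.get("n") or 1),
                        row.get("units") or "",
                    )
                )
        return table

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["condition", "rate", "sd", "n", "units"])
            for e in self._entries.values():
                w.writerow([e.label, repr(e.value), repr(e.sd), e.n, e.units])


# ---------------------------------------------------------------------------
# Depolymerization traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepolFit:
    rate_um_per_min: float  # positive = shrinking
    se_um_per_min: float
    intercept_um: float
    r_squared: float
    n_points: int


def depolymerization_rate(
    trace: LengthTrace,
    window: tuple[float, float] | None = None,
    resolution_floor_um: float = RESOLUTION_FLOOR,
    robust: bool = False,
) -> DepolFit:
    """Least-squares shrinkage rate in um/min after protein addition.

    Points are used from the addition time until the length first drops
    below the resolution floor; growing microtubules yield a signed
    negative rate.  ``robust=True`` switches to a Theil-Sen slope.
    """
    t = np.asarray(trace.times_s, dtype=float)
    y = np.asarray(trace.lengths_um, dtype=float)
    lo, hi = window if window is not None else (trace.addition_time_s, np.inf)
    mask = (t >= lo) & (t <= hi)
    t, y = t[mask], y[mask]
    below = np.nonzero(y < resolution_floor_um)[0]
    if below.size:
        t, y = t[: below[0]], y[: below[0]]
    if len(t) < 3:
        raise DataError(
            f"trace {trace.mt_id}: fewer than 3 usable points after truncation"
        )
    if np.ptp(t) == 0:
        raise DataError(f"trace {trace.mt_id}: zero variance in time")
    if robust:
        slope, intercept, *_ = stats.theilslopes(y, t)
        se = 0.0
        r2 = float("nan")
    else:
        fit = stats.linregress(t, y)
        slope, intercept, se = fit.slope, fit.intercept, fit.stderr
        r2 = fit.rvalue**2
    return DepolFit(
        rate_um_per_min=-slope * 60.0,
        se_um_per_min=(se or 0.0) * 60.0,
        intercept_um=float(intercept),
        r_squared=float(r2),
        n_points=len(t),
    )


@dataclass(frozen=True)
class RateSummary:
    mean: float
    sd: float
    n: int
    sd_defined: bool  # False when n == 1 (s.d. reported as 0 with flag)


def aggregate_rates(rates: Sequence[float]) -> RateSummary:
    """Mean and sample s.d. (n-1 denominator) of per-microtubule rates."""
    if len(rates) == 0:
        raise DataError("cannot aggregate an empty rate list")
    arr = np.asarray(rates, dtype=float)
    if arr.size == 1:
        return RateSummary(float(arr[0]), 0.0, 1, False)
    return RateSummary(
        float(arr.mean()), float(arr.std(ddof=1)), int(arr.size), True
    )


# ---------------------------------------------------------------------------
# Single-molecule dwell analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KoffEstimate:
    k_off: float  # s^-1
    se: float
    ci_low: float
    ci_high: float
    n_uncensored: int
    n_censored: int


def _frames_beyond_first(duration: float, dt: float) -> int:
    return max(int(round(duration / dt)) - 1, 0)


def koff_mle(dwells: DwellTimeSet, location: str) -> KoffEstimate:
    """Exponential off-rate MLE with right censoring and frame quantization.

    With a negligible frame interval this is the classic censored-exponential
    estimator k = U / sum(durations).  With frame-quantized durations the
    event lengths beyond the first (minimum observable) frame are geometric
    and the MLE is k = -ln(q)/dt with q = sum(frames) / (U + sum(frames)),
    which reduces to the continuous formula as dt -> 0.
    """
    events = dwells.at(location)
    unc = [e for e in events if not e.censored]
    cen = [e for e in events if e.censored]
    if not unc:
        raise DataError(f"no uncensored events at {location!r}: rate unidentifiable")
    dt = dwells.frame_interval_s
    U = len(unc)
    if dt <= 0:
        total = sum(e.duration_s for e in events)
        k = U / total
        loglik = lambda kk: U * math.log(kk) - kk * total  # noqa: E731
    else:
        m = sum(_frames_beyond_first(e.duration_s, dt) for e in events)
        if m == 0:
            raise DataError(
                "all events last a single frame; off-rate not identifiable"
            )
        q = m / (U + m)
        k = -math.log(q) / dt

        def loglik(kk: float) -> float:
            qq = math.exp(-kk * dt)
            return m * math.log(qq) + U * math.log(1 - qq)

    se = _koff_se(k, U, dt)
    lo, hi = _profile_ci(k, loglik)
    return KoffEstimate(k, se, lo, hi, U, len(cen))


def _koff_se(k: float, n_unc: int, dt: float) -> float:
    if dt <= 0:
        return k / math.sqrt(n_unc)
    q = math.exp(-k * dt)
    return (1 - q) / (dt * math.sqrt(n_unc * q))


def _profile_ci(k_hat: float, loglik, level_drop: float = 1.920729) -> tuple[float, float]:
    """Profile-likelihood CI: points where logL falls by chi2_1(0.95)/2."""
    l_hat = loglik(k_hat)

    def g(k: float) -> float:
        return loglik(k) - l_hat + level_drop

    lo = k_hat
    step = k_hat / 2
    while g(lo) > 0 and lo > k_hat * 1e-6:
        lo -= step
        step /= 1.5 if lo - step <= 0 else 1.0
        if lo <= 0:
            lo = k_hat * 1e-6
            break
    lo = optimize.brentq(g, lo, k_hat) if g(lo) < 0 else 0.0
    hi = k_hat * 2
    while g(hi) > 0 and hi < k_hat * 1e6:
        hi *= 2
    hi = optimize.brentq(g, k_hat, hi) if g(hi) < 0 else math.inf
    return float(lo), float(hi)


def kon_rate(dwells: DwellTimeSet) -> float:
    """Attachment rate in nM^-1 s^-1 um^-1 from the event count."""
    denom = (
        dwells.observation_time_s
        * dwells.mt_length_um
        * dwells.concentration_nM
    )
    if denom <= 0:
        raise DataError(
            "k_on needs positive observation time, length and concentration"
        )
    n_events = len(dwells.events)
    if n_events == 0:
        warnings.warn("no binding events observed; k_on reported as 0")
    return n_events / denom


def fraction_long_events(dwells: DwellTimeSet, threshold_s: float) -> float:
    """Proportion of events longer than the threshold.

    Censored events longer than the threshold are definitely long and count;
    censored events shorter than it are ambiguous and excluded from the
    denominator.
    """
    if not dwells.events:
        raise DataError("no events")
    long_n = sum(1 for e in dwells.events if e.duration_s > threshold_s)
    denom = sum(
        1
        for e in dwells.events
        if not e.censored or e.duration_s > threshold_s
    )
    if denom == 0:
        raise DataError("no classifiable events below the censoring horizon")
    return long_n / denom


# ---------------------------------------------------------------------------
# ATPase
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ATPaseFit:
    rate_per_s: float  # turnover per second per active site
    se: float


def atpase_fit(assay: ATPaseAssay) -> ATPaseFit:
    """ATP turnover per second per active site, with OLS standard error."""
    t = np.asarray(assay.times_s, dtype=float)
    y = np.asarray(assay.signal, dtype=float)
    fit = stats.linregress(t, y)
    slope, se = fit.slope, fit.stderr or 0.0
    if assay.mode == "hplc_adp":
        if slope < 0 and abs(slope) > 3 * se:
            raise DataError("[ADP] decreases over time; inconsistent with mode")
        adp_uM_per_s = max(slope, 0.0) if abs(slope) <= 3 * se else slope
        se_uM_per_s = se
    else:
        if slope > 0 and slope > 3 * se:
            raise DataError("absorbance increases over time; inconsistent with mode")
        resid = y - (fit.intercept + slope * t)
        if np.any(np.diff(y) > 3 * max(resid.std(), 1e-12)):
            warnings.warn("coupled-assay signal is non-monotone beyond noise")
        denom = assay.extinction_M_cm * assay.path_cm
        adp_uM_per_s = -min(slope, 0.0) / denom * 1e6
        se_uM_per_s = se / denom * 1e6
    return ATPaseFit(adp_uM_per_s / assay.motor_uM, se_uM_per_s / assay.motor_uM)


def atpase_rate(assay: ATPaseAssay) -> float:
    """ATP turnover per second per active site from a progress curve."""
    return atpase_fit(assay).rate_per_s


# ---------------------------------------------------------------------------
# Comparative layer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldChange:
    ratio: float
    se: float
    numerator: str
    denominator: str


def fold_change(rates: RateTable, numerator: str, denominator: str) -> FoldChange:
    """Ratio of mean rates; s.e.m.-based uncertainty combined on log scale."""
    num, den = rates[numerator], rates[denominator]
    if den.value <= 0:
        raise DataError(f"denominator rate {denominator!r} is not positive")
    ratio = num.value / den.value
    rel = 0.0
    if num.value > 0:
        rel = (num.sem / num.value) ** 2
    rel += (den.sem / den.value) ** 2
    return FoldChange(ratio, ratio * math.sqrt(rel), numerator, denominator)


def percent_of(rates: RateTable, part: str, whole: str) -> float:
    return fold_change(rates, part, whole).ratio * 100.0


@dataclass(frozen=True)
class Stoichiometry:
    tubulins_per_atp: float
    se: float
    comparator: str
    comparator_stoichiometry: float


def tubulins_per_atp(
    rates: RateTable,
    geometry: GeometryConstants | None = None,
    target_depol: str = "depol/Anc13",
    target_atpase: str = "atpase_mt/Anc13",
    comparator_depol: str = "depol/MCAK",
    comparator_atpase: str = "atpase_mt/MCAK",
    comparator_stoichiometry: float = 1.0,
) -> Stoichiometry:
    """Relative coupling: S_t = S_c * (v_t/v_c) * (k_c/k_t).

    v = depolymerization rate, k = microtubule-stimulated ATPase; the
    comparator's tubulins-per-ATP stoichiometry anchors the scale.
    ``geometry`` is exposed for the absolute route (dimers/s from
    v * dimers_per_um) when per-motor end occupancy is known.
    """
    del geometry  # only used by the absolute route (dimers_removed_per_s)
    vt, kt = rates[target_depol], rates[target_atpase]
    vc, kc = rates[comparator_depol], rates[comparator_atpase]
    for e in (vt, kt, vc, kc):
        if e.value <= 0:
            raise DataError(f"rate {e.label!r} must be positive for coupling")
    s = comparator_stoichiometry * (vt.value / vc.value) * (kc.value / kt.value)
    rel = sum((e.sem / e.value) ** 2 for e in (vt, kt, vc, kc))
    return Stoichiometry(
        s, s * math.sqrt(rel), comparator_depol, comparator_stoichiometry
    )


def dimers_removed_per_s(
    rate_um_per_min: float, geometry: GeometryConstants | None = None
) -> float:
    """Absolute removal flux implied by a shrinkage rate."""
    geometry = geometry or GeometryConstants()
    return rate_um_per_min / 60.0 * geometry.dimers_per_um


@dataclass(frozen=True)
class BreakRecord:
    mt_length_um: float
    n_breaks: int


def break_frequency(
    records: Sequence[BreakRecord], min_length_um: float = 5.0
) -> float:
    """Proportion of microtubules longer than the cutoff with >=1 break."""
    kept = [r for r in records if r.mt_length_um > min_length_um]
    if not kept:
        raise DataError(
            f"no microtubules longer than {min_length_um} um to score"
        )
    return sum(1 for r in kept if r.n_breaks >= 1) / len(kept)
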