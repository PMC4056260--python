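"""Endpoint battery: glycemic time-in-range metrics, episode counts, sensor
accuracy (MAD/MARD/%-within-20%), and the two between-group tests
(Mann-Whitney U, unpaired t) used to compare the trial arms."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OutcomeSummary",
    "band_fractions",
    "time_in_range",
    "glycemic_episodes",
    "sensor_accuracy",
    "mann_whitney_u",
    "unpaired_t",
    "summarize_record",
    "summarize",
]


# ---------------------------------------------------------------------------
# time in range


def _segment_split(g0: float, g1: float, low: float, high: float) -> tuple[float, float, float]:
    """Fractions of one linear segment spent below / within / above [low, high]."""
    if g0 == g1:
        if g0 < low:
            return 1.0, 0.0, 0.0
        if g0 > high:
            return 0.0, 0.0, 1.0
        return 0.0, 1.0, 0.0
    inv = 1.0 / (g1 - g0)

    def frac_below(c: float) -> float:
        # measure of {s in [0,1] : g(s) < c}
        s = (c - g0) * inv
        if g1 > g0:
            return min(max(s, 0.0), 1.0)
        return 1.0 - min(max(s, 0.0), 1.0)

    below = frac_below(low)
    not_above = frac_below(high)  # strictly-below-high measure; boundary has measure 0
    within = max(0.0, not_above - below)
    above = max(0.0, 1.0 - not_above)
    return below, within, above


def band_fractions(times, values, low: float, high: float) -> tuple[float, float, float]:
    """Exact (%, %, %) of total time spent below / within / above [low, high].

    The trace is the piecewise-linear interpolation of the samples; crossing
    times are solved analytically per segment, so the three percentages
    partition 100% exactly.
    """
    t = np.asarray(times, dtype=float)
    g = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if low > high:
        raise ValueError("low must not exceed high")
    dts = np.diff(t)
    total = float(dts.sum())
    acc = np.zeros(3)
    for i in range(t.size - 1):
        fr = _segment_split(g[i], g[i + 1], low, high)
        acc += np.array(fr) * dts[i]
    below, within, above = (100.0 * acc / total).tolist()
    return below, within, above


def time_in_range(times, values, low: float, high: float,
                  mode: str = "interpolate") -> float:
    """Percent of time with low <= G <= high.

    ``mode="interpolate"`` (default) integrates the piecewise-linear trace
    exactly; ``mode="samples"`` counts samples instead (sensitivity mode).
    """
    if mode == "samples":
        g = np.asarray(values, dtype=float)
        if g.size < 2:
            raise ValueError("need at least 2 samples")
        return 100.0 * float(np.mean((g >= low) & (g <= high)))
    return band_fractions(times, values, low, high)[1]


# ---------------------------------------------------------------------------
# episodes


def glycemic_episodes(values, threshold: float, direction: str = "above") -> int:
    """Count maximal runs of consecutive samples beyond a threshold.

    ``direction="above"`` flags samples >= threshold (hyperglycemia bands are
    reported as >=15 / >=17 mM); ``"below"`` flags samples < threshold
    (hypoglycemia < 4.0 mM). Runs separated by at least one in-range sample
    count separately.
    """
    g = np.asarray(values, dtype=float)
    if direction == "above":
        mask = g >= threshold
    elif direction == "below":
        mask = g < threshold
    else:
        raise ValueError("direction must be 'above' or 'below'")
    padded = np.concatenate([[False], mask])
    return int(np.sum(padded[1:] & ~padded[:-1]))


# ---------------------------------------------------------------------------
# sensor accuracy


def sensor_accuracy(sensor_times, sensor_values, ref_times, ref_values,
                    max_gap_min: float = 5.0) -> tuple[float, float, float]:
    """(MAD mM, MARD %, % within 20%) of sensor vs reference glucose.

    Each reference sample is paired with the nearest available sensor value
    within ``max_gap_min`` minutes; unpaired references are dropped.
    """
    st = np.asarray(sensor_times, dtype=float)
    sv = np.asarray(sensor_values, dtype=float)
    ok = np.isfinite(sv)
    st, sv = st[ok], sv[ok]
    pairs = []
    for rt, rv in zip(np.asarray(ref_times, float), np.asarray(ref_values, float)):
        if st.size == 0:
            break
        i = int(np.argmin(np.abs(st - rt)))
        if abs(st[i] - rt) <= max_gap_min:
            pairs.append((sv[i], rv))
    if not pairs:
        raise ValueError("no sensor/reference pairs within the pairing window")
    s, r = np.array(pairs).T
    abs_dev = np.abs(s - r)
    rel = abs_dev / r
    return (float(np.median(abs_dev)), 100.0 * float(np.median(rel)),
            100.0 * float(np.mean(rel <= 0.20)))


# ---------------------------------------------------------------------------
# two-sample tests


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-aware Mann-Whitney U of x over y."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_p(x: np.ndarray, y: np.ndarray, U_obs: float) -> float:
    """Exact two-sided p by enumerating all group assignments of the pooled values."""
    pooled = np.concatenate([x, y])
    n1, N = x.size, pooled.size
    # r_i = U-contribution of element i against all other elements; for a
    # chosen index set S, U(S) = sum_{i in S} r_i - C(|S|, 2)
    a = (pooled[:, None] > pooled[None, :]).astype(float) \
        + 0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(a, 0.0)
    r = a.sum(axis=1)
    const = n1 * (n1 - 1) / 2.0
    us = np.array([r[list(c)].sum() - const
                   for c in itertools.combinations(range(N), n1)])
    us = np.round(us * 2) / 2  # U values live on a half-integer lattice
    U_obs = round(U_obs * 2) / 2
    p_lo = float(np.mean(us <= U_obs + 1e-9))
    p_hi = float(np.mean(us >= U_obs - 1e-9))
    return min(1.0, 2.0 * min(p_lo, p_hi))


def mann_whitney_u(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Exact tie-aware p by enumeration when both groups have at most
    ``exact_max_n`` observations, otherwise the normal approximation with tie
    and continuity corrections. Returns ``(U, p)`` with U the statistic of
    the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs at least one observation")
    U = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return U, 1.0
    if x.size <= exact_max_n and y.size <= exact_max_n:
        return U, _exact_p(x, y, U)
    n1, n2 = x.size, y.size
    N = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return U, 1.0
    z = (abs(U - mu) - 0.5) / math.sqrt(var)
    return U, float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))


def unpaired_t(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample t test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    sp2 = (((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1))
           / (n1 + n2 - 2))
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(sps.t.sf(abs(t), df=n1 + n2 - 2))
    return float(t), p


# ---------------------------------------------------------------------------
# per-subject summary and group report


@dataclass
class OutcomeSummary:
    """Per-subject endpoint panel (percentages of study time unless noted)."""

    pct_time_6_8: float
    pct_4_10: float
    pct_5p6_10: float
    pct_gt8: float
    pct_gt10: float
    pct_lt6: float
    pct_lt5p6: float
    pct_lt4: float
    mean_G: float  # mM
    sd_G: float  # mM
    episodes_ge15: int
    episodes_ge17: int
    episodes_lt4: int
    insulin_24h: float  # U per 24 h
    insulin_hourly: float  # U/h
    dextrose_48h: float  # g over the record
    mad: float  # mM (NaN without a sensor)
    mard: float  # %
    pct_within20: float  # %
    cal_count_day1: int
    cal_count_day2: int
    sensor_unavail_min: float


def _dose_totals(commands: pd.DataFrame, duration_min: float) -> tuple[float, float, float]:
    """(total insulin U, mean rate U/h, total dextrose g) from a ZOH command log."""
    if commands.empty:
        return 0.0, 0.0, 0.0
    t = commands["t_min"].to_numpy(dtype=float)
    edges = np.append(t, duration_min)
    hold = np.diff(edges) / 60.0  # hours each command is active
    total_u = float(np.sum(commands["insulin_Uh"].to_numpy() * hold))
    total_dex_g = float(np.sum(commands["dextrose_mLh"].to_numpy() * hold) * 0.20)
    return total_u, total_u / (duration_min / 60.0), total_dex_g


def summarize_record(record) -> OutcomeSummary:
    """Compute the endpoint panel for one subject's trial record."""
    ref = record.reference
    t, g = ref["t_min"].to_numpy(float), ref["G_mM"].to_numpy(float)
    below6, in68, _ = band_fractions(t, g, 6.0, 8.0)
    _, in410, above10 = band_fractions(t, g, 4.0, 10.0)
    below56, in5610, _ = band_fractions(t, g, 5.6, 10.0)
    below4, _, above8 = band_fractions(t, g, 4.0, 8.0)
    dur = float(t[-1] - t[0])
    total_u, hourly_u, dex_g = _dose_totals(record.commands, dur)
    if record.sensor is not None and not record.sensor.empty:
        sf = record.sensor
        try:
            mad, mard, w20 = sensor_accuracy(sf["t_min"], sf["sensor_mM"],
                                             t, g)
        except ValueError:
            mad = mard = w20 = float("nan")
        unavail = float((~sf["available"].astype(bool)).sum())
    else:
        mad = mard = w20 = float("nan")
        unavail = float("nan")
    cals = record.calibrations
    day1 = int((cals["t_min"] < 1440).sum()) if cals is not None else 0
    day2 = int((cals["t_min"] >= 1440).sum()) if cals is not None else 0
    return OutcomeSummary(
        pct_time_6_8=in68,
        pct_4_10=in410,
        pct_5p6_10=in5610,
        pct_gt8=above8,
        pct_gt10=above10,
        pct_lt6=below6,
        pct_lt5p6=below56,
        pct_lt4=below4,
        mean_G=float(np.mean(g)),
        sd_G=float(np.std(g, ddof=1)),
        episodes_ge15=glycemic_episodes(g, 15.0, "above"),
        episodes_ge17=glycemic_episodes(g, 17.0, "above"),
        episodes_lt4=glycemic_episodes(g, 4.0, "below"),
        insulin_24h=total_u * 24.0 / (dur / 60.0),
        insulin_hourly=hourly_u,
        dextrose_48h=dex_g,
        mad=mad, mard=mard, pct_within20=w20,
        cal_count_day1=day1, cal_count_day2=day2,
        sensor_unavail_min=unavail,
    )


def _fmt_median_iqr(v: np.ndarray) -> str:
    q1, med, q3 = np.nanpercentile(v, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def _fmt_mean_sd(v: np.ndarray) -> str:
    return f"{np.nanmean(v):.1f} ({np.nanstd(v, ddof=1):.1f})"


#: metric -> (label, test) where test is "mwu" (median/IQR) or "t" (mean/SD)
_REPORT_ROWS = [
    ("pct_time_6_8", "Time glucose in target (%) (6.0-8.0 mM)", "mwu"),
    ("mean_G", "Mean glucose (mM)", "mwu"),
    ("sd_G", "Standard deviation of glucose (mM)", "t"),
    ("pct_4_10", "Time 4.0-10.0 mM (%)", "mwu"),
    ("pct_5p6_10", "Time 5.6-10.0 mM (%)", "mwu"),
    ("pct_gt8", "Time >8.0 mM (%)", "mwu"),
    ("pct_gt10", "Time >10.0 mM (%)", "mwu"),
    ("pct_lt6", "Time <6.0 mM (%)", "mwu"),
    ("pct_lt5p6", "Time <5.6 mM (%)", "mwu"),
    ("pct_lt4", "Time <4.0 mM (%)", "mwu"),
    ("insulin_24h", "Total insulin per 24 h (U)", "mwu"),
    ("insulin_hourly", "Hourly insulin rate (U/h)", "mwu"),
    ("dextrose_48h", "Total dextrose per 48 h (g)", "mwu"),
]


def summarize(records_by_arm: dict) -> dict:
    """Group the per-subject panels into a trial-report table with p-values.

    Returns ``{"per_subject": DataFrame, "table": DataFrame, "p_values": dict}``.
    Median (IQR) metrics are compared with the Mann-Whitney U test; the
    per-subject glucose SD is presented as mean (SD) and compared with the
    unpaired t test.
    """
    rows = []
    for arm, records in records_by_arm.items():
        if not records:
            raise ValueError(f"arm {arm!r} has no records")
        for rec in records:
            s = summarize_record(rec)
            d = {f.name: getattr(s, f.name) for f in fields(OutcomeSummary)}
            d["arm"] = arm
            d["subject_id"] = rec.subject_id
            rows.append(d)
    per_subject = pd.DataFrame(rows)
    arms = list(records_by_arm)
    table_rows, p_values = [], {}
    for metric, label, test in _REPORT_ROWS:
        cells = {}
        groups = []
        for arm in arms:
            v = per_subject.loc[per_subject["arm"] == arm, metric].to_numpy(float)
            groups.append(v)
            cells[arm] = _fmt_mean_sd(v) if test == "t" else _fmt_median_iqr(v)
        p = float("nan")
        if len(groups) == 2:
            a, b = groups
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if a.size and b.size:
                try:
                    p = unpaired_t(a, b)[1] if test == "t" else mann_whitney_u(a, b)[1]
                except ValueError:
                    p = float("nan")
        p_values[metric] = p
        table_rows.append({"metric": label, **cells, "p": p})
    table = pd.DataFrame(table_rows)
    return {"per_subject": per_subject, "table": table, "p_values": p_values}
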