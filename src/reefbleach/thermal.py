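"""Thermal stress metrics from daily sea-surface temperature.

Implements the NOAA Coral Reef Watch-style accumulation metrics used to
characterise marine heatwaves at reef sites:

* **MMM** — Maximum of the Monthly Mean SST climatology, the warmest
  calendar-month mean over a set of climatology years.  The coral
  bleaching threshold is defined as MMM + 1 °C.
* **HotSpot** — the positive part of the daily SST anomaly above MMM.
* **DHW** (Degree Heating Weeks, °C-weeks) — accumulation of qualifying
  HotSpots over the trailing 12-week (84-day) window, divided by 7.
  Following the CRW v3.1 convention only HotSpots >= 1 °C accumulate;
  the cutoff is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DHW_WINDOW_DAYS = 84
#: CRW v3.1: only HotSpots at or above this value accumulate into DHW.
DEFAULT_MIN_ACCUMULATING_HOTSPOT = 1.0
#: Bleaching threshold offset above the MMM climatology (°C).
BLEACHING_THRESHOLD_OFFSET = 1.0
#: Gaps longer than this are considered unrecoverable at ingest.
MAX_INTERPOLATED_GAP_DAYS = 3

_MONTH_NAMES = [
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
]


@dataclass
class SstSeries:
    """Daily SST series for one island/atoll buffer.

    ``dates`` must be daily and contiguous after ingest; use
    :func:`read_sst_csv` / :meth:`from_frame` to interpolate small gaps.
    """

    island_id: str
    dates: pd.DatetimeIndex
    sst: np.ndarray

    def __post_init__(self) -> None:
        self.sst = np.asarray(self.sst, dtype=float)
        if len(self.dates) != len(self.sst):
            raise ValueError("dates and sst must have equal length")
        if len(self.dates) > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]")
            if not (deltas == np.timedelta64(1, "D")).all():
                raise ValueError(f"{self.island_id}: dates must be daily and contiguous")
        if not np.isfinite(self.sst).all():
            raise ValueError(f"{self.island_id}: SST contains non-finite values")

    def __len__(self) -> int:
        return len(self.sst)

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.dates.year)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, island_id: str | None = None) -> "SstSeries":
        """Build a series from a (island_id, date, sst) frame, fixing small gaps.

        Missing days are reindexed in; runs of up to 3 missing days are
        linearly interpolated, longer runs raise ``ValueError``.
        """
        if island_id is not None:
            frame = frame[frame["island_id"] == island_id]
        elif frame["island_id"].nunique() == 1:
            island_id = str(frame["island_id"].iloc[0])
        else:
            raise ValueError("frame holds multiple islands; pass island_id")
        if frame.empty:
            raise ValueError(f"no SST rows for island {island_id!r}")
        s = (
            frame.assign(date=pd.to_datetime(frame["date"]))
            .set_index("date")["sst"]
            .sort_index()
        )
        if s.index.has_duplicates:
            raise ValueError(f"{island_id}: duplicate dates in SST input")
        full = pd.date_range(s.index[0], s.index[-1], freq="D")
        s = s.reindex(full)
        gap = s.isna()
        if gap.any():
            run = gap.astype(int).groupby((~gap).cumsum()).transform("sum")
            if int(run[gap].max()) > MAX_INTERPOLATED_GAP_DAYS:
                raise ValueError(
                    f"{island_id}: SST gap longer than {MAX_INTERPOLATED_GAP_DAYS} days"
                )
            s = s.interpolate(method="linear")
        return cls(island_id=str(island_id), dates=full, sst=s.to_numpy())


@dataclass
class ThermalMetrics:
    """Per-day HotSpot and DHW series derived from one :class:`SstSeries`."""

    island_id: str
    dates: pd.DatetimeIndex
    sst: np.ndarray
    mmm: float
    hotspot: np.ndarray
    dhw: np.ndarray
    spinup: np.ndarray  # True for the first window-1 days (incomplete window)
    min_accumulating_hotspot: float = DEFAULT_MIN_ACCUMULATING_HOTSPOT

    @property
    def bleaching_threshold(self) -> float:
        return self.mmm + BLEACHING_THRESHOLD_OFFSET

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "island_id": self.island_id,
                "date": self.dates,
                "sst": self.sst,
                "hotspot": self.hotspot,
                "dhw": self.dhw,
                "spinup": self.spinup,
            }
        )


@dataclass
class EventSummary:
    island_id: str
    max_dhw: float
    days_above_threshold: int
    peak_date: pd.Timestamp


def compute_mmm(series: SstSeries, climatology_years: "list[int] | None" = None) -> float:
    """Maximum of the monthly-mean SST climatology.

    Daily values within ``climatology_years`` are pooled by calendar month
    (leap days count toward February); the return value is the largest of
    the 12 pooled monthly means.  Every month must be represented.
    """
    if climatology_years is None:
        climatology_years = list(series.years)
    climatology_years = sorted(set(int(y) for y in climatology_years))
    missing_years = set(climatology_years) - set(series.years.tolist())
    if missing_years:
        raise ValueError(f"climatology years absent from series: {sorted(missing_years)}")
    mask = np.isin(series.dates.year, climatology_years)
    months = series.dates.month[mask]
    values = series.sst[mask]
    monthly = pd.Series(values).groupby(pd.Series(months)).mean()
    present = set(monthly.index.tolist())
    absent = [m for m in range(1, 13) if m not in present]
    if absent:
        raise ValueError(
            "months missing from climatology: "
            + ", ".join(_MONTH_NAMES[m - 1] for m in absent)
        )
    return float(monthly.max())


def compute_dhw(
    series: SstSeries,
    mmm: float,
    min_accumulating_hotspot: float = DEFAULT_MIN_ACCUMULATING_HOTSPOT,
    window_days: int = DHW_WINDOW_DAYS,
) -> ThermalMetrics:
    """Daily HotSpot and Degree Heating Week series.

    ``hotspot_d = max(0, sst_d - mmm)``; ``dhw_d`` sums hotspots that meet
    the accumulation cutoff over the trailing ``window_days`` days and
    divides by 7.  Days before one full window are flagged as spin-up but
    still carry the partial accumulation.
    """
    if len(series) < window_days:
        raise ValueError(
            f"series length {len(series)} is shorter than the {window_days}-day window"
        )
    hotspot = np.maximum(0.0, series.sst - mmm)
    qualifying = np.where(hotspot >= min_accumulating_hotspot, hotspot, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(qualifying)])
    n = len(qualifying)
    start = np.maximum(0, np.arange(1, n + 1) - window_days)
    dhw = (csum[1:] - csum[start]) / 7.0
    spinup = np.arange(n) < (window_days - 1)
    return ThermalMetrics(
        island_id=series.island_id,
        dates=series.dates,
        sst=series.sst,
        mmm=float(mmm),
        hotspot=hotspot,
        dhw=dhw,
        spinup=spinup,
        min_accumulating_hotspot=min_accumulating_hotspot,
    )


def event_summary(
    metrics: ThermalMetrics,
    window: "tuple[pd.Timestamp, pd.Timestamp] | None" = None,
) -> EventSummary:
    """Maximum DHW, days with SST above the bleaching threshold, and peak date.

    ``window`` is an inclusive (start, end) date pair; ties in the DHW
    maximum resolve to the earliest date.
    """
    if window is None:
        mask = np.ones(len(metrics.dhw), dtype=bool)
    else:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        mask = (metrics.dates >= start) & (metrics.dates <= end)
    if not mask.any():
        raise ValueError("summary window contains no days")
    dhw = metrics.dhw[mask]
    dates = metrics.dates[mask]
    sst = metrics.sst[mask]
    peak_idx = int(np.argmax(dhw))  # argmax returns the first maximum
    return EventSummary(
        island_id=metrics.island_id,
        max_dhw=float(dhw[peak_idx]),
        days_above_threshold=int((sst > metrics.bleaching_threshold).sum()),
        peak_date=dates[peak_idx],
    )


def read_sst_csv(path, island_id: str | None = None) -> "SstSeries | list[SstSeries]":
    """Read daily SST from a CSV with columns island_id, date, sst."""
    frame = pd.read_csv(path)
    if island_id is not None:
        return SstSeries.from_frame(frame, island_id)
    return [SstSeries.from_frame(g) for _, g in frame.groupby("island_id", sort=True)]


def island_metrics_table(metrics_list: "list[ThermalMetrics]", window=None) -> pd.DataFrame:
    """Per-island event summary table (max DHW, days above threshold, peak date)."""
    rows = []
    for m in metrics_list:
        s = event_summary(m, window)
        rows.append(
            {
                "island_id": s.island_id,
                "mmm": m.mmm,
                "bleaching_threshold": m.bleaching_threshold,
                "max_dhw": s.max_dhw,
                "days_above_threshold": s.days_above_threshold,
                "peak_date": s.peak_date,
            }
        )
    return pd.DataFrame(rows)
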