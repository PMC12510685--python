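"""Measured-ADC computation, sanitization and group averaging.

The study reads out metabolite diffusion two ways: the powder-averaged
decay S(b)/S(b0) at the shortest mixing time, and two-point apparent
diffusion coefficients across mixing times. ADC = −ln(S(b)/S(b0))/(b−b0);
negative ADCs indicate quantification failures and are removed before
modelling. Missing values are carried as NaN throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SignalDecay",
    "ADCSeries",
    "compute_adc",
    "filter_adc",
    "bin_and_average",
    "read_long_table",
    "write_long_table",
]


@dataclass
class SignalDecay:
    """Normalized powder-averaged decay E(b) = S(b)/S(b_min) for one dataset.

    b sorted ascending; E at the smallest b equals 1 by construction.
    Condition labels identify metabolite, region, postnatal age and pup.
    """

    b: np.ndarray
    E: np.ndarray
    metabolite: str = ""
    region: str = ""
    age: float = 0.0
    pup_id: str = ""
    tm: float = 100.0
    uncertainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.b.shape != self.E.shape:
            raise ValueError("b and E must have matching shapes")
        order = np.argsort(self.b)
        self.b = self.b[order]
        self.E = self.E[order]
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)[order]


@dataclass
class ADCSeries:
    """ADC versus diffusion time for one metabolite/region/age/pup."""

    t_d: np.ndarray
    adc: np.ndarray
    metabolite: str = ""
    region: str = ""
    age: float = 0.0
    pup_id: str = ""
    tm: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.t_d = np.asarray(self.t_d, dtype=float)
        self.adc = np.asarray(self.adc, dtype=float)
        if self.t_d.shape != self.adc.shape:
            raise ValueError("t_d and adc must have matching shapes")
        order = np.argsort(self.t_d)
        self.t_d = self.t_d[order]
        self.adc = self.adc[order]
        if self.tm is not None:
            self.tm = np.asarray(self.tm, dtype=float)[order]


def compute_adc(
    S_b: float | np.ndarray,
    S_b0: float | np.ndarray,
    b: float,
    b0: float,
) -> float | np.ndarray:
    """Two-point ADC = −ln(S(b)/S(b0)) / (b − b0), in µm²/ms.

    Natural logarithm; noisy inputs may legitimately produce negative
    values (handled downstream by :func:`filter_adc`). Non-positive
    signals yield NaN and a log entry rather than an exception.
    """
    if not b > b0:
        raise ValueError("need b > b0")
    S_b = np.asarray(S_b, dtype=float)
    S_b0 = np.asarray(S_b0, dtype=float)
    if np.any(S_b0 <= 0):
        raise ValueError("S_b0 must be > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = -np.log(S_b / S_b0) / (b - b0)
    bad = ~np.isfinite(adc)
    if np.any(bad):
        logger.warning("compute_adc: %d non-positive signal(s) -> NaN", int(np.sum(bad)))
        adc = np.where(bad, np.nan, adc)
    return float(adc) if adc.ndim == 0 else adc


def filter_adc(series: ADCSeries) -> ADCSeries:
    """Drop negative ADC entries (quantification errors); idempotent.

    NaN (missing) entries are kept — they mark excluded acquisitions, not
    sign errors — and removals are logged with the dataset labels.
    """
    neg = series.adc < 0  # NaN compares False, so missing entries survive
    if np.any(neg):
        logger.info(
            "filter_adc: removed %d negative ADC(s) [pup=%s region=%s age=%s met=%s]",
            int(np.sum(neg)),
            series.pup_id,
            series.region,
            series.age,
            series.metabolite,
        )
    keep = ~neg
    return replace(
        series,
        t_d=series.t_d[keep],
        adc=series.adc[keep],
        tm=None if series.tm is None else series.tm[keep],
    )


def bin_and_average(
    table: pd.DataFrame,
    value: str,
    abscissa: str,
    group_keys: tuple[str, ...] = ("age", "region", "metabolite"),
) -> pd.DataFrame:
    """Group-mean curves with SD per age × region (× metabolite) condition.

    ``table`` is a long-format frame; ``value`` the column to average
    (e.g. ``E`` or ``adc``) and ``abscissa`` the within-curve coordinate
    (``b`` or ``t_d``). NaNs are ignored pointwise; the returned frame
    reports mean, SD (ddof=0) and the contributing count ``n`` per point.
    Empty cells simply produce no rows (flagged by the caller via ``n``).
    """
    keys = [*group_keys, abscissa]
    grouped = table.groupby(keys, dropna=False)[value]
    out = grouped.agg(
        mean=lambda s: s.mean(),
        sd=lambda s: s.std(ddof=0),
        n=lambda s: int(s.notna().sum()),
    ).reset_index()
    out.loc[out["n"] == 0, ["mean", "sd"]] = np.nan
    return out


_DECAY_COLS = ["pup_id", "region", "age", "metabolite", "TM", "b", "E"]
_ADC_COLS = ["pup_id", "region", "age", "metabolite", "TM", "t_d", "adc"]


def write_long_table(df: pd.DataFrame, path: str) -> None:
    """Write a long-format decay or ADC table as CSV."""
    df.to_csv(path, index=False)


def read_long_table(path: str) -> pd.DataFrame:
    """Read a long-format CSV written by :func:`write_long_table`."""
    df = pd.read_csv(path)
    expected = set(_DECAY_COLS) | set(_ADC_COLS)
    missing = {"pup_id", "region", "age", "metabolite"} - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if not (set(df.columns) & (expected - {"pup_id", "region", "age", "metabolite"})):
        raise ValueError("table carries neither decay (b, E) nor ADC (t_d, adc) columns")
    return df
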