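"""Diffusion acquisition schemes for pulsed-gradient stimulated-echo dMRS.

All quantities use the microstructure-friendly unit system: lengths in µm,
times in ms, diffusivities in µm²/ms and b-values in ms/µm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DiffusionScheme", "make_scheme_table"]


@dataclass(frozen=True)
class DiffusionScheme:
    """Timing and weighting of one PGSE-like diffusion condition.

    Parameters
    ----------
    b_values : array-like
        Diffusion weightings in ms/µm² (all >= 0).
    delta : float
        Diffusion gradient duration δ in ms.
    Delta : float
        Separation between the two gradient pulses Δ in ms (Δ >= δ).
    mixing_time : float
        Stimulated-echo mixing time TM in ms (metadata).
    n_directions : int
        Number of gradient directions acquired.
    t_d_nominal : float or None
        Printed nominal diffusion time, carried as metadata when it differs
        from the internal Δ − δ/3 convention.
    """

    b_values: np.ndarray
    delta: float
    Delta: float
    mixing_time: float = 0.0
    n_directions: int = 1
    t_d_nominal: float | None = field(default=None)

    def __post_init__(self) -> None:
        b = np.atleast_1d(np.asarray(self.b_values, dtype=float))
        if np.any(b < 0):
            raise ValueError("b_values must be >= 0")
        if not self.delta > 0:
            raise ValueError("delta must be > 0")
        if self.Delta < self.delta:
            raise ValueError("Delta must be >= delta")
        if self.n_directions < 1:
            raise ValueError("n_directions must be >= 1")
        object.__setattr__(self, "b_values", b)

    @property
    def t_d(self) -> float:
        """Effective diffusion time Δ − δ/3 in ms."""
        return self.Delta - self.delta / 3.0

    @property
    def b_pair(self) -> tuple[float, float]:
        """(b0, b1) pair used for two-point ADC estimation."""
        b = np.sort(self.b_values)
        return float(b[0]), float(b[1])


# Printed nominal diffusion times per mixing time for the study design.
_TABLE_TD = {100.0: 104.25, 500.0: 504.25, 750.0: 754.25, 1000.0: 1004.25}
_TABLE_B0 = {100.0: 0.035, 500.0: 0.17, 750.0: 0.26, 1000.0: 0.35}
_HIGH_B = (0.035, 3.035, 6.0, 10.0, 20.0, 30.0)


def make_scheme_table(delta: float = 5.0) -> dict[float, DiffusionScheme]:
    """Build the study's four-mixing-time acquisition table.

    TM = 100 ms carries the full six-b high-weighting series
    (b = 0.035 … 30 ms/µm², Δ = 105.91 ms); the longer mixing times carry
    only the (b0, b0 + 3) pair used for ADC estimation, with Δ consistent
    with the nominal diffusion times. 16 directions, δ = 5 ms throughout.

    Returns a dict keyed by mixing time in ms.
    """
    schemes: dict[float, DiffusionScheme] = {}
    for tm, td in _TABLE_TD.items():
        b0 = _TABLE_B0[tm]
        if tm == 100.0:
            b = np.array(_HIGH_B)
            Delta = 105.91
        else:
            b = np.array([b0, b0 + 3.0])
            Delta = td + delta / 3.0
        schemes[tm] = DiffusionScheme(
            b_values=b,
            delta=delta,
            Delta=Delta,
            mixing_time=tm,
            n_directions=16,
            t_d_nominal=td,
        )
    return schemes
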