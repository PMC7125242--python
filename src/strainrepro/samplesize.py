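"""Reproducibility-based sample-size calculation.

The number of animals needed to detect a change delta (in strain points)
between two paired measurements, given the SD sigma of between-measurement
differences, is

    n = round(2 * f * sigma**2 / delta**2)

where f = f(alpha, P) is a tabulated factor (10.5 for alpha = 0.05 and
power 0.80) and rounding is half-away-from-zero with a floor of one animal.
sigma comes from a reproducibility study: either the SD of the
inter-observer differences at baseline, or the Cohen pooling
sqrt((SD1^2 + SD2^2) / 2) of the two observers' baseline SDs.  Planned
samples are inflated for expected dropout as ceil(n / (1 - rate)).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from strainrepro.model import GLOBAL_LABEL, Component
from strainrepro import refvalues

DEFAULT_F = refvalues.F_FACTOR
DEFAULT_ALPHA = 0.05
DEFAULT_POWER = 0.80
DEFAULT_DELTAS = refvalues.DELTAS

PLAN_COLUMNS = [
    "component", "sigma", "sigma_source", "delta", "f", "alpha", "power",
    "required_n", "dropout_rate", "inflated_n",
]


def pooled_sd(sd1: float, sd2: float) -> float:
    """Cohen pooled SD of two measurement series: sqrt((sd1^2 + sd2^2) / 2)."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError(f"standard deviations must be >= 0, got ({sd1}, {sd2})")
    return math.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def required_n(sigma: float, delta: float, f: float = DEFAULT_F) -> int:
    """Animals required to detect a change of ``delta`` strain points.

    ``n = round_half_away(2 * f * sigma^2 / delta^2)``, clamped to at least
    one animal.  The factor 2 reflects that the detected change is a
    difference of two measurements, each carrying variance sigma^2 / 2.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    if f <= 0:
        raise ValueError(f"f must be > 0, got {f}")
    return max(1, _round_half_away(2.0 * f * sigma ** 2 / delta ** 2))


def inflate_dropout(n: int, rate: float) -> int:
    """Inflate a planned sample for expected dropout: ceil(n / (1 - rate))."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    return int(math.ceil(n / (1.0 - rate)))


def sigma_from_agreement(
    agreement_df: pd.DataFrame,
    state: str = "BL",
    comparison: str = "inter_observer",
) -> dict[str, float]:
    """sigma per component = SD of paired differences at the given state.

    Takes the agreement table produced by
    :func:`strainrepro.agreement.agreement_table` and reads off ``sd_diff``
    of the requested comparison rows (baseline inter-observer by default).
    """
    sub = agreement_df[
        (agreement_df["state"] == state) & (agreement_df["comparison"] == comparison)
    ]
    sigma = {}
    for comp in Component:
        rows = sub[sub["component"] == comp.value]
        if rows.empty:
            raise ValueError(
                f"no {comparison} agreement row at state={state} for {comp.value}"
            )
        sigma[GLOBAL_LABEL[comp]] = float(rows["sd_diff"].iloc[0])
    return sigma


def sigma_cohen_pooled(globals_df: pd.DataFrame, state: str = "BL") -> dict[str, float]:
    """sigma per component = Cohen pooling of the two observers' SDs at a state.

    ``globals_df`` holds replicate-averaged global values (columns animal_id,
    state, component, observer_id, value).
    """
    sub = globals_df[globals_df["state"] == state]
    observers = sorted(sub["observer_id"].unique())
    if len(observers) < 2:
        raise ValueError("Cohen pooling needs two observers")
    sigma = {}
    for comp in Component:
        sds = []
        for obs in observers[:2]:
            vals = sub[(sub["component"] == comp.value) & (sub["observer_id"] == obs)]["value"]
            if len(vals) < 2:
                raise ValueError(f"need >= 2 animals per observer for {comp.value}")
            sds.append(float(np.std(vals, ddof=1)))
        sigma[GLOBAL_LABEL[comp]] = pooled_sd(*sds)
    return sigma


def build_sample_size_table(
    sigma: Mapping[str, float],
    *,
    deltas: Sequence[float] = DEFAULT_DELTAS,
    f: float = DEFAULT_F,
    alpha: float = DEFAULT_ALPHA,
    power: float = DEFAULT_POWER,
    dropout_rate: float = 0.0,
    sigma_source: str = "explicit",
    mean_diff: Mapping[str, float] | None = None,
    suppress_bias_exceeds_delta: bool = False,
) -> pd.DataFrame:
    """Required-n plan per component x delta (the study's planning table).

    ``sigma`` maps component labels (GLS/GCS/GRS) to the SD of
    between-measurement differences in strain points; ``deltas`` are the
    detectable changes in strain points.  ``required_n`` is non-increasing
    across increasing deltas.  With ``suppress_bias_exceeds_delta=True`` a
    cell whose systematic bias magnitude (``mean_diff``) exceeds delta is
    reported as missing (NaN) — a change smaller than the observer bias is
    not meaningfully detectable.
    """
    if not sigma:
        raise ValueError("sigma mapping is empty — no baseline rows available")
    rows = []
    for component, sig in sigma.items():
        for delta in deltas:
            n_req: float | int = required_n(sig, delta, f)
            n_inf: float | int = inflate_dropout(int(n_req), dropout_rate)
            if (
                suppress_bias_exceeds_delta
                and mean_diff is not None
                and abs(mean_diff.get(component, 0.0)) > delta
            ):
                n_req = math.nan
                n_inf = math.nan
            rows.append((
                component, float(sig), sigma_source, float(delta), f, alpha,
                power, n_req, dropout_rate, n_inf,
            ))
    return pd.DataFrame(rows, columns=PLAN_COLUMNS)


def sample_size_curve(
    sigma: Mapping[str, float],
    *,
    delta_grid: Sequence[float] | None = None,
    f: float = DEFAULT_F,
) -> pd.DataFrame:
    """Required n over a grid of deltas per component (planning curve data)."""
    if delta_grid is None:
        delta_grid = np.arange(1.0, 20.0 + 1e-9, 0.5)
    rows = [
        (component, float(delta), required_n(sig, float(delta), f))
        for component, sig in sigma.items()
        for delta in delta_grid
    ]
    return pd.DataFrame(rows, columns=["component", "delta", "required_n"])
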