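"""Bland-Altman and intraclass-correlation agreement analysis.

Two raters (or two analysis sessions of one rater) measure the same n
animals.  Bland-Altman analysis summarises the paired differences d = a - b
by their mean (bias), sample SD, and 95% limits of agreement
bias -/+ z * SD (z = 1.96).  The ICC is computed from the two-way ANOVA mean
squares of the n x k subject-by-rater matrix; the default variant is
two-way, absolute agreement, single measures — McGraw & Wong's ICC(A,1) —
with the consistency and average-measures forms selectable.  95% ICC
confidence bounds come from F-distribution quantiles (Satterthwaite degrees
of freedom for the absolute-agreement forms).

Agreement adjectives follow the study's categories: excellent for
ICC > 0.74, good for 0.60-0.74, fair for 0.40-0.59, poor below 0.40.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from strainrepro.model import Component, State

DEFAULT_Z = 1.96
DEFAULT_ICC_VARIANT = "A-1"
ICC_VARIANTS = ("A-1", "C-1", "A-k", "C-k")

COMPARISONS = ("inter_observer", "intra_observer")

AGREEMENT_COLUMNS = [
    "comparison", "component", "state", "n",
    "mean_diff", "sd_diff", "loa_lower", "loa_upper",
    "icc", "icc_ci_lower", "icc_ci_upper", "category",
]


class DegenerateDataError(ValueError):
    """Input has no variance to apportion (ICC undefined)."""


class MissingContextError(ValueError):
    """A requested comparison context cannot be extracted from the data."""


@dataclass(frozen=True)
class PairedSeries:
    """Aligned paired measurements of the same animals by two raters/sessions."""

    labels: tuple[str, ...]
    a: np.ndarray
    b: np.ndarray
    context: tuple[str, str, str] = ("", "", "")  # (state, component, comparison)

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if not (len(self.labels) == a.size == b.size):
            raise ValueError("labels, a and b must have equal length")
        if a.size < 2:
            raise ValueError("paired series needs n >= 2")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired series values must be finite")

    @property
    def n(self) -> int:
        return int(self.a.size)


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    z: float = DEFAULT_Z
    n: int = 0


@dataclass(frozen=True)
class IccResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    variant: str
    category: str
    n: int
    k: int


def bland_altman(series: PairedSeries | None = None, z: float = DEFAULT_Z,
                 *, a: Sequence[float] | None = None,
                 b: Sequence[float] | None = None) -> BlandAltmanResult:
    """Bias, SD of paired differences and limits of agreement for a - b.

    Accepts either a :class:`PairedSeries` or raw ``a``/``b`` arrays.  The SD
    uses the n-1 denominator; zero-variance differences are allowed (the
    limits collapse onto the bias).
    """
    if series is None:
        a_arr = np.asarray(a, dtype=float)
        b_arr = np.asarray(b, dtype=float)
        series = PairedSeries(tuple(str(i) for i in range(a_arr.size)), a_arr, b_arr)
    d = series.a - series.b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_lower=mean_diff - z * sd_diff,
        loa_upper=mean_diff + z * sd_diff,
        z=z,
        n=series.n,
    )


def classify_agreement(estimate: float) -> str:
    """Map an ICC estimate to the study's agreement adjective."""
    if not math.isfinite(estimate):
        raise ValueError(f"ICC estimate must be finite, got {estimate}")
    if estimate > 0.74:
        return "excellent"
    if estimate >= 0.60:
        return "good"
    if estimate >= 0.40:
        return "fair"
    return "poor"


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows = subjects, columns = raters)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def _spearman_brown(r: float, k: int) -> float:
    # Average-measures reliability of a single-measures value r.  The map has
    # a pole at r = -1/(k-1); at or below it the k-rater mean's reliability
    # is unbounded below, so CI bounds in that regime are -inf.
    denom = 1.0 + (k - 1) * r
    if denom <= 0:
        return -math.inf
    return k * r / denom


def icc(matrix: np.ndarray | Sequence[Sequence[float]],
        variant: str = DEFAULT_ICC_VARIANT, alpha: float = 0.05) -> IccResult:
    """ICC of an n-subjects x k-raters matrix with a 95% (1 - alpha) CI.

    Variants: ``"A-1"`` two-way absolute agreement single measures (default),
    ``"C-1"`` two-way consistency single measures, ``"A-k"``/``"C-k"`` the
    average-measures forms.  The matrix must be complete; zero total variance
    raises :class:`DegenerateDataError`.  Negative estimates and CI bounds
    are reported as computed (no truncation at zero).
    """
    if variant not in ICC_VARIANTS:
        raise ValueError(f"unknown ICC variant {variant!r}, expected one of {ICC_VARIANTS}")
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x raters)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need n >= 2 subjects and k >= 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("incomplete or non-finite rating matrix")
    msr, msc, mse = _mean_squares(x)
    if max(msr, msc, mse) <= 0.0:
        raise DegenerateDataError("zero total variance: ICC undefined")

    df_err = (n - 1) * (k - 1)
    q = 1.0 - alpha / 2.0

    if variant.startswith("C"):
        est1 = (msr - mse) / (msr + (k - 1) * mse) if mse > 0 else 1.0
        if mse > 0:
            f_obs = msr / mse
            fl = f_obs / stats.f.ppf(q, n - 1, df_err)
            fu = f_obs * stats.f.ppf(q, df_err, n - 1)
            lo1 = (fl - 1.0) / (fl + k - 1.0)
            hi1 = (fu - 1.0) / (fu + k - 1.0)
        else:
            lo1 = hi1 = 1.0
    else:
        if mse == 0.0 and msc == 0.0:
            est1, lo1, hi1 = 1.0, 1.0, 1.0
        else:
            est1 = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
            a_w = k * est1 / (n * (1.0 - est1)) if est1 < 1.0 else math.inf
            b_w = 1.0 + k * est1 * (n - 1) / (n * (1.0 - est1)) if est1 < 1.0 else math.inf
            if math.isinf(a_w):
                lo1 = hi1 = 1.0
            else:
                num_v = (a_w * msc + b_w * mse) ** 2
                den_v = (a_w * msc) ** 2 / (k - 1) + (b_w * mse) ** 2 / df_err
                v = num_v / den_v if den_v > 0 else 1.0
                fl = stats.f.ppf(q, n - 1, v)
                fu = stats.f.ppf(q, v, n - 1)
                lo1 = (n * (msr - fl * mse)
                       / (fl * (k * msc + (k * n - k - n) * mse) + n * msr))
                hi1 = (n * (fu * msr - mse)
                       / (k * msc + (k * n - k - n) * mse + n * fu * msr))

    if variant.endswith("-1"):
        est, lo, hi = est1, lo1, hi1
    else:
        # direct average-measures estimates; CI bounds via the (guarded)
        # Spearman-Brown map of the single-measures bounds
        if variant == "C-k":
            est = (msr - mse) / msr if msr > 0 else -math.inf
        else:
            est = (msr - mse) / (msr + (msc - mse) / n)
        lo = _spearman_brown(lo1, k)
        hi = _spearman_brown(hi1, k)
        lo = min(lo, est)
        hi = max(hi, est)

    return IccResult(
        estimate=float(est),
        ci_lower=float(lo),
        ci_upper=float(hi),
        variant=variant,
        category=classify_agreement(float(est)),
        n=n,
        k=k,
    )


def _canonical_order(values, enum_cls):
    order = [m.value for m in enum_cls]
    return [v for v in order if v in set(values)]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing column(s) {missing}")


def extract_series(globals_df: pd.DataFrame, comparison: str, component: str,
                   state: str, observers: Sequence[str] | None = None) -> PairedSeries:
    """Build the paired series for one agreement context.

    ``globals_df`` holds per-replicate global strain values (columns
    animal_id, state, component, observer_id, replicate, value).  For the
    inter-observer comparison, each observer's replicates are averaged and
    observer 1 is paired against observer 2; for the intra-observer
    comparison, observer 1's replicate 1 is paired against replicate 2.
    """
    _require_columns(
        globals_df,
        ["animal_id", "state", "component", "observer_id", "replicate", "value"],
        "per-replicate global strain table",
    )
    sub = globals_df[(globals_df["state"] == state) & (globals_df["component"] == component)]
    if sub.empty:
        raise MissingContextError(f"no data for state={state}, component={component}")
    if observers is None:
        observers = sorted(globals_df["observer_id"].unique())
    if comparison == "inter_observer":
        if len(observers) < 2:
            raise MissingContextError("inter-observer comparison needs two observers")
        o1, o2 = observers[0], observers[1]
        avg = sub.groupby(["animal_id", "observer_id"], as_index=False)["value"].mean()
        wide = avg.pivot(index="animal_id", columns="observer_id", values="value")
        if o1 not in wide.columns or o2 not in wide.columns:
            raise MissingContextError(f"observer(s) missing for state={state}, component={component}")
        wide = wide[[o1, o2]].dropna()
        a_col, b_col = o1, o2
    elif comparison == "intra_observer":
        o1 = observers[0]
        own = sub[sub["observer_id"] == o1]
        reps = sorted(own["replicate"].unique())
        if len(reps) < 2:
            raise MissingContextError(
                f"intra-observer comparison needs two replicates of observer {o1!r}"
            )
        wide = own.pivot(index="animal_id", columns="replicate", values="value")
        wide = wide[[reps[0], reps[1]]].dropna()
        a_col, b_col = reps[0], reps[1]
    else:
        raise ValueError(f"unknown comparison {comparison!r}")
    if len(wide) < 2:
        raise MissingContextError(
            f"fewer than 2 complete animals for {comparison}, state={state}, component={component}"
        )
    return PairedSeries(
        labels=tuple(str(i) for i in wide.index),
        a=wide[a_col].to_numpy(float),
        b=wide[b_col].to_numpy(float),
        context=(state, component, comparison),
    )


@dataclass
class AgreementTable:
    """Agreement rows plus per-context gaps that could not be computed."""

    table: pd.DataFrame
    gaps: list[dict] = field(default_factory=list)


def agreement_table(
    globals_df: pd.DataFrame,
    *,
    states: Sequence[str] | None = None,
    components: Sequence[str] | None = None,
    z: float = DEFAULT_Z,
    icc_variant: str = DEFAULT_ICC_VARIANT,
) -> AgreementTable:
    """Bland-Altman + ICC for every (comparison, component, state) context.

    The full two-observer, three-state, three-component design yields 18
    rows.  Contexts that cannot be extracted (state absent, observer or
    replicate missing, degenerate variance) are recorded as gaps; the
    remaining rows are still produced.
    """
    if states is None:
        states = [s.value for s in State]
    if components is None:
        components = [c.value for c in Component]
    observers = sorted(globals_df["observer_id"].unique())
    rows, gaps = [], []
    for comparison in COMPARISONS:
        for component in _canonical_order(components, Component):
            for state in _canonical_order(states, State):
                try:
                    series = extract_series(globals_df, comparison, component, state,
                                            observers=observers)
                    ba = bland_altman(series, z=z)
                    matrix = np.column_stack([series.a, series.b])
                    ic = icc(matrix, variant=icc_variant)
                except (MissingContextError, DegenerateDataError, ValueError) as exc:
                    gaps.append({
                        "comparison": comparison, "component": component,
                        "state": state, "reason": str(exc),
                    })
                    continue
                rows.append((
                    comparison, component, state, series.n,
                    ba.mean_diff, ba.sd_diff, ba.loa_lower, ba.loa_upper,
                    ic.estimate, ic.ci_lower, ic.ci_upper, ic.category,
                ))
    return AgreementTable(
        table=pd.DataFrame(rows, columns=AGREEMENT_COLUMNS),
        gaps=gaps,
    )


def bland_altman_points(
    globals_df: pd.DataFrame,
    *,
    states: Sequence[str] | None = None,
    components: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-animal (mean of pair, difference) points for Bland-Altman panels."""
    if states is None:
        states = [s.value for s in State]
    if components is None:
        components = [c.value for c in Component]
    observers = sorted(globals_df["observer_id"].unique())
    rows = []
    for comparison in COMPARISONS:
        for component in _canonical_order(components, Component):
            for state in _canonical_order(states, State):
                try:
                    series = extract_series(globals_df, comparison, component, state,
                                            observers=observers)
                except (MissingContextError, ValueError):
                    continue
                for label, a_val, b_val in zip(series.labels, series.a, series.b):
                    rows.append((
                        comparison, component, state, label,
                        (a_val + b_val) / 2.0, a_val - b_val,
                    ))
    return pd.DataFrame(
        rows,
        columns=["comparison", "component", "state", "animal_id",
                 "mean_of_pair", "difference"],
    )
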