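"""Registry-table statistics: descriptives, two-group U tests, trends, histograms.

Operates on registry-style patient tables (one row per repaired hernia, two
groups: primary and recurrent incisional hernia).  Group comparisons use the
Mann-Whitney U test with midrank tie handling: the exact null distribution of
the rank sum (computed by dynamic programming over the tied midranks) when
both groups have at most 20 observations, and a normal approximation with
tie-corrected variance and continuity correction for larger groups — the
convention of the common online calculators.  Two-sided p-values are
``min(1, 2*min(P(U<=u), P(U>=u)))``.  No multiple-testing adjustment is
applied by default (raw per-variable p-values); Holm adjustment is available
as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as _dc_fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as _sstats

__all__ = [
    "PatientRecord",
    "GroupComparison",
    "Summary",
    "RegistryLoadResult",
    "REGISTRY_SCHEMA",
    "load_registry",
    "save_registry",
    "records_to_frame",
    "describe",
    "mann_whitney_u",
    "compare_groups",
    "trend_line",
    "histogram",
    "HistogramResult",
]

GROUPS = ("primary", "recurrent")
REGISTRY_SCHEMA = "herniamech-registry/1"

#: Column order of the registry table format.
REGISTRY_COLUMNS = [
    "group", "age", "sex", "asa", "height", "weight", "bmi",
    "risk_factor_count", "prior_surgeries", "hernia_area", "distension",
    "crip", "mesh_area", "min_overlap", "mdar", "fixation_points", "grip",
    "op_time", "los", "complication", "nas_rest", "nas_load", "recurrence",
]
#: ``distension`` may be missing (patients scanned at rest only).
MANDATORY_COLUMNS = [c for c in REGISTRY_COLUMNS if c != "distension"]


@dataclass
class PatientRecord:
    """One registry row: biometrics, biomechanical scores, operative course."""

    group: str
    age: float
    sex: str
    asa: int
    height: float  # cm
    weight: float  # kg
    bmi: float  # kg/m²
    risk_factor_count: int
    prior_surgeries: int
    hernia_area: float  # cm², effective (larger of imaging / intraop)
    distension: Optional[float]  # percent; None when not measured
    crip: float
    mesh_area: float  # cm²
    min_overlap: float  # mm
    mdar: float
    fixation_points: int
    grip: float
    op_time: float  # minutes
    los: float  # days
    complication: bool
    nas_rest: int  # 0-10 pain at rest, 1-year follow-up
    nas_load: int  # 0-10 pain under load
    recurrence: bool

    def validation_errors(self) -> List[str]:
        errs: List[str] = []
        if self.group not in GROUPS:
            errs.append(f"group must be one of {GROUPS}, got {self.group!r}")
        for name in ("nas_rest", "nas_load"):
            v = getattr(self, name)
            if not (0 <= v <= 10):
                errs.append(f"{name} must be in [0, 10], got {v}")
        for name in ("risk_factor_count", "prior_surgeries", "fixation_points"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be >= 0")
        if self.asa not in (1, 2, 3, 4):
            errs.append(f"asa must be 1-4, got {self.asa}")
        if self.height > 0 and self.weight > 0:
            implied = self.weight / (self.height / 100.0) ** 2
            if abs(implied - self.bmi) > 0.6:  # rounding slack on h/w/bmi
                errs.append(
                    f"bmi {self.bmi} inconsistent with height/weight (implies {implied:.1f})"
                )
        return errs


@dataclass
class Summary:
    """Descriptive summary of one numeric variable."""

    variable: str
    n: int
    missing: int
    median: float
    mean: float
    sd: float
    range: Tuple[float, float]


@dataclass
class GroupComparison:
    """Mann-Whitney U comparison of one variable between the two groups."""

    variable: str
    median_primary: float
    median_recurrent: float
    u_statistic: float
    p_value: float
    n_primary: int
    n_recurrent: int
    method: str = "exact"
    p_adjusted: Optional[float] = None


@dataclass
class RegistryLoadResult:
    records: List[PatientRecord]
    rejects: pd.DataFrame  # original row + 'reject_reason'

    def __iter__(self):
        return iter(self.records)


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=REGISTRY_COLUMNS)


def save_registry(records: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    """Write records as a delimited-text registry table with a schema header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# schema: {REGISTRY_SCHEMA}\n")
        records_to_frame(records).to_csv(fh, index=False)


def _coerce_record(row: pd.Series) -> PatientRecord:
    kwargs = {}
    for f in _dc_fields(PatientRecord):
        raw = row.get(f.name)
        if f.name == "distension":
            kwargs[f.name] = None if pd.isna(raw) else float(raw)
        elif f.name in ("group", "sex"):
            kwargs[f.name] = str(raw)
        elif f.name in ("complication", "recurrence"):
            kwargs[f.name] = bool(raw) if isinstance(raw, (bool, np.bool_)) else str(raw).strip().lower() in ("true", "1", "yes")
        elif f.name in ("asa", "risk_factor_count", "prior_surgeries", "fixation_points", "nas_rest", "nas_load"):
            kwargs[f.name] = int(raw)
        else:
            kwargs[f.name] = float(raw)
    return PatientRecord(**kwargs)


def load_registry(path: Union[str, Path]) -> RegistryLoadResult:
    """Load a registry table; invalid rows go to a rejects report, not dropped silently."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path.name}: missing mandatory columns {missing_cols}")
    records: List[PatientRecord] = []
    reject_rows: List[Dict] = []
    for _, row in df.iterrows():
        try:
            rec = _coerce_record(row)
            errs = rec.validation_errors()
        except (ValueError, TypeError) as exc:
            errs = [str(exc)]
            rec = None
        if errs:
            rd = row.to_dict()
            rd["reject_reason"] = "; ".join(errs)
            reject_rows.append(rd)
        else:
            records.append(rec)
    rejects = pd.DataFrame(reject_rows)
    return RegistryLoadResult(records=records, rejects=rejects)


def _values(records, variable: str) -> pd.Series:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if variable not in df.columns:
        raise KeyError(f"unknown variable {variable!r}")
    return pd.to_numeric(df[variable], errors="coerce")


def describe(records, variable: str) -> Summary:
    """Median, mean, SD, range, n and missing count of a numeric variable.

    Missing values are excluded from n; they are never imputed here (the 20%
    default distension belongs to the planning pipeline, not to statistics).
    """
    s = _values(records, variable)
    valid = s.dropna()
    if valid.empty:
        raise ValueError(f"variable {variable!r} has no non-missing values")
    return Summary(
        variable=variable,
        n=int(valid.size),
        missing=int(s.size - valid.size),
        median=float(valid.median()),
        mean=float(valid.mean()),
        sd=float(valid.std(ddof=1)) if valid.size > 1 else 0.0,
        range=(float(valid.min()), float(valid.max())),
    )


# -- Mann-Whitney U ----------------------------------------------------------

EXACT_MAX_N = 20


def _exact_two_sided_p(pooled_ranks: np.ndarray, n1: int, u1: float) -> float:
    """Exact two-sided p over the permutation null of the rank sum.

    Works with midranks (ties): doubled midranks are integers, so the null
    distribution of the first sample's doubled rank sum is computed by a
    subset-sum dynamic program over the pooled values, conditioning on the
    observed tie pattern.  Subset counts stay below 2^53 for N <= 40, so
    float64 arithmetic is exact.
    """
    d = np.round(2 * pooled_ranks).astype(np.int64)
    max_sum = int(d.sum())
    dp = np.zeros((n1 + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for v in d:
        # descending k so each pooled value enters a subset at most once
        for k in range(n1, 0, -1):
            dp[k, v:] += dp[k - 1, : max_sum + 1 - v]
    dist = dp[n1]
    # doubled U for each doubled rank sum s: 2*U = s - n1*(n1+1)
    u2 = np.arange(max_sum + 1) - n1 * (n1 + 1)
    target = round(2 * u1)
    total = dist.sum()
    p_le = dist[u2 <= target].sum() / total
    p_ge = dist[u2 >= target].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_approx_p(pooled: np.ndarray, n1: int, n2: int, u1: float) -> float:
    """Two-sided normal approximation with tie-corrected variance and
    continuity correction."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # every pooled value identical
        return 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * _sstats.norm.sf(z)))


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], *, exact_max_n: int = EXACT_MAX_N
) -> Tuple[float, float, str]:
    """Mann-Whitney U of two samples: ``(U, two-sided p, method)``.

    U is the statistic of the first sample (number of (x, y) pairs with
    x > y, counting ties as 1/2); ``U <= n1*n2`` always.  The exact
    permutation null is used when both samples have at most ``exact_max_n``
    observations, the tie-corrected normal approximation with continuity
    correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _sstats.rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    if max(n1, n2) <= exact_max_n:
        return u1, _exact_two_sided_p(ranks, n1, u1), "exact"
    return u1, _normal_approx_p(pooled, n1, n2, u1), "normal_approx"


def compare_groups(
    records,
    variables: Sequence[str],
    *,
    holm: bool = False,
) -> List[GroupComparison]:
    """One U-test comparison (primary vs recurrent) per variable.

    Missing values are dropped per variable.  Raw p-values by default; pass
    ``holm=True`` for a Holm step-down adjustment (off by default to mirror
    standard per-variable registry reporting).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    out: List[GroupComparison] = []
    for var in variables:
        s = pd.to_numeric(df[var], errors="coerce")
        grp = df["group"]
        xs = s[grp == "primary"].dropna().to_numpy()
        ys = s[grp == "recurrent"].dropna().to_numpy()
        if xs.size < 2 or ys.size < 2:
            raise ValueError(f"variable {var!r}: need >= 2 observations per group")
        u, p, method = mann_whitney_u(xs, ys)
        out.append(
            GroupComparison(
                variable=var,
                median_primary=float(np.median(xs)),
                median_recurrent=float(np.median(ys)),
                u_statistic=u,
                p_value=p,
                n_primary=int(xs.size),
                n_recurrent=int(ys.size),
                method=method,
            )
        )
    if holm:
        order = np.argsort([c.p_value for c in out])
        m = len(out)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, min(1.0, (m - rank) * out[i].p_value))
            out[i].p_adjusted = running
    return out


def trend_line(records, x_variable: str, y_variable: str) -> Tuple[float, float, float]:
    """Least-squares line and product-moment correlation of two variables.

    Returns ``(slope, intercept, r)``; requires at least three complete pairs.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    sub = df[[x_variable, y_variable]].apply(pd.to_numeric, errors="coerce").dropna()
    if len(sub) < 3:
        raise ValueError("trend line needs at least 3 paired observations")
    res = _sstats.linregress(sub[x_variable], sub[y_variable])
    return float(res.slope), float(res.intercept), float(res.rvalue)


@dataclass
class HistogramResult:
    variable: str
    edges: np.ndarray  # bin edges, len = n_bins + 1
    counts: np.ndarray  # len = n_bins
    overflow: int  # values at/above the truncation bound
    truncated_at: Optional[float]
    median: Optional[float]  # median of all (untruncated) values


def histogram(
    records,
    variable: str,
    bin_width: float,
    *,
    origin: float = 0.0,
    truncate_at: Optional[float] = None,
) -> HistogramResult:
    """Fixed-width histogram with an optional overflow bucket.

    With ``truncate_at`` set, values at or beyond the bound are counted in
    ``overflow`` instead of a bin (display truncation for heavy right tails);
    the returned median is computed on all values, untruncated.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    vals = _values(records, variable).dropna().to_numpy()
    if vals.size == 0:
        return HistogramResult(variable, np.array([origin]), np.array([], dtype=int), 0,
                               truncate_at, None)
    median = float(np.median(vals))
    if truncate_at is not None:
        overflow = int(np.sum(vals >= truncate_at))
        vals_binned = vals[vals < truncate_at]
        upper = truncate_at
    else:
        overflow = 0
        vals_binned = vals
        upper = vals.max() + bin_width
    n_bins = max(1, int(np.ceil((upper - origin) / bin_width)))
    edges = origin + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals_binned, bins=edges)
    return HistogramResult(variable, edges, counts, overflow, truncate_at, median)
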