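"""Method-comparison statistics for markerless vs clinical goniometry.

Core quantities for validating an angle-measurement algorithm against a
clinical reference on paired per-subject values:

* **ICC(A,1)** — single-measure intraclass correlation under a two-way
  model with *absolute agreement* (McGraw & Wong 1996), which penalizes
  both correlation loss and systematic offset between methods. From the
  two-way ANOVA mean squares (n subjects × k raters)::

      ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

  with the 95% CI from the F-based procedure (Satterthwaite df for the
  column/error combination) and a p-value testing ICC = 0 via
  F = MS_R / MS_E on (n-1, (n-1)(k-1)) df.

* **Bland–Altman** — mean bias and 95% limits of agreement
  bias ± 1.96·sd of the differences (sd with the n−1 denominator).
  Differences are oriented **algorithm − clinical** throughout, so a
  negative bias means the algorithm under-reads the goniometer.

* **Proportional bias** — OLS of differences on pair means; a non-zero
  slope means accuracy depends on the magnitude of flexion.

* **Error vs covariate** — OLS and Spearman rank association of the
  (absolute or signed) measurement error with a per-subject covariate
  such as months since surgery.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "ICCResult",
    "BlandAltmanResult",
    "CovariateErrorResult",
    "CohortSummary",
    "icc_a1",
    "icc_c1",
    "bland_altman",
    "proportional_bias",
    "error_vs_covariate",
    "summarize_cohort",
    "plot_bland_altman",
]


@dataclass
class PairedMeasurements:
    """Per-subject paired values: clinical goniometry vs algorithm output."""

    subjects: list[str]
    clinical_deg: np.ndarray
    algorithm_deg: np.ndarray
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.clinical_deg = np.asarray(self.clinical_deg, dtype=float)
        self.algorithm_deg = np.asarray(self.algorithm_deg, dtype=float)
        n = len(self.subjects)
        if not (len(self.clinical_deg) == len(self.algorithm_deg) == n):
            raise ValueError("subjects, clinical_deg, algorithm_deg lengths differ")
        if n < 3:
            raise ValueError(f"need >= 3 paired subjects, got {n}")
        if np.isnan(self.clinical_deg).any() or np.isnan(self.algorithm_deg).any():
            raise ValueError("missing values in measurement columns")
        self.covariates = {
            k: np.asarray(v, dtype=float) for k, v in self.covariates.items()
        }
        for k, v in self.covariates.items():
            if len(v) != n:
                raise ValueError(f"covariate {k!r} length {len(v)} != n {n}")

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def differences(self) -> np.ndarray:
        """algorithm − clinical."""
        return self.algorithm_deg - self.clinical_deg

    @property
    def means(self) -> np.ndarray:
        return (self.algorithm_deg + self.clinical_deg) / 2.0

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedMeasurements":
        """Read ``subject_id,clinical_deg,algorithm_deg[,covariate...]``."""
        df = pd.read_csv(path)
        required = {"subject_id", "clinical_deg", "algorithm_deg"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"pairs CSV missing columns: {sorted(missing)}")
        cov_cols = [c for c in df.columns if c not in required]
        return cls(
            subjects=df["subject_id"].astype(str).tolist(),
            clinical_deg=df["clinical_deg"].to_numpy(float),
            algorithm_deg=df["algorithm_deg"].to_numpy(float),
            covariates={c: df[c].to_numpy(float) for c in cov_cols},
        )


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    f_value: float
    df1: float
    df2: float
    p_value: float
    n_subjects: int
    model: str = "two-way, absolute agreement, single measure (A,1)"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must contain the estimate")


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_multiplier: float = 1.96
    prop_slope: Optional[float] = None
    prop_p: Optional[float] = None


@dataclass(frozen=True)
class CovariateErrorResult:
    beta: float
    beta_p: float
    r_squared: float
    rho: float
    rho_p: float
    error_kind: str


def _mean_squares(x: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares for an n-subjects × k-raters table."""
    n, k = x.shape
    grand = x.mean()
    rows = x.mean(axis=1)
    cols = x.mean(axis=0)
    msr = k * np.sum((rows - grand) ** 2) / (n - 1)
    msc = n * np.sum((cols - grand) ** 2) / (k - 1)
    resid = x - rows[:, None] - cols[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse), n, k


def icc_a1(pairs: PairedMeasurements, alpha: float = 0.05) -> ICCResult:
    """Single-measure absolute-agreement ICC with 95% CI and F test."""
    x = np.column_stack([pairs.clinical_deg, pairs.algorithm_deg])
    msr, msc, mse, n, k = _mean_squares(x)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-30:
        raise ValueError("zero total variance: ICC undefined")
    est = (msr - mse) / denom

    df1 = n - 1
    if mse < 1e-30:
        # perfect residual agreement: interval degenerates at the estimate
        return ICCResult(
            estimate=est, ci_low=est, ci_high=est, f_value=math.inf,
            df1=df1, df2=(n - 1) * (k - 1), p_value=0.0, n_subjects=n,
        )

    f_value = msr / mse
    df2_null = (n - 1) * (k - 1)
    p_value = float(stats.f.sf(f_value, df1, df2_null))

    # Satterthwaite df for the denominator combination at the point estimate
    a = k * est / (n * (1.0 - est)) if est < 1.0 else math.inf
    if math.isinf(a):
        v = df2_null
    else:
        b = 1.0 + k * est * (n - 1) / (n * (1.0 - est))
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den
    fl = stats.f.ppf(1 - alpha / 2, df1, v)
    fu = stats.f.ppf(1 - alpha / 2, v, df1)
    c = k * msc + (k * n - k - n) * mse
    lower = n * (msr - fl * mse) / (fl * c + n * msr)
    upper = n * (fu * msr - mse) / (c + n * fu * msr)
    lower = float(np.clip(lower, -1.0, min(est, 1.0)))
    upper = float(np.clip(upper, max(est, -1.0), 1.0))
    return ICCResult(
        estimate=float(est), ci_low=lower, ci_high=upper,
        f_value=float(f_value), df1=float(df1), df2=float(v),
        p_value=p_value, n_subjects=n,
    )


def icc_c1(pairs: PairedMeasurements) -> float:
    """Consistency ICC(C,1) point estimate (cross-check only, no CI)."""
    x = np.column_stack([pairs.clinical_deg, pairs.algorithm_deg])
    msr, _, mse, _, k = _mean_squares(x)
    denom = msr + (k - 1) * mse
    if abs(denom) < 1e-30:
        raise ValueError("zero total variance: ICC undefined")
    return float((msr - mse) / denom)


def bland_altman(
    pairs: PairedMeasurements, loa_multiplier: float = 1.96
) -> BlandAltmanResult:
    """Bias, limits of agreement, and the proportional-bias regression."""
    d = pairs.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    slope = p = None
    if pairs.n >= 4 and np.ptp(pairs.means) > 0:
        slope, p = proportional_bias(pairs)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        loa_multiplier=loa_multiplier,
        prop_slope=slope,
        prop_p=p,
    )


def proportional_bias(pairs: PairedMeasurements) -> tuple[float, float]:
    """OLS slope of differences on pair means, with its two-sided p."""
    if pairs.n < 4:
        raise ValueError(f"need >= 4 subjects, got {pairs.n}")
    m = pairs.means
    if np.ptp(m) == 0:
        raise ValueError("pair means are constant: no regressor variance")
    res = stats.linregress(m, pairs.differences)
    return float(res.slope), float(res.pvalue)


def _spearman_exact_p(a: np.ndarray, b: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 10, midranks)."""
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    n = len(ra)
    count = 0
    total = 0
    rb_c = rb - rb.mean()
    denom_b = math.sqrt(np.sum(rb_c**2))
    for perm in itertools.permutations(range(n)):
        pa = ra[list(perm)]
        pa_c = pa - pa.mean()
        denom_a = math.sqrt(np.sum(pa_c**2))
        r = float(np.dot(pa_c, rb_c) / (denom_a * denom_b))
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def error_vs_covariate(
    pairs: PairedMeasurements,
    covariate: str,
    error_kind: str = "absolute",
    spearman_method: str = "approx",
) -> CovariateErrorResult:
    """Regress measurement error on a covariate (e.g. months since surgery).

    ``error_kind='absolute'`` uses |algorithm − clinical|; ``'signed'``
    keeps the orientation. Spearman p uses the t-approximation with
    midrank ties by default; ``spearman_method='exact'`` enumerates all
    permutations (n ≤ 10 only).
    """
    if covariate not in pairs.covariates:
        raise ValueError(
            f"covariate {covariate!r} not present for subjects {pairs.subjects}"
        )
    cov = pairs.covariates[covariate]
    if np.isnan(cov).any():
        bad = [s for s, v in zip(pairs.subjects, cov) if np.isnan(v)]
        raise ValueError(f"missing covariate values for subjects: {bad}")
    if pairs.n < 4:
        raise ValueError(f"need >= 4 subjects, got {pairs.n}")
    if error_kind == "absolute":
        err = np.abs(pairs.differences)
    elif error_kind == "signed":
        err = pairs.differences
    else:
        raise ValueError("error_kind must be 'absolute' or 'signed'")

    ols = stats.linregress(cov, err)
    rho, rho_p = stats.spearmanr(cov, err)
    if spearman_method == "exact":
        if pairs.n > 10:
            raise ValueError("exact Spearman permutation limited to n <= 10")
        rho_p = _spearman_exact_p(cov, err, float(rho))
    return CovariateErrorResult(
        beta=float(ols.slope),
        beta_p=float(ols.pvalue),
        r_squared=float(ols.rvalue**2),
        rho=float(rho),
        rho_p=float(rho_p),
        error_kind=error_kind,
    )


# ---------------------------------------------------------------------------
# Cohort table

_SURGERY_RE = re.compile(
    r"^\s*(Left and Right|Right and Left|Left|Right|Bilateral)\s+(THA|TKA)\s*$",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class CohortSummary:
    n: int
    numeric: dict[str, dict[str, float]]  # column -> {mean, min, max}
    procedure_counts: dict[str, int]  # THA / TKA patient counts


def parse_surgery_type(cell: str) -> tuple[str, bool]:
    """Return (procedure, bilateral) from a surgery-type cell."""
    m = _SURGERY_RE.match(str(cell))
    if not m:
        raise ValueError(f"unparseable surgery type: {cell!r}")
    side, proc = m.group(1).lower(), m.group(2).upper()
    bilateral = side in ("left and right", "right and left", "bilateral")
    return proc, bilateral


def summarize_cohort(table: pd.DataFrame) -> CohortSummary:
    """Cohort descriptives: n, per-column mean (2 dp)/min/max, procedure counts.

    A bilateral arthroplasty row counts as one patient of its procedure.
    """
    if "surgery_type" not in table.columns:
        raise ValueError("cohort table needs a 'surgery_type' column")
    counts = {"THA": 0, "TKA": 0}
    for cell in table["surgery_type"]:
        proc, _ = parse_surgery_type(cell)
        counts[proc] += 1
    numeric = {}
    for col in table.columns:
        if col == "surgery_type":
            continue
        vals = pd.to_numeric(table[col])
        if (vals <= 0).any():
            raise ValueError(f"non-positive value in numeric column {col!r}")
        numeric[col] = {
            "mean": round(float(vals.mean()), 2),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return CohortSummary(n=len(table), numeric=numeric, procedure_counts=counts)


def plot_bland_altman(
    pairs: PairedMeasurements,
    result: Optional[BlandAltmanResult] = None,
    path: str | Path | None = None,
    title: str = "Bland–Altman",
):
    """Differences-vs-means plot: '×' markers, dashed bias and LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result is None:
        result = bland_altman(pairs)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.plot(pairs.means, pairs.differences, "x", color="k")
    for y, label in (
        (result.bias, f"bias {result.bias:.2f}°"),
        (result.loa_low, f"LoA {result.loa_low:.2f}°"),
        (result.loa_high, f"LoA {result.loa_high:.2f}°"),
    ):
        ax.axhline(y, linestyle="--", color="gray")
        ax.annotate(label, (0.99, y), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=8)
    ax.set_xlabel("mean of methods (deg)")
    ax.set_ylabel("algorithm − clinical (deg)")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
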