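"""Method-agreement statistics for paired per-case index tables.

Implements the three-way comparison conventionally reported when a new
(automated) measurement pipeline is validated against a reference (manual)
one:

* Pearson product-moment correlation,
* single-measures intraclass correlation under the two-way model with
  absolute agreement, ICC(A,1), with its F-based 95% CI
  (McGraw & Wong parameterisation), and
* Bland-Altman analysis of the paired differences d = a - b (reference
  minus automated): bias = mean(d), limits of agreement bias +/- 1.96*sd(d),
  a one-sample t-test of the bias against zero, and 95% CIs for the bias
  (t * s/sqrt(n)) and for each limit (t * sqrt(3/n) * s).

The module-level functions operate on paired vectors; the
:class:`MethodAgreement` model wraps two per-case tables and its
:meth:`~MethodAgreement.fit` returns an :class:`AgreementResults` carrying
one row per index with a ``summary()`` table and CSV export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pearson_r",
    "icc_absolute_agreement",
    "bland_altman",
    "BlandAltmanResult",
    "MethodAgreement",
    "AgreementResults",
    "compare_indices",
]


def _paired(a, b, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values in paired sample")
    if len(a) < min_n:
        raise ValueError(f"need at least {min_n} paired cases, got {len(a)}")
    return a, b


def pearson_r(a, b) -> tuple[float, float]:
    """Pearson correlation with its two-sided p-value."""
    a, b = _paired(a, b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson correlation undefined: zero variance")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def icc_absolute_agreement(a, b) -> tuple[float, float, float, float]:
    """ICC(A,1): single-measures, two-way, absolute agreement, k = 2 raters.

    From the two-way ANOVA mean squares (rows = subjects, columns = raters)

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

    with the 95% CI from the F-based procedure of the McGraw-Wong
    framework and the p-value from F = MSR/MSE on (n-1, (n-1)(k-1)) df.

    Returns ``(icc, ci_lo, ci_hi, p)``.
    """
    a, b = _paired(a, b)
    x = np.column_stack([a, b])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    mse = np.sum(
        (x - row_means[:, None] - col_means[None, :] + grand) ** 2
    ) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("ICC undefined: no variance in the data")
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:
        return float(icc), 1.0, 1.0, 0.0

    alpha = 0.05
    with np.errstate(divide="ignore", invalid="ignore"):
        a_cf = (k * icc) / (n * (1.0 - icc))
        b_cf = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
        v = (a_cf * msc + b_cf * mse) ** 2 / (
            (a_cf * msc) ** 2 / (k - 1)
            + (b_cf * mse) ** 2 / ((n - 1) * (k - 1))
        )
    if not np.isfinite(v):
        lo, hi = icc, icc
    else:
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = (
            n
            * (msr - f_l * mse)
            / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        hi = (
            n
            * (f_u * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        )
    if mse == 0:
        p = 0.0
    else:
        p = float(stats.f.sf(msr / mse, n - 1, (n - 1) * (k - 1)))
    return float(icc), float(lo), float(hi), p


@dataclass
class BlandAltmanResult:
    """Bland-Altman summary for one paired sample (differences a - b)."""

    n: int
    bias: float
    sd_d: float
    bias_ci: tuple[float, float]
    bias_p: float
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(a, b, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman bias, limits of agreement and their 95% CIs.

    The differences are taken reference-minus-automated, ``d = a - b``.
    The LoA use a fixed 1.96 multiplier; the CIs use Student t quantiles:
    bias CI halfwidth ``t * s/sqrt(n)``, LoA CI halfwidth
    ``t * sqrt(3/n) * s``.
    """
    a, b = _paired(a, b)
    d = a - b
    n = len(d)
    bias = float(d.mean())
    s = float(d.std(ddof=1))
    tq = stats.t.ppf(0.975, n - 1)
    hw_bias = tq * s / np.sqrt(n)
    hw_loa = tq * np.sqrt(3.0 / n) * s
    lo = bias - loa_multiplier * s
    hi = bias + loa_multiplier * s
    if s == 0:
        p = np.nan if bias == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd_d=s,
        bias_ci=(bias - hw_bias, bias + hw_bias),
        bias_p=p,
        loa_lower=lo,
        loa_upper=hi,
        loa_lower_ci=(lo - hw_loa, lo + hw_loa),
        loa_upper_ci=(hi - hw_loa, hi + hw_loa),
        means=(a + b) / 2.0,
        diffs=d,
    )


# ---------------------------------------------------------------------------
# model / results objects


class MethodAgreement:
    """Agreement model over two per-case index tables (A = reference/manual,
    B = automated).

    Parameters
    ----------
    table_a, table_b : DataFrame
        Per-case tables sharing a ``case_id`` column and identical index
        columns.  Rows are aligned on ``case_id``; a mismatch raises with
        the offending ids.
    index_columns : list of str, optional
        Index columns to analyse (default: all shared non-id numeric
        columns, in table order).
    min_n : int
        Minimum paired cases required per index (default 3).
    """

    def __init__(
        self,
        table_a: pd.DataFrame,
        table_b: pd.DataFrame,
        index_columns: list[str] | None = None,
        min_n: int = 3,
    ):
        if "case_id" in table_a.columns and "case_id" in table_b.columns:
            ids_a = set(table_a["case_id"])
            ids_b = set(table_b["case_id"])
            if ids_a != ids_b:
                missing = sorted(ids_a ^ ids_b)
                raise ValueError(f"case-id mismatch between tables: {missing}")
            table_a = table_a.set_index("case_id").sort_index()
            table_b = table_b.set_index("case_id").sort_index()
        if index_columns is None:
            index_columns = [
                c
                for c in table_a.columns
                if c in table_b.columns
                and np.issubdtype(table_a[c].dtype, np.number)
            ]
        if not index_columns:
            raise ValueError("no shared numeric index columns to compare")
        self.table_a = table_a
        self.table_b = table_b
        self.index_columns = list(index_columns)
        self.min_n = min_n

    @classmethod
    def from_csv(cls, path_a, path_b, **kwargs) -> "MethodAgreement":
        return cls(pd.read_csv(path_a), pd.read_csv(path_b), **kwargs)

    def fit(self) -> "AgreementResults":
        """Compute r, ICC(A,1) and Bland-Altman statistics per index."""
        rows = {}
        ba = {}
        diagnostics = {}
        for col in self.index_columns:
            a = self.table_a[col].to_numpy(dtype=float)
            b = self.table_b[col].to_numpy(dtype=float)
            ok = ~(np.isnan(a) | np.isnan(b))
            a, b = a[ok], b[ok]
            if len(a) < self.min_n:
                raise ValueError(
                    f"index {col!r}: only {len(a)} complete pairs"
                )
            r, r_p = pearson_r(a, b)
            icc, icc_lo, icc_hi, icc_p = icc_absolute_agreement(a, b)
            res = bland_altman(a, b)
            # Shapiro-Wilk on the differences: diagnostic only, never gating
            sw_p = (
                float(stats.shapiro(res.diffs).pvalue)
                if res.sd_d > 0
                else np.nan
            )
            rows[col] = {
                "index": col,
                "n": len(a),
                "mean_a": a.mean(),
                "sd_a": a.std(ddof=1),
                "mean_b": b.mean(),
                "sd_b": b.std(ddof=1),
                "pearson_r": r,
                "pearson_p": r_p,
                "icc": icc,
                "icc_ci_lo": icc_lo,
                "icc_ci_hi": icc_hi,
                "icc_p": icc_p,
                "bias": res.bias,
                "bias_ci_lo": res.bias_ci[0],
                "bias_ci_hi": res.bias_ci[1],
                "bias_p": res.bias_p,
                "loa_lower": res.loa_lower,
                "loa_lower_ci_lo": res.loa_lower_ci[0],
                "loa_lower_ci_hi": res.loa_lower_ci[1],
                "loa_upper": res.loa_upper,
                "loa_upper_ci_lo": res.loa_upper_ci[0],
                "loa_upper_ci_hi": res.loa_upper_ci[1],
                "shapiro_p": sw_p,
            }
            ba[col] = res
        return AgreementResults(self, rows, ba, diagnostics)


class AgreementResults:
    """Fitted agreement statistics, one row per index."""

    def __init__(self, model, rows, bland_altman_results, diagnostics):
        self.model = model
        self._rows = rows
        self.bland_altman_ = bland_altman_results
        self.diagnostics = diagnostics

    def summary(self) -> pd.DataFrame:
        """Full per-index statistics table."""
        return pd.DataFrame(list(self._rows.values())).set_index("index")

    def agreement_table(self) -> pd.DataFrame:
        """Descriptive means, Pearson r and ICC (CI) per index."""
        s = self.summary()
        return s[
            [
                "n",
                "mean_a",
                "sd_a",
                "mean_b",
                "sd_b",
                "pearson_r",
                "pearson_p",
                "icc",
                "icc_ci_lo",
                "icc_ci_hi",
                "icc_p",
            ]
        ]

    def bland_altman_table(self) -> pd.DataFrame:
        """Bias and limits of agreement (with CIs) per index."""
        s = self.summary()
        return s[
            [
                "n",
                "loa_lower",
                "loa_lower_ci_lo",
                "loa_lower_ci_hi",
                "loa_upper",
                "loa_upper_ci_lo",
                "loa_upper_ci_hi",
                "bias",
                "bias_ci_lo",
                "bias_ci_hi",
                "bias_p",
                "shapiro_p",
            ]
        ]

    def ba_points(self, index: str) -> pd.DataFrame:
        """Per-case (mean, difference) pairs for a Bland-Altman plot."""
        res = self.bland_altman_[index]
        return pd.DataFrame({"mean": res.means, "diff": res.diffs})

    def __getitem__(self, index: str) -> dict:
        return dict(self._rows[index])


def compare_indices(
    table_a: pd.DataFrame, table_b: pd.DataFrame, **kwargs
) -> AgreementResults:
    """One-call agreement analysis of two per-case index tables."""
    return MethodAgreement(table_a, table_b, **kwargs).fit()
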