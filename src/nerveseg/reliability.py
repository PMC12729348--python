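"""Cross-sectional-area extraction and manual-vs-automated agreement.

The clinically meaningful output of nerve segmentation is the
cross-sectional area (CSA) in mm², obtained from a binary mask by counting
foreground pixels (optionally restricted to the largest 4-connected
component, since the nerve is a single structure and stray false-positive
islands would corrupt the area) and scaling by the squared pixel spacing.

Agreement between manual and automated CSA series is quantified the way
method-comparison studies report it:

* paired-difference inference — d = manual − predicted, one-sample t on d
  with a 95% CI for the mean difference;
* Pearson correlation with a Fisher-z 95% CI,
  z = atanh(r) ± 1.96/√(n−3), back-transformed;
* ICC(2,1) — two-way ANOVA, absolute agreement, single rater — with a
  Shrout–Fleiss F-based 95% CI;
* Bland–Altman bias and limits of agreement, bias ± 1.96·SD(d).

The model/results surface: build :class:`CSAAgreement` from paired series
(or a DataFrame), call :meth:`~CSAAgreement.fit`, and read the
:class:`AgreementResults` fields or its :meth:`~AgreementResults.summary`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import label

__all__ = [
    "csa_mm2",
    "PairedDifference",
    "paired_difference_inference",
    "paired_difference_from_summary",
    "pearson_with_fisher_ci",
    "icc_2_1",
    "bland_altman",
    "CSAAgreement",
    "AgreementResults",
]


def csa_mm2(mask: np.ndarray, pixel_spacing: float,
            largest_component_only: bool = True) -> float:
    """Cross-sectional area of a binary mask in mm²."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask must be binary")
        mask = mask.astype(bool)
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be > 0")
    if largest_component_only and mask.any():
        lab, n = label(mask)  # default structure = 4-connectivity
        if n > 1:
            sizes = np.bincount(lab.ravel())[1:]
            mask = lab == (1 + int(np.argmax(sizes)))
    return float(mask.sum()) * pixel_spacing**2


@dataclass(frozen=True)
class PairedDifference:
    """One-sample t inference on paired differences d = manual − predicted."""

    n: int
    mean_diff: float
    sd_diff: float
    t_stat: float  # nan when sd_diff == 0
    df: int
    p_value: float
    ci_low: float
    ci_high: float


def _paired_stats(mean: float, sd: float, n: int) -> PairedDifference:
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    se = sd / math.sqrt(n)
    tcrit = float(stats.t.ppf(0.975, n - 1))
    if sd == 0:
        return PairedDifference(n=n, mean_diff=mean, sd_diff=0.0,
                                t_stat=float("nan"), df=n - 1,
                                p_value=float("nan"), ci_low=mean, ci_high=mean)
    t = mean / se
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return PairedDifference(n=n, mean_diff=mean, sd_diff=sd, t_stat=t, df=n - 1,
                            p_value=p, ci_low=mean - tcrit * se,
                            ci_high=mean + tcrit * se)


def paired_difference_inference(manual, predicted) -> PairedDifference:
    """Paired t-test and 95% CI from the raw CSA series."""
    manual = np.asarray(manual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if manual.shape != predicted.shape:
        raise ValueError("manual and predicted series must have equal length")
    d = manual - predicted
    return _paired_stats(float(d.mean()), float(d.std(ddof=1)), len(d))


def paired_difference_from_summary(mean_diff: float, sd_diff: float,
                                   n: int) -> PairedDifference:
    """Same inference reconstructed from published summary statistics."""
    return _paired_stats(float(mean_diff), float(sd_diff), int(n))


def pearson_with_fisher_ci(x, y) -> tuple[float, float, float]:
    """Pearson r with a Fisher-z 95% confidence interval.

    Requires n >= 4 and nonzero variance in both series. |r| is clamped to
    1 − 1e-12 before atanh so a perfect correlation yields a degenerate
    interval at ±1 rather than an overflow.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has no defined correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    lo, hi = fisher_ci(r, n)
    return r, lo, hi


def fisher_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher-z interval for a correlation given only (r, n)."""
    if n < 4:
        raise ValueError("need n >= 4")
    zcrit = float(stats.norm.ppf(0.5 + conf / 2.0))
    rc = max(min(r, 1 - 1e-12), -1 + 1e-12)
    z = math.atanh(rc)
    half = zcrit / math.sqrt(n - 3)
    return math.tanh(z - half), math.tanh(z + half)


def icc_2_1(ratings: np.ndarray) -> tuple[float, float, float]:
    """ICC(2,1): two-way ANOVA, absolute agreement, single measurement.

    ``ratings`` is an n_subjects x k_raters matrix with no missing cells.
    Returns (icc, ci_low, ci_high) with the Shrout–Fleiss F-based 95% CI
    (Satterthwaite degrees of freedom for the lower/upper bounds).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D matrix")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 subjects and >= 2 raters")
    if not np.isfinite(x).all():
        raise ValueError("missing cells are not supported")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)  # between-subject
    msc = ss_cols / (k - 1)  # between-rater
    mse = ss_err / ((n - 1) * (k - 1))  # residual

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else 1.0

    # Shrout & Fleiss CI for the absolute-agreement single-measure form
    fj = msc / mse if mse > 0 else float("inf")
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else float("inf")
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else float("inf")
    if not (np.isfinite(a) and np.isfinite(b) and np.isfinite(fj)):
        return float(icc), 1.0, 1.0
    v_num = (a * fj + b) ** 2
    v_den = (a**2 * fj**2) / (k - 1) + b**2 / ((n - 1) * (k - 1))
    v = v_num / v_den if v_den > 0 else (n - 1)
    f_low = float(stats.f.ppf(0.975, n - 1, v))
    f_up = float(stats.f.ppf(0.975, v, n - 1))
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return float(icc), float(lower), float(upper)


def bland_altman(x, y):
    """Bland–Altman agreement: bias, limits of agreement, per-pair data.

    Returns ``(bias, loa_low, loa_high, frame)`` where ``frame`` holds the
    per-pair means and differences for plotting. Differences are x − y and
    the limits are bias ± 1.96·sample SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need equal-length series with n >= 2")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    frame = pd.DataFrame({"mean": (x + y) / 2.0, "difference": d})
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, frame


class CSAAgreement:
    """Agreement model for paired manual/automated CSA measurements.

    Parameters
    ----------
    manual, predicted : array-like
        Paired CSA series in mm² (difference direction: manual − predicted).
    """

    def __init__(self, manual, predicted):
        self.manual = np.asarray(manual, dtype=float)
        self.predicted = np.asarray(predicted, dtype=float)
        if self.manual.shape != self.predicted.shape:
            raise ValueError("manual and predicted must have equal length")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       manual_col: str = "manual_csa",
                       predicted_col: str = "predicted_csa") -> "CSAAgreement":
        return cls(frame[manual_col].to_numpy(), frame[predicted_col].to_numpy())

    def fit(self) -> "AgreementResults":
        pdiff = paired_difference_inference(self.manual, self.predicted)
        r, r_lo, r_hi = pearson_with_fisher_ci(self.manual, self.predicted)
        icc, icc_lo, icc_hi = icc_2_1(np.column_stack([self.manual, self.predicted]))
        bias, loa_lo, loa_hi, ba = bland_altman(self.manual, self.predicted)
        return AgreementResults(
            n=pdiff.n, mean_diff=pdiff.mean_diff, sd_diff=pdiff.sd_diff,
            t_stat=pdiff.t_stat, df=pdiff.df, p_value=pdiff.p_value,
            ci_low=pdiff.ci_low, ci_high=pdiff.ci_high,
            pearson_r=r, r_ci_low=r_lo, r_ci_high=r_hi,
            icc21=icc, icc_ci_low=icc_lo, icc_ci_high=icc_hi,
            ba_bias=bias, ba_loa_low=loa_lo, ba_loa_high=loa_hi,
            ba_frame=ba,
        )


@dataclass
class AgreementResults:
    """All agreement statistics for one manual-vs-automated comparison."""

    n: int
    mean_diff: float
    sd_diff: float
    t_stat: float
    df: int
    p_value: float
    ci_low: float
    ci_high: float
    pearson_r: float
    r_ci_low: float
    r_ci_high: float
    icc21: float
    icc_ci_low: float
    icc_ci_high: float
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float
    ba_frame: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("ba_frame")
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [
            "CSA agreement (manual − predicted)",
            "==================================",
            f"n pairs            {self.n}",
            f"mean difference    {self.mean_diff:.3f} ± {self.sd_diff:.3f} mm²",
            f"paired t ({self.df} df)   t = {self.t_stat:.2f}, p = {self.p_value:.4g}",
            f"95% CI of diff     ({self.ci_low:.3f}, {self.ci_high:.3f}) mm²",
            f"Pearson r          {self.pearson_r:.3f} "
            f"(95% CI {self.r_ci_low:.3f}–{self.r_ci_high:.3f})",
            f"ICC(2,1)           {self.icc21:.3f} "
            f"(95% CI {self.icc_ci_low:.3f}–{self.icc_ci_high:.3f})",
            f"Bland–Altman       bias {self.ba_bias:.3f} mm², "
            f"LoA ({self.ba_loa_low:.3f}, {self.ba_loa_high:.3f})",
        ]
        return "\n".join(lines)

    def plot_bland_altman(self, ax=None):
        """Difference-vs-mean scatter with bias and limits of agreement."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.ba_frame
        ax.scatter(f["mean"], f["difference"], s=12, alpha=0.7)
        ax.axhline(self.ba_bias, color="k", lw=1)
        ax.axhline(self.ba_loa_low, color="k", lw=1, ls="--")
        ax.axhline(self.ba_loa_high, color="k", lw=1, ls="--")
        ax.set_xlabel("mean CSA (mm²)")
        ax.set_ylabel("manual − predicted (mm²)")
        return ax
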