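"""Bias of predicted clinical doses against measured clinical doses.

Predicted organ doses from a preclinical model are regressed on the
corresponding measured clinical doses; the slope of that line is the
model's scalar calibration.  The mean percent bias is |1 − slope|·100
(0 for a model sitting on the line of identity).  A model "differs" from
the identity line when 1 lies outside the slope's 95% confidence
interval.  Agreement is additionally summarised Bland–Altman style
(mean difference ± 1.96 SD limits of agreement).

Mass-normalised, FBP-reconstructed models systematically *under*estimate
clinical doses; averaging their biases gives a single correction factor
that can be applied to future predictions (``apply_correction``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import MissingOrganError, ValidationError
from .organs import LLI_WALL


@dataclass(frozen=True)
class FitResult:
    """OLS fit of predicted ~ true: slope, its SEM, r² and slope 95% CI."""

    slope: float
    sem: float
    r2: float
    ci_low: float
    ci_high: float
    intercept: float
    n: int

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


@dataclass(frozen=True)
class BiasReport:
    """One dosimetry model's bias summary (mirrors a regression-table row)."""

    model: str
    fit: FitResult
    lli_included: bool = True

    @property
    def slope(self) -> float:
        return self.fit.slope

    @property
    def mean_percent_bias(self) -> float:
        return mean_percent_bias(self.fit.slope)

    @property
    def differs_from_identity(self) -> bool:
        return identity_line_test(self.fit.slope, self.fit.ci95)


@dataclass(frozen=True)
class AgreementSummary:
    """Bland–Altman agreement: differences vs pair means."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    diffs: pd.Series
    means: pd.Series

    @property
    def loa(self) -> tuple[float, float]:
        return (self.loa_low, self.loa_high)


@dataclass(frozen=True)
class CorrectionFactor:
    """Mean and range of underestimation biases across models."""

    mean_percent: float
    range_percent: tuple[float, float]

    @property
    def rounded_percent(self) -> int:
        return int(round(self.mean_percent))


def _align(predicted, true) -> tuple[pd.Series, pd.Series]:
    p = pd.Series(predicted, dtype=float)
    t = pd.Series(true, dtype=float)
    if isinstance(predicted, (pd.Series, dict)) and isinstance(true, (pd.Series, dict)):
        common = p.index.intersection(t.index)
        p, t = p.reindex(common), t.reindex(common)
    elif len(p) != len(t):
        raise ValidationError("predicted and true dose arrays differ in length")
    return p, t


def fit_prediction_line(
    predicted, true, through_origin: bool = False
) -> FitResult:
    """OLS regression of predicted doses on true doses.

    Series inputs are matched by organ label; arrays by position.  The
    slope 95% CI uses the t distribution with the fit's residual degrees
    of freedom.  An intercept is included by default (only the slope
    feeds the bias summary); ``through_origin`` drops it.
    """
    p, t = _align(predicted, true)
    if len(p) < 3:
        raise ValidationError(f"need ≥ 3 matched dose pairs, got {len(p)}")
    if np.ptp(t.to_numpy()) == 0:
        raise ValidationError("zero variance in true doses")
    X = t.to_numpy()[:, None] if through_origin else sm.add_constant(t.to_numpy())
    res = sm.OLS(p.to_numpy(), X).fit()
    ci = res.conf_int(alpha=0.05)
    return FitResult(
        slope=float(res.params[-1]),
        sem=float(res.bse[-1]),
        r2=float(res.rsquared),
        ci_low=float(ci[-1][0]),
        ci_high=float(ci[-1][1]),
        intercept=0.0 if through_origin else float(res.params[0]),
        n=int(res.nobs),
    )


def mean_percent_bias(slope: float) -> float:
    """|1 − slope| · 100."""
    if not np.isfinite(slope):
        raise ValidationError("slope must be finite")
    return abs(1.0 - slope) * 100.0


def identity_line_test(slope: float, ci95: tuple[float, float]) -> bool:
    """True iff the model differs from the line of identity, i.e. 1 lies
    outside the inclusive 95% CI of the slope."""
    low, high = ci95
    if not (low <= slope <= high):
        raise ValidationError(f"slope {slope} outside its own CI ({low}, {high})")
    return not (low <= 1.0 <= high)


def bias_report(
    predicted, true, model: str = "", through_origin: bool = False,
    lli_included: bool = True,
) -> BiasReport:
    fit = fit_prediction_line(predicted, true, through_origin=through_origin)
    return BiasReport(model=model, fit=fit, lli_included=lli_included)


def bland_altman(predicted, true) -> AgreementSummary:
    """Bland–Altman agreement of predicted vs true doses.

    Differences predicted − true against pair means; limits of agreement
    at mean ± 1.96 SD (SD with n−1 denominator)."""
    p, t = _align(predicted, true)
    if len(p) < 2:
        raise ValidationError("need ≥ 2 matched pairs")
    diffs = p - t
    means = (p + t) / 2.0
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementSummary(
        mean_diff=mean_diff,
        sd_diff=sd,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        diffs=diffs,
        means=means,
    )


@dataclass(frozen=True)
class LLISensitivity:
    bias_with: float
    bias_without: float

    @property
    def improvement_ratio(self) -> float:
        return self.bias_with / self.bias_without


def lli_sensitivity(
    predicted, true, lli_label: str = LLI_WALL, through_origin: bool = False
) -> LLISensitivity:
    """Bias with and without the LLI wall pair.

    Rat and human lower gastrointestinal anatomy differ (rats lack a
    gallbladder), so the LLI wall often behaves as an outlier;
    ``improvement_ratio`` > 1 means excluding it tightened the bias.
    """
    p, t = _align(predicted, true)
    if lli_label not in p.index:
        raise MissingOrganError(f"{lli_label!r} not among the dose pairs")
    with_lli = fit_prediction_line(p, t, through_origin=through_origin)
    without = fit_prediction_line(
        p.drop(lli_label), t.drop(lli_label), through_origin=through_origin
    )
    return LLISensitivity(
        bias_with=mean_percent_bias(with_lli.slope),
        bias_without=mean_percent_bias(without.slope),
    )


def correction_factor(reports) -> CorrectionFactor:
    """Mean and range of mean-percent-biases across bias reports.

    Intended for the normalised + FBP model family (the systematically
    underestimating one); mixing other model types only warns, since the
    check relies on free-text model descriptors.
    """
    reports = list(reports)
    if not reports:
        raise ValidationError("no bias reports given")
    for r in reports:
        desc = r.model.lower()
        if "iterative" in desc or "non-norm" in desc:
            warnings.warn(
                f"correction factor expects normalised-FBP models, got {r.model!r}",
                stacklevel=2,
            )
    biases = [r.mean_percent_bias for r in reports]
    return CorrectionFactor(
        mean_percent=float(np.mean(biases)),
        range_percent=(float(min(biases)), float(max(biases))),
    )


def apply_correction(
    predicted, slope: float | None = None, bias_percent: float | None = None
) -> pd.Series:
    """Map predicted doses onto the line of identity.

    With ``slope``: corrected = predicted / slope.  With
    ``bias_percent`` (simplified mode, underestimating models):
    corrected = predicted / (1 − bias/100).
    """
    p = pd.Series(predicted, dtype=float)
    if (slope is None) == (bias_percent is None):
        raise ValidationError("give exactly one of slope or bias_percent")
    if slope is not None:
        if slope <= 0:
            raise ValidationError("slope must be positive")
        return p / slope
    if bias_percent >= 100:
        raise ValidationError("simplified correction undefined for bias ≥ 100%")
    return p / (1.0 - bias_percent / 100.0)


@dataclass(frozen=True)
class ReconComparison:
    """Iterative vs FBP residence-time relation across organ/subject pairs."""

    fit: FitResult
    mean_ratio: float
    n: int


def compare_reconstructions(
    tau_fbp, tau_iterative, through_origin: bool = False
) -> ReconComparison:
    """Regress iterative τ on FBP τ over matched organ/subject pairs."""
    it, fbp = _align(tau_iterative, tau_fbp)
    if (fbp <= 0).any():
        raise ValidationError("FBP τ must be positive to form ratios")
    fit = fit_prediction_line(
        it.to_numpy(), fbp.to_numpy(), through_origin=through_origin
    )
    return ReconComparison(
        fit=fit,
        mean_ratio=float((it.to_numpy() / fbp.to_numpy()).mean()),
        n=len(fbp),
    )


# ------------------------------------------------------------ simple plots


def bland_altman_plot(summary: AgreementSummary, path, title: str = "") -> None:
    """Write a minimal Bland–Altman figure to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(summary.means, summary.diffs, s=18)
    for y, style in ((summary.mean_diff, "-"), (summary.loa_low, "--"),
                     (summary.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="grey")
    ax.set_xlabel("mean of predicted and measured dose (mGy/MBq)")
    ax.set_ylabel("predicted − measured (mGy/MBq)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def regression_plot(predicted, true, fit: FitResult, path, title: str = "") -> None:
    """Write a predicted-vs-true scatter with the fitted line and identity."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p, t = _align(predicted, true)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(t, p, s=18)
    xs = np.linspace(0, float(t.max()) * 1.05, 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, label=f"fit (slope {fit.slope:.3g})")
    ax.plot(xs, xs, "--", color="grey", label="identity")
    ax.set_xlabel("measured clinical dose (mGy/MBq)")
    ax.set_ylabel("predicted dose (mGy/MBq)")
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
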