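"""Model comparison and cohort-level statistics.

Per-participant negative log-likelihoods become BIC values (2*NLL + k*ln n,
with k = 2 free parameters and n the number of free decisions).  Models are
compared two ways: Bayesian and frequentist paired tests on mean BIC, and
counts of participants best fitted by each model.  Sampling-bias reports
compare participant sampling rates against the Ideal Observer using default
(JZS) Bayes-factor t-tests with a Cauchy prior on effect size, at scales
0.5, 0.71 = sqrt(2)/2 and 1, alongside Bonferroni-corrected frequentist
t-tests; equivalence is concluded at BF01 > 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

#: Default Cauchy scale on effect size: sqrt(2)/2, to two decimals.
DEFAULT_CAUCHY_SCALE = round(np.sqrt(2.0) / 2.0, 2)

#: Sensitivity scales reported alongside the default.
CAUCHY_SCALES = (0.5, DEFAULT_CAUCHY_SCALE, 1.0)

#: Moderate-evidence threshold used for equivalence / difference calls.
EVIDENCE_THRESHOLD = 3.0


def bic(nll: float, k: int = 2, n: int | None = None) -> float:
    """Bayesian information criterion: 2*NLL + k*ln(n); lower is better."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if n is None or n < 1:
        raise ValueError("n (number of free decisions) must be at least 1")
    return 2.0 * float(nll) + k * np.log(n)


def _t_stat(diffs: np.ndarray) -> tuple[float, int]:
    n = diffs.size
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero-variance differences")
    return float(diffs.mean() / (sd / np.sqrt(n))), n


def jzs_bayes_factor(
    x=None,
    *,
    t: float | None = None,
    n: int | None = None,
    scale: float = DEFAULT_CAUCHY_SCALE,
) -> tuple[float, float]:
    """One-sample / paired JZS Bayes factor (BF10, BF01).

    Pass either a sample of paired differences ``x`` or a t statistic with its
    sample size.  The alternative places a Cauchy prior with the given scale
    on the standardised effect size; the Bayes factor is the ratio of marginal
    likelihoods, computed by numerical integration over the variance-ratio
    parameter g (which carries an inverse-gamma(1/2, scale^2/2) prior).
    """
    if scale <= 0:
        raise ValueError("Cauchy scale must be positive")
    if x is not None:
        diffs = np.asarray(x, dtype=float)
        if diffs.size < 2:
            raise ValueError("need at least two paired observations")
        t, n = _t_stat(diffs)
    elif t is None or n is None:
        raise ValueError("provide either differences or (t, n)")
    if n < 2:
        raise ValueError("need n >= 2")

    nu = n - 1
    t2 = float(t) ** 2
    g_prior = stats.invgamma(0.5, scale=scale**2 / 2.0)

    def integrand(g: float) -> float:
        shrink = 1.0 + n * g
        return (
            shrink**-0.5
            * (1.0 + t2 / (shrink * nu)) ** (-(nu + 1) / 2.0)
            * g_prior.pdf(g)
        )

    marginal_alt, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    marginal_null = (1.0 + t2 / nu) ** (-(nu + 1) / 2.0)
    bf10 = marginal_alt / marginal_null
    return float(bf10), float(1.0 / bf10)


@dataclass(frozen=True)
class TestResult:
    """Two-tailed t-test with Bonferroni-adjusted p and confidence interval."""

    t: float
    df: int
    p: float
    p_adj: float
    cohens_d: float
    ci_low: float
    ci_high: float
    n_comparisons: int
    paired: bool


def paired_frequentist(x, y=None, n_comparisons: int = 1, paired: bool = True) -> TestResult:
    """Two-tailed t-test (paired by default) with Bonferroni correction.

    ``x`` may be paired differences (y omitted) or the first sample.  The
    confidence interval on the (mean) difference is computed at level
    1 - 0.05/n_comparisons.  Cohen's d is mean(diff)/sd(diff) for paired
    designs and uses the pooled SD for independent samples.
    """
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be at least 1")
    x = np.asarray(x, dtype=float)
    if paired:
        diffs = x if y is None else x - np.asarray(y, dtype=float)
        tval, n = _t_stat(diffs)
        df = n - 1
        d = float(diffs.mean() / diffs.std(ddof=1))
        se = diffs.std(ddof=1) / np.sqrt(n)
        centre = diffs.mean()
    else:
        if y is None:
            raise ValueError("independent-samples test needs both samples")
        y = np.asarray(y, dtype=float)
        res = stats.ttest_ind(x, y)
        tval = float(res.statistic)
        n1, n2 = x.size, y.size
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
        if sp2 == 0:
            raise ZeroDivisionError("zero-variance samples")
        d = float((x.mean() - y.mean()) / np.sqrt(sp2))
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        centre = x.mean() - y.mean()
    p = float(2.0 * stats.t.sf(abs(tval), df))
    p_adj = min(1.0, p * n_comparisons)
    alpha = 0.05 / n_comparisons
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return TestResult(
        t=tval,
        df=int(df),
        p=p,
        p_adj=p_adj,
        cohens_d=d,
        ci_low=float(centre - crit * se),
        ci_high=float(centre + crit * se),
        n_comparisons=n_comparisons,
        paired=paired,
    )


def best_fit_counts(bic_table: pd.DataFrame) -> pd.Series:
    """Participants best fitted (lowest BIC) per model; ties split equally.

    ``bic_table``: participants as rows, model variants as columns.
    """
    if bic_table.isna().any().any():
        raise ValueError("BIC table has missing cells")
    counts = pd.Series(0.0, index=bic_table.columns)
    for _, row in bic_table.iterrows():
        winners = row.index[row == row.min()]
        if len(winners) > 1:
            warnings.warn("BIC tie split equally between models", stacklevel=2)
        counts[winners] += 1.0 / len(winners)
    return counts


def compare_models(fits: pd.DataFrame, scales=CAUCHY_SCALES) -> pd.DataFrame:
    """Pairwise mean-BIC comparisons between fitted model variants.

    ``fits`` needs columns participant_id, model (optionally value_kind) and
    bic.  Returns one row per model pair with JZS Bayes factors at each Cauchy
    scale, the frequentist t-test (Bonferroni corrected for the number of
    pairs) and Cohen's d.
    """
    label_cols = ["model"] + (["value_kind"] if "value_kind" in fits else [])
    labelled = fits.assign(
        label=fits[label_cols].astype(str).agg(" ".join, axis=1)
    )
    table = labelled.pivot(index="participant_id", columns="label", values="bic")
    labels = list(table.columns)
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    rows = []
    for a, b in pairs:
        diffs = (table[a] - table[b]).to_numpy()
        test = paired_frequentist(diffs, n_comparisons=max(1, len(pairs)))
        row = {"model1": a, "model2": b, "n": diffs.size}
        for r in scales:
            bf10, _ = jzs_bayes_factor(diffs, scale=r)
            row[f"bf10_r{r}"] = bf10
        row.update(
            t=test.t, df=test.df, p_adj=test.p_adj, cohens_d=test.cohens_d,
            ci_low=test.ci_low, ci_high=test.ci_high,
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BiasReport:
    """Cohort sampling compared against an Ideal Observer benchmark."""

    mean_participant_samples: float
    mean_ideal_samples: float
    mean_difference: float
    bf10: dict = field(default_factory=dict)  # per Cauchy scale
    bf01: dict = field(default_factory=dict)
    test: TestResult | None = None
    classification: str = "degenerate"


def cohort_bias_report(
    participant_samples,
    ideal_samples,
    scales=CAUCHY_SCALES,
    n_comparisons: int = 1,
) -> BiasReport:
    """Classify a cohort as undersampling / equivalent / oversampling.

    Inputs are per-participant mean samples-to-decision under matched designs
    (paired).  Equivalence is concluded at BF01 > 3 (default scale); a
    difference at BF10 > 3 is labelled under- or oversampling by its sign;
    anything else is inconclusive.  Zero-variance differences are flagged
    as degenerate rather than tested.
    """
    x = np.asarray(participant_samples, dtype=float)
    y = np.asarray(ideal_samples, dtype=float)
    if x.shape != y.shape:
        raise ValueError("participant and ideal samples must be paired")
    diffs = x - y
    report = BiasReport(
        mean_participant_samples=float(x.mean()),
        mean_ideal_samples=float(y.mean()),
        mean_difference=float(diffs.mean()),
    )
    if diffs.std(ddof=1) == 0:
        return report  # degenerate: no variability to test
    for r in scales:
        bf10, bf01 = jzs_bayes_factor(diffs, scale=r)
        report.bf10[r] = bf10
        report.bf01[r] = bf01
    report.test = paired_frequentist(diffs, n_comparisons=n_comparisons)
    key = DEFAULT_CAUCHY_SCALE if DEFAULT_CAUCHY_SCALE in report.bf10 else next(iter(report.bf10))
    bf10 = report.bf10[key]
    bf01 = report.bf01[key]
    if bf01 > EVIDENCE_THRESHOLD:
        report.classification = "equivalent"
    elif bf10 > EVIDENCE_THRESHOLD:
        report.classification = (
            "undersampling" if report.mean_difference < 0 else "oversampling"
        )
    else:
        report.classification = "inconclusive"
    return report
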