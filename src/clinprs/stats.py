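"""Validation statistics: 2x2 odds ratios with Woolf confidence intervals,
quantile log-odds association curves, paired dichotomous concordance
(agreement and Matthews correlation coefficient), and variant-site
sensitivity/PPV against a truth set."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import VariantKey


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a = high-PRS cases, b = high-PRS controls,
    c = other cases, d = other controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("table must contain at least one observation")


@dataclass(frozen=True)
class OddsRatioResult:
    oddsratio: float  # 0.0 or inf in degenerate zero-cell tables
    ci_low: float  # NaN when degenerate
    ci_high: float  # NaN when degenerate
    alpha: float
    degenerate: bool


def odds_ratio_ci(t: ContingencyTable, alpha: float = 0.05) -> OddsRatioResult:
    """Cross-product odds ratio with the Woolf (log-scale) confidence
    interval exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).

    Any zero cell makes the interval undefined; the point estimate is then
    reported as 0 (zero numerator) or infinity (zero denominator), matching
    the degenerate display convention of published tables.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        num_zero = a == 0 or d == 0
        den_zero = b == 0 or c == 0
        if num_zero and den_zero:
            or_ = math.nan
        elif num_zero:
            or_ = 0.0
        else:
            or_ = math.inf
        return OddsRatioResult(oddsratio=or_, ci_low=math.nan,
                               ci_high=math.nan, alpha=alpha, degenerate=True)
    or_ = (a * d) / (b * c)
    z = sps.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return OddsRatioResult(
        oddsratio=or_,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        alpha=alpha,
        degenerate=False,
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding (half away from zero), as used in printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class QuantileCurve:
    """Per-quantile mean score and log-odds of disease, with Pearson r over
    the non-degenerate quantiles."""

    mean_score: np.ndarray
    log_odds: np.ndarray
    n_cases: np.ndarray
    n_controls: np.ndarray
    kept: np.ndarray  # False where a bin had zero cases or zero controls
    n_quantiles: int
    pearson_r: float


def quantile_log_odds(scores: np.ndarray, labels: np.ndarray,
                      n_quantiles: int = 50) -> QuantileCurve:
    """Bin samples into rank-based equal-count score quantiles and compute
    log(n_cases / n_controls) per bin.

    Bin sizes differ by at most one; ties are broken by stable input order
    after sorting by score, so results are deterministic. Bins with zero
    cases or zero controls have undefined log-odds: they are flagged,
    excluded from the correlation, and reported with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if n_quantiles < 2:
        raise ValueError("need at least 2 quantiles")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    order = np.argsort(scores, kind="stable")
    bins = np.array_split(order, n_quantiles)

    mean_score = np.empty(n_quantiles)
    n_cases = np.empty(n_quantiles, dtype=int)
    n_controls = np.empty(n_quantiles, dtype=int)
    for i, idx in enumerate(bins):
        mean_score[i] = scores[idx].mean() if idx.size else math.nan
        n_cases[i] = int(labels[idx].sum())
        n_controls[i] = int(idx.size - labels[idx].sum())
    kept = (n_cases > 0) & (n_controls > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_odds = np.where(kept, np.log(n_cases / np.maximum(n_controls, 1)),
                            math.nan)
    if not np.any(kept) or kept.sum() < 2:
        raise ValueError(
            "all (or all but one) quantiles are degenerate; cannot correlate"
        )
    if not np.all(kept):
        warnings.warn(
            f"{int((~kept).sum())} of {n_quantiles} quantiles have zero cases "
            "or zero controls; excluded from the correlation"
        )
    r = float(sps.pearsonr(mean_score[kept], log_odds[kept]).statistic)
    return QuantileCurve(mean_score=mean_score, log_odds=log_odds,
                         n_cases=n_cases, n_controls=n_controls, kept=kept,
                         n_quantiles=n_quantiles, pearson_r=r)


@dataclass(frozen=True)
class ConcordanceResult:
    n_pairs: int
    n_concordant: int
    agreement: float
    mcc: float  # NaN when any marginal is zero
    mcc_defined: bool


def concordance(pairs: Iterable[tuple[bool, bool]]) -> ConcordanceResult:
    """Agreement fraction and Matthews correlation coefficient for paired
    dichotomous classifications (e.g. array-based vs sequencing-based
    high-risk calls)."""
    pairs = [(bool(x), bool(y)) for x, y in pairs]
    if not pairs:
        raise ValueError("need at least one pair")
    tp = sum(1 for x, y in pairs if x and y)
    tn = sum(1 for x, y in pairs if not x and not y)
    fp = sum(1 for x, y in pairs if x and not y)
    fn = sum(1 for x, y in pairs if not x and y)
    n = len(pairs)
    n_conc = tp + tn
    denom = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    if denom == 0:
        mcc, defined = math.nan, False
    else:
        mcc, defined = (tp * tn - fp * fn) / denom, True
    return ConcordanceResult(n_pairs=n, n_concordant=n_conc,
                             agreement=n_conc / n, mcc=mcc, mcc_defined=defined)


@dataclass(frozen=True)
class SiteConcordance:
    tp: int
    fp: int
    fn: int
    sensitivity: float  # NaN when no truth sites
    ppv: float  # NaN when no called sites


def _in_regions(key: VariantKey, regions: Sequence[tuple[str, int, int]]) -> bool:
    chrom, pos = key[0], key[1]
    # BED half-open 0-based intervals; VCF pos is 1-based.
    return any(c == chrom and start <= pos - 1 < end for c, start, end in regions)


def site_concordance(calls: Iterable[VariantKey], truth: Iterable[VariantKey],
                     regions: Sequence[tuple[str, int, int]] | None = None
                     ) -> SiteConcordance:
    """Sensitivity and PPV for presence/absence of variant sites versus a
    truth set, optionally restricted to benchmarking regions (BED-style
    half-open intervals)."""
    calls, truth = set(calls), set(truth)
    if regions is not None:
        calls = {k for k in calls if _in_regions(k, regions)}
        truth = {k for k in truth if _in_regions(k, regions)}
    tp = len(calls & truth)
    fp = len(calls - truth)
    fn = len(truth - calls)
    sens = tp / (tp + fn) if tp + fn else math.nan
    ppv = tp / (tp + fp) if tp + fp else math.nan
    return SiteConcordance(tp=tp, fp=fp, fn=fn, sensitivity=sens, ppv=ppv)


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read chrom/start/end from a BED file (half-open, 0-based)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    return [(r.chrom, int(r.start), int(r.end)) for r in df.itertuples(index=False)]
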