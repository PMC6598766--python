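"""Dose-response and plate statistics.

SSMD effect sizes for screen group comparisons, a maximum-likelihood
logistic (or probit) LD50 model with profile-likelihood confidence
intervals, per-concentration ordinal score tables, and the ear-width
normalisation used for the swelling phenotype.

The LD50 fit follows the model/results convention: build a
``DoseResponseModel`` from survival counts, call ``fit()``, and read the
estimate, CI and ``summary()`` off the returned ``DoseResponseFit``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupStats:
    """Mean, standard deviation and size of one comparison group."""

    mu: float
    sigma: float
    n: int

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n < 1:
            raise ValueError("n must be at least 1")

    @classmethod
    def from_scores(cls, scores, ddof: int = 1) -> "GroupStats":
        a = np.asarray(scores, dtype=float)
        sd = float(a.std(ddof=ddof)) if a.size > ddof else 0.0
        return cls(mu=float(a.mean()), sigma=sd, n=a.size)


@dataclass(frozen=True)
class SSMDResult:
    beta: float


def ssmd(g1: GroupStats, g2: GroupStats) -> SSMDResult:
    """Strictly standardised mean difference beta = (mu1-mu2)/sqrt(s1^2+s2^2).

    With both SDs zero the denominator vanishes: equal means give 0,
    unequal means a signed-infinity sentinel (with a warning) so callers
    can still rank.
    """
    denom = math.sqrt(g1.sigma**2 + g2.sigma**2)
    diff = g1.mu - g2.mu
    if denom == 0.0:
        if diff == 0.0:
            return SSMDResult(0.0)
        logger.warning("SSMD with zero variance in both groups; returning inf")
        return SSMDResult(math.copysign(math.inf, diff))
    return SSMDResult(diff / denom)


@dataclass
class DoseResponseSeries:
    """Concentration-indexed scores and survival for one compound.

    Each concentration carries per-embryo ordinal intensity scores (0-3),
    per-embryo projection counts (0-3 stained projections), an optional
    ear-width ratio, and survival counts (n_total, n_dead). Designed for
    a 1.5-fold dilution series.
    """

    compound_id: str
    concentrations: np.ndarray
    intensity_scores: list[list[int]] = field(default_factory=list)
    projection_scores: list[list[int]] = field(default_factory=list)
    ear_width_ratio: list[float | None] = field(default_factory=list)
    survival: list[tuple[int, int]] = field(default_factory=list)  # (n_total, n_dead)

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        for n_total, n_dead in self.survival:
            if n_dead > n_total:
                raise ValueError("n_dead exceeds n_total")


class NonIdentifiableError(ValueError):
    """Raised when mortality never leaves {0%, 100%} asymmetrically enough
    for the LD50 to be located."""


@dataclass
class DoseResponseFit:
    """Fitted LD50 results: point estimate, slope, profile-likelihood CI."""

    ld50: float
    slope: float
    ci_low: float
    ci_high: float
    method: str
    loglik: float
    n_per_concentration: list[int]

    def summary(self) -> str:
        return (
            f"LD50 fit ({self.method}, log10 concentration)\n"
            f"  LD50:   {self.ld50:.3g} uM  (95% profile CI {self.ci_low:.3g}"
            f" - {self.ci_high:.3g})\n"
            f"  slope:  {self.slope:.3g} per log10 unit\n"
            f"  loglik: {self.loglik:.4f}\n"
            f"  n/conc: {self.n_per_concentration}"
        )


class DoseResponseModel:
    """Two-parameter sigmoid mortality model on log10 concentration.

    P(death | c) = F(slope * (log10 c - m)) with F the logistic (default)
    or probit link; LD50 = 10**m. Deaths at each concentration are
    binomial. ``fit`` maximises the likelihood and derives a 95%
    profile-likelihood interval for the LD50.
    """

    MAX_SLOPE = 100.0

    def __init__(self, concentrations, n_total, n_dead, method: str = "logistic"):
        self.x = np.log10(np.asarray(concentrations, dtype=float))
        self.n = np.asarray(n_total, dtype=float)
        self.d = np.asarray(n_dead, dtype=float)
        if np.any(self.d > self.n) or np.any(self.d < 0):
            raise ValueError("invalid death counts")
        if method not in ("logistic", "probit"):
            raise ValueError("method must be 'logistic' or 'probit'")
        self.method = method

    @classmethod
    def from_series(cls, series: DoseResponseSeries, method: str = "logistic"):
        n_total = [s[0] for s in series.survival]
        n_dead = [s[1] for s in series.survival]
        return cls(series.concentrations, n_total, n_dead, method=method)

    def _cdf(self, z):
        if self.method == "logistic":
            return sps.logistic.cdf(z)
        return sps.norm.cdf(z)

    def _nll(self, m: float, slope: float) -> float:
        p = np.clip(self._cdf(slope * (self.x - m)), 1e-12, 1 - 1e-12)
        return float(-np.sum(self.d * np.log(p) + (self.n - self.d) * np.log(1 - p)))

    def _profile_nll(self, m: float) -> float:
        res = optimize.minimize_scalar(
            lambda s: self._nll(m, s), bounds=(1e-3, self.MAX_SLOPE), method="bounded"
        )
        return float(res.fun)

    def fit(self) -> DoseResponseFit:
        frac = self.d / self.n
        if np.all(frac == 0) or np.all(frac == 1):
            raise NonIdentifiableError(
                "mortality is constant at 0% or 100%; LD50 not identifiable"
            )
        lo, hi = self.x.min() - 2.0, self.x.max() + 2.0
        # scan the profile likelihood in m, polish the minimum, then read
        # the 95% interval off the same profile (chi-square 1 df cutoff)
        grid = np.linspace(lo, hi, 81)
        prof = np.array([self._profile_nll(m) for m in grid])
        k = int(np.argmin(prof))
        res = optimize.minimize_scalar(
            self._profile_nll,
            bounds=(grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]),
            method="bounded",
        )
        m_hat = float(res.x)
        nll_hat = min(float(res.fun), float(prof[k]))
        slope_hat = float(
            optimize.minimize_scalar(
                lambda s: self._nll(m_hat, s),
                bounds=(1e-3, self.MAX_SLOPE),
                method="bounded",
            ).x
        )
        cutoff = nll_hat + sps.chi2.ppf(0.95, df=1) / 2.0

        def above(m):
            return self._profile_nll(m) - cutoff

        ci_lo, ci_hi = lo, hi
        below = prof <= cutoff
        idx = np.flatnonzero(below)
        if idx.size == 0:
            # profile narrower than the grid spacing: bracket around m_hat
            step = grid[1] - grid[0]
            return DoseResponseFit(
                ld50=float(10**m_hat),
                slope=slope_hat,
                ci_low=float(10 ** (m_hat - step)),
                ci_high=float(10 ** (m_hat + step)),
                method=self.method,
                loglik=-nll_hat,
                n_per_concentration=[int(v) for v in self.n],
            )
        left, right = grid[idx[0]], grid[idx[-1]]
        if idx[0] > 0:
            ci_lo = optimize.brentq(above, grid[idx[0] - 1], left, xtol=1e-4)
        if idx[-1] < len(grid) - 1:
            ci_hi = optimize.brentq(above, right, grid[idx[-1] + 1], xtol=1e-4)
        return DoseResponseFit(
            ld50=float(10**m_hat),
            slope=float(slope_hat),
            ci_low=float(10**ci_lo),
            ci_high=float(10**ci_hi),
            method=self.method,
            loglik=-nll_hat,
            n_per_concentration=[int(v) for v in self.n],
        )


def fit_ld50(series: DoseResponseSeries, method: str = "logistic") -> DoseResponseFit:
    """Fit the LD50 model to a dose-response series (see DoseResponseModel)."""
    return DoseResponseModel.from_series(series, method=method).fit()


def dose_response_table(series: DoseResponseSeries) -> dict:
    """Per-concentration contingency counts of ordinal scores.

    Returns two DataFrames (intensity scores 0-3 and stained-projection
    counts 0p-3p, rows indexed by concentration) plus a Spearman summary
    of mean intensity against concentration. Dead embryos carry no
    scores by construction and appear only in the survival counts.
    """
    conc = series.concentrations
    intensity = pd.DataFrame(
        [
            [scores.count(k) for k in range(4)]
            for scores in series.intensity_scores
        ],
        index=pd.Index(conc, name="concentration_uM"),
        columns=[str(k) for k in range(4)],
    )
    projections = pd.DataFrame(
        [
            [scores.count(k) for k in range(4)]
            for scores in series.projection_scores
        ],
        index=pd.Index(conc, name="concentration_uM"),
        columns=[f"{k}p" for k in range(4)],
    )
    means = [np.mean(s) if s else np.nan for s in series.intensity_scores]
    ok = ~np.isnan(means)
    if ok.sum() >= 3 and np.ptp(np.asarray(means)[ok]) > 0:
        rho, pval = sps.spearmanr(conc[ok], np.asarray(means)[ok])
    else:
        rho, pval = np.nan, np.nan
    return {
        "intensity": intensity,
        "projections": projections,
        "spearman_rho": float(rho) if rho == rho else np.nan,
        "spearman_p": float(pval) if pval == pval else np.nan,
    }


def normalize_ear_width(ear_to_ear_width: float, head_width: float) -> float:
    """Ear-to-ear width as a plain ratio to head width (both um, both > 0)."""
    if ear_to_ear_width <= 0 or head_width <= 0:
        raise ValueError("widths must be positive")
    return ear_to_ear_width / head_width


def dilution_series(top: float, n: int, factor: float = 1.5) -> np.ndarray:
    """n concentrations ending at `top`, descending by `factor` (ascending order)."""
    return top / factor ** np.arange(n - 1, -1, -1, dtype=float)
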