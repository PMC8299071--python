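"""JZS Bayes-factor paired comparisons and posterior effect sizes.

Paired condition contrasts reduce to a one-sample design on the
per-participant differences.  Under the null the standardized effect
delta = mu / sigma is zero; under the alternative delta follows a Cauchy
prior with scale ``r`` (default 1, the study's wide prior), with the
Jeffreys prior on the variance.  The marginal likelihood of the observed t
statistic under H1 is then the noncentral-t density integrated against the
Cauchy prior — the standard default ("JZS") Bayes-factor construction:

    BF10 = Integral nct(t; nu, delta*sqrt(n)) pi_r(delta) d delta
           -----------------------------------------------------
                          t(t; nu)

Directed hypotheses use the half-Cauchy (prior mass folded onto one
half-line).  Posterior summaries of delta (mean, central 95% credible
interval) come from the same model on an adaptively refined grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import gammaln

from .errors import DegenerateDataError
from .io import COMPARISON_COLUMNS

logger = logging.getLogger(__name__)

DIRECTIONS = ("two_sided", "greater", "less")

#: Default comparison plan: fatigue contrast (undirected), then the directed
#: demand ladder.  Directions are phrased for the mean channel (A - B > 0:
#: more demanding condition shows the higher value); the diff channel flips
#: them because lower between-eye difference is expected under load.
DEFAULT_PLAN = (
    ("fix2", "fix1", "two_sided"),
    ("a", "fix1", "greater"),
    ("a", "fix2", "greater"),
    ("b", "a", "greater"),
    ("c", "b", "greater"),
    ("d", "c", "greater"),
    ("e", "d", "greater"),
    ("f", "e", "greater"),
)

_FLIP = {"greater": "less", "less": "greater", "two_sided": "two_sided"}

EVIDENCE_CATEGORIES = (
    "anecdotal_H1", "moderate_H1", "strong_H1", "very_strong_H1",
    "extreme_H1",
    "anecdotal_H0", "moderate_H0", "strong_H0", "very_strong_H0",
    "extreme_H0",
)


@dataclass(frozen=True)
class BayesResult:
    """One pairwise condition contrast."""

    pair: tuple[str, str]
    channel: str
    standardized: bool
    direction: str
    n: int
    t_stat: float
    bf10: float
    es_mean: float
    es_ci: tuple[float, float]
    evidence: str


def paired_t(differences: Sequence[float]) -> tuple[float, int]:
    """Paired t statistic and n from per-participant differences."""
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    n = len(d)
    if n < 2:
        raise DegenerateDataError(f"need >= 2 paired differences, got {n}")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("degenerate t: zero variance in differences")
    return float(d.mean() / (sd / math.sqrt(n))), n


_LOG_2PI = math.log(2.0 * math.pi)


@lru_cache(maxsize=64)
def _s_grid(df: int) -> np.ndarray:
    """Linear grid covering the bulk of s = sqrt(V/df), V ~ chi-square(df).

    The noncentral-t likelihood is the expectation of s*phi(s*t - nc) under
    this scale-mixture variable; a grid spanning its 1e-10..1-1e-12
    quantiles resolves every feature when the Gaussian factor is the wider
    of the two.
    """
    lo = stats.chi.ppf(1e-10, df) / math.sqrt(df)
    hi = stats.chi.ppf(1.0 - 1e-12, df) / math.sqrt(df)
    # the grid only has to resolve the chi bulk itself (the Gaussian factor
    # is wider whenever this branch is used), so ~40 points per sd suffice
    s = np.linspace(lo, hi, 601)
    w = np.full(s.shape, s[1] - s[0])
    w[0] = w[-1] = 0.5 * (s[1] - s[0])          # trapezoid weights
    return s, np.log(s) + _log_chi_s(s, df), w


def _log_chi_s(s: np.ndarray, df: int) -> np.ndarray:
    """Log density of s = sqrt(V/df) for V ~ chi-square(df)."""
    half = df / 2.0
    return (math.log(2.0) + half * math.log(half) - gammaln(half)
            + (df - 1.0) * np.log(s) - half * s * s)


def nct_likelihood(t: float, df: int, ncs) -> np.ndarray:
    """Noncentral-t density at ``t`` as a function of the noncentrality.

    Evaluates nct_pdf(t; df, nc) for an array of noncentralities via the
    scale-mixture representation  integral_0^inf s phi(s t - nc) q_df(s) ds,
    on a quadrature grid aligned with whichever factor is narrower.  This
    stays accurate and fast for the extreme t and nc values that arise in
    Bayes-factor integrands, where special-function series become
    unreliable.
    """
    ncs = np.atleast_1d(np.asarray(ncs, dtype=float))
    sd_s = 1.0 / math.sqrt(2.0 * df)       # approximate sd of s
    if abs(t) * sd_s > 1.0:
        # Gaussian factor is the narrow one: integrate over z = s*t - nc
        z = np.linspace(-8.6, 8.6, 301)
        h = z[1] - z[0]
        s = (ncs[:, None] + z[None, :]) / t
        ok = s > 0
        s_safe = np.where(ok, s, 1.0)
        logf = (np.log(s_safe) - 0.5 * z[None, :] ** 2 - 0.5 * _LOG_2PI
                + _log_chi_s(s_safe, df))
        f = np.where(ok, np.exp(logf), 0.0)
        f[:, 0] *= 0.5
        f[:, -1] *= 0.5
        return f.sum(axis=1) * (h / abs(t))
    s, log_sq, wq = _s_grid(df)
    z = np.subtract.outer(ncs, s * t)       # nc - s*t, shape (m, len(s))
    np.multiply(z, z, out=z)
    z *= -0.5
    z += log_sq[None, :] - 0.5 * _LOG_2PI
    np.exp(z, out=z)
    return z @ wq


def _bf10_two_sided(t: float, n: int, r: float) -> float:
    """Two-sided JZS BF10 via the g-mixture form of the Cauchy prior.

    delta ~ Cauchy(0, r) is an inverse-gamma(1/2, 1/2) scale mixture of
    normals; marginalising delta and the variance analytically leaves a
    one-dimensional integral over g with an elementary integrand, evaluated
    in log space relative to the null likelihood (so the ratio never
    overflows for any realistic t).
    """
    df = n - 1
    log_null = -((df + 1.0) / 2.0) * math.log1p(t * t / df)

    def ratio(g: float) -> float:
        c = 1.0 + n * g * r * r
        # InvGamma(1/2, 1/2) mixing density: (2 pi)^(-1/2) g^(-3/2) e^(-1/(2g))
        lg = (-0.5 * math.log(c)
              - ((df + 1.0) / 2.0) * math.log1p(t * t / (c * df))
              - 0.5 * _LOG_2PI - 1.5 * math.log(g) - 0.5 / g
              - log_null)
        return math.exp(min(lg, 700.0))

    def integrand(u: float) -> float:
        g = (1.0 - u) / u
        return ratio(g) * (1.0 + g) ** 2 if 0.0 < u < 1.0 else 0.0

    # hint quad at the integrand's bulk: small g (prior mode) through
    # g ~ t^2/n, where the likelihood part of the mixture peaks
    marks = sorted({1.0 / (1.0 + g)
                    for g in (0.1, 1.0, 10.0, max(1.0, t * t / n))})
    val, _ = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-12, epsrel=1e-10,
                            limit=300, points=marks)
    return val


def _posterior_grid(t: float, n: int, r: float, m: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalised posterior of delta on a grid spanning its support."""
    df = n - 1
    sn = math.sqrt(n)
    d0 = t / sn
    s = math.sqrt((1.0 + t * t / (2.0 * df)) / n)
    lo = min(d0 - 10.0 * s, -2.0 * s)
    hi = max(d0 + 10.0 * s, 2.0 * s)
    # place a node exactly at zero: sign masses and half-line truncations
    # then split additively, which keeps directed BFs mirror-symmetric
    k = int(round((0.0 - lo) / (hi - lo) * (m - 1)))
    k = min(max(k, 1), m - 2)
    grid = np.concatenate([np.linspace(lo, 0.0, k + 1),
                           np.linspace(0.0, hi, m - k)[1:]])
    w = nct_likelihood(t, df, grid * sn) * stats.cauchy.pdf(grid, 0.0, r)
    return grid, w


def jzs_bf(t: float, n: int, r: float = 1.0,
           direction: str = "two_sided") -> float:
    """JZS Bayes factor BF10 from the t statistic of a paired design.

    Directed hypotheses use the half-Cauchy prior, computed as
    2 * BF10_two_sided * P(sign | data, H1), which makes
    bf10(greater) + bf10(less) = 2 * bf10(two_sided) hold exactly.
    """
    if n < 2:
        raise DegenerateDataError(f"need n >= 2, got {n}")
    if r <= 0:
        raise ValueError("prior scale r must be > 0")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    bf2 = _bf10_two_sided(t, n, r)
    if direction == "two_sided":
        return bf2
    grid, w = _posterior_grid(t, n, r, 2049)
    norm = np.trapezoid(w, grid)
    if norm <= 0:
        raise DegenerateDataError("posterior mass vanished numerically")
    pos = grid >= 0
    p_pos = float(np.trapezoid(w[pos], grid[pos]) / norm)
    p_pos = min(max(p_pos, 1e-300), 1.0)
    mass = p_pos if direction == "greater" else 1.0 - p_pos
    return 2.0 * bf2 * max(mass, 1e-300)


def jzs_bf_paired(differences: Sequence[float], r: float = 1.0,
                  direction: str = "two_sided") -> float:
    """JZS Bayes factor directly from per-participant paired differences."""
    t, n = paired_t(differences)
    return jzs_bf(t, n, r=r, direction=direction)


def posterior_effect_size(t: float, n: int, r: float = 1.0,
                          direction: str = "two_sided",
                          tol: float = 1e-6
                          ) -> tuple[float, tuple[float, float]]:
    """Posterior mean and central 95% credible interval of delta.

    The unnormalised posterior  L(delta) * pi_r(delta)  is evaluated on a
    grid over its support and refined by doubling until the mean changes by
    less than ``tol``.  Directed analyses truncate the posterior to the
    hypothesised half-line (the half-Cauchy prior's doubling constant
    cancels in the normalisation).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if n < 2:
        raise DegenerateDataError(f"need n >= 2, got {n}")
    prev_mean = None
    m = 1025
    for _ in range(4):       # m caps at 16385 points
        grid, w = _posterior_grid(t, n, r, m)
        if direction == "greater":
            keep = grid >= 0
        elif direction == "less":
            keep = grid <= 0
        else:
            keep = np.ones_like(grid, dtype=bool)
        grid_d, w_d = grid[keep], w[keep]
        norm = np.trapezoid(w_d, grid_d)
        if norm <= 0 or not np.isfinite(norm):
            raise DegenerateDataError("posterior mass vanished numerically")
        mean = float(np.trapezoid(grid_d * w_d, grid_d) / norm)
        if prev_mean is not None and abs(mean - prev_mean) < tol:
            break
        prev_mean = mean
        m = 2 * (m - 1) + 1
    cdf = integrate.cumulative_trapezoid(w_d, grid_d, initial=0.0) / norm
    # cdf is monotone; interpolate the central-interval quantiles
    ci_lo = float(np.interp(0.025, cdf, grid_d))
    ci_hi = float(np.interp(0.975, cdf, grid_d))
    return mean, (ci_lo, ci_hi)


def _comparison_stats(t: float, n: int, r: float, direction: str
                      ) -> tuple[float, float, tuple[float, float]]:
    """BF10, posterior mean and 95% CI sharing one posterior grid.

    Equivalent to calling :func:`jzs_bf` and :func:`posterior_effect_size`
    separately, but evaluates the likelihood grid only once per refinement —
    the comparison battery calls this for every plan row.
    """
    bf2 = _bf10_two_sided(t, n, r)
    prev_mean = None
    m = 1025
    for _ in range(4):
        grid, w = _posterior_grid(t, n, r, m)
        norm_full = np.trapezoid(w, grid)
        if norm_full <= 0 or not np.isfinite(norm_full):
            raise DegenerateDataError("posterior mass vanished numerically")
        if direction == "greater":
            keep = grid >= 0
        elif direction == "less":
            keep = grid <= 0
        else:
            keep = np.ones_like(grid, dtype=bool)
        grid_d, w_d = grid[keep], w[keep]
        norm = np.trapezoid(w_d, grid_d)
        if norm <= 0 or not np.isfinite(norm):
            raise DegenerateDataError("posterior mass vanished numerically")
        mean = float(np.trapezoid(grid_d * w_d, grid_d) / norm)
        if prev_mean is not None and abs(mean - prev_mean) < 1e-6:
            break
        prev_mean = mean
        m = 2 * (m - 1) + 1
    if direction == "two_sided":
        bf = bf2
    else:
        pos = grid >= 0
        p_pos = float(np.trapezoid(w[pos], grid[pos]) / norm_full)
        p_pos = min(max(p_pos, 1e-300), 1.0)
        mass = p_pos if direction == "greater" else 1.0 - p_pos
        bf = 2.0 * bf2 * max(mass, 1e-300)
    cdf = integrate.cumulative_trapezoid(w_d, grid_d, initial=0.0) / norm
    ci = (float(np.interp(0.025, cdf, grid_d)),
          float(np.interp(0.975, cdf, grid_d)))
    return bf, mean, ci


def classify_evidence(bf10: float) -> str:
    """Map a Bayes factor onto the anecdotal...extreme evidence bands.

    Boundaries 3, 10, 30, 100 for H1 and their reciprocals for H0;
    BF10 = 1 itself falls on the H0 side of the bracket (boundary case,
    logged once).
    """
    if not (bf10 > 0) or not math.isfinite(bf10):
        if bf10 == math.inf:
            return "extreme_H1"
        raise ValueError(f"bf10 must be a positive number, got {bf10!r}")
    if bf10 > 1:
        b, side = bf10, "H1"
    else:
        if bf10 == 1.0:
            logger.info("classify_evidence: BF10 = 1 assigned to the H0 side")
        b, side = 1.0 / bf10, "H0"
    if b > 100:
        grade = "extreme"
    elif b > 30:
        grade = "very_strong"
    elif b > 10:
        grade = "strong"
    elif b > 3:
        grade = "moderate"
    else:
        grade = "anecdotal"
    return f"{grade}_{side}"


_MARKS = {"anecdotal": 0, "moderate": 1, "strong": 2, "very_strong": 3,
          "extreme": 4}


def evidence_marker(evidence: str) -> str:
    """Render an evidence category as the report marker: '*' per grade for
    H1, a prime (') per grade for H0; anecdotal evidence has no marker."""
    grade, _, side = evidence.rpartition("_")
    if grade not in _MARKS or side not in ("H0", "H1"):
        return ""
    return ("*" if side == "H1" else "'") * _MARKS[grade]


def run_pairwise_comparisons(aggregates: pd.DataFrame,
                             plan: Sequence[tuple[str, str, str]] = DEFAULT_PLAN,
                             channels: Sequence[str] = ("mean", "diff"),
                             standardized: Sequence[bool] = (False, True),
                             r: float = 1.0,
                             flip_diff_direction: bool = True) -> pd.DataFrame:
    """The full comparison battery over a per-label aggregate table.

    One row per plan entry x channel x standardization.  Participants
    missing either member of a pair are dropped from that pair only; pairs
    with n < 2 or zero-variance differences are flagged instead of
    computed.  For the diff channel, directed hypotheses are flipped
    (``flip_diff_direction``): higher demand predicts *smaller* between-eye
    differences.
    """
    rows = []
    for std in standardized:
        sub = aggregates[aggregates["standardized"] == std]
        for channel in channels:
            chan = sub[sub["channel"] == channel]
            wide = chan.pivot_table(index="participant_id", columns="label",
                                    values="value", aggfunc="first",
                                    dropna=False)
            for label_a, label_b, direction in plan:
                if channel == "diff" and flip_diff_direction:
                    direction = _FLIP[direction]
                row = {"pair_a": label_a, "pair_b": label_b,
                       "channel": channel, "standardized": std,
                       "direction": direction}
                if label_a not in wide.columns or label_b not in wide.columns:
                    rows.append({**row, "n": 0, "t_stat": np.nan,
                                 "bf10": np.nan, "es_mean": np.nan,
                                 "es_lo": np.nan, "es_hi": np.nan,
                                 "evidence": "not_computable"})
                    continue
                diffs = (wide[label_a] - wide[label_b]).dropna().to_numpy()
                try:
                    t, n = paired_t(diffs)
                    bf, es, (lo, hi) = _comparison_stats(t, n, r, direction)
                    evidence = classify_evidence(bf)
                except DegenerateDataError as err:
                    logger.warning("comparison %s-%s (%s, std=%s): %s",
                                   label_a, label_b, channel, std, err)
                    rows.append({**row, "n": len(diffs), "t_stat": np.nan,
                                 "bf10": np.nan, "es_mean": np.nan,
                                 "es_lo": np.nan, "es_hi": np.nan,
                                 "evidence": "degenerate" if len(diffs) >= 2
                                 else "not_computable"})
                    continue
                rows.append({**row, "n": n, "t_stat": t, "bf10": bf,
                             "es_mean": es, "es_lo": lo, "es_hi": hi,
                             "evidence": evidence})
    return pd.DataFrame(rows, columns=list(COMPARISON_COLUMNS))
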