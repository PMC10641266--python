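"""Melt-curve fits and the summary statistics of the stability comparisons.

Thermal unfolding followed by CD or dye fluorescence is summarised by the
midpoint temperature Tm.  CD melts are fitted to a Boltzmann sigmoid

    y(T) = lower + (upper - lower) / (1 + exp((Tm - T) / slope))

(`slope` in degrees C controls the transition width); DSF melts take Tm as
the temperature of the maximum first derivative of the fluorescence signal.
Thermal refolding efficiency (the alpha-value) is the ratio of the second
melt's upper plateau to the first's on a shared normalisation.  Paired
wild-type/engineered comparisons use the exact two-sided Wilcoxon
matched-pairs signed-rank test, and expression-proportion comparisons use
Fisher's exact test; both exact tests are computed by full enumeration of
the null distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MeltCurve",
    "BoltzmannMeltModel",
    "BoltzmannMeltResults",
    "RefoldResult",
    "SignedRankResult",
    "DeltaSummary",
    "FitError",
    "fit_boltzmann",
    "refolding_alpha",
    "dsf_tm",
    "paired_signed_rank",
    "fisher_exact",
    "delta_summary",
    "boltzmann",
]


class FitError(RuntimeError):
    """A melt curve could not be fitted (non-sigmoidal or degenerate data)."""


@dataclass(frozen=True)
class MeltCurve:
    """A thermal melt: ascending temperatures (degrees C) and a signal channel."""

    temperature: np.ndarray
    signal: np.ndarray
    kind: str = "CD"  # CD | DSF

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", y)
        if self.kind not in ("CD", "DSF"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("temperature and signal must be matching 1-D arrays")
        if len(t) < 10:
            raise ValueError("a melt curve needs at least 10 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")

    def __len__(self) -> int:
        return len(self.temperature)


def boltzmann(t, tm, slope, lower, upper):
    """The Boltzmann sigmoid used for CD melts."""
    t = np.asarray(t, dtype=float)
    return lower + (upper - lower) / (1.0 + np.exp((tm - t) / slope))


class BoltzmannMeltModel:
    """Boltzmann sigmoid model of a CD melt curve.

    Follows the model/results idiom: construct from a :class:`MeltCurve`,
    call :meth:`fit` to obtain :class:`BoltzmannMeltResults`.

    Parameters are initialised from the data (Tm at the half-range
    crossing, slope from the 25-75% signal span) and optimised by bounded
    least squares with Tm constrained to the observed temperature range.
    ``constrain_plateaus=True`` pins the plateaus to the 0/100 ends of the
    percent-normalised scale; the default leaves them free.
    """

    #: minimum signal range, as a fraction of |median|+range, below which the
    #: curve is considered to span no transition
    MIN_RELATIVE_RANGE = 1e-9

    def __init__(self, curve: MeltCurve):
        if curve.kind != "CD":
            raise ValueError("BoltzmannMeltModel fits CD melts")
        self.curve = curve

    def _initial_guess(self):
        t, y = self.curve.temperature, self.curve.signal
        lo, hi = float(np.min(y)), float(np.max(y))
        if hi - lo <= self.MIN_RELATIVE_RANGE * max(1.0, abs(hi) + abs(lo)):
            raise FitError("signal range too small: no transition to fit")
        half = (lo + hi) / 2.0
        tm0 = float(t[np.argmin(np.abs(y - half))])
        q25, q75 = lo + 0.25 * (hi - lo), lo + 0.75 * (hi - lo)
        t25 = float(t[np.argmin(np.abs(y - q25))])
        t75 = float(t[np.argmin(np.abs(y - q75))])
        # 25->75% of a Boltzmann spans ~2.2 slope units
        slope0 = max((t75 - t25) / 2.2, 1e-3)
        return tm0, slope0, lo, hi

    def fit(self, constrain_plateaus: bool = False) -> "BoltzmannMeltResults":
        t, y = self.curve.temperature, self.curve.signal
        tm0, slope0, lo, hi = self._initial_guess()
        span = hi - lo
        if constrain_plateaus:
            # normalise to percent scale, fit Tm and slope only
            yn = 100.0 * (y - lo) / span

            def f(tt, tm, slope):
                return boltzmann(tt, tm, slope, 0.0, 100.0)

            p0 = [tm0, slope0]
            bounds = ([t[0], 1e-4], [t[-1], (t[-1] - t[0])])
            popt, pcov = optimize.curve_fit(f, t, yn, p0=p0, bounds=bounds,
                                            maxfev=20000)
            params = np.array([popt[0], popt[1], lo, hi])
            fitted = boltzmann(t, popt[0], popt[1], lo, hi)
            cov = np.full((4, 4), np.nan)
            cov[:2, :2] = pcov
        else:
            p0 = [tm0, slope0, lo, hi]
            bounds = ([t[0], 1e-4, lo - 2 * span, lo - 2 * span],
                      [t[-1], (t[-1] - t[0]), hi + 2 * span, hi + 2 * span])
            params, cov = optimize.curve_fit(boltzmann, t, y, p0=p0,
                                             bounds=bounds, maxfev=20000)
            fitted = boltzmann(t, *params)

        tm, slope, lower, upper = map(float, params)
        if upper < lower:  # canonicalise orientation
            lower, upper = upper, lower
        resid = y - fitted
        rss = float(np.sum(resid ** 2))
        n = len(t)
        # refuse non-sigmoidal data: the fit must beat a flat line on AIC
        # (4 vs 1 parameters)
        rss_flat = float(np.sum((y - np.mean(y)) ** 2))
        eps = np.finfo(float).tiny
        aic_fit = n * math.log(max(rss, eps) / n) + 2 * 4
        aic_flat = n * math.log(max(rss_flat, eps) / n) + 2 * 1
        if aic_fit >= aic_flat:
            raise FitError("non-sigmoidal data: Boltzmann fit no better than flat line")
        return BoltzmannMeltResults(
            model=self, tm=tm, slope=slope, lower_plateau=lower,
            upper_plateau=upper, cov=cov,
            rms_residual=math.sqrt(rss / n), constrained=constrain_plateaus)


@dataclass
class BoltzmannMeltResults:
    """Fitted Boltzmann melt: estimates, uncertainties, diagnostics."""

    model: BoltzmannMeltModel
    tm: float
    slope: float
    lower_plateau: float
    upper_plateau: float
    cov: np.ndarray
    rms_residual: float
    constrained: bool

    _names = ("tm", "slope", "lower_plateau", "upper_plateau")

    @property
    def params(self) -> np.ndarray:
        return np.array([self.tm, self.slope, self.lower_plateau, self.upper_plateau])

    @property
    def bse(self) -> np.ndarray:
        """Standard errors from the least-squares covariance."""
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov))

    def predict(self, temperature) -> np.ndarray:
        return boltzmann(temperature, self.tm, self.slope,
                         self.lower_plateau, self.upper_plateau)

    def normalized_plateaus(self) -> tuple[float, float]:
        """Plateaus on the percent scale of this fit (by construction 0/100)."""
        return 0.0, 100.0

    def summary(self) -> str:
        lines = ["Boltzmann melt fit"
                 + (" (plateaus constrained)" if self.constrained else ""),
                 f"  n points      {len(self.model.curve):>10d}",
                 f"  rms residual  {self.rms_residual:>10.4g}"]
        for name, value, se in zip(self._names, self.params, self.bse):
            se_txt = f"+/- {se:.3g}" if np.isfinite(se) else ""
            lines.append(f"  {name:<13s} {value:>10.4f} {se_txt}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data and fitted curve; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.curve.temperature
        ax.plot(t, self.model.curve.signal, ".", label="data", alpha=0.6)
        tt = np.linspace(t[0], t[-1], 300)
        ax.plot(tt, self.predict(tt), "-", label=f"fit (Tm = {self.tm:.1f} C)")
        ax.axvline(self.tm, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("temperature (C)")
        ax.set_ylabel("signal")
        ax.legend()
        return ax


def fit_boltzmann(curve: MeltCurve, constrain_plateaus: bool = False
                  ) -> BoltzmannMeltResults:
    """Convenience wrapper: fit a CD melt, returning the results object."""
    return BoltzmannMeltModel(curve).fit(constrain_plateaus=constrain_plateaus)


@dataclass(frozen=True)
class RefoldResult:
    """Thermal refolding efficiency (alpha-value)."""

    alpha: float
    first_upper: float
    second_upper: float

    TOLERANCE = 0.1  # alpha may exceed 1 by noise, not by much

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.alpha > 1.0 + self.TOLERANCE:
            raise ValueError(f"alpha {self.alpha:.3f} implausibly exceeds 1")


def refolding_alpha(first_fit: BoltzmannMeltResults,
                    second_fit: BoltzmannMeltResults) -> RefoldResult:
    """Alpha-value: second melt's upper plateau over the first's.

    Both plateaus are normalised on the first melt's fitted scale (its
    lower plateau -> 0, upper -> 100), so identical curves give exactly 1.
    """
    scale = first_fit.upper_plateau - first_fit.lower_plateau
    if scale <= 0:
        raise ValueError("first melt has a nonpositive plateau span")
    first_norm = 100.0
    second_norm = 100.0 * (second_fit.upper_plateau - first_fit.lower_plateau) / scale
    return RefoldResult(alpha=second_norm / first_norm,
                        first_upper=first_fit.upper_plateau,
                        second_upper=second_fit.upper_plateau)


def dsf_tm(curve: MeltCurve, smooth_window: int = 1) -> float:
    """DSF Tm: temperature of the maximum rate of signal change.

    First derivative by central differences on the temperature grid, with an
    optional odd moving-average ``smooth_window`` applied to the signal
    first.  Fails on flat or linear traces, where the maximum is not
    meaningful (all-tied or zero derivative).
    """
    if len(curve) < 3:
        raise ValueError("need at least 3 points")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    t, y = curve.temperature, curve.signal
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        y = np.convolve(np.pad(y, pad, mode="edge"), kernel, mode="valid")
    dy = np.gradient(y, t)
    span = float(np.max(y) - np.min(y))
    grid = float(np.median(np.diff(t)))
    if span <= 0:
        raise FitError("flat signal: no transition")
    # a linear/flat trace has an essentially constant derivative: no peak
    if float(np.max(dy) - np.median(dy)) <= 1e-9 * span / grid:
        raise FitError("no defined derivative maximum (flat or linear signal)")
    if float(np.max(dy)) <= 0:
        raise FitError("signal never increases: no unfolding transition")
    return float(t[int(np.argmax(dy))])


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignedRankResult:
    p_value: float
    statistic: float   # W+ (sum of ranks of positive deltas), midranks
    n_used: int
    n_zero: int        # zero deltas dropped (reported, never silent)


def paired_signed_rank(deltas) -> SignedRankResult:
    """Exact two-sided Wilcoxon matched-pairs signed-rank test.

    Zero deltas are dropped (count reported); ties among |delta| take
    midranks.  The null distribution of W+ over all 2^n sign assignments is
    computed exactly by dynamic programming on the doubled (integer) ranks,
    and the two-sided p is the null probability of a |W+ - mean| at least as
    large as observed (the distribution is symmetric, so this equals the
    doubled smaller tail, capped at 1).
    """
    d = np.asarray(list(deltas), dtype=float)
    if d.ndim != 1 or len(d) == 0:
        raise ValueError("deltas must be a nonempty 1-D collection")
    if len(d) > 25:
        raise ValueError("exact enumeration supported for n <= 25")
    nonzero = d[d != 0]
    n_zero = len(d) - len(nonzero)
    if len(nonzero) == 0:
        raise ValueError("all deltas are zero: test undefined")
    ranks = stats.rankdata(np.abs(nonzero))       # midranks, multiples of 0.5
    ranks2 = np.rint(2 * ranks).astype(np.int64)  # doubled -> exact integers
    w2_obs = int(np.sum(ranks2[nonzero > 0]))
    total = int(np.sum(ranks2))

    # distribution of doubled W+ by DP: counts[s] = #assignments with sum s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:len(counts) - r]
        counts = counts + shifted
    counts /= counts.sum()

    dev_obs = abs(2 * w2_obs - total)  # integer-exact distance from the mean
    sums = np.arange(total + 1)
    p = float(np.sum(counts[np.abs(2 * sums - total) >= dev_obs]))
    return SignedRankResult(p_value=min(p, 1.0), statistic=w2_obs / 2.0,
                            n_used=len(nonzero), n_zero=n_zero)


def fisher_exact(table) -> float:
    """Exact two-sided Fisher test p for a 2x2 count table.

    Sums the hypergeometric probabilities of every table with the same
    margins whose point probability does not exceed the observed table's.
    Degenerate margins (an empty row or column) leave no association to
    test: p = 1.
    """
    a, b, c, d = np.asarray(table, dtype=float).ravel()
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = map(int, (a, b, c, d))
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0
    rv = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    # relative tolerance guards against float noise at equal-probability tables
    return float(np.sum(pmf[pmf <= p_obs * (1 + 1e-7)]))


# ---------------------------------------------------------------------------
# Paired delta summaries
# ---------------------------------------------------------------------------

DELTA_KINDS = ("tm", "alpha", "monomer", "kd")


@dataclass
class DeltaSummary:
    """Wild-type vs engineered paired comparison for one property.

    Deltas follow the reporting convention of the property: Tm, alpha and
    monomer fraction as differences (engineered - wild-type; positive is
    improvement), K_D as the engineered/wild-type ratio (>1 is weaker
    binding).  The signed-rank test for the K_D kind is run on log-ratios
    (ratio 1 is the null).
    """

    kind: str
    table: pd.DataFrame  # index: domain id; columns wild_type, engineered, delta
    median_delta: float
    p_value: float
    n_pairs: int

    def summary(self) -> str:
        unit = {"tm": "C", "alpha": "", "monomer": "%", "kd": "x"}[self.kind]
        return (f"Delta summary ({self.kind}): n = {self.n_pairs}, "
                f"median delta = {self.median_delta:.3g}{unit}, "
                f"exact signed-rank p = {self.p_value:.4g}")


def delta_summary(wild_type: dict[str, float], engineered: dict[str, float],
                  kind: str) -> DeltaSummary:
    """Pair domains by id and summarise the engineered-vs-wild-type deltas."""
    if kind not in DELTA_KINDS:
        raise ValueError(f"kind must be one of {DELTA_KINDS}")
    ids = sorted(set(wild_type) & set(engineered))
    if not ids:
        raise ValueError("no overlapping domain ids between the two sets")
    wt = np.array([wild_type[i] for i in ids], dtype=float)
    eng = np.array([engineered[i] for i in ids], dtype=float)
    if kind == "kd":
        if np.any(wt <= 0) or np.any(eng <= 0):
            raise ValueError("K_D values must be positive")
        delta = eng / wt
        test_deltas = np.log(delta)
    else:
        delta = eng - wt
        test_deltas = delta
    if np.all(test_deltas == 0):
        p = 1.0
    else:
        p = paired_signed_rank(test_deltas).p_value
    table = pd.DataFrame({"wild_type": wt, "engineered": eng, "delta": delta},
                         index=pd.Index(ids, name="domain"))
    return DeltaSummary(kind=kind, table=table,
                        median_delta=float(np.median(delta)),
                        p_value=p, n_pairs=len(ids))
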