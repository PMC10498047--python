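"""Circular statistics, dose-response modelling and group comparisons.

Phases of activity peaks live on the 24 h circle (24 h = 360 degrees, so
ZT h maps to the angle 2*pi*h/24).  Phase control -- the requirement that a
truly entrained fly keep its entrained phase on the first day after release
into constant conditions -- is assessed with the V-test, a Rayleigh test of
circular uniformity whose alternative specifies a known mean angle (here the
circular median of the entrained phases, supplied externally and never
estimated from the release sample itself).

Dose-response period lengthening under constant light is modelled with the
four-parameter logistic curve

    y(x) = alpha_L + delta / (1 + exp(-eta * (x - phi_m)))

(lower asymptote ``alpha_L`` in hours, asymptote span ``delta``, growth rate
``eta``, midpoint dose ``phi_m``), and the fitted curve is tested against the
null of a flat line with an extra-sum-of-squares F test.

Group comparisons mirror the pipeline's reporting: Kruskal-Wallis with
Bonferroni-corrected pairwise rank tests summarized as a compact letter
display (groups sharing a letter do not differ significantly), and the
Wilcoxon rank-sum test for two independent samples (the reported W follows
the R convention, i.e. the Mann-Whitney U of the first sample).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps

TWO_PI = 2 * np.pi


# -- angles --------------------------------------------------------------------


def zt_to_angle(zt_h):
    """Map ZT hours to radians in [0, 2*pi); ZT0 and ZT24 coincide."""
    return (np.asarray(zt_h, dtype=float) % 24.0) * TWO_PI / 24.0


def angle_to_zt(rad):
    """Inverse of :func:`zt_to_angle`, wrapped into [0, 24)."""
    return (np.asarray(rad, dtype=float) % TWO_PI) * 24.0 / TWO_PI


@dataclass
class CircularSample:
    """A sample of angles in radians, wrapped into [0, 2*pi)."""

    angles_rad: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_rad, dtype=float)
        if a.ndim != 1 or len(a) < 1:
            raise ValueError("need a 1-D sample of at least one angle")
        self.angles_rad = a % TWO_PI

    @property
    def n(self) -> int:
        return len(self.angles_rad)


def _as_angles(sample) -> np.ndarray:
    if isinstance(sample, CircularSample):
        return sample.angles_rad
    return CircularSample(np.asarray(sample)).angles_rad


def circ_mean(angles) -> float:
    """Mean direction of a circular sample, in [0, 2*pi)."""
    a = _as_angles(angles)
    return float(np.angle(np.exp(1j * a).mean()) % TWO_PI)


def resultant_length(angles) -> float:
    """Mean resultant length R = |sum exp(i*theta)| / n, in [0, 1]."""
    a = _as_angles(angles)
    return float(np.abs(np.exp(1j * a).mean()))


def circ_median(angles) -> float:
    """Circular median: the sample angle minimizing the mean circular
    absolute deviation; ties are broken toward the circular mean."""
    a = _as_angles(angles)
    dev = np.pi - np.abs(np.pi - np.abs(a[:, None] - a[None, :]))
    mad = dev.mean(axis=1)
    best = np.flatnonzero(np.isclose(mad, mad.min()))
    if len(best) == 1:
        return float(a[best[0]])
    mu = circ_mean(a)
    dist_to_mean = np.pi - np.abs(np.pi - np.abs(a[best] - mu))
    return float(a[best[np.argmin(dist_to_mean)]])


# -- uniformity tests ----------------------------------------------------------


def rayleigh_test(sample) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns (R, p) with R the mean resultant length and p from the standard
    approximation with finite-n correction,
    p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)), Rn = n R.
    """
    a = _as_angles(sample)
    n = len(a)
    if n < 2:
        raise ValueError("Rayleigh test needs n >= 2")
    r = resultant_length(a)
    rn = n * r
    p = math.exp(math.sqrt(1 + 4 * n + 4 * (n * n - rn * rn)) - (1 + 2 * n))
    return r, float(min(1.0, p))


@dataclass
class VTestResult:
    """V-test outcome: concentration toward a hypothesized mean angle."""

    mu0_rad: float
    v: float
    u: float
    p: float
    n: int
    r: float
    mean_angle_rad: float


def v_test(sample, mu0_rad: float) -> VTestResult:
    """V-test (modified Rayleigh) against a known mean angle ``mu0_rad``.

    V = R cos(theta_bar - mu0); u = V sqrt(2 n); p is the one-sided upper
    tail normal probability of u.  ``mu0_rad`` must come from outside the
    sample being tested.
    """
    a = _as_angles(sample)
    n = len(a)
    if n < 2:
        raise ValueError("V-test needs n >= 2")
    r = resultant_length(a)
    theta = circ_mean(a)
    v = r * math.cos(theta - mu0_rad)
    u = v * math.sqrt(2 * n)
    p = float(sps.norm.sf(u))
    return VTestResult(
        mu0_rad=float(mu0_rad % TWO_PI),
        v=float(v),
        u=float(u),
        p=p,
        n=n,
        r=float(r),
        mean_angle_rad=theta,
    )


def assess_phase_control(entrained_phases_zt_h, release_phases_zt_h) -> VTestResult:
    """Phase-control V-test for a released cohort.

    The hypothesized mean angle is the circular median of the entrained
    phases; the V-test is applied to the release-day phases.
    """
    ent = np.atleast_1d(np.asarray(entrained_phases_zt_h, dtype=float))
    rel = np.atleast_1d(np.asarray(release_phases_zt_h, dtype=float))
    if len(ent) == 0 or len(rel) == 0:
        raise ValueError("both phase samples must be non-empty")
    mu0 = circ_median(zt_to_angle(ent))
    return v_test(zt_to_angle(rel), mu0)


# -- dose-response -------------------------------------------------------------


def logistic4(x, alpha_l, delta, eta, phi_m):
    """Four-parameter logistic: alpha_l + delta / (1 + exp(-eta (x - phi_m)))."""
    z = np.clip(-eta * (np.asarray(x, float) - phi_m), -700.0, 700.0)
    return alpha_l + delta / (1.0 + np.exp(z))


@dataclass
class DoseResponseFit:
    """Fitted 4PL dose-response curve with fit diagnostics."""

    alpha_l: float
    delta: float
    eta: float
    phi_m: float
    rss: float
    n: int
    converged: bool
    n_doses: int = 4  # distinct dose levels in the fitted data

    def predict(self, x):
        return logistic4(x, self.alpha_l, self.delta, self.eta, self.phi_m)


def fit_logistic4(
    dose,
    response,
    n_starts: int = 8,
    seed: int = 0,
    log_dose: bool = False,
) -> DoseResponseFit:
    """Least-squares 4PL fit with multi-start optimization.

    Starting points are data-driven (asymptotes from the response range,
    midpoint from dose quantiles, both slope signs) plus seeded jitter; the
    best residual sum of squares wins.  A fit that never converges is
    returned flagged with the best parameters found.
    """
    x = np.asarray(dose, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("dose and response must be matching 1-D arrays")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct doses")
    if log_dose:
        if np.any(x <= 0):
            raise ValueError("log-dose requires strictly positive doses")
        x = np.log(x)
    rng = np.random.default_rng(seed)
    span = float(y.max() - y.min())
    xr = float(x.max() - x.min()) or 1.0
    qs = np.quantile(x, [0.25, 0.5, 0.75])
    base_starts = [
        (y.min(), span, 4.0 / xr, q) for q in qs
    ] + [
        (y.max(), -span, 4.0 / xr, qs[1]),
        (y.min(), span, 1.0 / xr, qs[1]),
        (float(y.mean()), 0.0, 1.0 / xr, qs[1]),
    ]
    while len(base_starts) < n_starts:
        base_starts.append(
            (
                y.min() + rng.uniform(-0.5, 0.5) * (span or 1.0),
                span * rng.uniform(-1.5, 1.5),
                rng.uniform(0.2, 8.0) / xr,
                float(rng.uniform(x.min(), x.max())),
            )
        )
    best = None
    converged = False
    for p0 in base_starts[:max(n_starts, 6)]:
        try:
            with warnings.catch_warnings(), np.errstate(over="ignore"):
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                popt, _ = optimize.curve_fit(
                    logistic4, x, y, p0=p0, maxfev=10000, method="lm"
                )
        except (RuntimeError, TypeError):
            continue
        if not np.all(np.isfinite(popt)):
            continue
        rss = float(((y - logistic4(x, *popt)) ** 2).sum())
        if not np.isfinite(rss):
            continue
        converged = True
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        # fall back to the flat line so callers still get a defined rss
        popt = np.array([float(y.mean()), 0.0, 1.0 / xr, float(np.median(x))])
        best = (float(((y - y.mean()) ** 2).sum()), popt)
    rss, popt = best
    return DoseResponseFit(
        alpha_l=float(popt[0]),
        delta=float(popt[1]),
        eta=float(popt[2]),
        phi_m=float(popt[3]),
        rss=rss,
        n=len(y),
        converged=converged,
        n_doses=len(np.unique(x)),
    )


def anova_vs_flat(fit: DoseResponseFit, response) -> tuple[float, float]:
    """Extra-sum-of-squares F test of the 4PL fit against a flat line.

    F = ((RSS0 - RSS1)/(p1 - p0)) / (RSS1/(n - p1)) with the flat model
    (1 parameter) as null and the 4PL as alternative.  When the data hold
    fewer distinct doses than the 4PL has parameters, the curve saturates
    the per-dose means and the effective model dimension is the number of
    dose levels; the degrees of freedom use that effective dimension (the
    test is then the exact one-way F test under Gaussian errors).
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    p1, p0 = min(4, fit.n_doses), 1
    if n <= p1:
        raise ValueError("need more observations than model parameters")
    rss0 = float(((y - y.mean()) ** 2).sum())
    rss1 = fit.rss
    if rss1 <= 0:
        return float("inf"), 0.0
    f = max(0.0, (rss0 - rss1) / (p1 - p0)) / (rss1 / (n - p1))
    p = float(sps.f.sf(f, p1 - p0, n - p1))
    return float(f), p


# -- rank-based group comparisons ----------------------------------------------


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum test for two independent samples.

    Exact p-value when the smaller sample has <= 25 observations and there
    are no ties across samples, otherwise the tie-corrected normal
    approximation with continuity correction.  The statistic W is the
    Mann-Whitney U of the first sample (R's convention).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 25 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_with_letters(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[float, float, dict[str, str]]:
    """Kruskal-Wallis H test with a Bonferroni-corrected compact letter display.

    Pairwise Wilcoxon rank-sum comparisons are Bonferroni-corrected over all
    pairs; the letter display assigns groups sharing a letter whenever they
    are *not* significantly different (insert-absorb algorithm).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(len(arr) < 2 for arr in arrays):
        raise ValueError("every group needs n >= 2")
    if np.ptp(np.concatenate(arrays)) == 0:
        h, p = 0.0, 1.0  # all values identical; H degenerates to 0
    else:
        h, p = sps.kruskal(*arrays)
    m = len(labels) * (len(labels) - 1) // 2
    sig_pairs: list[tuple[str, str]] = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(labels), 2):
        if np.ptp(np.concatenate([arrays[i], arrays[j]])) == 0:
            continue
        _, pij = wilcoxon_rank_sum(arrays[i], arrays[j])
        if min(1.0, pij * m) < alpha:
            sig_pairs.append((gi, gj))
    letters = _compact_letter_display(labels, sig_pairs, groups)
    return float(h), float(p), letters


def _compact_letter_display(
    labels: list[str], sig_pairs: list[tuple[str, str]], groups
) -> dict[str, str]:
    """Insert-absorb compact letter display from significant pairs."""
    cols: list[set[str]] = [set(labels)]
    for gi, gj in sig_pairs:
        for col in [c for c in cols if gi in c and gj in c]:
            cols.remove(col)
            for new in (col - {gi}, col - {gj}):
                if new and not any(new <= c for c in cols):
                    cols.append(new)
    # absorb subsets that may remain after later splits
    cols = [c for c in cols if not any(c < d for d in cols)]
    # stable letter order: by median of the member groups
    order = sorted(labels, key=lambda g: np.median(np.asarray(groups[g], float)))
    cols.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in labels}
    for letter, col in zip(alphabet, cols):
        for g in col:
            out[g] += letter
    return {g: "".join(sorted(s)) for g, s in out.items()}
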