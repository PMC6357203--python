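"""Binomial null model and division-fraction estimator for two-color doublet counts.

The model
---------
Red- and green-labeled platelets are mixed in a viscous semisolid medium.
Doublets arise two ways: incidental contact during mixing ("happen-to-be"
doublets) and division, where a platelet's progeny stays adjacent.  Contact
is color-blind, so with R red and G green platelets present the contact
doublets split among the red-red / red-green / green-green classes in the
binomial proportions R^2 : 2RG : G^2 (over (R+G)^2).  Division can only
produce same-color doublets.  An excess of same-color doublets — equivalently
a deficit of red-green doublets — relative to the binomial pattern is
therefore evidence of division, and its size identifies the divided fraction.

Writing R0, G0 for the (unobserved) numbers of platelets originally seeded
and F_r, F_g for the fractions of them that divided during culture, the five
observed counts satisfy

    n_red   = R0 (1 + F_r)                      n_green = G0 (1 + F_g)
    d_rr    = d_rg * R0 / (2 G0) + F_r R0       d_gg    = d_rg * G0 / (2 R0) + F_g G0

(the d_rg-proportional terms are the happen-to-be doublets predicted from
the red-green count through the binomial ratio RR : RG = R0 : 2G0).  The
four equations admit a closed-form solution for (R0, G0, F_r, F_g), which
`estimate_division_fractions` implements.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .counts import FieldCounts, InvalidCountsError

__all__ = [
    "BinomialExpectation",
    "DoubletNullTest",
    "DivisionEstimate",
    "DegenerateCountsError",
    "expected_doublet_proportions",
    "doublet_null_test",
    "estimate_division_fractions",
    "bootstrap_division_ci",
    "analyze_experiment",
]


class DegenerateCountsError(ValueError):
    """Raised when the equation system has no admissible solution."""


@dataclasses.dataclass(frozen=True)
class BinomialExpectation:
    """Null-model proportions of the three doublet color classes."""

    p_rr: float
    p_rg: float
    p_gg: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_rr, self.p_rg, self.p_gg])


@dataclasses.dataclass(frozen=True)
class DoubletNullTest:
    """Lower-tail test of the red-green doublet count against the binomial null.

    ``p_le`` is the probability, under the no-division null, of seeing a
    red-green doublet count as small as or smaller than the one observed.
    """

    t_doublets: int
    observed_fracs: tuple[float, float, float]  # (rr, rg, gg)
    expected: BinomialExpectation
    z: float
    p_le: float
    method: str


@dataclasses.dataclass(frozen=True)
class DivisionEstimate:
    """Division fractions and the inferred seeding state behind them.

    ``f_red``/``f_green`` may be negative: with no true division, sampling
    noise scatters the estimate around zero.
    """

    f_red: float
    f_green: float
    r0: float
    g0: float
    htb_rr: float
    htb_gg: float
    ci_red: tuple[float, float] | None = None
    ci_green: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None


def expected_doublet_proportions(n_red: int, n_green: int) -> BinomialExpectation:
    """Binomial null proportions of RR : RG : GG doublets.

    With ``R`` red and ``G`` green platelets present, color-blind pairing
    predicts the doublet classes in proportions R^2/(R+G)^2, 2RG/(R+G)^2
    and G^2/(R+G)^2.
    """
    if n_red < 0 or n_green < 0:
        raise InvalidCountsError("platelet totals must be non-negative")
    total = n_red + n_green
    if total == 0:
        raise InvalidCountsError("cannot form doublet expectations with zero platelets")
    r = n_red / total
    g = n_green / total
    return BinomialExpectation(p_rr=r * r, p_rg=2.0 * r * g, p_gg=g * g)


def doublet_null_test(counts: FieldCounts, method: str = "normal_approx") -> DoubletNullTest:
    """Probability of a red-green doublet count this small under the null.

    Under the no-division null each of the ``T`` doublets is red-green with
    probability ``p = 2RG/(R+G)^2`` independently.  ``normal_approx`` uses
    the plain normal approximation to the binomial with no continuity
    correction, z = (d_rg - T p) / sqrt(T p (1-p)), p_le = Phi(z);
    ``exact_binomial`` sums the binomial lower tail exactly.  A small p_le
    flags a deficit of mixed-color doublets, i.e. division.
    """
    if method not in ("normal_approx", "exact_binomial"):
        raise ValueError(f"unknown method {method!r}")
    T = counts.total_doublets
    if T < 1:
        raise InvalidCountsError(
            f"{counts.experiment_id}: tail test undefined with zero doublets"
        )
    expected = expected_doublet_proportions(counts.n_red, counts.n_green)
    p = expected.p_rg
    if p <= 0.0 or p >= 1.0:
        raise InvalidCountsError(
            f"{counts.experiment_id}: tail test requires both colors present"
        )
    if method == "normal_approx":
        z = (counts.d_rg - T * p) / math.sqrt(T * p * (1.0 - p))
        p_le = float(stats.norm.cdf(z))
    else:
        z = float("nan")
        p_le = float(stats.binom.cdf(counts.d_rg, T, p))
    observed = (counts.d_rr / T, counts.d_rg / T, counts.d_gg / T)
    return DoubletNullTest(
        t_doublets=T,
        observed_fracs=observed,
        expected=expected,
        z=z,
        p_le=p_le,
        method=method,
    )


def _solve_division(
    n_red: float, n_green: float, d_rr: float, d_gg: float, d_rg: float
) -> tuple[float, float, float, float]:
    """Closed-form (f_red, f_green, r0, g0) from the five counts.

    Substituting the happen-to-be terms into the totals gives
    R0 = (n_red - d_rr) + (d_rg/2) * (R0/G0) and the symmetric relation for
    G0; the ratio t = R0/G0 then solves linearly:
    t = (n_red - d_rr - d_rg/2) / (n_green - d_gg - d_rg/2).
    """
    a = d_rg / 2.0
    num = n_red - d_rr - a
    den = n_green - d_gg - a
    if num <= 0 or den <= 0:
        raise DegenerateCountsError(
            "degenerate counts: n - d_same - d_rg/2 must be positive for both colors "
            f"(got red {num}, green {den})"
        )
    t = num / den
    r0 = (n_red - d_rr) + a * t
    g0 = (n_green - d_gg) + a / t
    if r0 <= 0 or g0 <= 0:
        raise DegenerateCountsError("infeasible solution: inferred R0/G0 not positive")
    return n_red / r0 - 1.0, n_green / g0 - 1.0, r0, g0


def estimate_division_fractions(counts: FieldCounts) -> DivisionEstimate:
    """Divided fractions of each color from the five observed counts.

    Solves the four-equation system described in the module docstring in
    closed form.  Residuals of the same-color doublet equations are checked
    to 1e-9 relative as a guard on the algebra.
    """
    if counts.n_red <= 0 or counts.n_green <= 0:
        raise InvalidCountsError(
            f"{counts.experiment_id}: both colors must be observed"
        )
    f_red, f_green, r0, g0 = _solve_division(
        counts.n_red, counts.n_green, counts.d_rr, counts.d_gg, counts.d_rg
    )
    htb_rr = counts.d_rg * r0 / (2.0 * g0)
    htb_gg = counts.d_rg * g0 / (2.0 * r0)
    # residual guard on the two doublet equations
    scale = max(1.0, counts.d_rr, counts.d_gg)
    res_r = counts.d_rr - (htb_rr + f_red * r0)
    res_g = counts.d_gg - (htb_gg + f_green * g0)
    if abs(res_r) > 1e-9 * scale or abs(res_g) > 1e-9 * scale:
        raise DegenerateCountsError(
            f"{counts.experiment_id}: closed-form solution failed the residual check"
        )
    return DivisionEstimate(
        f_red=f_red, f_green=f_green, r0=r0, g0=g0, htb_rr=htb_rr, htb_gg=htb_gg
    )


def _bootstrap_replicates(
    counts: FieldCounts, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized resampled (f_red, f_green); invalid replicates are NaN."""
    T = counts.total_doublets
    probs = np.array([counts.d_rr, counts.d_gg, counts.d_rg], dtype=float) / T
    doublets = rng.multinomial(T, probs, size=n_boot).astype(float)
    s_r = rng.poisson(counts.singlets_red, size=n_boot).astype(float)
    s_g = rng.poisson(counts.singlets_green, size=n_boot).astype(float)
    d_rr, d_gg, d_rg = doublets[:, 0], doublets[:, 1], doublets[:, 2]
    n_red = s_r + 2.0 * d_rr + d_rg
    n_green = s_g + 2.0 * d_gg + d_rg
    a = d_rg / 2.0
    num = n_red - d_rr - a
    den = n_green - d_gg - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / den
        r0 = (n_red - d_rr) + a * t
        g0 = (n_green - d_gg) + a / t
        f_r = n_red / r0 - 1.0
        f_g = n_green / g0 - 1.0
    bad = (num <= 0) | (den <= 0) | (r0 <= 0) | (g0 <= 0)
    f_r = np.where(bad, np.nan, f_r)
    f_g = np.where(bad, np.nan, f_g)
    return f_r, f_g


def bootstrap_division_ci(
    counts: FieldCounts,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> DivisionEstimate:
    """Percentile-bootstrap confidence intervals for the division fractions.

    Each replicate redraws the doublet class vector from a multinomial over
    the observed total ``T`` and the singlet totals from Poisson laws around
    the observed singlets (field-to-field sampling), then re-runs the
    closed-form estimator.  Replicates where the system degenerates are
    dropped; if more than 20% degenerate a warning is issued and the
    achieved replicate count reported.
    """
    import warnings

    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if counts.total_doublets == 0:
        raise DegenerateCountsError(
            f"{counts.experiment_id}: no doublets observed; nothing to resample"
        )
    point = estimate_division_fractions(counts)  # validates counts
    rng = np.random.default_rng(seed)
    f_r, f_g = _bootstrap_replicates(counts, n_boot, rng)
    ok = ~(np.isnan(f_r) | np.isnan(f_g))
    n_ok = int(ok.sum())
    if n_ok == 0:
        raise DegenerateCountsError(
            f"{counts.experiment_id}: estimator degenerate on every bootstrap replicate"
        )
    if n_ok < 0.8 * n_boot:
        warnings.warn(
            f"{counts.experiment_id}: estimator failed on {n_boot - n_ok} of "
            f"{n_boot} bootstrap replicates; intervals use {n_ok} replicates",
            RuntimeWarning,
            stacklevel=2,
        )
    alpha = (1.0 - level) / 2.0
    lo_r, hi_r = np.quantile(f_r[ok], [alpha, 1.0 - alpha])
    lo_g, hi_g = np.quantile(f_g[ok], [alpha, 1.0 - alpha])
    return dataclasses.replace(
        point,
        ci_red=(float(lo_r), float(hi_r)),
        ci_green=(float(lo_g), float(hi_g)),
        n_boot=n_ok,
        seed=seed,
    )


def analyze_experiment(
    counts: FieldCounts,
    n_boot: int = 10_000,
    seed: int | None = None,
    ci: bool = True,
) -> dict:
    """Full per-experiment report: observed vs expected doublet composition,
    the lower-tail probability, and the division fractions with intervals.

    Percentages are reported to one decimal and probabilities to three
    significant figures under the ``display`` key; full-precision values are
    kept alongside.
    """
    test = doublet_null_test(counts)
    if ci:
        est = bootstrap_division_ci(counts, n_boot=n_boot, seed=seed)
    else:
        est = estimate_division_fractions(counts)
    obs_rr, obs_rg, obs_gg = test.observed_fracs
    exp = test.expected
    report = {
        "experiment": counts.experiment_id,
        "condition": counts.condition,
        "counts": {
            "n_red": counts.n_red,
            "n_green": counts.n_green,
            "d_rr": counts.d_rr,
            "d_gg": counts.d_gg,
            "d_rg": counts.d_rg,
            "singlets_red": counts.singlets_red,
            "singlets_green": counts.singlets_green,
            "total_doublets": counts.total_doublets,
        },
        "observed_pct": {
            "rr": 100.0 * obs_rr,
            "rg": 100.0 * obs_rg,
            "gg": 100.0 * obs_gg,
        },
        "expected_pct": {
            "rr": 100.0 * exp.p_rr,
            "rg": 100.0 * exp.p_rg,
            "gg": 100.0 * exp.p_gg,
        },
        "p_le": test.p_le,
        "z": test.z,
        "f_red": est.f_red,
        "f_green": est.f_green,
        "r0": est.r0,
        "g0": est.g0,
        "ci_red": list(est.ci_red) if est.ci_red else None,
        "ci_green": list(est.ci_green) if est.ci_green else None,
        "n_boot": est.n_boot,
        "seed": seed,
    }
    report["display"] = {
        "observed_pct": {k: round(v, 1) for k, v in report["observed_pct"].items()},
        "expected_pct": {k: round(v, 1) for k, v in report["expected_pct"].items()},
        "p_le": float(f"{test.p_le:.3g}"),
        "f_red_pct": round(100.0 * est.f_red, 1),
        "f_green_pct": round(100.0 * est.f_green, 1),
    }
    return report
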