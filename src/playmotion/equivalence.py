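"""Observed-vs-estimated activity volumes: median differences and TOST.

Per child and intensity class, the percentage of time is the class's share
of valid epochs (x100).  Agreement between directly observed and
classifier-estimated shares is summarized by the per-child paired
differences (estimated - observed; negative = underestimate), their median
with a seeded percentile-bootstrap 90% CI, and a nonparametric Two
One-Sided Tests (TOST) equivalence procedure at margins of 10% and 20%:
two one-sided Wilcoxon signed-rank tests of the shifted differences, with
the larger of the two one-sided p-values reported and equivalence declared
at alpha = 0.05.  A sign-test TOST is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

INTENSITIES = ("SED", "LPA", "MVPA")


def time_shares(observed: pd.DataFrame, estimated: pd.DataFrame) -> pd.DataFrame:
    """Per-child observed and estimated %time per intensity class.

    Inputs carry columns ``child_id`` and ``intensity`` (one row per valid
    epoch).  Children with zero valid epochs in either source are excluded
    with a warning.  Within each source a child's three shares sum to 100.
    """
    for name, df in (("observed", observed), ("estimated", estimated)):
        if not {"child_id", "intensity"}.issubset(df.columns):
            raise ValueError(f"{name} needs child_id and intensity columns")
    children = sorted(set(observed["child_id"]) | set(estimated["child_id"]))
    rows = []
    for child in children:
        obs = observed[observed["child_id"] == child]
        est = estimated[estimated["child_id"] == child]
        if len(obs) == 0 or len(est) == 0:
            warnings.warn(f"child {child!r} has no valid epochs; excluded", stacklevel=2)
            continue
        for cls in INTENSITIES:
            rows.append(
                {
                    "child_id": child,
                    "intensity": cls,
                    "observed_pct": 100.0 * (obs["intensity"] == cls).mean(),
                    "estimated_pct": 100.0 * (est["intensity"] == cls).mean(),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class EquivalenceResult:
    intensity: str | None
    delta: float
    median_difference: float
    ci90: tuple[float, float]
    p_value: float
    equivalent: bool
    n: int


def _one_sided_wilcoxon(shifted: np.ndarray, alternative: str) -> float:
    if np.all(shifted == 0):
        # degenerate: every difference sits exactly on the margin
        return 0.5
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(
            stats.wilcoxon(
                shifted, alternative=alternative, zero_method="zsplit", method="auto"
            ).pvalue
        )


def _one_sided_sign(shifted: np.ndarray, alternative: str) -> float:
    n_pos = int(np.sum(shifted > 0))
    n_neg = int(np.sum(shifted < 0))
    n = n_pos + n_neg
    if n == 0:
        return 0.5
    if alternative == "greater":  # H1: median > shift point
        return float(stats.binom.cdf(n_neg, n, 0.5))
    return float(stats.binom.cdf(n_pos, n, 0.5))


def tost(
    diffs,
    delta: float,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
    method: str = "wilcoxon",
    intensity: str | None = None,
) -> EquivalenceResult:
    """Nonparametric TOST for equivalence of paired %time differences.

    Rejecting both H0: median(diff) <= -delta and H0: median(diff) >= +delta
    (each via a one-sided signed-rank or sign test on the shifted
    differences) declares the sources equivalent within +-delta.  The
    reported p-value is the larger of the two one-sided p-values.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 5:
        raise ValueError("need at least 5 paired differences")
    if delta <= 0:
        raise ValueError("delta must be positive")
    one_sided = _one_sided_wilcoxon if method == "wilcoxon" else _one_sided_sign
    if method not in ("wilcoxon", "sign"):
        raise ValueError("method must be 'wilcoxon' or 'sign'")
    p_lower = one_sided(d + delta, "greater")   # H0: median <= -delta
    p_upper = one_sided(d - delta, "less")      # H0: median >= +delta
    p = max(p_lower, p_upper)
    rng = np.random.default_rng(seed)
    boots = np.median(
        d[rng.integers(0, d.size, size=(n_boot, d.size))], axis=1
    )
    ci = (float(np.percentile(boots, 5)), float(np.percentile(boots, 95)))
    return EquivalenceResult(
        intensity=intensity,
        delta=float(delta),
        median_difference=float(np.median(d)),
        ci90=ci,
        p_value=p,
        equivalent=bool(p < alpha),
        n=int(d.size),
    )


def run_equivalence(
    shares: pd.DataFrame,
    deltas=(10.0, 20.0),
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
    method: str = "wilcoxon",
) -> list[EquivalenceResult]:
    """TOST per intensity class and margin on a :func:`time_shares` table."""
    results = []
    for cls in INTENSITIES:
        sub = shares[shares["intensity"] == cls]
        d = (sub["estimated_pct"] - sub["observed_pct"]).to_numpy(float)
        for delta in deltas:
            results.append(
                tost(
                    d, delta, alpha=alpha, n_boot=n_boot, seed=seed,
                    method=method, intensity=cls,
                )
            )
    return results


def equivalence_table(results: list[EquivalenceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "intensity": [r.intensity for r in results],
            "delta_pct": [r.delta for r in results],
            "median_difference_pct": [r.median_difference for r in results],
            "ci90_lower": [r.ci90[0] for r in results],
            "ci90_upper": [r.ci90[1] for r in results],
            "p_value": [r.p_value for r in results],
            "equivalent": [r.equivalent for r in results],
            "n_children": [r.n for r in results],
        }
    )
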