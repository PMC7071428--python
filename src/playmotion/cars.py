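"""Direct-observation ground truth: CARS codes, epochs, and rater reliability.

Second-by-second observation codes (1 lying/sitting, 2 standing, 3 walking,
4 running/jumping, 5 not in frame) are reintegrated into 5-s epochs with a
weighted average — each code weighted by its frequency in the epoch, which
equals the arithmetic mean of the scored codes — and the weighted score is
recoded into intensity classes:

    SED  score < 2;  LPA  2 <= score < 3;  MVPA  score >= 3.

Code-5 (not in frame) seconds are dropped from the epoch mean; an epoch is
missing only when every second is code 5.  Inter-rater reliability of the
epoch-level weighted scores is the two-way random-effects, absolute-
agreement, single-measure intraclass correlation, ICC(2,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

VALID_CODES = frozenset({1, 2, 3, 4, 5})
NOT_IN_FRAME = 5


@dataclass
class EpochIntensity:
    child_id: str | None
    epoch_index: int
    weighted_score: float
    intensity: str
    n_scored_seconds: int


def recode(score: float, cut_sed: float = 2.0, cut_mvpa: float = 3.0) -> str:
    if score < cut_sed:
        return "SED"
    if score < cut_mvpa:
        return "LPA"
    return "MVPA"


def reintegrate(
    codes,
    child_id: str | None = None,
    epoch_index: int = 0,
    cut_sed: float = 2.0,
    cut_mvpa: float = 3.0,
) -> EpochIntensity | None:
    """Weighted-average reintegration of one epoch's codes (1-5 of them).

    Returns None (missing epoch) when no scored (non-code-5) second exists.
    """
    codes = [int(c) for c in codes]
    if not 1 <= len(codes) <= 5:
        raise ValueError("an epoch holds 1-5 second-level codes")
    if any(c not in VALID_CODES for c in codes):
        raise ValueError(f"codes must be in {sorted(VALID_CODES)}")
    scored = [c for c in codes if c != NOT_IN_FRAME]
    if not scored:
        return None
    # sum(code * freq(code)) / sum(freq(code)) over codes 1..4 == plain mean
    score = float(np.mean(scored))
    return EpochIntensity(
        child_id=child_id,
        epoch_index=epoch_index,
        weighted_score=score,
        intensity=recode(score, cut_sed, cut_mvpa),
        n_scored_seconds=len(scored),
    )


def reintegrate_stream(records: pd.DataFrame, epoch_s: int = 5, **cuts) -> pd.DataFrame:
    """Reintegrate a child_id/second/code table into epoch intensities.

    Missing epochs (all seconds not-in-frame) are omitted from the output.
    """
    required = {"child_id", "second", "code"}
    if not required.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    rows = []
    for child, grp in records.groupby("child_id", sort=True):
        grp = grp.sort_values("second")
        for epoch, sub in grp.groupby(grp["second"] // epoch_s, sort=True):
            ep = reintegrate(
                sub["code"].tolist(), child_id=child, epoch_index=int(epoch), **cuts
            )
            if ep is not None:
                rows.append(
                    {
                        "child_id": ep.child_id,
                        "epoch_index": ep.epoch_index,
                        "weighted_score": ep.weighted_score,
                        "intensity": ep.intensity,
                        "n_scored_seconds": ep.n_scored_seconds,
                    }
                )
    return pd.DataFrame(rows)


def icc(rater_a, rater_b, form: str = "agreement") -> float:
    """Single-measure two-way random-effects ICC between two raters.

    ``form='agreement'`` gives ICC(2,1) (absolute agreement, the
    conventional choice for coder reliability); ``form='consistency'``
    gives ICC(3,1).  Returns NaN with a warning when both raters are
    constant (no between-target variance to apportion).
    """
    a = np.asarray(rater_a, dtype=float)
    b = np.asarray(rater_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("raters must be paired 1-D score arrays")
    if a.size < 2:
        raise ValueError("need at least 2 epochs")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        warnings.warn("zero variance in both raters; ICC undefined", stacklevel=2)
        return float("nan")
    import pingouin as pg  # noqa: PLC0415

    n = a.size
    df = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "score": np.concatenate([a, b]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=df, targets="target", raters="rater", ratings="score"
        )
    key = "ICC(A,1)" if form == "agreement" else "ICC(C,1)"
    value = table.loc[table["Type"] == key, "ICC"].iloc[0]
    return float(value)


def read_cars_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"child_id", "second", "code"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df
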