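"""Hit calling for reporter screens: Student's t-test and SSMD.

Two complementary decision rules are used on each (miRNA, reporter)
interaction:

* a classic two-sample Student t-test (pooled variance, two-sided) of the
  interaction's normalized replicate ratios against the same-plate control
  ratios, with a positive call requiring both P < alpha and repression
  (fold change < 1);
* the strictly standardized mean difference (SSMD),
  beta = (mu_test - mu_control) / sqrt(sigma_test^2 + sigma_control^2),
  an effect-size statistic for high-throughput screens, thresholded on the
  dual-flashlight scale: <= -2 "strong", <= -3 "extreme" down-regulation.

The default SSMD estimator is the method-of-moments plug-in with sample
variances; a UMVUE-style small-sample correction is available via
``estimator="umvue"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

SSMD_STRONG_CUT = -2.0
SSMD_EXTREME_CUT = -3.0

CLASS_NONE = "none"
CLASS_STRONG = "strong"
CLASS_EXTREME = "extreme"


@dataclass
class InteractionResult:
    """Per-interaction statistics and classification labels."""

    mirna_id: str
    reporter_id: str
    replicates: np.ndarray
    controls: np.ndarray
    fold_change: float
    t_stat: float = math.nan
    p_value: float = math.nan
    ssmd: float = math.nan
    t_positive: bool = False
    up_regulated: bool = False
    ssmd_class: str = CLASS_NONE
    plate_ids: tuple = field(default_factory=tuple)


def student_t_test(test, control) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample t-test.

    Classic Student's test with df = n1 + n2 - 2. Degenerate input (both
    groups constant and equal) yields (t=0, p=1); constant groups with
    different means yield t = +/-inf, p -> 0.

    Returns
    -------
    (t statistic, two-sided p-value), p in (0, 1].
    """
    test = np.asarray(test, dtype=float)
    control = np.asarray(control, dtype=float)
    if test.size < 2 or control.size < 2:
        raise InputError(
            f"t-test needs >= 2 values per group, got {test.size} and {control.size}"
        )
    sp2 = (
        (test.size - 1) * test.var(ddof=1) + (control.size - 1) * control.var(ddof=1)
    ) / (test.size + control.size - 2)
    if sp2 == 0.0:
        if test.mean() == control.mean():
            return 0.0, 1.0
        t = math.inf if test.mean() > control.mean() else -math.inf
        logger.warning("zero pooled variance with unequal means; t = %s", t)
        return t, float(np.nextafter(0.0, 1.0))
    t, p = stats.ttest_ind(test, control, equal_var=True)
    return float(t), float(p)


def ssmd_mm(test, control, estimator: str = "mm") -> float:
    """Strictly standardized mean difference of test versus control.

    Method-of-moments estimate (``estimator="mm"``, default):
    (mean_t - mean_c) / sqrt(s_t^2 + s_c^2) with sample (ddof=1) variances.
    ``estimator="umvue"`` applies Zhang's small-sample correction, dividing
    the pooled spread term by K = n1 + n2 - 3.48 instead of n1 + n2 - 2.

    Zero combined variance returns a signed infinity sentinel (0 when the
    means are also equal), with a warning.
    """
    test = np.asarray(test, dtype=float)
    control = np.asarray(control, dtype=float)
    if test.size < 2 or control.size < 2:
        raise InputError(
            f"SSMD needs >= 2 values per group, got {test.size} and {control.size}"
        )
    diff = test.mean() - control.mean()
    if estimator == "mm":
        denom2 = test.var(ddof=1) + control.var(ddof=1)
    elif estimator == "umvue":
        k = test.size + control.size - 3.48
        denom2 = (
            2.0
            * ((test.size - 1) * test.var(ddof=1) + (control.size - 1) * control.var(ddof=1))
            / k
        )
    else:
        raise InputError(f"unknown SSMD estimator {estimator!r}")
    if denom2 == 0.0:
        logger.warning("zero combined variance in SSMD; returning sentinel")
        if diff == 0.0:
            return 0.0
        return math.inf if diff > 0 else -math.inf
    return float(diff / math.sqrt(denom2))


def classify_dual_flashlight(
    ssmd: float,
    fold_change: float,
    strong_cut: float = SSMD_STRONG_CUT,
    extreme_cut: float = SSMD_EXTREME_CUT,
) -> str:
    """Classify an interaction's effect size on the dual-flashlight scale.

    ``extreme`` if ssmd <= extreme_cut (default -3), ``strong`` if
    extreme_cut < ssmd <= strong_cut (default -2), else ``none``.
    Non-finite SSMD is classified ``none`` with a warning.
    """
    if extreme_cut > strong_cut:
        raise InputError(
            f"extreme_cut ({extreme_cut}) must be <= strong_cut ({strong_cut})"
        )
    if not math.isfinite(ssmd):
        logger.warning("non-finite SSMD %r classified as %s", ssmd, CLASS_NONE)
        return CLASS_NONE
    if ssmd <= extreme_cut:
        return CLASS_EXTREME
    if ssmd <= strong_cut:
        return CLASS_STRONG
    return CLASS_NONE


def score_interaction(
    mirna_id: str,
    reporter_id: str,
    replicates,
    controls,
    plate_ids=(),
    alpha: float = 0.05,
    strong_cut: float = SSMD_STRONG_CUT,
    extreme_cut: float = SSMD_EXTREME_CUT,
    ssmd_estimator: str = "mm",
) -> InteractionResult:
    """Compute fold change, t-test, SSMD and labels for one interaction."""
    replicates = np.asarray(replicates, dtype=float)
    controls = np.asarray(controls, dtype=float)
    fc = float(replicates.mean())
    t, p = student_t_test(replicates, controls)
    ssmd = ssmd_mm(replicates, controls, estimator=ssmd_estimator)
    return InteractionResult(
        mirna_id=mirna_id,
        reporter_id=reporter_id,
        replicates=replicates,
        controls=controls,
        fold_change=fc,
        t_stat=t,
        p_value=p,
        ssmd=ssmd,
        t_positive=(p < alpha and fc < 1.0),
        up_regulated=(p < alpha and fc > 1.0),
        ssmd_class=classify_dual_flashlight(ssmd, fc, strong_cut, extreme_cut),
        plate_ids=tuple(plate_ids),
    )


def call_hits(results: list[InteractionResult], alpha: float = 0.05) -> pd.DataFrame:
    """Label interactions positive (repressing, significant) or not.

    An interaction is positive iff p < alpha and fold change < 1.
    Significant up-regulation (p < alpha, fold > 1) is flagged in its own
    column but never counted positive — the screen's readout is inhibition.
    """
    rows = []
    for r in results:
        positive = r.p_value < alpha and r.fold_change < 1.0
        rows.append(
            {
                "mirna_id": r.mirna_id,
                "reporter_id": r.reporter_id,
                "fold_change": r.fold_change,
                "t_stat": r.t_stat,
                "p_value": r.p_value,
                "ssmd": r.ssmd,
                "ssmd_class": r.ssmd_class,
                "positive": positive,
                "up_regulated": (r.p_value < alpha and r.fold_change > 1.0),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "reporter_id",
            "fold_change",
            "t_stat",
            "p_value",
            "ssmd",
            "ssmd_class",
            "positive",
            "up_regulated",
        ],
    )
    if not df.empty:
        # BH-adjusted p-values emitted for information only; never used in calls
        df["p_bh"] = _benjamini_hochberg(df["p_value"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def positive_rate(positives: int, tested: int) -> float:
    """Percentage of positive interactions among tested, one decimal."""
    if tested <= 0:
        raise InputError("positive_rate of an empty subset")
    return round_half_up(100.0 * positives / tested, 1)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, matching report-table formatting."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
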