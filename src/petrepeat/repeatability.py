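"""Test-retest repeatability statistics for paired lesion features.

The central quantity is the per-lesion natural-log ratio

    r = ln(retest / test)

of a feature.  Because patients contribute multiple lesions and share
scan-level conditions, the r of one patient's lesions are correlated; the
standard deviation sigma entering the 95% limits of agreement is therefore
estimated with a one-way random-effects decomposition (patients as groups)
for repeated observations per individual:

    d_bar        = mean of r over all lesions
    MS_between   = sum_i m_i (rbar_i - d_bar)^2 / (n - 1)
    MS_within    = sum_ij (r_ij - rbar_i)^2 / (N - n)
    m_0          = (N - sum_i m_i^2 / N) / (n - 1)
    var_between  = max(0, (MS_between - MS_within) / m_0)
    sigma        = sqrt(var_between + MS_within)

and the limits of agreement are back-transformed to percentages:

    95% LOA = (exp(d_bar -/+ 1.96 sigma) - 1) x 100.

Also provided: the intraclass correlation (two-way absolute-agreement,
single measurement, with lesions as subjects and the two scans as raters),
the within-subject coefficient of variation, and strict volume-threshold
stratification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .cohort import FEATURES
from .errors import InsufficientDataError, ParameterError, ValidationError

__all__ = [
    "VarianceComponents",
    "LimitsOfAgreement",
    "DEFAULT_THRESHOLDS_CC",
    "pairs_from_long",
    "pairs_to_long",
    "log_ratios",
    "variance_components",
    "limits_of_agreement",
    "icc",
    "wcov",
    "filter_by_volume",
    "repeatability_table",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS_CC = (1.0, 1.5)

#: Columns of the Table-1-style report emitted by :func:`repeatability_table`.
REPORT_COLUMNS = [
    "feature",
    "stratum",
    "n_lesions",
    "bias_pct",
    "loa_lower_pct",
    "loa_upper_pct",
    "icc",
    "wcov_pct",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Pieces of the multiple-observations-per-individual sigma estimate."""

    d_bar: float
    ms_between: float
    ms_within: float
    m0: float
    var_between: float
    sigma: float
    n_patients: int
    n_lesions: int


class LimitsOfAgreement(NamedTuple):
    bias_pct: float
    loa_lower_pct: float
    loa_upper_pct: float


def _require_feature(feature: str) -> None:
    if feature not in FEATURES:
        raise ParameterError(f"unknown feature {feature!r}; expected one of {FEATURES}")


def _pair_values(pairs: pd.DataFrame, feature: str) -> tuple[np.ndarray, np.ndarray]:
    _require_feature(feature)
    for col in (f"{feature}_test", f"{feature}_retest"):
        if col not in pairs.columns:
            raise ValidationError(f"pair table missing column {col!r}")
    a = pairs[f"{feature}_test"].to_numpy(dtype=float)
    b = pairs[f"{feature}_retest"].to_numpy(dtype=float)
    bad = ~((a > 0) & (b > 0) & np.isfinite(a) & np.isfinite(b))
    if bad.any():
        i = int(np.argmax(bad))
        raise ValidationError(
            f"nonpositive or non-finite {feature} for patient "
            f"{pairs['patient_id'].iloc[i]}, lesion {pairs['lesion_id'].iloc[i]}"
        )
    return a, b


def pairs_from_long(frame: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long feature table (one row per lesion per timepoint) into the
    wide matched-pair table; lesions lacking either timepoint are dropped."""
    wide = frame.pivot_table(
        index=["patient_id", "lesion_id"],
        columns="timepoint",
        values=list(FEATURES),
        aggfunc="first",
    )
    wide = wide.dropna()
    out = pd.DataFrame(index=wide.index)
    for f in FEATURES:
        out[f"{f}_test"] = wide[(f, "test")]
        out[f"{f}_retest"] = wide[(f, "retest")]
    return out.reset_index()


def pairs_to_long(pairs: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`pairs_from_long` (up to row order)."""
    frames = []
    for tp in ("test", "retest"):
        sub = pairs[["patient_id", "lesion_id"] + [f"{f}_{tp}" for f in FEATURES]].copy()
        sub.columns = ["patient_id", "lesion_id"] + list(FEATURES)
        sub.insert(2, "timepoint", tp)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def log_ratios(pairs: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Per-lesion r = ln(retest/test); columns patient_id, lesion_id, log_ratio."""
    a, b = _pair_values(pairs, feature)
    return pd.DataFrame(
        {
            "patient_id": pairs["patient_id"].to_numpy(),
            "lesion_id": pairs["lesion_id"].to_numpy(),
            "log_ratio": np.log(b / a),
        }
    )


def variance_components(samples: pd.DataFrame) -> VarianceComponents:
    """One-way random-effects decomposition of log-ratios grouped by patient.

    With a single patient (or all patients contributing one lesion each) the
    estimate reduces to the ordinary sample SD of r.
    """
    if len(samples) < 2:
        raise InsufficientDataError("variance_components needs at least 2 log-ratio samples")
    r = samples["log_ratio"].to_numpy(dtype=float)
    groups = samples["patient_id"].to_numpy()
    N = len(r)
    d_bar = float(r.mean())
    uniq, inverse, counts = np.unique(groups, return_inverse=True, return_counts=True)
    n = len(uniq)
    if n == 1:
        sd = float(np.std(r, ddof=1))
        return VarianceComponents(
            d_bar=d_bar,
            ms_between=0.0,
            ms_within=sd**2,
            m0=1.0,
            var_between=0.0,
            sigma=sd,
            n_patients=1,
            n_lesions=N,
        )
    group_means = np.bincount(inverse, weights=r) / counts
    ms_between = float(np.sum(counts * (group_means - d_bar) ** 2) / (n - 1))
    if N == n:  # every patient contributes one lesion: no within-patient replication
        ms_within = 0.0
    else:
        ms_within = float(np.sum((r - group_means[inverse]) ** 2) / (N - n))
    m0 = float((N - np.sum(counts**2) / N) / (n - 1))
    var_between = max(0.0, (ms_between - ms_within) / m0)
    return VarianceComponents(
        d_bar=d_bar,
        ms_between=ms_between,
        ms_within=ms_within,
        m0=m0,
        var_between=var_between,
        sigma=math.sqrt(var_between + ms_within),
        n_patients=n,
        n_lesions=N,
    )


def limits_of_agreement(vc: VarianceComponents) -> LimitsOfAgreement:
    """Back-transform (d_bar, sigma) to percentage bias and 95% LOA.

    bias = (e^d_bar - 1) x 100; bounds = (e^(d_bar -/+ 1.96 sigma) - 1) x 100.
    The multiplier is fixed at 1.96 (normal 95% quantile), not a t quantile.
    """
    return LimitsOfAgreement(
        bias_pct=(math.exp(vc.d_bar) - 1.0) * 100.0,
        loa_lower_pct=(math.exp(vc.d_bar - 1.96 * vc.sigma) - 1.0) * 100.0,
        loa_upper_pct=(math.exp(vc.d_bar + 1.96 * vc.sigma) - 1.0) * 100.0,
    )


def icc(pairs: pd.DataFrame, feature: str, variant: str = "two_way") -> float:
    """Intraclass correlation of the raw feature values.

    ``variant="two_way"`` (default): two-way absolute-agreement single-
    measurement ICC with lesions as subjects (n) and the two scans as the
    k = 2 repeated measurements,

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)).

    ``variant="one_way"``: one-way random-effects ICC(1,1),
    (MS_B - MS_W) / (MS_B + (k-1) MS_W).
    """
    if variant not in ("two_way", "one_way"):
        raise ParameterError(f"unknown ICC variant {variant!r}")
    a, b = _pair_values(pairs, feature)
    n = len(a)
    if n < 2:
        raise InsufficientDataError("icc needs at least 2 lesion pairs")
    x = np.column_stack([a, b])  # n subjects x k=2 measurements
    k = 2
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(row_means, row_means[0]):
        raise ValidationError("ICC undefined: zero between-lesion variance")
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ms_r = ss_rows / (n - 1)
    if variant == "one_way":
        ss_within = ss_total - ss_rows
        ms_w = ss_within / (n * (k - 1))
        return float((ms_r - ms_w) / (ms_r + (k - 1) * ms_w))
    ss_err = ss_total - ss_rows - ss_cols
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return float((ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)))


def wcov(pairs: pd.DataFrame, feature: str, method: str = "rms") -> float:
    """Within-subject coefficient of variation, in percent.

    ``method="rms"`` (default): per lesion, within-pair SD = |x1 - x2|/sqrt(2)
    and pair mean m; wCOV = 100 sqrt(mean of (SD/m)^2).
    ``method="pooled"``: 100 x (pooled within-pair SD) / (grand mean).
    """
    if method not in ("rms", "pooled"):
        raise ParameterError(f"unknown wCOV method {method!r}")
    a, b = _pair_values(pairs, feature)
    sd = np.abs(a - b) / math.sqrt(2.0)
    m = (a + b) / 2.0
    if method == "rms":
        return float(100.0 * math.sqrt(np.mean((sd / m) ** 2)))
    return float(100.0 * math.sqrt(np.mean(sd**2)) / m.mean())


def filter_by_volume(
    pairs: pd.DataFrame, threshold_cc: float, statistic: str = "mean"
) -> pd.DataFrame:
    """Retain pairs whose lesion volume exceeds ``threshold_cc`` (strictly).

    The volume assigned to a lesion is the mean of its test and retest
    ``volume_cc`` by default (``statistic="mean"``); ``statistic="test"``
    uses the test-scan volume alone.
    """
    if threshold_cc < 0:
        raise ParameterError("threshold_cc must be nonnegative")
    if statistic not in ("mean", "test"):
        raise ParameterError(f"unknown volume statistic {statistic!r}")
    if statistic == "mean":
        vol = (pairs["volume_cc_test"] + pairs["volume_cc_retest"]) / 2.0
    else:
        vol = pairs["volume_cc_test"]
    return pairs.loc[vol > threshold_cc].reset_index(drop=True)


def repeatability_table(
    pairs: pd.DataFrame,
    features: Iterable[str] = FEATURES,
    thresholds_cc: Iterable[float] = DEFAULT_THRESHOLDS_CC,
    *,
    icc_variant: str = "two_way",
    wcov_method: str = "rms",
    volume_statistic: str = "mean",
) -> pd.DataFrame:
    """Full stratified repeatability report, one row per feature x stratum.

    Strata are "all" plus one per volume threshold; each stratum uses the
    same filtered pair set for every feature.  A stratum with fewer than two
    pairs is skipped with a logged warning.  Columns: feature, stratum,
    n_lesions, bias_pct, loa_lower_pct, loa_upper_pct, icc, wcov_pct.
    """
    if len(pairs) == 0:
        raise InsufficientDataError("repeatability_table needs a nonempty pair table")
    strata: list[tuple[str, pd.DataFrame]] = [("all", pairs)]
    for t in thresholds_cc:
        strata.append((f">{t:g}cc", filter_by_volume(pairs, t, statistic=volume_statistic)))
    rows = []
    for label, sub in strata:
        if len(sub) < 2:
            logger.warning("stratum %s has %d pairs; skipped", label, len(sub))
            continue
        for feature in features:
            vc = variance_components(log_ratios(sub, feature))
            loa = limits_of_agreement(vc)
            rows.append(
                {
                    "feature": feature,
                    "stratum": label,
                    "n_lesions": len(sub),
                    "bias_pct": loa.bias_pct,
                    "loa_lower_pct": loa.loa_lower_pct,
                    "loa_upper_pct": loa.loa_upper_pct,
                    "icc": icc(sub, feature, variant=icc_variant),
                    "wcov_pct": wcov(sub, feature, method=wcov_method),
                }
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
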