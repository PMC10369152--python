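"""Test-retest and between-pipeline agreement statistics.

Implements the reliability battery used to validate automated PET
quantification against repeated sessions or a second pipeline: two-way
mixed-model intraclass correlation (single measures), within-subject
absolute percentage test-retest difference (%VAR), Bland-Altman bias
and 95% limits of agreement, Pearson correlation and mean absolute
percentage difference (MAPD).

The ICC is computed from the subject x session ANOVA decomposition.
"Two-way mixed" is reported in SPSS terminology; the default here is
the consistency form ICC(3,1) = (BMS - EMS) / (BMS + (k-1) EMS), which
is invariant to a constant per-session shift — appropriate when a fixed
pipeline/session offset should not count as disagreement.  The absolute
agreement form ICC(2,1)-style (including the session variance term) is
available via ``kind="agreement"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PairedOutcomes:
    """Matched session-1 / session-2 values for a set of subjects."""

    subjects: tuple
    session1: np.ndarray
    session2: np.ndarray
    outcome: str = ""

    def __post_init__(self):
        s1 = np.asarray(self.session1, dtype=float)
        s2 = np.asarray(self.session2, dtype=float)
        object.__setattr__(self, "session1", s1)
        object.__setattr__(self, "session2", s2)
        object.__setattr__(self, "subjects", tuple(self.subjects))
        if not (len(self.subjects) == s1.size == s2.size):
            raise ValueError("subjects and both sessions must have equal length")
        if s1.size < 2:
            raise ValueError("need at least 2 subjects")
        if not (np.all(np.isfinite(s1)) and np.all(np.isfinite(s2))):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return self.session1.size

    @property
    def table(self) -> np.ndarray:
        """n x 2 matrix, subjects in rows, sessions in columns."""
        return np.column_stack([self.session1, self.session2])


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    var_pct: float
    bias: float
    loa_low: float
    loa_high: float
    pearson_r: float
    mapd_pct: float
    outcome: str = ""

    def to_dict(self) -> dict:
        return {k: (v if isinstance(v, str) else float(v))
                for k, v in self.__dict__.items()}


def _anova_mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    """(BMS, JMS, EMS): between-subject, between-session and residual
    mean squares of the two-way subjects x sessions ANOVA."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = table - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    bms = ss_rows / (n - 1)
    jms = ss_cols / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    return float(bms), float(jms), float(ems)


def icc_two_way(data: PairedOutcomes, kind: str = "consistency") -> float:
    """Two-way mixed-model single-measures ICC.

    ``kind="consistency"`` (default): (BMS - EMS)/(BMS + (k-1) EMS).
    ``kind="agreement"``: adds the session variance component to the
    denominator, penalizing systematic session offsets.
    """
    if data.n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    table = data.table
    if np.ptp(table) == 0:
        raise ValueError("zero total variance: ICC undefined")
    n, k = table.shape
    bms, jms, ems = _anova_mean_squares(table)
    if kind == "consistency":
        denom = bms + (k - 1) * ems
        if denom == 0:
            raise ValueError("zero variance: ICC undefined")
        return (bms - ems) / denom
    if kind == "agreement":
        denom = bms + (k - 1) * ems + k * (jms - ems) / n
        if denom == 0:
            raise ValueError("zero variance: ICC undefined")
        return (bms - ems) / denom
    raise ValueError(f"unknown ICC kind {kind!r}")


def icc_confidence_interval(data: PairedOutcomes, alpha: float = 0.05
                            ) -> tuple[float, float]:
    """F-distribution CI for the consistency ICC(3,1)."""
    table = data.table
    n, k = table.shape
    bms, _, ems = _anova_mean_squares(table)
    if ems == 0:
        return (1.0, 1.0)
    f_obs = bms / ems
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_u = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_l = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (f_u - 1) / (f_u + k - 1)
    hi = (f_l - 1) / (f_l + k - 1)
    return float(lo), float(hi)


def percent_var(data: PairedOutcomes) -> float:
    """Mean absolute percentage test-retest difference (%VAR).

    Per subject: 100 * |test - retest| / mean(test, retest); pairs with
    zero mean are excluded with a warning.
    """
    s1, s2 = data.session1, data.session2
    pair_mean = (s1 + s2) / 2.0
    ok = pair_mean != 0
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} zero-mean pair(s) "
                      "from %VAR", RuntimeWarning)
    if not ok.any():
        raise ValueError("no usable pairs for %VAR")
    return float(np.mean(100.0 * np.abs(s1[ok] - s2[ok]) / pair_mean[ok]))


def bland_altman(data: PairedOutcomes) -> dict:
    """Bland-Altman bias and 95% limits of agreement.

    LoA = bias +/- 1.96 * SD(differences) (sample SD).  The per-pair
    differences and averages are returned for plotting.
    """
    diff = data.session1 - data.session2
    avg = (data.session1 + data.session2) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sd_diff": sd,
        "differences": diff.tolist(),
        "averages": avg.tolist(),
    }


def agreement_summary(a, b) -> tuple[float, float]:
    """Pearson r and mean absolute percentage difference between vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(a, b).statistic)
    denom = (a + b) / 2.0
    ok = denom != 0
    mapd = float(np.mean(100.0 * np.abs(a[ok] - b[ok]) / denom[ok]))
    return r, mapd


def reliability_summary(data: PairedOutcomes,
                        icc_kind: str = "consistency") -> ReliabilityResult:
    """Full reliability battery for one outcome."""
    ba = bland_altman(data)
    r, mapd = agreement_summary(data.session1, data.session2)
    return ReliabilityResult(
        icc=icc_two_way(data, kind=icc_kind),
        var_pct=percent_var(data),
        bias=ba["bias"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
        pearson_r=r,
        mapd_pct=mapd,
        outcome=data.outcome,
    )
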