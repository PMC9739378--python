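"""One-way repeated-measures ANOVA for the within-subject condition factor.

Each subject contributes one RMSE per condition, so the total sum of
squares partitions as

    SS_total = SS_subjects + SS_conditions + SS_error

with F = MS_conditions / MS_error on (k-1, (k-1)(n-1)) degrees of freedom.
By default no sphericity correction is applied (the design assumes
sphericity); a Greenhouse-Geisser-corrected variant is available behind a
flag for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

log = logging.getLogger(__name__)


@dataclass
class RepeatedMeasuresMatrix:
    """Subjects x conditions table of a repeated measure (e.g. angle RMSE)."""

    values: np.ndarray
    subjects: list[str]
    conditions: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape if self.values.ndim == 2 else (0, 0)
        if n < 2 or k < 2:
            raise InputError("need >= 2 subjects and >= 2 conditions")
        if len(self.subjects) != n or len(self.conditions) != k:
            raise InputError("label lengths do not match the value matrix")
        if not np.all(np.isfinite(self.values)):
            raise InputError("repeated-measures matrix must have no missing cells")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str = "rmse_deg",
                   subject_col: str = "subject",
                   condition_col: str = "condition") -> "RepeatedMeasuresMatrix":
        wide = df.pivot(index=subject_col, columns=condition_col, values=value_col)
        if wide.isna().any().any():
            raise InputError("incomplete subject x condition design")
        return cls(values=wide.to_numpy(),
                   subjects=[str(s) for s in wide.index],
                   conditions=[str(c) for c in wide.columns])


@dataclass
class AnovaResult:
    F: float
    df_condition: int
    df_error: int
    p_value: float
    condition_means: dict[str, float]
    ss_conditions: float = 0.0
    ss_subjects: float = 0.0
    ss_error: float = 0.0
    epsilon: float | None = None     # Greenhouse-Geisser ε when corrected


def rm_anova(matrix: RepeatedMeasuresMatrix, gg_correction: bool = False) -> AnovaResult:
    """One-way repeated-measures F test on a complete subjects x conditions table.

    Degenerate designs are resolved deterministically: a zero error mean
    square yields F = 0, p = 1 when the condition effect is also zero, and
    F = inf, p = 0 otherwise (both logged).
    """
    x = matrix.values
    n, k = x.shape
    grand = x.mean()
    subj_means = x.mean(axis=1)
    cond_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_subjects = float(k * ((subj_means - grand) ** 2).sum())
    ss_conditions = float(n * ((cond_means - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_conditions
    ss_error = max(ss_error, 0.0)        # guard tiny negative round-off

    df_c = k - 1
    df_e = (k - 1) * (n - 1)
    ms_c = ss_conditions / df_c
    ms_e = ss_error / df_e

    eps = None
    if ms_e == 0.0:
        if ss_conditions == 0.0:
            log.warning("rm_anova: no variability at all; F := 0, p := 1")
            F, p = 0.0, 1.0
        else:
            log.warning("rm_anova: zero error mean square with a condition "
                        "effect; F := inf, p := 0")
            F, p = float("inf"), 0.0
    else:
        F = ms_c / ms_e
        if gg_correction:
            eps = _greenhouse_geisser_epsilon(x)
            p = float(sps.f.sf(F, eps * df_c, eps * df_e))
        else:
            p = float(sps.f.sf(F, df_c, df_e))
    return AnovaResult(
        F=float(F), df_condition=df_c, df_error=df_e, p_value=p,
        condition_means={c: float(m) for c, m in zip(matrix.conditions, cond_means)},
        ss_conditions=ss_conditions, ss_subjects=ss_subjects, ss_error=ss_error,
        epsilon=eps,
    )


def _greenhouse_geisser_epsilon(x: np.ndarray) -> float:
    """Box/Greenhouse-Geisser ε from the double-centred covariance matrix."""
    k = x.shape[1]
    S = np.cov(x, rowvar=False, bias=True)
    J = np.eye(k) - np.ones((k, k)) / k
    Sc = J @ S @ J
    tr = np.trace(Sc)
    denom = (k - 1) * float((Sc ** 2).sum())
    if denom <= 0:
        return 1.0
    eps = tr ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def significance_table(results: dict[str, AnovaResult], alpha: float = 0.05) -> pd.DataFrame:
    """Per-angle p-values with a strict p < alpha significance flag.

    No multiplicity adjustment is applied; each angle is tested on its own.
    """
    if not results:
        raise InputError("significance_table requires at least one result")
    rows = [
        {"angle": angle, "F": res.F, "df1": res.df_condition, "df2": res.df_error,
         "p_value": res.p_value, "significant": bool(res.p_value < alpha)}
        for angle, res in results.items()
    ]
    return pd.DataFrame(rows).set_index("angle")
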