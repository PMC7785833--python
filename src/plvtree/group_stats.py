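"""Group comparison and clinical correlation of global network metrics.

Between-group contrasts use the non-parametric Mann-Whitney U (Wilcoxon
rank-sum) test, two-sided.  The exact null distribution is used for small
samples (combined n <= 25) without ties; otherwise the normal approximation
with tie correction (no continuity correction, so identical samples give
p = 1 exactly).  Within the patient group, associations between global
metrics and clinical scores (disease duration in years; ALSFRS-R, a 0-48
functional scale where higher is better) use Spearman rank correlation with
average ranks for ties.

No multiple-testing correction is applied by default; ``adjust_pvalues``
offers Benjamini-Hochberg as an opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .graph_metrics import GLOBAL_METRIC_NAMES, GlobalMetrics

PATIENT = "patient"
CONTROL = "control"


@dataclass
class SubjectRecord:
    """One subject: group membership, clinical scores, and tree metrics.

    ``clinical_score`` keeps the raw (continuous) synthetic severity value
    from which the integer ALSFRS-R was derived, so that exact monotone
    relationships survive rounding; real cohorts can leave it NaN.
    """

    subject_id: str
    group: str
    disease_duration: float = float("nan")
    alsfrs_r: int | None = None
    metrics: GlobalMetrics | None = None
    clinical_score: float = float("nan")
    coupling_kappa: float = float("nan")

    def __post_init__(self) -> None:
        if self.group not in (PATIENT, CONTROL):
            raise ValueError(f"group must be '{PATIENT}' or '{CONTROL}'")
        if self.alsfrs_r is not None and not 0 <= self.alsfrs_r <= 48:
            raise ValueError("ALSFRS-R must lie in [0, 48]")
        if not np.isnan(self.disease_duration) and self.disease_duration < 0:
            raise ValueError("disease duration must be non-negative")

    def value(self, name: str) -> float:
        """Look up a metric or clinical field by name."""
        if self.metrics is not None and hasattr(self.metrics, name):
            return float(getattr(self.metrics, name))
        val = getattr(self, name)
        return float("nan") if val is None else float(val)


@dataclass
class MannWhitneyResult:
    statistic: float  # U for the first (patient) sample
    p_value: float
    n_patient: int
    n_control: int
    method: str  # "exact", "asymptotic", or "degenerate"


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int


def _split_groups(records: list[SubjectRecord], name: str):
    x = np.array([r.value(name) for r in records if r.group == PATIENT])
    y = np.array([r.value(name) for r in records if r.group == CONTROL])
    return x, y


def mannwhitney(x: np.ndarray, y: np.ndarray) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test on two samples (patient first).

    Exact distribution when the combined sample is small (n <= 25) and free
    of ties; normal approximation with tie correction otherwise.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 subjects")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        # rank-sum completely degenerate: no evidence of separation
        return MannWhitneyResult(
            statistic=len(x) * len(y) / 2.0, p_value=1.0,
            n_patient=len(x), n_control=len(y), method="degenerate",
        )
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= 25 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        method = "asymptotic"
    return MannWhitneyResult(
        statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
        n_patient=len(x), n_control=len(y), method=method,
    )


def compare_groups(records: list[SubjectRecord], metric_name: str) -> MannWhitneyResult:
    """Mann-Whitney U test of a named metric between patients and controls."""
    x, y = _split_groups(records, metric_name)
    return mannwhitney(x, y)


def correlate_clinical(
    records: list[SubjectRecord],
    metric_name: str,
    clinical_field: str,
    patients_only: bool = True,
) -> SpearmanResult:
    """Spearman rank correlation between a global metric and a clinical score."""
    subset = [r for r in records if (not patients_only) or r.group == PATIENT]
    pairs = [
        (r.value(metric_name), r.value(clinical_field))
        for r in subset
        if np.isfinite(r.value(metric_name)) and np.isfinite(r.value(clinical_field))
    ]
    if len(pairs) < 4:
        raise ValueError("need >= 4 subjects with both values")
    x, y = map(np.asarray, zip(*pairs))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(rho=float("nan"), p_value=float("nan"), n=len(pairs))
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p_value=float(p), n=len(pairs))


def adjust_pvalues(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (opt-in; not applied by default)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float),
                                         method=method)


def group_table(
    records: list[SubjectRecord],
    metric_names: tuple[str, ...] = GLOBAL_METRIC_NAMES,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-metric group means/SDs and Mann-Whitney p-values (Table-style)."""
    rows = []
    for name in metric_names:
        x, y = _split_groups(records, name)
        res = compare_groups(records, name)
        rows.append(
            {
                "metric": name,
                "control_mean": y.mean(),
                "control_sd": y.std(ddof=1),
                "patient_mean": x.mean(),
                "patient_sd": x.std(ddof=1),
                "u_statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    table = pd.DataFrame(rows)
    if adjust:
        table["p_adjusted"] = adjust_pvalues(table["p_value"].to_numpy())
    return table


def clinical_table(
    records: list[SubjectRecord],
    metric_names: tuple[str, ...] = GLOBAL_METRIC_NAMES,
    clinical_fields: tuple[str, ...] = ("disease_duration", "alsfrs_r"),
) -> pd.DataFrame:
    """Spearman correlations of each metric with each clinical score."""
    rows = []
    for name in metric_names:
        for clin in clinical_fields:
            res = correlate_clinical(records, name, clin)
            rows.append(
                {"metric": name, "clinical": clin, "rho": res.rho,
                 "p_value": res.p_value, "n": res.n}
            )
    return pd.DataFrame(rows)
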