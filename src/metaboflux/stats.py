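"""Two-group comparison with normality-based test routing, derived
energetic indices, and the ddCt relative-expression transform.

Routing: both groups must pass Shapiro-Wilk at the routing alpha for the
unpaired Student's t-test (pooled variance); otherwise a two-sided
Mann-Whitney U (exact for min(n) <= 8 without ties, normal approximation
with tie correction otherwise). No multiple-testing correction by default,
mirroring per-metabolite testing at alpha = 0.05; Benjamini-Hochberg is
available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .table import ConcentrationTable

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


@dataclass
class NormalityResult:
    classification: str  # "normal" | "non_normal"
    statistic: float
    p: float


@dataclass
class ComparisonResult:
    metabolite: str
    tissue: str
    test_used: str  # "t" | "mannwhitney"
    statistic: float
    p_value: float
    mean_control: float
    sem_control: float
    mean_treated: float
    sem_treated: float
    n_control: int
    n_treated: int
    significant: bool


def test_normality(values, alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk; classified normal iff p > alpha.

    Undefined for fewer than 3 values or a constant sample.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise StatsError("Shapiro-Wilk needs at least 3 values")
    if np.ptp(x) == 0:
        raise StatsError("Shapiro-Wilk undefined for a constant sample")
    stat, p = sps.shapiro(x)
    return NormalityResult(
        classification="normal" if p > alpha else "non_normal",
        statistic=float(stat), p=float(p),
    )


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(np.concatenate([a, b])) == 0:
        # every labeling is equally extreme; no evidence of a difference
        return float(len(a) * len(b) / 2), 1.0
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan


def compare_groups(
    table: ConcentrationTable,
    metabolite: str,
    tissue: str,
    alpha: float = 0.05,
    welch: bool = False,
) -> ComparisonResult:
    """Route to t-test or Mann-Whitney U on per-group Shapiro-Wilk outcomes.

    Constant samples (where Shapiro-Wilk is undefined) route non-parametric.
    ``significant`` is ``p <= alpha``.
    """
    sub = table.subset(tissue)
    if len(table.group_order) != 2:
        raise StatsError("two-group comparison requires exactly two groups")
    control, treated = table.group_order
    a = sub.values(metabolite, group=control)
    b = sub.values(metabolite, group=treated)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise StatsError(f"{metabolite}/{tissue}: a group has no data")
    if a.size < 3 or b.size < 3:
        raise StatsError(f"{metabolite}/{tissue}: need >= 3 values per group")

    def _normal(x: np.ndarray) -> bool:
        try:
            return test_normality(x, alpha=alpha).classification == "normal"
        except StatsError:
            return False  # constant sample -> non-parametric route

    if _normal(a) and _normal(b):
        res = sps.ttest_ind(a, b, equal_var=not welch)
        test_used, stat, p = "t", float(res.statistic), float(res.pvalue)
    else:
        test_used = "mannwhitney"
        stat, p = _mannwhitney(a, b)
    return ComparisonResult(
        metabolite=metabolite, tissue=tissue, test_used=test_used,
        statistic=stat, p_value=p,
        mean_control=float(a.mean()), sem_control=_sem(a),
        mean_treated=float(b.mean()), sem_treated=_sem(b),
        n_control=int(a.size), n_treated=int(b.size),
        significant=bool(p <= alpha),
    )


def compare_all(
    table: ConcentrationTable,
    tissue: str,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-metabolite comparisons for one tissue as a results frame."""
    rows = []
    for met in table.metabolites:
        try:
            r = compare_groups(table, met, tissue, alpha=alpha)
        except StatsError as exc:
            logger.warning("skipping %s/%s: %s", met, tissue, exc)
            continue
        rows.append({
            "metabolite": r.metabolite, "tissue": r.tissue,
            "test_used": r.test_used, "statistic": r.statistic, "p": r.p_value,
            "mean_sham": r.mean_control, "sem_sham": r.sem_control,
            "mean_rupp": r.mean_treated, "sem_rupp": r.sem_treated,
            "n_sham": r.n_control, "n_rupp": r.n_treated,
            "significant": r.significant,
        })
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["p_adjusted"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["significant"] = out["p_adjusted"] <= alpha
    return out


# ---------------------------------------------------------------------------
# derived energetic indices

INDEX_COMPONENTS = {
    "TAN": ["AMP", "ADP", "ATP"],
    "PCr/ATP": ["PCr", "ATP"],
    "NAD/NADH": ["NAD", "NADH"],
    "succinate/fumarate": ["succinate", "fumarate"],
}


def derived_indices(table: ConcentrationTable) -> ConcentrationTable:
    """Add TAN (= AMP+ADP+ATP), PCr/ATP, NAD/NADH and succinate/fumarate.

    Ratios with denominator <= 0 are flagged missing (NaN) and logged.
    """
    for cols in INDEX_COMPONENTS.values():
        for col in cols:
            if col not in table.data.columns:
                raise StatsError(f"missing component column {col!r}")
    df = table.data.copy()
    df["TAN"] = df["AMP"] + df["ADP"] + df["ATP"]
    for name, (num, den) in (
        ("PCr/ATP", ("PCr", "ATP")),
        ("NAD/NADH", ("NAD", "NADH")),
        ("succinate/fumarate", ("succinate", "fumarate")),
    ):
        denom = df[den].to_numpy(dtype=float)
        bad = ~(denom > 0)
        if bad.any():
            logger.warning(
                "%s undefined for samples %s (denominator <= 0)",
                name, list(df["sample_id"][bad]),
            )
        ratio = np.where(bad, np.nan, df[num].to_numpy(dtype=float) / np.where(bad, 1.0, denom))
        df[name] = ratio
    return ConcentrationTable(df, group_order=list(table.group_order))


# ---------------------------------------------------------------------------
# ddCt

def fold_change_ddct(ct: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Relative expression by the ddCt method.

    Expects columns ``sample_id, group, ct_target, ct_reference``. Per
    sample, dCt = Ct_target - Ct_reference; ddCt = dCt minus the
    control-group mean dCt; fold = 2 ** (-ddCt).
    """
    required = {"sample_id", "group", "ct_target", "ct_reference"}
    if not required <= set(ct.columns):
        raise StatsError(f"CtTable needs columns {sorted(required)}")
    if not np.isfinite(ct[["ct_target", "ct_reference"]].to_numpy(dtype=float)).all():
        raise StatsError("Ct values must be finite")
    if not (ct["group"] == control_group).any():
        raise StatsError(f"control group {control_group!r} absent")
    out = ct.copy()
    out["dct"] = out["ct_target"] - out["ct_reference"]
    control_mean = out.loc[out["group"] == control_group, "dct"].mean()
    out["ddct"] = out["dct"] - control_mean
    out["fold"] = 2.0 ** (-out["ddct"])
    return out
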