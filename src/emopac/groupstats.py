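"""Group-level statistics on behavioral tables and PAC band features.

One-way ANOVAs over the three emotion-induction conditions (neutral /
happy / sad) with Tukey-adjusted pairwise post hocs, Cohen's kappa for
interrater agreement, and Pearson correlations among fronto-parietal PAC
band features within and across conditions, optionally split by gender.

The ANOVA runs in two modes. ``within`` (default) is the repeated-measures
decomposition appropriate for a complete participant x condition design;
``between`` pools all observations and ignores the pairing. Both are kept
because published reports of this design sometimes quote degrees of
freedom matching the pooled decomposition.

No multiple-testing correction is applied across the correlation family by
default (stars reflect unadjusted p-values); a Holm adjustment is
available behind a flag.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

from .pac import AMP_BANDS, PHASE_BANDS, band_feature, feature_label


@dataclasses.dataclass
class PosthocComparison:
    pair: tuple[str, str]
    mean_difference: float
    t: float
    p_adjusted: float


@dataclasses.dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    eta_squared_partial: float
    mode: str
    posthoc: list[PosthocComparison] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class CorrelationResult:
    feature_a: str
    feature_b: str
    path: str
    r: float
    n: int
    p: float
    group: str
    stars: str


@dataclasses.dataclass
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _check_table(table: pd.DataFrame, dv: str) -> None:
    for col in ("participant", "condition", dv):
        if col not in table.columns:
            raise ValueError(f"behavioral table lacks column {col!r}")


def _wide(table: pd.DataFrame, dv: str) -> pd.DataFrame:
    wide = table.pivot(index="participant", columns="condition", values=dv)
    if wide.isna().any().any():
        raise ValueError("within-subject ANOVA needs a complete participant x condition crossing")
    return wide


def oneway_anova(table: pd.DataFrame, dv: str, mode: str = "within") -> AnovaResult:
    """One-way ANOVA over condition with Tukey post hocs.

    ``within``: repeated-measures F with partial eta squared
    SS_cond / (SS_cond + SS_error). ``between``: observations pooled
    across participants.
    """
    _check_table(table, dv)
    if mode == "within":
        import pingouin as pg

        wide = _wide(table, dv)
        if len(wide) < 3:
            raise ValueError("within-subject ANOVA needs at least 3 participants")
        if np.allclose(wide.to_numpy().var(axis=0), 0):
            raise ValueError("zero variance everywhere; F undefined")
        aov = pg.rm_anova(data=table, dv=dv, within="condition",
                          subject="participant", detailed=True)
        ss_cond = float(aov.loc[0, "SS"])
        ss_err = float(aov.loc[1, "SS"])
        result = AnovaResult(
            F=float(aov.loc[0, "F"]),
            df=(int(aov.loc[0, "DF"]), int(aov.loc[1, "DF"])),
            p=float(aov.loc[0, "p_unc"]),
            eta_squared_partial=ss_cond / (ss_cond + ss_err),
            mode=mode,
        )
    elif mode == "between":
        groups = [g[dv].to_numpy() for _, g in table.groupby("condition")]
        if min(len(g) for g in groups) < 2:
            raise ValueError("need at least 2 observations per condition")
        if np.allclose([g.var() for g in groups], 0):
            raise ValueError("zero variance everywhere; F undefined")
        F, p = stats.f_oneway(*groups)
        k = len(groups)
        n_total = sum(len(g) for g in groups)
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        result = AnovaResult(
            F=float(F), df=(k - 1, n_total - k), p=float(p),
            eta_squared_partial=ss_between / (ss_between + ss_within),
            mode=mode,
        )
    else:
        raise ValueError(f"unknown ANOVA mode {mode!r}")
    result.posthoc = tukey_posthoc(table, dv, mode=mode)
    return result


def tukey_posthoc(table: pd.DataFrame, dv: str, mode: str = "within") -> list[PosthocComparison]:
    """All pairwise condition comparisons with Tukey HSD adjustment.

    In ``within`` mode the error term is the repeated-measures residual
    mean square with (k-1)(n-1) degrees of freedom; p-values come from the
    studentized range distribution. ``between`` mode uses the standard
    independent-groups Tukey HSD.
    """
    _check_table(table, dv)
    conditions = sorted(table["condition"].unique())
    k = len(conditions)
    out: list[PosthocComparison] = []
    if mode == "within":
        wide = _wide(table, dv)[conditions]
        values = wide.to_numpy()
        n = values.shape[0]
        grand = values.mean()
        subj_means = values.mean(axis=1, keepdims=True)
        cond_means = values.mean(axis=0, keepdims=True)
        resid = values - subj_means - cond_means + grand
        df_err = (k - 1) * (n - 1)
        ms_err = (resid ** 2).sum() / df_err
        se = np.sqrt(2.0 * ms_err / n)
        for a, b in itertools.combinations(conditions, 2):
            diff = float(wide[a].mean() - wide[b].mean())
            t = diff / se if se > 0 else np.inf * np.sign(diff)
            q = abs(t) * np.sqrt(2.0)
            p_adj = float(np.clip(studentized_range.sf(q, k, df_err), 0.0, 1.0))
            out.append(PosthocComparison((a, b), diff, float(t), p_adj))
    elif mode == "between":
        groups = {c: g[dv].to_numpy() for c, g in table.groupby("condition")}
        res = stats.tukey_hsd(*[groups[c] for c in conditions])
        n_total = sum(len(g) for g in groups.values())
        ms_within = np.mean([g.var(ddof=1) for g in groups.values()])
        for i, a in enumerate(conditions):
            for j, b in enumerate(conditions):
                if j <= i:
                    continue
                diff = float(groups[a].mean() - groups[b].mean())
                se = np.sqrt(ms_within * (1 / len(groups[a]) + 1 / len(groups[b])))
                t = diff / se if se > 0 else np.inf * np.sign(diff)
                out.append(PosthocComparison((a, b), diff, float(t),
                                             float(res.pvalue[i, j])))
    else:
        raise ValueError(f"unknown posthoc mode {mode!r}")
    return out


def cohens_kappa(ratings_a, ratings_b) -> KappaResult:
    """Unweighted Cohen's kappa from two categorical rating vectors."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rating vectors must be equal-length 1-D arrays")
    categories = np.union1d(np.unique(a), np.unique(b))
    if len(categories) < 2:
        raise ValueError("kappa undefined with a single category")
    index = {c: i for i, c in enumerate(categories)}
    table = np.zeros((len(categories), len(categories)))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    return kappa_from_table(table)


def kappa_from_table(table: np.ndarray) -> KappaResult:
    """Cohen's kappa from a square contingency table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    po = np.trace(table) / n
    pe = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if pe == 1.0:
        raise ValueError("kappa undefined: expected agreement is 1")
    return KappaResult(kappa=(po - pe) / (1 - pe), observed_agreement=po,
                       expected_agreement=pe)


# ---------------------------------------------------------------------------
# PAC band-feature correlations
# ---------------------------------------------------------------------------

def pac_feature_table(matrices: dict, genders: dict | None = None) -> pd.DataFrame:
    """Long table of band features from participant PAC matrices.

    ``matrices`` maps (participant_id, condition, path) to a PACMatrix.
    Columns: participant, gender, condition, path, phase_band, amp_band,
    feature (the label used in correlation reports), value.
    """
    rows = []
    for (pid, condition, path), matrix in matrices.items():
        gender = (genders or {}).get(pid, "unknown")
        for pband in PHASE_BANDS:
            for aband in AMP_BANDS:
                rows.append({
                    "participant": pid, "gender": gender, "condition": condition,
                    "path": path, "phase_band": pband, "amp_band": aband,
                    "feature": feature_label(condition, pband, aband),
                    "value": band_feature(matrix, pband, aband),
                })
    return pd.DataFrame(rows)


def pac_correlations(features: pd.DataFrame, group: str = "all",
                     holm: bool = False, min_n: int = 4) -> list[CorrelationResult]:
    """Pearson correlations between all PAC band-feature pairs, per path.

    Pairs cover every combination of (condition, phase band, amplitude
    band) features within a path — both within one condition and across
    conditions. ``group`` restricts to a gender subgroup ('male' /
    'female') or uses everyone ('all'). Zero-variance features are skipped
    with a warning.
    """
    table = features if group == "all" else features[features["gender"] == group]
    results: list[CorrelationResult] = []
    for path, sub in table.groupby("path"):
        wide = sub.pivot(index="participant", columns="feature", values="value")
        if len(wide) < min_n:
            raise ValueError(
                f"need at least {min_n} participants per group (path {path})"
            )
        labels = list(wide.columns)
        for fa, fb in itertools.combinations(labels, 2):
            x, y = wide[fa].to_numpy(), wide[fb].to_numpy()
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"skipping zero-variance pair {fa} vs {fb}", stacklevel=2)
                continue
            r, p = stats.pearsonr(x, y)
            results.append(CorrelationResult(
                feature_a=fa, feature_b=fb, path=path, r=float(r),
                n=len(x), p=float(p), group=group,
                stars=significance_stars(float(p)),
            ))
    if holm:
        order = np.argsort([c.p for c in results])
        m = len(results)
        running = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (m - rank) * results[idx].p)
            running = max(running, adj)
            results[idx].p = running
            results[idx].stars = significance_stars(running)
    return results


def correlations_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in results])
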