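"""Clinical association of deregulated features and prognosis calling.

Each DE feature's tumor-sample expression is compared between clinical
subgroups (Welch t-test, linear group fold change) and, for overall
survival, between median-expression groups with a two-group log-rank test.
A feature is then called *worse-prognostic* when it is up in tumors and
every significant association points to higher expression in the worse
clinical group, *better-prognostic* when it is down in tumors and every
significant association points the other way, and *unclear* otherwise.

Each clinical variable carries a declared "worse" level (higher grade,
absent capsule, invasion present, larger size, later stage, shorter
survival); the coding table below is total over the supported variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust, welch_t_test
from .io import ClinicalTable, ExpressionMatrix, FEATURE_CATEGORY

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupCoding:
    """Binary split of a clinical variable plus which side is prognostically worse."""

    worse: tuple[int, ...]
    better: tuple[int, ...]
    worse_label: str
    better_label: str


#: total worse-level coding for every supported clinical variable
WORSE_CODING: dict[str, GroupCoding] = {
    "grade": GroupCoding((3, 4), (1, 2), "grade 3-4", "grade 1-2"),
    "size_group": GroupCoding((1,), (0,), "large", "small"),
    "encapsulation": GroupCoding((0,), (1,), "capsule absent", "capsule present"),
    "degree_encapsulation": GroupCoding((0,), (1,), "incomplete capsule", "complete capsule"),
    "vascular_invasion": GroupCoding((1,), (0,), "invasion present", "invasion absent"),
    "tumor_invasion": GroupCoding((1,), (0,), "invasion present", "invasion absent"),
    "stage_group": GroupCoding((1,), (0,), "late stage", "early stage"),
}


def associate_binary(
    expr_worse: np.ndarray, expr_better: np.ndarray
) -> tuple[float, float, float]:
    """(group_fc, t, p) of tumor expression between the worse and better groups.

    group_fc = 2**(mean_worse - mean_better) on log2 input; the t-test is
    two-sided Welch.  Each group needs >= 2 non-missing values.
    """
    w = np.asarray(expr_worse, dtype=float)
    b = np.asarray(expr_better, dtype=float)
    w = w[~np.isnan(w)]
    b = b[~np.isnan(b)]
    if w.size < 2 or b.size < 2:
        raise ValueError("each clinical group needs >= 2 samples")
    t, p = welch_t_test(w, b)
    group_fc = float(2.0 ** (w.mean() - b.mean()))
    return group_fc, t, p


def logrank_test(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float]:
    """Two-group log-rank test.

    ``groups`` is boolean/0-1 (group 1 = True).  Returns
    (chi2, p, observed_minus_expected_group1): a positive last term means
    group 1 accumulated more events than expected, i.e. fared worse.
    Computed from the standard risk-set tabulation over distinct event
    times (hypergeometric variance); requires >= 1 event.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups).astype(bool)
    keep = ~np.isnan(t)
    t, e, g = t[keep], e[keep], g[keep]
    if e.sum() < 1:
        raise ValueError("log-rank test requires at least one event")
    if g.all() or (~g).all():
        raise ValueError("log-rank test requires two non-empty groups")

    o_minus_e = 0.0
    var = 0.0
    for tau in np.unique(t[e == 1]):
        at_risk = t >= tau
        n = at_risk.sum()
        n1 = (at_risk & g).sum()
        d = ((t == tau) & (e == 1)).sum()
        d1 = ((t == tau) & (e == 1) & g).sum()
        exp1 = d * n1 / n
        o_minus_e += d1 - exp1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0, float(o_minus_e)
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, float(o_minus_e)


def associate_features(
    matrix: ExpressionMatrix,
    clinical: ClinicalTable,
    de_table: pd.DataFrame,
    clin_fc: float = 1.5,
    clin_p: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Clinical associations for every DE (up/down) feature.

    One row per (feature, clinical variable): binary variables get a Welch
    t-test and group fold change on tumor samples; survival gets a log-rank
    test between median-split tumor-expression groups.  ``significant``
    requires |group FC| beyond ``clin_fc`` and p <= ``clin_p`` (p only, for
    survival).  ``direction`` is higher_in_worse / higher_in_better.
    """
    de_ids = de_table.loc[de_table["status"] != "ns", "feature_id"].tolist()
    patients = clinical.patients
    tumor_ids = [clinical.sample_of(p, "tumor") for p in patients]
    expr = matrix.values.loc[[f for f in de_ids if f in matrix.values.index], tumor_ids]

    records = []
    skipped = 0
    for var, coding in WORSE_CODING.items():
        if var not in clinical.data.columns:
            continue
        vals = clinical.patient_value(var)
        worse_mask = vals.isin(coding.worse).to_numpy()
        better_mask = vals.isin(coding.better).to_numpy()
        if worse_mask.sum() < 2 or better_mask.sum() < 2:
            log.info("associate_features: %s skipped (a group has <2 patients)", var)
            continue
        for fid in expr.index:
            x = expr.loc[fid].to_numpy(dtype=float)
            try:
                group_fc, t, p = associate_binary(x[worse_mask], x[better_mask])
            except ValueError:
                skipped += 1
                continue
            records.append(
                dict(
                    feature_id=fid,
                    clinical_variable=var,
                    category=FEATURE_CATEGORY[var],
                    group_defs=f"{coding.worse_label} vs {coding.better_label}",
                    group_fc=group_fc,
                    statistic=t,
                    p_value=p,
                    direction="higher_in_worse" if group_fc > 1 else "higher_in_better",
                )
            )

    # survival: median split of tumor expression, log-rank
    if {"os_time", "os_event"} <= set(clinical.data.columns):
        times = clinical.patient_value("os_time").to_numpy(dtype=float)
        events = clinical.patient_value("os_event").to_numpy()
        usable = ~np.isnan(times) & ~pd.isna(events)
        for fid in expr.index:
            x = expr.loc[fid].to_numpy(dtype=float)
            keep = usable & ~np.isnan(x)
            if keep.sum() < 4 or events[keep].astype(float).sum() < 1:
                skipped += 1
                continue
            high = x[keep] > np.median(x[keep])
            if high.all() or (~high).all():
                skipped += 1
                continue
            chi2, p, ome_high = logrank_test(
                times[keep], events[keep].astype(int), high
            )
            # high-expression group faring worse => higher expression in the
            # worse-prognosis stratum
            direction = "higher_in_worse" if ome_high > 0 else "higher_in_better"
            records.append(
                dict(
                    feature_id=fid,
                    clinical_variable="survival",
                    category=FEATURE_CATEGORY["survival"],
                    group_defs="high vs low tumor expression (median split)",
                    group_fc=np.nan,
                    statistic=chi2,
                    p_value=p,
                    direction=direction,
                )
            )
    if skipped:
        log.info("associate_features: %d feature-variable tests skipped", skipped)

    df = pd.DataFrame(
        records,
        columns=["feature_id", "clinical_variable", "category", "group_defs",
                 "group_fc", "statistic", "p_value", "direction"],
    )
    if adjust and len(df):
        df["p_adj"] = bh_adjust(df["p_value"].to_numpy())
    p_col = "p_adj" if adjust and len(df) else "p_value"
    if len(df):
        fc_ok = df["group_fc"].isna() | (
            (df["group_fc"] >= clin_fc) | (df["group_fc"] <= 1.0 / clin_fc)
        )
        df["significant"] = fc_ok & (df[p_col] <= clin_p)
    else:
        df["significant"] = pd.Series(dtype=bool)
    return df


def call_prognosis(de_table: pd.DataFrame, assoc: pd.DataFrame) -> pd.DataFrame:
    """Prognosis call per clinically associated feature.

    worse_prognostic: DE status up and all significant associations
    higher_in_worse; better_prognostic: status down and all significant
    associations higher_in_better; anything mixed is unclear.  Features
    with no significant association are not called.  Deterministic and
    order-independent.
    """
    status = de_table.set_index("feature_id")["status"]
    sig = assoc[assoc["significant"]]
    records = []
    for fid in sorted(sig["feature_id"].unique()):
        dirs = set(sig.loc[sig["feature_id"] == fid, "direction"])
        st = status.get(fid, "ns")
        if st == "up" and dirs == {"higher_in_worse"}:
            call = "worse_prognostic"
        elif st == "down" and dirs == {"higher_in_better"}:
            call = "better_prognostic"
        else:
            call = "unclear"
        n_sup = int((sig["feature_id"] == fid).sum())
        vars_ = ",".join(sorted(sig.loc[sig["feature_id"] == fid, "clinical_variable"].unique()))
        records.append(dict(feature_id=fid, call=call, n_supporting=n_sup,
                            clinical_variables=vars_))
    return pd.DataFrame(
        records, columns=["feature_id", "call", "n_supporting", "clinical_variables"]
    )
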