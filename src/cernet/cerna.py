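"""Competing-endogenous-RNA (ceRNA) pair scoring and triplet construction.

Two transcripts that share miRNA response elements can buffer each other's
miRNA repression; such pairs are detected here in four steps:

1. *Interaction filtering*: a predicted miRNA->target link is retained only
   if it is called by at least ``min_predictors`` prediction algorithms and
   the miRNA and target expression are significantly inversely correlated
   (Spearman rho < 0, p <= alpha).
2. *Shared-miRNA test*: for a candidate pair, the number of shared retained
   miRNAs ``m`` out of K1 and K2 per-transcript miRNAs is tested against an
   upper-tail hypergeometric null over the miRNA universe N.
3. *Conditional statistics*: Pearson correlation (PC), partial Pearson
   correlation given each shared miRNA (PPC), the sensitivity of the
   correlation to conditioning (SPPC = r - r|z, averaged over shared
   miRNAs), and Gaussian conditional mutual information with a stratified
   permutation p-value (CMI).
4. *Tiering*: highly_confident needs every test to pass; moderate needs
   only PC (r > 0, p <= alpha) and PPC; one triplet is emitted per
   (pair, shared miRNA), flagged clinically relevant when the pair is also
   a retained clinically relevant co-expression edge.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coexpr import correlation_p
from .io import ExpressionMatrix, TargetTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# step 1: miRNA-target interaction filtering


def filter_interactions(
    targets: TargetTable,
    mirna_expr: ExpressionMatrix,
    target_exprs: dict[str, ExpressionMatrix],
    min_predictors: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman-filtered miRNA->target interactions.

    One row per predicted link present in the matrices, with columns
    (mirna_id, target_id, target_class, n_predictors, spearman_rho,
    spearman_p, retained).  Links whose ids are absent from the expression
    matrices are dropped with a log entry.
    """
    samples = list(mirna_expr.sample_ids)
    mirna_vals = mirna_expr.values
    dropped = 0
    records = []
    for row in targets.data.itertuples(index=False):
        expr = target_exprs.get(row.target_class)
        if expr is None or row.mirna_id not in mirna_vals.index \
                or row.target_id not in expr.values.index:
            dropped += 1
            continue
        x = mirna_vals.loc[row.mirna_id, samples].to_numpy(dtype=float)
        y = expr.values.loc[row.target_id, samples].to_numpy(dtype=float)
        rho, p = stats.spearmanr(x, y)
        n_pred = len(row.predictors)
        retained = bool(n_pred >= min_predictors and rho < 0 and p <= alpha)
        records.append(
            dict(
                mirna_id=row.mirna_id,
                target_id=row.target_id,
                target_class=row.target_class,
                n_predictors=n_pred,
                spearman_rho=float(rho),
                spearman_p=float(p),
                retained=retained,
            )
        )
    if dropped:
        log.info("filter_interactions: dropped %d links absent from matrices", dropped)
    df = pd.DataFrame(
        records,
        columns=["mirna_id", "target_id", "target_class", "n_predictors",
                 "spearman_rho", "spearman_p", "retained"],
    )
    log.info(
        "filter_interactions: %d/%d links retained", int(df["retained"].sum()), len(df)
    )
    return df


# ---------------------------------------------------------------------------
# step 2: shared-miRNA hypergeometric test


def shared_mirna_hypergeom(N: int, K1: int, K2: int, m: int) -> float:
    """Upper-tail P(X >= m), X ~ Hypergeometric(N; K1 draws from K2 marked).

    N is the miRNA universe, K1 and K2 the per-transcript miRNA counts,
    m the shared count.
    """
    if not (0 <= m <= min(K1, K2) <= N) or K1 > N or K2 > N:
        raise ValueError(f"inconsistent counts N={N}, K1={K1}, K2={K2}, m={m}")
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, N, K1, K2))


# ---------------------------------------------------------------------------
# step 3: conditional statistics


@dataclass
class PartialCorr:
    r: float
    p: float
    degenerate: bool


def partial_pearson(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> PartialCorr:
    """First-order partial Pearson correlation of x and y given z.

    r_xy|z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)), with a
    two-sided t p-value on n-3 degrees of freedom.  If z is perfectly
    collinear with x or y the result is flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("partial correlation needs n >= 4")
    r_xy = _pearson(x, y)
    r_xz = _pearson(x, z)
    r_yz = _pearson(y, z)
    denom2 = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom2 <= 1e-12:
        return PartialCorr(float("nan"), float("nan"), True)
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom2)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return PartialCorr(r, p, False)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt((a**2).sum())
    nb = np.sqrt((b**2).sum())
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip((a * b).sum() / (na * nb), -1.0, 1.0))


def sensitivity_correlation(
    x: np.ndarray, y: np.ndarray, conditioners: list[np.ndarray]
) -> float:
    """Mean drop in correlation on conditioning: mean_i (r_xy - r_xy|z_i).

    Large values indicate the x-y coupling is mediated by the shared
    miRNAs.  Degenerate conditioners are skipped; if all are degenerate the
    result is NaN.
    """
    if not conditioners:
        raise ValueError("need at least one conditioning vector")
    r_xy = _pearson(np.asarray(x, float), np.asarray(y, float))
    drops = []
    for z in conditioners:
        pc = partial_pearson(x, y, z)
        if not pc.degenerate:
            drops.append(r_xy - pc.r)
    return float(np.mean(drops)) if drops else float("nan")


def conditional_mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    stratum_size: int = 10,
) -> tuple[float, float]:
    """Gaussian conditional mutual information I(X;Y|Z) with a permutation p.

    The estimator is the closed form -0.5 * ln(1 - r_xy|z^2) (nats), zero
    exactly when the partial correlation vanishes.  The p-value permutes x
    within z-rank strata of ~``stratum_size`` samples (preserving the
    x-z dependence structure under the conditional-independence null):
    p = (1 + #{perm CMI >= observed}) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("CMI estimation needs n >= 10")
    pc = partial_pearson(x, y, z)
    if pc.degenerate:
        raise ValueError("degenerate conditioner: z collinear with x or y")
    value = float(-0.5 * np.log(max(1.0 - pc.r**2, 1e-300)))
    if n_perm <= 0:
        return value, float("nan")

    if rng is None:
        rng = np.random.default_rng(0)
    n_strata = max(2, n // stratum_size)
    # contiguous z-rank strata of near-equal size
    order = np.argsort(z, kind="mergesort")
    strata = np.array_split(order, n_strata)

    # vectorized permutations: build n_perm permuted copies of x
    xp = np.tile(x, (n_perm, 1))
    for idx in strata:
        cols = np.tile(idx, (n_perm, 1))
        shuffled = rng.permuted(cols, axis=1)
        xp[:, idx] = np.take_along_axis(xp, shuffled, axis=1)

    r_perm = _partial_corr_many(xp, y, z)
    cmi_perm = -0.5 * np.log(np.clip(1.0 - r_perm**2, 1e-300, None))
    p = float((1 + np.sum(cmi_perm >= value - 1e-15)) / (n_perm + 1))
    return value, p


def _partial_corr_many(xs: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Partial correlation of each row of ``xs`` with y given z (vectorized)."""
    xc = xs - xs.mean(axis=1, keepdims=True)
    xn = np.sqrt((xc**2).sum(axis=1))
    xn[xn == 0.0] = 1.0
    xc /= xn[:, None]
    yc = y - y.mean()
    yc /= max(np.sqrt((yc**2).sum()), 1e-300)
    zc = z - z.mean()
    zc /= max(np.sqrt((zc**2).sum()), 1e-300)
    r_xy = xc @ yc
    r_xz = xc @ zc
    r_yz = float(yc @ zc)
    denom2 = np.clip((1.0 - r_xz**2) * (1.0 - r_yz**2), 1e-24, None)
    return np.clip((r_xy - r_xz * r_yz) / np.sqrt(denom2), -1.0, 1.0)


# ---------------------------------------------------------------------------
# step 4: pair scoring, tiering and triplets


@dataclass
class CeRNAThresholds:
    hyper_alpha: float = 0.05
    pc_alpha: float = 0.05
    ppc_alpha: float = 0.05
    sppc_min: float = 0.1
    cmi_alpha: float = 0.05


def score_pairs(
    interactions: pd.DataFrame,
    exprs: dict[str, ExpressionMatrix],
    pair_classes: tuple[tuple[str, str], ...] = (
        ("circRNA", "circRNA"), ("circRNA", "mRNA"), ("mRNA", "mRNA"),
    ),
    thresholds: CeRNAThresholds | None = None,
    cmi_perms: int = 1000,
    seed: int = 0,
    ppc_aggregate: str = "max",
) -> pd.DataFrame:
    """Score all candidate ceRNA pairs sharing >= 1 retained miRNA.

    The miRNA universe N is the set of distinct miRNAs in the retained
    interaction table.  PPC conditions on each shared miRNA separately;
    ``ppc_aggregate`` picks the reported p ("max" is most conservative).
    SPPC averages the correlation drop over shared miRNAs; the CMI value /
    permutation p are taken at the PPC-aggregating miRNA, and the (costly)
    permutation p is computed only for pairs still eligible for the
    highly_confident tier.  Output is deterministically ordered.
    """
    th = thresholds or CeRNAThresholds()
    retained = interactions[interactions["retained"]]
    if retained.empty:
        return _empty_pairs()
    mirnas_of: dict[str, set[str]] = {}
    class_of: dict[str, str] = {}
    for row in retained.itertuples(index=False):
        mirnas_of.setdefault(row.target_id, set()).add(row.mirna_id)
        class_of[row.target_id] = row.target_class
    universe = sorted(set(retained["mirna_id"]))
    N = len(universe)

    samples = list(exprs["miRNA"].sample_ids)
    mirna_vals = exprs["miRNA"].values

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    allowed = {tuple(sorted(pc)) for pc in pair_classes}
    records = []
    targets_sorted = sorted(mirnas_of)
    for t1, t2 in itertools.combinations(targets_sorted, 2):
        c1, c2 = class_of[t1], class_of[t2]
        if tuple(sorted((c1, c2))) not in allowed:
            continue
        shared = sorted(mirnas_of[t1] & mirnas_of[t2])
        if not shared:
            continue
        K1, K2 = len(mirnas_of[t1]), len(mirnas_of[t2])
        m = len(shared)
        hyper_p = shared_mirna_hypergeom(N, K1, K2, m)

        x = exprs[c1].values.loc[t1, samples].to_numpy(dtype=float)
        y = exprs[c2].values.loc[t2, samples].to_numpy(dtype=float)
        pc_r = _pearson(x, y)
        pc_p = float(correlation_p(np.array([pc_r]), len(samples))[0])

        zs = [mirna_vals.loc[mid, samples].to_numpy(dtype=float) for mid in shared]
        partials = [partial_pearson(x, y, z) for z in zs]
        ok = [(pc, z) for pc, z in zip(partials, zs) if not pc.degenerate]
        if ok:
            pick = max if ppc_aggregate == "max" else min
            ppc_best, z_best = pick(ok, key=lambda t: t[0].p)
            ppc_value, ppc_p = ppc_best.r, ppc_best.p
            sppc_value = float(np.mean([pc_r - pc.r for pc, _ in ok]))
            cmi_value = float(-0.5 * np.log(max(1.0 - ppc_best.r**2, 1e-300)))
        else:
            ppc_value = ppc_p = sppc_value = cmi_value = float("nan")
            z_best = None

        # permutation p only where the cheaper gates already pass
        cmi_p = float("nan")
        eligible = (
            z_best is not None
            and hyper_p <= th.hyper_alpha
            and pc_r > 0 and pc_p <= th.pc_alpha
            and ppc_p <= th.ppc_alpha
            and sppc_value >= th.sppc_min
        )
        if eligible and cmi_perms > 0:
            cmi_value, cmi_p = conditional_mutual_information(
                x, y, z_best, n_perm=cmi_perms, rng=rng
            )

        records.append(
            dict(
                rna1_id=t1, rna2_id=t2, class1=c1, class2=c2,
                shared_mirnas=",".join(shared),
                N_universe=N, K1=K1, K2=K2, m=m,
                hyper_p=hyper_p, pc_r=pc_r, pc_p=pc_p,
                ppc_value=ppc_value, ppc_p=ppc_p,
                sppc_value=sppc_value,
                cmi_value=cmi_value, cmi_p=cmi_p,
            )
        )
    pairs = pd.DataFrame(records, columns=_PAIR_COLUMNS[:-1])
    if pairs.empty:
        return _empty_pairs()
    pairs["tier"] = [classify_pair(row, th) for row in pairs.itertuples(index=False)]
    pairs = pairs.sort_values(["rna1_id", "rna2_id"], kind="mergesort").reset_index(drop=True)
    log.info(
        "score_pairs: %d pairs (%d highly_confident, %d moderate)",
        len(pairs),
        int((pairs["tier"] == "highly_confident").sum()),
        int((pairs["tier"] == "moderate").sum()),
    )
    return pairs


_PAIR_COLUMNS = [
    "rna1_id", "rna2_id", "class1", "class2", "shared_mirnas",
    "N_universe", "K1", "K2", "m", "hyper_p", "pc_r", "pc_p",
    "ppc_value", "ppc_p", "sppc_value", "cmi_value", "cmi_p", "tier",
]


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(columns=_PAIR_COLUMNS)


def classify_pair(pair, thresholds: CeRNAThresholds | None = None) -> str:
    """Tier of a scored pair: highly_confident, moderate, or none.

    highly_confident: hypergeometric AND PC (r > 0) AND PPC AND SPPC AND
    CMI all pass; moderate: PC and PPC pass.  NaN statistics never pass.
    """
    th = thresholds or CeRNAThresholds()
    def _le(v, a):
        return bool(v == v) and v <= a  # NaN-safe
    pc_ok = pair.pc_r > 0 and _le(pair.pc_p, th.pc_alpha)
    ppc_ok = _le(pair.ppc_p, th.ppc_alpha)
    if (
        _le(pair.hyper_p, th.hyper_alpha)
        and pc_ok and ppc_ok
        and (pair.sppc_value == pair.sppc_value and pair.sppc_value >= th.sppc_min)
        and _le(pair.cmi_p, th.cmi_alpha)
    ):
        return "highly_confident"
    if pc_ok and ppc_ok:
        return "moderate"
    return "none"


def build_triplets(pairs: pd.DataFrame, min_tier: str = "moderate") -> pd.DataFrame:
    """One triplet per (tiered pair, shared miRNA), deduplicated and sorted.

    ``min_tier`` of "moderate" includes highly_confident pairs too.
    """
    want = {"highly_confident"} if min_tier == "highly_confident" else {
        "highly_confident", "moderate"}
    records = []
    for row in pairs.itertuples(index=False):
        if row.tier not in want:
            continue
        for mid in str(row.shared_mirnas).split(","):
            if mid:
                records.append(
                    dict(ceRNA1=row.rna1_id, mirna=mid, ceRNA2=row.rna2_id,
                         class1=row.class1, class2=row.class2, tier=row.tier)
                )
    df = pd.DataFrame(
        records, columns=["ceRNA1", "mirna", "ceRNA2", "class1", "class2", "tier"]
    ).drop_duplicates()
    return df.sort_values(["ceRNA1", "mirna", "ceRNA2"], kind="mergesort").reset_index(drop=True)


def intersect_clinical(triplets: pd.DataFrame, coexpr_edges: pd.DataFrame) -> pd.DataFrame:
    """Flag triplets whose (ceRNA1, ceRNA2) is a clinically relevant co-expression edge."""
    edge_set = {
        tuple(sorted((a, b)))
        for a, b in zip(coexpr_edges["a_id"], coexpr_edges["b_id"])
    }
    out = triplets.copy()
    out["clinical_flag"] = [
        tuple(sorted((r.ceRNA1, r.ceRNA2))) in edge_set
        for r in triplets.itertuples(index=False)
    ]
    return out


# ---------------------------------------------------------------------------
# built-in seed-match target predictor (stand-in for external algorithms)

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def seed_match_targets(
    mirna_seqs: dict[str, str],
    target_seqs: dict[str, str],
    target_class: str,
    predictor_name: str = "seed7",
) -> pd.DataFrame:
    """Predict miRNA targets by 7-mer seed complementarity.

    A target is called when the reverse complement of miRNA positions 2-8
    (the seed) occurs in the target sequence (DNA alphabet; U treated
    as T).  Returns rows (mirna_id, target_id, target_class, predictors).
    """
    records = []
    for mid in sorted(mirna_seqs):
        seq = mirna_seqs[mid].upper().replace("U", "T")
        if len(seq) < 8:
            continue
        seed = seq[1:8]
        site = seed.translate(_COMPLEMENT)[::-1]
        for tid in sorted(target_seqs):
            tseq = target_seqs[tid].upper().replace("U", "T")
            if site in tseq:
                records.append((mid, tid, target_class, (predictor_name,)))
    return pd.DataFrame(
        records, columns=["mirna_id", "target_id", "target_class", "predictors"]
    )
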