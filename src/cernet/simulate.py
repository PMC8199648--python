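"""Synthetic paired tumor/non-tumor cohorts with planted structure.

The generator emulates the study design every stage of the pipeline is
tested against: matched tumor and adjacent non-tumor profiles from
``n_patients`` patients for three RNA classes, with

* planted differentially expressed (DE) features (additive log2 shift in
  tumor samples),
* a subset of DE features additionally shifted by tumor grade (the planted
  clinical associations),
* planted miRNA-mediated ceRNA triplets: per patient, the triplet miRNA
  gets an abundance deviation ``m`` in the tumor sample and both its
  circRNA and mRNA partner receive ``-coupling_b * (m - mean(m))``,
  inducing the inverse miRNA-target correlation and the positive
  circRNA-mRNA correlation that attenuates when conditioning on the miRNA,
* survival-associated features coupled to a latent per-patient frailty
  that scales an exponential hazard.

The emitted :class:`CohortTruth` lists every planted id so recovery can be
scored per stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .io import (
    ClinicalTable,
    ExpressionMatrix,
    TargetTable,
    DEFAULT_PREDICTOR_REGISTRY,
)


@dataclass
class SimulationConfig:
    """Cohort-level knobs; defaults define the standard test conditions."""

    n_patients: int = 49
    n_circ: int = 200
    n_mirna: int = 120
    n_mrna: int = 400
    frac_de: float = 0.10          # fraction of features DE, per class
    log2fc_de: float = 1.5         # planted tumor-vs-non-tumor shift (log2)
    n_clin_assoc: int = 15         # DE features per class additionally grade-shifted
    grade_shift: float = 0.6       # log2 units per grade step above 1
    n_triplets: int = 10           # planted circRNA-miRNA-mRNA triplets
    mirnas_per_pair: int = 2       # shared miRNAs per planted circRNA-mRNA pair
    coupling_b: float = 1.0        # miRNA -> target suppression strength
    mirna_spread: float = 1.5      # sd of per-patient miRNA abundance deviation (log2)
    mirna_grade_coef: float = 0.6  # miRNA abundance drop per grade step (log2)
    noise_sd: float = 0.5          # per-sample noise sd (log2)
    baseline_mean: float = 8.0     # per feature-patient baseline (log2)
    baseline_sd: float = 1.0
    n_survival: int = 5            # survival-coupled features per class
    survival_coupling: float = 1.0 # log2 expression shift per unit frailty
    survival_scale: float = 36.0   # baseline mean survival (months)
    survival_effect: float = 2.0   # hazard multiplier per unit frailty
    censor_time: float = 120.0     # uniform censoring horizon (months)
    decoy_factor: float = 5.0      # decoy target links per planted link
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_circ, self.n_mirna, self.n_mrna) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must be in [0,1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class CohortTruth:
    """Planted ground truth for recovery scoring."""

    de_features: dict[str, dict[str, int]]          # class -> id -> direction (+1/-1)
    clin_assoc_features: dict[str, dict[str, str]]  # class -> id -> clinical variable
    triplets: list[tuple[str, str, str]]            # (circ, mirna, mrna)
    survival_features: dict[str, list[str]]         # class -> ids

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "de_features": self.de_features,
            "clin_assoc_features": self.clin_assoc_features,
            "triplets": [list(t) for t in self.triplets],
            "survival_features": self.survival_features,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortTruth":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            de_features=raw["de_features"],
            clin_assoc_features=raw["clin_assoc_features"],
            triplets=[tuple(t) for t in raw["triplets"]],
            survival_features=raw["survival_features"],
        )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, ExpressionMatrix], ClinicalTable, TargetTable, CohortTruth]:
    """Generate a cohort; returns ({class: matrix}, clinical, targets, truth)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_p = cfg.n_patients

    patients = [f"P{i:03d}" for i in range(1, n_p + 1)]
    tumor_ids = [f"{p}_T" for p in patients]
    normal_ids = [f"{p}_N" for p in patients]

    # --- clinical covariates (grade drives the planted associations) ------
    grade = rng.integers(1, 5, size=n_p)
    frailty = rng.standard_normal(n_p)  # latent prognosis driver
    binaries = {
        col: rng.integers(0, 2, size=n_p)
        for col in ("size_group", "encapsulation", "degree_encapsulation",
                    "vascular_invasion", "tumor_invasion", "stage_group")
    }
    hazard = (1.0 / cfg.survival_scale) * cfg.survival_effect ** frailty
    event_time = rng.exponential(1.0 / hazard)
    censor = rng.uniform(0, cfg.censor_time, size=n_p)
    os_time = np.minimum(event_time, censor)
    os_event = (event_time <= censor).astype(int)

    # --- feature ids and planted assignments -------------------------------
    sizes = {"circRNA": cfg.n_circ, "miRNA": cfg.n_mirna, "mRNA": cfg.n_mrna}
    prefix = {"circRNA": "circ", "miRNA": "mir", "mRNA": "gene"}
    ids = {
        cls: [f"{prefix[cls]}{i:04d}" for i in range(1, n + 1)]
        for cls, n in sizes.items()
    }

    de_features: dict[str, dict[str, int]] = {}
    for cls in sizes:
        n_de = int(round(cfg.frac_de * sizes[cls]))
        if n_de > sizes[cls]:
            raise ValueError(f"more DE features requested than exist for {cls}")
        chosen = rng.choice(ids[cls], size=n_de, replace=False)
        directions = rng.choice([1, -1], size=n_de)
        de_features[cls] = {str(fid): int(d) for fid, d in zip(chosen, directions)}

    def _planted_subset(cls: str, k: int, prefer: Iterable[str] = ()) -> list[str]:
        """k DE features of class cls, always including `prefer`, capped by what exists."""
        pool = sorted(de_features[cls])
        prefer = [f for f in prefer if f in de_features[cls]]
        k = min(k, len(pool))
        rest = [f for f in pool if f not in set(prefer)]
        n_extra = min(max(0, k - len(prefer)), len(rest))
        extra = [str(f) for f in rng.choice(rest, size=n_extra, replace=False)] if rest else []
        return sorted(prefer + extra)[: max(k, len(prefer))]

    # triplets need DE members; the circRNA end must also be clinically
    # associated for the pair to survive the clinical-relevance gate.
    # Each planted circRNA-mRNA pair shares `mirnas_per_pair` miRNAs, so
    # the shared-miRNA overlap is non-trivial under the hypergeometric null.
    n_trip = cfg.n_triplets
    mpp = max(1, cfg.mirnas_per_pair)
    n_pairs = -(-n_trip // mpp)  # ceil
    de_circ_pool = sorted(de_features["circRNA"])
    de_mirna = sorted(de_features["miRNA"])
    de_mrna = sorted(de_features["mRNA"])
    if n_pairs > min(len(de_circ_pool), len(de_mrna)) or n_trip > len(de_mirna):
        raise ValueError(
            f"n_triplets={n_trip} (-> {n_pairs} pairs) exceeds available DE "
            f"features ({len(de_circ_pool)} circ, {len(de_mirna)} miRNA, "
            f"{len(de_mrna)} mRNA)"
        )
    pair_circ = [str(f) for f in rng.choice(de_circ_pool, size=n_pairs, replace=False)]
    pair_mrna = [str(f) for f in rng.choice(de_mrna, size=n_pairs, replace=False)]
    trip_mirna = [str(f) for f in rng.choice(de_mirna, size=n_trip, replace=False)]
    triplets = []
    for j, mid in enumerate(trip_mirna):
        i = j % n_pairs
        triplets.append((pair_circ[i], mid, pair_mrna[i]))
    triplets.sort()
    trip_circ = sorted(set(pair_circ))
    trip_mrna = sorted(set(pair_mrna))
    # canonical sponge pattern: circRNA and target mRNA up in tumors, the
    # shared miRNA down, so tissue shifts reinforce the planted coupling
    for circ_id, mid, mrna_id in triplets:
        de_features["circRNA"][circ_id] = 1
        de_features["mRNA"][mrna_id] = 1
        de_features["miRNA"][mid] = -1

    clin_assoc: dict[str, dict[str, str]] = {}
    for cls in sizes:
        prefer = {"circRNA": trip_circ, "mRNA": trip_mrna}.get(cls, [])
        chosen = _planted_subset(cls, cfg.n_clin_assoc, prefer=prefer)
        clin_assoc[cls] = {fid: "grade" for fid in chosen}

    survival_features: dict[str, list[str]] = {}
    for cls in sizes:
        pool = [f for f in sorted(de_features[cls]) if f not in clin_assoc[cls]]
        k = min(cfg.n_survival, len(pool))
        survival_features[cls] = sorted(str(f) for f in rng.choice(pool, size=k, replace=False)) if k else []

    # --- expression ---------------------------------------------------------
    matrices: dict[str, ExpressionMatrix] = {}
    # per-patient abundance deviation of each planted miRNA: lower in
    # higher-grade tumors (the clinically relevant sponge axis) plus
    # patient-level noise
    mirna_dev: dict[str, np.ndarray] = {}
    for mid in trip_mirna:
        mirna_dev[mid] = (
            -cfg.mirna_grade_coef * (grade - grade.mean())
            + rng.normal(0.0, cfg.mirna_spread, size=n_p)
        )

    for cls in ("circRNA", "miRNA", "mRNA"):
        n_f = sizes[cls]
        base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=(n_f, n_p))
        tumor = base + rng.normal(0.0, cfg.noise_sd, size=(n_f, n_p))
        normal = base + rng.normal(0.0, cfg.noise_sd, size=(n_f, n_p))

        index = pd.Index(ids[cls], name="feature_id")
        pos = {fid: i for i, fid in enumerate(ids[cls])}

        for fid, direction in de_features[cls].items():
            tumor[pos[fid]] += direction * cfg.log2fc_de
        for fid in clin_assoc[cls]:
            sign = de_features[cls][fid]
            tumor[pos[fid]] += sign * cfg.grade_shift * (grade - 1)
        for fid in survival_features[cls]:
            tumor[pos[fid]] += cfg.survival_coupling * frailty

        if cls == "miRNA":
            for mid, dev in mirna_dev.items():
                tumor[pos[mid]] += dev
        else:
            for circ_id, mid, mrna_id in triplets:
                dev = mirna_dev[mid]
                centered = dev - dev.mean()
                target = circ_id if cls == "circRNA" else mrna_id
                tumor[pos[target]] += -cfg.coupling_b * centered

        values = pd.DataFrame(
            np.hstack([tumor, normal]),
            index=index,
            columns=tumor_ids + normal_ids,
        )
        matrices[cls] = ExpressionMatrix(values, cls)

    # --- clinical table -----------------------------------------------------
    rows = []
    for i, pid in enumerate(patients):
        common = dict(
            patient_id=pid,
            grade=int(grade[i]),
            os_time=float(os_time[i]),
            os_event=int(os_event[i]),
            **{col: int(vals[i]) for col, vals in binaries.items()},
        )
        rows.append(dict(sample_id=tumor_ids[i], tissue="tumor", **common))
        rows.append(dict(sample_id=normal_ids[i], tissue="non_tumor", **common))
    clinical = ClinicalTable(pd.DataFrame(rows))

    # --- target table: planted links + decoys -------------------------------
    planted_links = []
    for circ_id, mid, mrna_id in triplets:
        planted_links.append((mid, circ_id, "circRNA"))
        planted_links.append((mid, mrna_id, "mRNA"))
    planted_set = {(m, t) for m, t, _ in planted_links}

    n_decoy = int(round(cfg.decoy_factor * len(planted_links)))
    decoys: list[tuple[str, str, str]] = []
    seen = set(planted_set)
    guard = 0
    while len(decoys) < n_decoy and guard < 100 * max(1, n_decoy):
        guard += 1
        mid = str(rng.choice(de_mirna)) if de_mirna else str(rng.choice(ids["miRNA"]))
        if rng.random() < 0.5:
            tcls, pool = "circRNA", ids["circRNA"]
        else:
            tcls, pool = "mRNA", ids["mRNA"]
        tid = str(rng.choice(pool))
        if (mid, tid) in seen:
            continue
        seen.add((mid, tid))
        decoys.append((mid, tid, tcls))

    records = []
    both = tuple(sorted(DEFAULT_PREDICTOR_REGISTRY))
    for mid, tid, tcls in planted_links:
        records.append((mid, tid, tcls, both))
    for j, (mid, tid, tcls) in enumerate(decoys):
        # half the decoys carry a single predictor to exercise the
        # min_predictors gate; the rest must be removed by correlation
        preds = both if j % 2 == 0 else (both[j // 2 % len(both)],)
        records.append((mid, tid, tcls, preds))
    targets = TargetTable(
        pd.DataFrame(records, columns=["mirna_id", "target_id", "target_class", "predictors"])
        .sort_values(["mirna_id", "target_id"], kind="mergesort")
        .reset_index(drop=True)
    )

    truth = CohortTruth(
        de_features=de_features,
        clin_assoc_features=clin_assoc,
        triplets=triplets,
        survival_features=survival_features,
    )
    return matrices, clinical, targets, truth


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryReport:
    sensitivity: float
    fdp: float
    n_true: int
    n_called: int
    n_hit: int


def score_recovery(calls: Iterable, truth: Iterable) -> RecoveryReport:
    """Sensitivity = |calls & truth| / |truth|; FDP = |calls - truth| / |calls|.

    Elements may be ids or tuples (e.g. triplets); both sides are
    set-normalized.  FDP is 0 when there are no calls; sensitivity is 0
    when truth is empty.
    """
    calls_s = {tuple(c) if isinstance(c, (list, tuple)) else c for c in calls}
    truth_s = {tuple(t) if isinstance(t, (list, tuple)) else t for t in truth}
    n_hit = len(calls_s & truth_s)
    sens = n_hit / len(truth_s) if truth_s else 0.0
    fdp = (len(calls_s) - n_hit) / len(calls_s) if calls_s else 0.0
    return RecoveryReport(
        sensitivity=sens, fdp=fdp,
        n_true=len(truth_s), n_called=len(calls_s), n_hit=n_hit,
    )
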