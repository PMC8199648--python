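"""Run configuration: every threshold used anywhere in the pipeline.

A single :class:`RunConfig` object travels through all stages so that a run
is a pure function of (inputs, config, seed).  The file representation is
YAML with the same field names.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # differential expression
    fc_threshold: float = 1.5        # linear fold-change gate, per spec'd |FC| > 1.5
    de_fdr: float = 0.05             # BH q-value gate
    paired: bool = True              # paired t-test (matched design); Welch if False
    fdr_method: str = "bh"           # "bh" or "by"

    # clinical association
    clin_fc: float = 1.5             # |group FC| gate between clinical groups
    clin_p: float = 0.05             # raw p gate (no multiplicity correction by default)
    clin_adjust: bool = False        # optionally BH-adjust across clinical variables

    # co-expression network
    coexpr_r: float = 0.7            # |Pearson r| gate
    coexpr_fdr: float = 0.05         # BH q gate across all tested pairs
    tumor_only: bool = False         # correlate over tumor samples only
    coverage_target: float = 0.93    # nodal circRNA greedy-cover stopping fraction

    # ceRNA scoring
    min_predictors: int = 2          # miRNA-target link must be called by >= this many predictors
    spearman_alpha: float = 0.05     # miRNA-target inverse-correlation gate
    hyper_alpha: float = 0.05        # shared-miRNA hypergeometric gate
    pc_alpha: float = 0.05           # Pearson (r > 0) gate
    ppc_alpha: float = 0.05          # partial Pearson gate
    sppc_min: float = 0.1            # mean correlation drop on conditioning
    cmi_alpha: float = 0.05          # conditional-mutual-information permutation gate
    cmi_perms: int = 1000            # permutations for the CMI p-value
    ppc_aggregate: str = "max"       # "max" (most conservative) or "min" p across shared miRNAs
    cerna_fdr: bool = False          # optionally BH-adjust ceRNA p-values

    # biomarker panels
    logistic_ridge: float = 1e-6     # L2 stabilizer for separable logistic fits
    ora_fdr: float = 0.05

    # io
    pseudocount: float = 1.0         # log2(x + pseudocount) for linear-scale input
    missing_policy: str = "error"    # "error" or "drop" rows with missing expression

    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
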