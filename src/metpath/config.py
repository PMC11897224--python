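"""Run configuration: every numeric rule of the pipeline in one place.

The defaults encode the analysis rules: strict-greater missingness filters
(20% per metabolite, 50% per person), pathway inclusion at >=10 matched
metabolites, at most three principal components per pathway with a 5
percentage-point variance-gain retention rule, cross-pathway pruning at
|r| > 0.9, forward selection controlled at FDR 0.05, the six-month
(183-day) diagnosis-span rule and the 140/90 mmHg blood-pressure cut-offs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

log = logging.getLogger(__name__)

#: ICD-10 rubrics of essential and hypertensive heart/renal disease.
HYPERTENSION_ICD = ("I10", "I11", "I12", "I13")

#: ATC classes covering antihypertensive medication.
ANTIHYPERTENSIVE_ATC = ("C02", "C03", "C04", "C07", "C08", "C09")

#: Pathways excluded from mapping: the global metabolic super-pathway and the
#: nucleotide-metabolism roll-up whose members are already covered by purine
#: and pyrimidine metabolism.
EXCLUDED_PATHWAYS = ("hsa01100", "hsa01232")


@dataclass
class RunConfig:
    metabolite_missing_max: float = 0.20
    person_missing_max: float = 0.50
    pathway_min_size: int = 10
    pc_cap: int = 3
    variance_gain_min: float = 5.0          # percentage points
    corr_prune: float = 0.9                 # absolute Pearson correlation
    fdr_level: float = 0.05
    six_months_days: int = 183
    bp_sys_cut: float = 140.0               # mmHg, strict >
    bp_dia_cut: float = 90.0                # mmHg, strict >
    excluded_pathways: tuple[str, ...] = EXCLUDED_PATHWAYS
    hypertension_icd: tuple[str, ...] = HYPERTENSION_ICD
    antihypertensive_atc: tuple[str, ...] = ANTIHYPERTENSIVE_ATC
    pca_scale: str = "correlation"          # or "covariance"
    prune_unit: str = "component"           # or "pathway"
    missing_tokens: tuple[str, ...] = ("", "NA")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("metabolite_missing_max", "person_missing_max", "fdr_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        if not 0.0 < self.corr_prune <= 1.0:
            raise ValueError(f"corr_prune must lie in (0, 1], got {self.corr_prune!r}")
        if self.pathway_min_size < 2:
            raise ValueError("pathway_min_size must be >= 2")
        if self.pc_cap < 1:
            raise ValueError("pc_cap must be >= 1")
        if self.six_months_days <= 0:
            raise ValueError("six_months_days must be positive")
        if self.variance_gain_min < 0:
            raise ValueError("variance_gain_min must be non-negative")
        for name in ("hypertension_icd", "antihypertensive_atc"):
            prefixes = tuple(getattr(self, name))
            if len(prefixes) == 0:
                raise ValueError(f"{name} must be a non-empty prefix list")
            object.__setattr__(self, name, prefixes)
        self.excluded_pathways = tuple(self.excluded_pathways)
        self.missing_tokens = tuple(self.missing_tokens)
        if self.pca_scale not in ("correlation", "covariance"):
            raise ValueError("pca_scale must be 'correlation' or 'covariance'")
        if self.prune_unit not in ("component", "pathway"):
            raise ValueError("prune_unit must be 'component' or 'pathway'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML run configuration; unspecified keys take the defaults.

    Unknown keys raise (guards against silent typos); out-of-range values
    raise through :class:`RunConfig` validation. The fully resolved
    configuration is echoed to the log.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update(overrides)

    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    cfg = RunConfig(**data)
    log.info("resolved config: %s", cfg.to_dict())
    return cfg
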