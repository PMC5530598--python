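"""Pipeline configuration.

Every filtering / calling / reconstruction threshold used anywhere in the
package lives here, with the published study values as defaults, so a run is
fully described by one declarative object (or YAML file).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and tuning knobs for the full pipeline.

    Attributes
    ----------
    fisher_p_max : float
        One-sided tumour-vs-germline Fisher exact p-value ceiling for
        exome candidate calls (pass iff p <= this).
    wes_vaf_min : float
        Minimum tumour VAF for an exome candidate (inclusive). Applied to
        the maximal tumour sample ("in at least one tumour sample").
    deep_vaf_min : float
        Deep-sequencing detection cutoff: called iff VAF >= this and the
        variant base is the second-highest base at the position.
        0.002 means 20 variant reads at 10,000x.
    validation_delta : float
        Minimum tumour-minus-germline VAF difference (percentage points of
        VAF, inclusive) for a mutation to count as validated.
    colony_present_vaf : float
        Colony genotype: present iff VAF strictly above this.
    colony_absent_vaf : float
        Colony genotype: absent iff VAF strictly below this; VAFs between
        the two bounds are ambiguous (possibly mixed colony).
    cna_min_len : float
        Copy-number aberrations longer than this (bp) are kept regardless
        of gene content; shorter ones need a cancer-gene overlap.
    cnloh_min_len : float
        CN-LOH segments are kept only if longer than this (bp) AND
        reaching a telomere.
    detection_floor : float
        VAF floor for clonal reconstruction; entries below it become
        explicit CCF zeros with a flag.
    z_threshold : float
        Agglomerative clustering stop: merging halts once the minimum
        inter-cluster average linkage (worst-sample z) reaches this.
    eps_floor : float
        Floor of the per-comparison CCF tolerance epsilon used by the
        pigeonhole / sum / root constraints; the effective epsilon is
        max(eps_floor, 2 * pooled centroid se).
    lambda_root : float
        Score penalty per extra root (forest parsimony).
    mu_branch : float
        Score penalty per branching node (tree parsimony).
    max_clusters_exhaustive : int
        Hard cap on cluster count for exhaustive forest enumeration.
    fisher_alternative : str
        "greater" (tumour-enriched, default) or "two-sided".
    """

    fisher_p_max: float = 0.001
    wes_vaf_min: float = 0.07
    deep_vaf_min: float = 0.002
    validation_delta: float = 0.05
    colony_present_vaf: float = 0.40
    colony_absent_vaf: float = 0.05
    cna_min_len: float = 5e6
    cnloh_min_len: float = 10e6
    detection_floor: float = 0.002
    z_threshold: float = 3.0
    eps_floor: float = 0.05
    lambda_root: float = 1.0
    mu_branch: float = 0.25
    max_clusters_exhaustive: int = 12
    fisher_alternative: str = "greater"

    def __post_init__(self) -> None:
        for name in ("fisher_p_max", "wes_vaf_min", "deep_vaf_min",
                     "validation_delta", "colony_present_vaf",
                     "colony_absent_vaf", "detection_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.colony_absent_vaf >= self.colony_present_vaf:
            raise ValueError("colony_absent_vaf must be < colony_present_vaf")
        if self.fisher_alternative not in ("greater", "two-sided"):
            raise ValueError("fisher_alternative must be 'greater' or 'two-sided'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


DEFAULT_CONFIG = PipelineConfig()
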