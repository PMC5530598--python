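"""VAF ↔ cancer-cell-fraction conversion under local copy number.

The quantity clustered and ordered downstream is the cancer cell fraction
(CCF): the fraction of nucleated cells carrying a mutation. For a mutation
present at multiplicity ``m`` on a tumour segment of total copy number
``CN_t``, against a normal locus ploidy ``n_p`` (1 for male X/Y, else 2),
the expected VAF of a clone at CCF ``c`` is the standard mixture

    vaf = m * c / (n_p * (1 - c) + CN_t * c)

which reduces to the familiar het-diploid doubling rule ``c = 2 * vaf`` and
handles del(5q), monosomy, CN-LOH and male-X coherently. Tumour purity is
not modelled separately: CCF is defined against all nucleated cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .filters import CnaSegment


class InvalidStateError(ValueError):
    """Copy-number state incompatible with the requested conversion."""


class AmbiguousSegmentError(ValueError):
    """A position is covered by contradictory copy-number segments."""


@dataclass(frozen=True)
class CopyNumberState:
    """Local copy-number context of one mutation.

    cn_total : tumour total copy number at the locus (>= 0)
    multiplicity : copies of the mutated allele per tumour cell (>= 1)
    normal_ploidy : locus copy number in normal cells (1 for male X/Y, else 2)
    """

    cn_total: int = 2
    multiplicity: int = 1
    normal_ploidy: int = 2

    def __post_init__(self) -> None:
        if self.cn_total < 0:
            raise InvalidStateError("cn_total must be >= 0")
        if self.multiplicity < 1:
            raise InvalidStateError("multiplicity must be >= 1")
        if self.multiplicity > max(self.cn_total, 1):
            raise InvalidStateError(
                f"multiplicity {self.multiplicity} exceeds cn_total {self.cn_total}")
        if self.normal_ploidy not in (1, 2):
            raise InvalidStateError("normal_ploidy must be 1 or 2")


DIPLOID_HET = CopyNumberState(2, 1, 2)


@dataclass(frozen=True)
class CcfEstimate:
    """Point CCF with delta-method standard error.

    ``overflow`` marks raw values that exceeded 1 by more than 3 se before
    clipping (suggesting a wrong copy-number state or multiplicity).
    """

    ccf: float
    se: float
    overflow: bool = False
    below_detection: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.ccf <= 1.0:
            raise ValueError("stored ccf must be clipped to [0, 1]")
        if self.se < 0:
            raise ValueError("se must be >= 0")


def expected_vaf(ccf: float, state: CopyNumberState = DIPLOID_HET) -> float:
    """Expected VAF of a clone at fraction ``ccf`` under ``state``."""
    if not 0.0 <= ccf <= 1.0:
        raise ValueError("ccf must lie in [0, 1]")
    denom = state.normal_ploidy * (1.0 - ccf) + state.cn_total * ccf
    if denom <= 0:
        raise InvalidStateError("degenerate mixture: zero total copies")
    return state.multiplicity * ccf / denom


def vaf_to_ccf(vaf: float, state: CopyNumberState = DIPLOID_HET,
               depth: int | None = None) -> CcfEstimate:
    """Invert the mixture: ccf = n_p * vaf / (m - vaf * (CN_t - n_p)).

    Values above 1 are clipped; the overflow flag is raised only when the
    raw value exceeds 1 + 3 se (se = 0 when no depth is supplied, so any
    excursion flags).
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError("vaf must lie in [0, 1]")
    denom = state.multiplicity - vaf * (state.cn_total - state.normal_ploidy)
    if denom <= 0:
        raise InvalidStateError(
            f"vaf {vaf} unreachable under state {state}: non-positive denominator")
    raw = state.normal_ploidy * vaf / denom
    se = ccf_se_from_vaf(vaf, depth, state) if depth else 0.0
    overflow = raw > 1.0 + 3.0 * se
    return CcfEstimate(ccf=min(max(raw, 0.0), 1.0), se=se, overflow=overflow)


def _dccf_dvaf(vaf: float, state: CopyNumberState) -> float:
    denom = state.multiplicity - vaf * (state.cn_total - state.normal_ploidy)
    return state.normal_ploidy * state.multiplicity / denom**2


def ccf_se_from_vaf(vaf: float, depth: int | None,
                    state: CopyNumberState = DIPLOID_HET) -> float:
    """Delta-method CCF standard error from the binomial VAF error."""
    if not depth or depth <= 0:
        return 0.0
    se_vaf = float(np.sqrt(max(vaf * (1.0 - vaf), 0.0) / depth))
    return abs(_dccf_dvaf(vaf, state)) * se_vaf


def ccf_se(alt: int, depth: int, state: CopyNumberState = DIPLOID_HET) -> float:
    """CCF standard error from observed counts."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    return ccf_se_from_vaf(alt / depth, depth, state)


def assign_cn_state(
    chrom: str,
    pos: int,
    segments: list[CnaSegment] = (),
    sex: str = "female",
    alt: int | None = None,
    depth: int | None = None,
    candidate_ccfs: list[float] | None = None,
) -> CopyNumberState:
    """Copy-number state of a variant position from kept CNA segments.

    Variant coordinates are 1-based; segments are 0-based half-open. When no
    segment covers the position the default is a heterozygous diploid state
    (normal ploidy 1 on X/Y in males). Contradictory overlapping segments
    raise :class:`AmbiguousSegmentError`.

    Under CN-LOH the multiplicity is ambiguous: mutation-then-LOH duplicates
    the mutant allele (m=2) while mutation-after-LOH leaves one copy (m=1).
    When observed counts and candidate CCFs (e.g. of co-clustered mutations)
    are supplied, the multiplicity maximising the binomial likelihood of the
    alt count is chosen; ties and missing data default to m=2, the common
    somatic pattern.
    """
    male = str(sex).lower() in ("male", "m", "xy")
    n_p = 1 if (male and chrom.lstrip("chr") in ("X", "Y")) else 2
    hits = [s for s in segments if s.overlaps_point(chrom, pos)]
    if not hits:
        return CopyNumberState(cn_total=n_p if n_p == 1 else 2,
                               multiplicity=1, normal_ploidy=n_p)
    states = {(s.cn_total, s.cn_minor, s.is_cnloh) for s in hits}
    if len(states) > 1:
        raise AmbiguousSegmentError(
            f"{chrom}:{pos} covered by contradictory segments {sorted(states)}")
    seg = hits[0]
    if seg.is_cnloh:
        m = choose_multiplicity(alt, depth, candidate_ccfs,
                                cn_total=2, normal_ploidy=n_p)
        return CopyNumberState(cn_total=2, multiplicity=m, normal_ploidy=n_p)
    return CopyNumberState(cn_total=seg.cn_total, multiplicity=1,
                           normal_ploidy=n_p)


def choose_multiplicity(alt: int | None, depth: int | None,
                        candidate_ccfs: list[float] | None,
                        cn_total: int = 2, normal_ploidy: int = 2) -> int:
    """Pick m in {1, 2} by binomial likelihood of the observed alt count.

    For each m the expected VAF is evaluated at each candidate CCF and the
    best log-likelihood is kept; the m with the higher optimum wins, ties
    going to m=2 (mutation-before-LOH). Without counts or candidates, m=2.
    """
    if alt is None or not depth or not candidate_ccfs:
        return 2
    from scipy import stats

    best = {}
    for m in (1, 2):
        state = CopyNumberState(cn_total, m, normal_ploidy)
        lls = [stats.binom.logpmf(alt, depth, expected_vaf(c, state))
               for c in candidate_ccfs]
        best[m] = max(lls)
    return 2 if best[2] >= best[1] else 1


class CcfMatrix:
    """Per-mutation, per-sample CCF estimates with uncertainties.

    Thin wrapper around three aligned DataFrames (mutations x time-ordered
    samples): point estimates, standard errors and below-detection flags.
    Missing entries are NaN in ``ccf`` and must be explicit.
    """

    def __init__(self, ccf: pd.DataFrame, se: pd.DataFrame,
                 below_detection: pd.DataFrame,
                 sample_times: pd.Series | None = None):
        if not (ccf.index.equals(se.index) and ccf.columns.equals(se.columns)
                and ccf.index.equals(below_detection.index)
                and ccf.columns.equals(below_detection.columns)):
            raise ValueError("component frames must be aligned")
        self.ccf = ccf
        self.se = se
        self.below_detection = below_detection
        self.sample_times = sample_times

    @property
    def mutations(self) -> list[str]:
        return list(self.ccf.index)

    @property
    def samples(self) -> list[str]:
        return list(self.ccf.columns)

    def __len__(self) -> int:
        return len(self.ccf)

    def subset(self, mutation_ids) -> "CcfMatrix":
        ids = list(mutation_ids)
        return CcfMatrix(self.ccf.loc[ids], self.se.loc[ids],
                         self.below_detection.loc[ids], self.sample_times)


def build_ccf_matrix(
    records: pd.DataFrame,
    states: dict[str, CopyNumberState],
    sample_sheet: pd.DataFrame,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> CcfMatrix:
    """Assemble the CCF matrix over validated mutations x time-ordered samples.

    ``records`` is long-format with columns ``mutation_id, sample_id,
    alt_count, depth``; ``sample_sheet`` must carry ``sample_id`` and
    ``time_days``. Entries whose VAF falls below the detection floor (0.2%)
    are set to CCF 0 and flagged; their se is evaluated at the floor so a
    zero is still statistically comparable. Samples absent for a mutation
    stay NaN (explicitly missing).
    """
    sheet = sample_sheet.drop_duplicates("sample_id").set_index("sample_id")
    unknown = set(records["sample_id"]) - set(sheet.index)
    if unknown:
        raise KeyError(f"samples missing from sample sheet: {sorted(unknown)}")
    order = sheet["time_days"].sort_values(kind="mergesort").index.tolist()
    order = [s for s in order if s in set(records["sample_id"])]
    muts = sorted(records["mutation_id"].unique())

    ccf = pd.DataFrame(np.nan, index=muts, columns=order, dtype=float)
    se = pd.DataFrame(np.nan, index=muts, columns=order, dtype=float)
    below = pd.DataFrame(False, index=muts, columns=order, dtype=bool)

    for row in records.itertuples():
        state = states.get(row.mutation_id, DIPLOID_HET)
        depth = int(row.depth)
        if depth <= 0:
            continue
        vaf = row.alt_count / depth
        if vaf < config.detection_floor:
            # censored observation: the true CCF lies anywhere below the
            # floor, so the floor's CCF equivalent is the uncertainty —
            # wide enough not to split near-floor trajectories, yet tiny
            # against any established clone
            floor_ccf = vaf_to_ccf(config.detection_floor, state).ccf
            ccf.at[row.mutation_id, row.sample_id] = 0.0
            se.at[row.mutation_id, row.sample_id] = max(
                floor_ccf, ccf_se_from_vaf(config.detection_floor, depth,
                                           state))
            below.at[row.mutation_id, row.sample_id] = True
        else:
            est = vaf_to_ccf(min(vaf, 1.0), state, depth=depth)
            ccf.at[row.mutation_id, row.sample_id] = est.ccf
            se.at[row.mutation_id, row.sample_id] = est.se
    times = sheet.loc[order, "time_days"]
    return CcfMatrix(ccf, se, below, sample_times=times)
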