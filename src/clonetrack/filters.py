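"""Somatic variant and copy-number-aberration filters.

Every published calling, validation and aberration-filtering threshold is
implemented here exactly as worded: non-strict where the rule says "at
least" / ">=" / "<=", strict where it says ">" / "<".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_CONFIG, PipelineConfig

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class ReadCountRecord:
    """Alt/ref read counts for one variant in one sample.

    ``base_counts`` optionally carries the full four-base composition at the
    position (needed by the second-highest-base rule); when present, depth is
    its sum and alt/ref counts must be consistent with it.
    """

    mutation_id: str
    sample_id: str
    alt_count: int
    ref_count: int
    base_counts: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.alt_count < 0 or self.ref_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.base_counts is not None:
            if set(self.base_counts) != set(BASES):
                raise ValueError("base_counts must cover A, C, G, T")
            if any(c < 0 for c in self.base_counts.values()):
                raise ValueError("base counts must be non-negative")
            if self.alt_count + self.ref_count > sum(self.base_counts.values()):
                raise ValueError("alt+ref exceed total base counts")

    @property
    def depth(self) -> int:
        if self.base_counts is not None:
            return int(sum(self.base_counts.values()))
        return self.alt_count + self.ref_count

    @property
    def vaf(self) -> float:
        d = self.depth
        return self.alt_count / d if d > 0 else 0.0


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of one filter rule for one (mutation, sample)."""

    mutation_id: str
    sample_id: str
    rule: str
    passed: bool
    p_value: float | None = None


@dataclass(frozen=True)
class CnaSegment:
    """Copy-number segment, 0-based half-open coordinates in base pairs."""

    chrom: str
    start: int
    end: int
    cn_total: int
    cn_minor: int
    is_cnloh: bool = False
    reaches_telomere: bool = False
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment start {self.start} >= end {self.end}")
        if self.cn_total < 0:
            raise ValueError("total copy number must be >= 0")
        if self.is_cnloh and not (self.cn_total == 2 and self.cn_minor == 0):
            raise ValueError("CN-LOH requires cn_total=2, cn_minor=0")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps_point(self, chrom: str, pos_1based: int) -> bool:
        # variant positions are 1-based; segment is 0-based half-open
        return self.chrom == chrom and self.start < pos_1based <= self.end


class UndefinedTestError(ValueError):
    """A contingency table with an empty margin has no defined test."""


class PairedControlError(KeyError):
    """A tumour record is missing its germline counterpart."""


def fisher_exact_one_sided(alt_t: int, ref_t: int, alt_c: int, ref_c: int,
                           alternative: str = "greater") -> float:
    """One-sided Fisher exact p-value for tumour alt-allele enrichment.

    Tests whether the tumour alt fraction is higher than the control
    (germline) alt fraction: p = P(X >= alt_t) with X hypergeometric over
    2x2 tables with the observed margins. ``alternative="two-sided"`` is
    exposed but non-default.
    """
    p = fisher_exact_one_sided_many(
        np.asarray([alt_t]), np.asarray([ref_t]),
        np.asarray([alt_c]), np.asarray([ref_c]),
        alternative=alternative,
    )
    return float(p[0])


def fisher_exact_one_sided_many(alt_t, ref_t, alt_c, ref_c,
                                alternative: str = "greater") -> np.ndarray:
    """Vectorised Fisher exact test over parallel count arrays.

    The one-sided p is the upper hypergeometric tail
    ``P(X >= alt_t | N, K, n_t)`` with N = all reads, K = all alt reads,
    n_t = tumour depth; the two-sided p sums all tables with point
    probability <= that of the observed table (scipy's convention).
    """
    alt_t = np.asarray(alt_t, dtype=np.int64)
    ref_t = np.asarray(ref_t, dtype=np.int64)
    alt_c = np.asarray(alt_c, dtype=np.int64)
    ref_c = np.asarray(ref_c, dtype=np.int64)
    if np.any(alt_t < 0) or np.any(ref_t < 0) or np.any(alt_c < 0) or np.any(ref_c < 0):
        raise ValueError("counts must be non-negative")
    n_t = alt_t + ref_t
    n_c = alt_c + ref_c
    if np.any(n_t == 0) or np.any(n_c == 0):
        raise UndefinedTestError("both margins must be positive")
    if alternative == "greater":
        total = n_t + n_c
        k = alt_t + alt_c
        # P(X >= alt_t); sf is exclusive, hence alt_t - 1
        p = stats.hypergeom.sf(alt_t - 1, total, k, n_t)
        return np.minimum(np.asarray(p, dtype=float), 1.0)
    if alternative == "two-sided":
        out = np.empty(alt_t.shape, dtype=float)
        flat = zip(alt_t.ravel(), ref_t.ravel(), alt_c.ravel(), ref_c.ravel())
        for i, (a, b, c, d) in enumerate(flat):
            out.ravel()[i] = stats.fisher_exact(
                [[a, b], [c, d]], alternative="two-sided")[1]
        return out
    raise ValueError(f"unknown alternative {alternative!r}")


def wes_candidate_filter(
    records: pd.DataFrame,
    snp_ids: Iterable[str] = (),
    incomplete_orf_genes: Iterable[str] = (),
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Exome candidate-mutation filter.

    ``records`` is a long-format frame with one row per mutation carrying
    tumour and germline counts:
    ``mutation_id, alt_t, ref_t, alt_c, ref_c, consequence, gene``
    (``alt_t``/``ref_t`` from the tumour sample with the highest VAF when
    several exist). A candidate passes iff

    * one-sided Fisher exact p <= 0.001 (tumour-enriched), AND
    * tumour VAF >= 0.07, AND
    * consequence is not synonymous, AND
    * not listed in any supplied SNP database, AND
    * gene not flagged as having incomplete ORF annotation.

    Returns the input with ``p_value``, ``passed`` and ``rule`` columns; the
    rule names the first criterion that failed ("pass" when none did).
    """
    required = {"mutation_id", "alt_t", "ref_t", "alt_c", "ref_c",
                "consequence", "gene"}
    missing = required - set(records.columns)
    if missing:
        raise PairedControlError(
            f"records missing paired tumour/germline columns: {sorted(missing)}")
    out = records.copy()
    if len(out) == 0:
        out["p_value"] = pd.Series(dtype=float)
        out["tumour_vaf"] = pd.Series(dtype=float)
        out["passed"] = pd.Series(dtype=bool)
        out["rule"] = pd.Series(dtype=object)
        return out
    out["p_value"] = fisher_exact_one_sided_many(
        out["alt_t"].to_numpy(), out["ref_t"].to_numpy(),
        out["alt_c"].to_numpy(), out["ref_c"].to_numpy(),
        alternative=config.fisher_alternative)
    depth_t = out["alt_t"] + out["ref_t"]
    out["tumour_vaf"] = out["alt_t"] / depth_t.replace(0, np.nan)
    snp_ids = set(snp_ids)
    bad_genes = set(incomplete_orf_genes)

    rules = []
    for row in out.itertuples():
        if row.p_value > config.fisher_p_max:
            rules.append("fisher_p")
        elif not (row.tumour_vaf >= config.wes_vaf_min):
            rules.append("tumour_vaf")
        elif str(row.consequence).lower().startswith("synonymous"):
            rules.append("synonymous")
        elif row.mutation_id in snp_ids:
            rules.append("known_snp")
        elif row.gene in bad_genes:
            rules.append("incomplete_orf")
        else:
            rules.append("pass")
    out["rule"] = rules
    out["passed"] = out["rule"] == "pass"
    return out


def deep_seq_call(
    base_counts: dict[str, int],
    ref_base: str,
    alt_base: str,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[bool, float, bool]:
    """Deep-sequencing detection call at one position.

    A variant is called iff its VAF is at or above the detection cutoff
    (0.2%: 20 variant reads at 10,000x) AND the variant base ranks second
    among the four base counts, the reference ranking first. A tie between
    the variant base and another non-reference base still counts as
    second-highest (the call stands) but is reported through the third
    return element.

    Returns ``(called, vaf, tied_second)``.
    """
    if alt_base == ref_base:
        raise ValueError("alt base equals reference base")
    if set(base_counts) != set(BASES):
        raise ValueError("base_counts must cover A, C, G, T")
    depth = sum(base_counts.values())
    if depth <= 0:
        raise ValueError("depth must be positive")
    alt = base_counts[alt_base]
    vaf = alt / depth
    others = [base_counts[b] for b in BASES if b not in (ref_base, alt_base)]
    ref = base_counts[ref_base]
    # ref must be the top count and alt at least ties every other base
    second_highest = ref >= alt and all(alt >= o for o in others)
    tied = second_highest and any(alt == o for o in others) and alt > 0
    called = vaf >= config.deep_vaf_min and second_highest
    return called, vaf, tied


def validate_mutation(tumour_vaf: float, germline_vaf: float,
                      config: PipelineConfig = DEFAULT_CONFIG) -> bool:
    """Deep-sequencing validation: tumour VAF exceeds germline by at least
    5 percentage points (inclusive)."""
    if not (0 <= tumour_vaf <= 1 and 0 <= germline_vaf <= 1):
        raise ValueError("VAFs must lie in [0, 1]")
    # small slack so the inclusive boundary survives float subtraction
    return tumour_vaf - germline_vaf >= config.validation_delta - 1e-12


def fish_cutoff(control_fractions: Sequence[float]) -> float:
    """FISH positivity cutoff: mean + 3 sample s.d. of control false-positive
    nucleus fractions (n-1 denominator)."""
    x = np.asarray(control_fractions, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 control values")
    return float(x.mean() + 3.0 * x.std(ddof=1))


# Default immunoglobulin / T-cell-receptor locus gene prefixes; focal CNAs
# there reflect physiological rearrangement in lymphocytes, not tumour events.
IG_TCR_PREFIXES = ("IGH", "IGK", "IGL", "TRA", "TRB", "TRG", "TRD")


def _is_ig_tcr(genes: Iterable[str]) -> bool:
    return any(g.upper().startswith(IG_TCR_PREFIXES) for g in genes)


def filter_cna_segments(
    segments: Iterable[CnaSegment],
    cancer_genes: Iterable[str] = (),
    normal_variant_db: Iterable[tuple[str, int, int]] = (),
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[CnaSegment]:
    """Keep true copy-number aberrations, drop artefacts and normal variants.

    * CNA kept iff longer than 5 Mb (karyotype resolution), or <= 5 Mb but
      overlapping a known cancer gene;
    * then dropped if matching an entry of the normal-variant database
      (reciprocal overlap of the same chromosome >= 50%) or lying in an
      IG/TCR locus;
    * CN-LOH kept iff longer than 10 Mb AND extending to a telomere.

    Output order is canonical (chrom, start, end); the filter is idempotent
    and independent of input order.
    """
    cancer_genes = {g.upper() for g in cancer_genes}
    normal_db = list(normal_variant_db)
    kept = []
    for seg in segments:
        if seg.is_cnloh:
            if not (seg.length > config.cnloh_min_len and seg.reaches_telomere):
                continue
        else:
            big = seg.length > config.cna_min_len
            rescued = any(g.upper() in cancer_genes for g in seg.genes)
            if not (big or rescued):
                continue
        if _is_ig_tcr(seg.genes):
            continue
        if any(_reciprocal_overlap(seg, chrom, s, e) >= 0.5
               for chrom, s, e in normal_db):
            continue
        kept.append(seg)
    kept.sort(key=lambda s: (s.chrom, s.start, s.end))
    # drop exact duplicates so the filter is idempotent over concatenations
    uniq: list[CnaSegment] = []
    for seg in kept:
        if not uniq or seg != uniq[-1]:
            uniq.append(seg)
    return uniq


def _reciprocal_overlap(seg: CnaSegment, chrom: str, start: int, end: int) -> float:
    if seg.chrom != chrom:
        return 0.0
    inter = min(seg.end, end) - max(seg.start, start)
    if inter <= 0:
        return 0.0
    return inter / max(seg.length, end - start)
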