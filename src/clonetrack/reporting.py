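"""Cohort-level summaries: mutation spectra, age correlation, patient counts,
and deterministic tabular export of a reconstruction."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .reconstruct import CloneForestEstimate, clone_fractions

TRANSITION_CLASSES = ("G:C>A:T", "A:T>G:C")
SUBSTITUTION_CLASSES = (
    "G:C>A:T", "A:T>G:C", "G:C>T:A", "G:C>C:G", "A:T>C:G", "A:T>T:A",
)

_PAIR_TO_CLASS = {
    ("C", "T"): "G:C>A:T", ("G", "A"): "G:C>A:T",
    ("A", "G"): "A:T>G:C", ("T", "C"): "A:T>G:C",
    ("C", "A"): "G:C>T:A", ("G", "T"): "G:C>T:A",
    ("C", "G"): "G:C>C:G", ("G", "C"): "G:C>C:G",
    ("A", "C"): "A:T>C:G", ("T", "G"): "A:T>C:G",
    ("A", "T"): "A:T>T:A", ("T", "A"): "A:T>T:A",
}


def substitution_class(ref: str, alt: str) -> str:
    """Strand-symmetric class of a single-base substitution."""
    key = (ref.upper(), alt.upper())
    if key not in _PAIR_TO_CLASS:
        raise ValueError(f"not an ACGT single-base substitution: {ref}>{alt}")
    return _PAIR_TO_CLASS[key]


def is_transition(ref: str, alt: str) -> bool:
    return substitution_class(ref, alt) in TRANSITION_CLASSES


@dataclass
class SpectrumSummary:
    """Counts by alteration class and by substitution class."""

    by_consequence: dict[str, int] = field(default_factory=dict)
    by_substitution: dict[str, int] = field(default_factory=dict)
    n_transitions: int = 0
    n_transversions: int = 0

    @property
    def n_alterations(self) -> int:
        return sum(self.by_consequence.values())

    @property
    def n_snvs(self) -> int:
        return sum(self.by_substitution.values())

    @property
    def transition_fraction(self) -> float:
        n = self.n_snvs
        return self.n_transitions / n if n else float("nan")


def mutation_spectrum(mutations: pd.DataFrame) -> SpectrumSummary:
    """Spectrum over a mutation table with columns ref, alt, consequence.

    Single-base ref/alt pairs are classed into the six strand-symmetric
    substitution categories; multi-base alleles (indels) contribute to the
    consequence tally only. Every mutation lands in exactly one consequence
    class and every SNV in exactly one substitution class.
    """
    summary = SpectrumSummary(
        by_substitution={c: 0 for c in SUBSTITUTION_CLASSES})
    for row in mutations.itertuples():
        cons = str(row.consequence)
        summary.by_consequence[cons] = summary.by_consequence.get(cons, 0) + 1
        ref, alt = str(row.ref), str(row.alt)
        if len(ref) == 1 and len(alt) == 1:
            klass = substitution_class(ref, alt)
            summary.by_substitution[klass] += 1
            if klass in TRANSITION_CLASSES:
                summary.n_transitions += 1
            else:
                summary.n_transversions += 1
    return summary


def early_late_spectrum(mutations: pd.DataFrame,
                        ) -> dict[str, object]:
    """Transition/transversion composition of early vs late mutations.

    ``mutations`` needs columns ref, alt, consequence and ``early`` (bool:
    detected in the first sample). Returns per-stratum spectra and a
    two-sided Fisher exact comparison of the transition fraction — reported
    as numbers only, no decision threshold. Empty strata are flagged and
    leave the comparison undefined.
    """
    early = mutation_spectrum(mutations[mutations["early"]])
    late = mutation_spectrum(mutations[~mutations["early"]])
    out: dict[str, object] = {"early": early, "late": late}
    if early.n_snvs == 0 or late.n_snvs == 0:
        out["p_value"] = None
        out["note"] = "empty stratum; comparison undefined"
        return out
    table = [[early.n_transitions, early.n_transversions],
             [late.n_transitions, late.n_transversions]]
    out["p_value"] = float(stats.fisher_exact(table,
                                              alternative="two-sided")[1])
    return out


def age_defect_correlation(ages, defect_counts) -> tuple[float, float]:
    """Pearson correlation of patient age with first-sample defect count.

    Two-tailed p from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom. Requires n >= 3 and non-degenerate variance in both vectors.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(defect_counts, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def patient_summary(mutations_by_patient: dict[str, pd.DataFrame],
                    driver_genes) -> pd.DataFrame:
    """Per-patient mutation totals and driver counts plus cohort rows.

    ``driver_genes`` is any iterable of gene symbols (a bundled myeloid
    panel ships with the package). The returned frame has one row per
    patient and a trailing ``cohort`` row holding medians and ranges.
    """
    drivers = {g.upper() for g in driver_genes}
    rows = []
    for patient in sorted(mutations_by_patient):
        muts = mutations_by_patient[patient]
        total = len(muts)
        n_driver = int(muts["gene"].str.upper().isin(drivers).sum())
        rows.append((patient, total, n_driver))
    frame = pd.DataFrame(rows, columns=["patient", "n_mutations", "n_drivers"])
    if len(frame):
        cohort = pd.DataFrame([{
            "patient": "cohort",
            "n_mutations": float(frame["n_mutations"].median()),
            "n_drivers": float(frame["n_drivers"].median()),
            "mutations_range": f"{frame['n_mutations'].min()}-"
                               f"{frame['n_mutations'].max()}",
            "drivers_range": f"{frame['n_drivers'].min()}-"
                             f"{frame['n_drivers'].max()}",
        }])
        frame = pd.concat([frame, cohort], ignore_index=True)
    return frame


def export_outputs(estimate: CloneForestEstimate,
                   assignment: dict[str, str],
                   out_dir: str | Path,
                   spectrum: SpectrumSummary | None = None,
                   ) -> dict[str, Path]:
    """Write a reconstruction as deterministic plain-text tables.

    Emits cluster assignments, a fishplot-ready clone-fraction table
    (clone, parent, time/sample, fraction), a forest JSON with score and
    violations, and optionally spectrum tallies. Identical inputs produce
    identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    assign = pd.DataFrame(sorted(assignment.items()),
                          columns=["mutation_id", "cluster_id"])
    paths["clusters"] = out / "cluster_assignments.tsv"
    assign.to_csv(paths["clusters"], sep="\t", index=False)

    fracs = clone_fractions(estimate)
    rows = []
    for clone in fracs.index:
        parent = estimate.parent.get(clone)
        for sample in fracs.columns:
            rows.append((clone, "" if parent is None else parent,
                         sample, float(fracs.at[clone, sample])))
    fish = pd.DataFrame(rows, columns=["clone_id", "parent_id", "sample",
                                       "fraction"])
    paths["fishplot"] = out / "clone_fractions.tsv"
    fish.to_csv(paths["fishplot"], sep="\t", index=False,
                float_format="%.6f")

    forest = {
        "parent": {c: estimate.parent[c] for c in sorted(estimate.parent)},
        "roots": estimate.roots,
        "score": estimate.score,
        "n_admissible": estimate.n_admissible,
        "violations": list(estimate.violations),
        "unrelated_roots": dict(sorted(estimate.unrelated_roots.items())),
        "ccf": {c: [float(x) for x in estimate.ccf.loc[c].fillna(-1)]
                for c in sorted(estimate.parent)},
        "samples": [str(s) for s in estimate.ccf.columns],
    }
    paths["forest"] = out / "forest.json"
    with open(paths["forest"], "w") as fh:
        json.dump(forest, fh, indent=1, sort_keys=True)

    if spectrum is not None:
        spec_rows = (
            [("consequence", k, v)
             for k, v in sorted(spectrum.by_consequence.items())]
            + [("substitution", k, spectrum.by_substitution[k])
               for k in SUBSTITUTION_CLASSES]
            + [("total", "transitions", spectrum.n_transitions),
               ("total", "transversions", spectrum.n_transversions)])
        spec = pd.DataFrame(spec_rows, columns=["kind", "class", "count"])
        paths["spectrum"] = out / "spectrum.tsv"
        spec.to_csv(paths["spectrum"], sep="\t", index=False)
    return paths
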