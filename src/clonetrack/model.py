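"""Model/Results interface tying the pipeline together.

:class:`ClonalEvolution` is built from the tabular inputs of one patient
(read counts, sample sheet, copy-number segments, optional colony VAFs and
variant annotations); ``fit()`` runs validation, CCF construction,
trajectory clustering and clone-forest selection, returning a
:class:`ClonalEvolutionResults` that carries the estimates, diagnostics and
a ``summary()`` table, and can export fishplot-ready files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ct_io
from .ccf import (CcfMatrix, CopyNumberState, assign_cn_state,
                  build_ccf_matrix)
from .clustering import MutationCluster, cluster_centroids, cluster_mutations
from .config import DEFAULT_CONFIG, PipelineConfig
from .filters import CnaSegment, validate_mutation
from .reconstruct import (CloneForestEstimate, ColonyConstraints,
                          EvolutionPattern, best_violating_forest,
                          classify_pattern, clone_fractions,
                          colony_constraints, constraints_to_clusters,
                          detect_unrelated_clones, enumerate_forests,
                          genotype_matrix, score_and_select)
from .reporting import export_outputs, mutation_spectrum

GERMLINE_TISSUES = {"T_cells", "MSC"}


class ClonalEvolution:
    """Clonal-evolution model for one patient's serial samples.

    Parameters
    ----------
    counts : long-format frame with columns patient, sample_id,
        mutation_id, alt_count, depth.
    sample_sheet : frame with patient, sample_id, tissue, time_days,
        platform, treatment_label. Samples with tissue in {T_cells, MSC}
        serve as germline controls.
    segments : kept copy-number segments (already through the aberration
        filter, or raw simulator truth).
    colonies : optional long colony VAF table (colony_id, mutation_id, vaf).
    variants : optional annotation frame (mutation_id, chrom, pos, ref,
        alt, gene, consequence); needed for copy-number state assignment
        and spectra.
    sex : "female" or "male" (sets normal ploidy on X/Y).
    """

    def __init__(self, counts: pd.DataFrame, sample_sheet: pd.DataFrame,
                 segments: list[CnaSegment] = (),
                 colonies: pd.DataFrame | None = None,
                 variants: pd.DataFrame | None = None,
                 sex: str = "female",
                 config: PipelineConfig = DEFAULT_CONFIG):
        self.counts = counts.copy()
        self.sample_sheet = sample_sheet.copy()
        self.segments = list(segments)
        self.colonies = colonies
        self.variants = variants
        self.sex = sex
        self.config = config
        patients = set(self.counts["patient"].unique())
        if len(patients) != 1:
            raise ValueError(
                f"one patient per model; got {sorted(patients)}")
        self.patient = patients.pop()

    @classmethod
    def from_dir(cls, path: str | Path, sex: str = "female",
                 config: PipelineConfig = DEFAULT_CONFIG) -> "ClonalEvolution":
        """Build from a cohort directory written by the simulator or CLI."""
        d = Path(path)
        counts = ct_io.read_counts_tsv(d / "counts.tsv")
        sheet = ct_io.read_sample_sheet(d / "samples.tsv")
        segments = (ct_io.read_segments_tsv(d / "segments.tsv")
                    if (d / "segments.tsv").exists() else [])
        colonies = (ct_io.read_colonies_tsv(d / "colonies.tsv")
                    if (d / "colonies.tsv").exists() else None)
        variants = (pd.read_csv(d / "variants.tsv", sep="\t")
                    if (d / "variants.tsv").exists() else None)
        return cls(counts, sheet, segments, colonies, variants, sex=sex,
                   config=config)

    # ------------------------------------------------------------------
    def _split_samples(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        sheet = self.sample_sheet
        germ = sheet[sheet["tissue"].isin(GERMLINE_TISSUES)]
        tum = sheet[~sheet["tissue"].isin(GERMLINE_TISSUES)]
        return tum, germ

    def _validated_mutations(self) -> list[str]:
        """Deep-sequencing validation: max tumour VAF exceeds the germline
        VAF by at least the configured difference (5 points)."""
        tum_sheet, germ_sheet = self._split_samples()
        counts = self.counts
        vaf = counts.assign(
            vaf=counts["alt_count"] / counts["depth"].clip(lower=1))
        tum = vaf[vaf["sample_id"].isin(tum_sheet["sample_id"])]
        germ = vaf[vaf["sample_id"].isin(germ_sheet["sample_id"])]
        max_t = tum.groupby("mutation_id")["vaf"].max()
        max_g = (germ.groupby("mutation_id")["vaf"].max()
                 if len(germ) else pd.Series(0.0, index=max_t.index))
        validated = []
        for mid, tv in max_t.items():
            gv = float(max_g.get(mid, 0.0))
            if validate_mutation(min(tv, 1.0), min(gv, 1.0), self.config):
                validated.append(mid)
        return sorted(validated)

    def _cn_states(self, mutation_ids) -> dict[str, CopyNumberState]:
        states: dict[str, CopyNumberState] = {}
        if self.variants is None:
            return states
        var = self.variants.set_index("mutation_id")
        for mid in mutation_ids:
            if mid not in var.index:
                continue
            v = var.loc[mid]
            states[mid] = assign_cn_state(
                str(v.chrom), int(v.pos), self.segments, sex=self.sex)
        return states

    def fit(self) -> "ClonalEvolutionResults":
        tum_sheet, _ = self._split_samples()
        validated = self._validated_mutations()
        counts = self.counts[
            self.counts["mutation_id"].isin(validated)
            & self.counts["sample_id"].isin(tum_sheet["sample_id"])]
        states = self._cn_states(validated)
        matrix = build_ccf_matrix(counts, states, tum_sheet, self.config)

        clusters = cluster_mutations(matrix, config=self.config)
        centroids = cluster_centroids(clusters, matrix)
        centroid_se = pd.DataFrame(
            {cl.cluster_id: cl.centroid_se for cl in clusters}).T

        assignment = {m: cl.cluster_id for cl in clusters for m in cl.members}
        cons = ColonyConstraints()
        cluster_cons = ColonyConstraints()
        if self.colonies is not None and len(self.colonies):
            gmat = genotype_matrix(self.colonies, self.config)
            keep = [m for m in gmat.columns if m in assignment]
            cons = colony_constraints(gmat[keep])
            cluster_cons = constraints_to_clusters(cons, assignment)

        if len(clusters) == 0:
            estimate = CloneForestEstimate(
                parent={}, ccf=centroids, score=0.0, n_admissible=0)
            pattern = EvolutionPattern("single_clone", False)
            return ClonalEvolutionResults(
                model=self, ccf_matrix=matrix, clusters=clusters,
                assignment={}, estimate=estimate, pattern=pattern,
                colony_cons=cons, validated=validated)

        forests = enumerate_forests(centroids, centroid_se, cluster_cons,
                                    self.config)
        if forests:
            estimate = score_and_select(forests, centroids, centroid_se,
                                        self.config)
        else:
            estimate = best_violating_forest(centroids, centroid_se,
                                             cluster_cons, self.config)
        detect_unrelated_clones(estimate, cluster_cons, self.config)
        pattern = classify_pattern(estimate)
        return ClonalEvolutionResults(
            model=self, ccf_matrix=matrix, clusters=clusters,
            assignment=assignment, estimate=estimate, pattern=pattern,
            colony_cons=cons, validated=validated)


@dataclass
class ClonalEvolutionResults:
    """Fitted clonal reconstruction for one patient."""

    model: ClonalEvolution
    ccf_matrix: CcfMatrix
    clusters: list[MutationCluster]
    assignment: dict[str, str]
    estimate: CloneForestEstimate
    pattern: EvolutionPattern
    colony_cons: ColonyConstraints
    validated: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def clone_fractions(self) -> pd.DataFrame:
        return clone_fractions(self.estimate)

    def summary(self) -> str:
        """Human-readable account of the fit, statsmodels-style."""
        lines = []
        e = self.estimate
        lines.append("Clonal evolution reconstruction")
        lines.append("=" * 46)
        lines.append(f"Patient:              {self.model.patient}")
        lines.append(f"Validated mutations:  {len(self.validated)}")
        lines.append(f"Mutation clusters:    {self.n_clusters}")
        lines.append(f"Pattern:              {self.pattern.kind}"
                     + (" + unrelated clone(s)"
                        if self.pattern.unrelated_clones else ""))
        lines.append(f"Admissible forests:   {e.n_admissible}")
        lines.append(f"Parsimony score:      {e.score:.4f}")
        if e.violations:
            lines.append("Violations:")
            for v in e.violations:
                lines.append(f"  - {v}")
        if e.unrelated_roots:
            for r, grade in sorted(e.unrelated_roots.items()):
                lines.append(f"Unrelated root {r}: {grade}")
        lines.append("-" * 46)
        lines.append("Cluster CCF trajectories (parent <- cluster):")
        for cid in sorted(e.parent):
            par = e.parent[cid] or "root"
            vals = " ".join(f"{x:6.3f}" for x in
                            e.ccf.loc[cid].fillna(float('nan')))
            n_mut = sum(1 for m, c in self.assignment.items() if c == cid)
            lines.append(f"  {cid} <- {par:>6s}  [{n_mut:2d} mut]  {vals}")
        return "\n".join(lines)

    def export(self, out_dir: str | Path) -> dict[str, Path]:
        spectrum = None
        if self.model.variants is not None:
            var = self.model.variants
            spectrum = mutation_spectrum(
                var[var["mutation_id"].isin(self.validated)])
        return export_outputs(self.estimate, self.assignment, out_dir,
                              spectrum=spectrum)
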