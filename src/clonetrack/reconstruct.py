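"""Clone-forest inference from cluster trajectories and colony genotypes.

Given time-ordered CCF centroids per mutation cluster, every assignment of
a parent (or root status) to each cluster is enumerated and kept when it
satisfies, at every timepoint and within a depth-scaled tolerance:

* the pigeonhole rule — a child's CCF never exceeds its parent's;
* the sum rule — siblings' CCFs never sum beyond their parent's;
* the root bound — root CCFs sum to at most 1;
* temporal precedence — a parent is first detected no later than its child;
* colony constraints — pairs proved mutually exclusive by single-colony
  genotyping never share a root path, and colony-proved ancestry is never
  inverted.

Among admissible forests the selected one minimises a parsimony score:
squared sum-rule slack plus penalties for extra roots and branch points.
Enumeration is exhaustive (deterministic and auditable) and capped at a
cluster count far above what serial-sample patients produce.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .clustering import MutationCluster
from .config import DEFAULT_CONFIG, PipelineConfig

ROOT = "__root__"


class CombinatorialLimitError(ValueError):
    """Too many clusters for exhaustive forest enumeration."""


class Genotype(Enum):
    PRESENT = 1
    ABSENT = 0
    AMBIGUOUS = -1


def genotype_colony(vafs: pd.Series,
                    config: PipelineConfig = DEFAULT_CONFIG) -> pd.Series:
    """Ternary genotype of one colony from its per-mutation VAFs.

    VAF > 40% -> present; VAF < 5% -> absent; anything between is ambiguous
    (the colony may be mixed) and excluded from phylogenetic constraints.
    """
    if ((vafs < 0) | (vafs > 1)).any():
        raise ValueError("colony VAFs must lie in [0, 1]")
    out = pd.Series(Genotype.AMBIGUOUS, index=vafs.index, dtype=object)
    out[vafs > config.colony_present_vaf] = Genotype.PRESENT
    out[vafs < config.colony_absent_vaf] = Genotype.ABSENT
    return out


def genotype_matrix(colony_table: pd.DataFrame,
                    config: PipelineConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Colonies x mutations ternary matrix from a long colony VAF table
    (columns colony_id, mutation_id, vaf)."""
    wide = colony_table.pivot(index="colony_id", columns="mutation_id",
                              values="vaf")
    return wide.apply(lambda row: genotype_colony(row.dropna(), config),
                      axis=1).reindex(columns=sorted(wide.columns))


@dataclass
class ColonyConstraints:
    """Pairwise mutation relations implied by unambiguous colonies.

    nested : (i, j) pairs where i is ancestral to j (every colony with j
        also carries i, and some colony has i without j)
    exclusive : unordered pairs never co-occurring though each occurs alone
    violations : pairs showing all three patterns (perfect-phylogeny breach)
    """

    nested: set[tuple[str, str]] = field(default_factory=set)
    exclusive: set[frozenset] = field(default_factory=set)
    violations: set[frozenset] = field(default_factory=set)
    n_colonies_used: int = 0


def colony_constraints(matrix: pd.DataFrame) -> ColonyConstraints:
    """Derive nesting/exclusivity from a ternary colony genotype matrix.

    Colonies containing any ambiguous entry are dropped (possibly mixed).
    For each mutation pair the observed patterns among {(1,0), (0,1), (1,1)}
    decide the relation; all three together break the perfect phylogeny and
    are reported, never silently resolved.
    """
    clean = matrix[~matrix.apply(
        lambda r: (r == Genotype.AMBIGUOUS).any(), axis=1)]
    out = ColonyConstraints(n_colonies_used=len(clean))
    if len(clean) == 0:
        return out
    muts = list(clean.columns)
    present = (clean == Genotype.PRESENT).to_numpy()
    for a, b in itertools.combinations(range(len(muts)), 2):
        i, j = muts[a], muts[b]
        both = bool(np.any(present[:, a] & present[:, b]))
        only_i = bool(np.any(present[:, a] & ~present[:, b]))
        only_j = bool(np.any(~present[:, a] & present[:, b]))
        if both and only_i and only_j:
            out.violations.add(frozenset((i, j)))
        elif both and only_i:
            out.nested.add((i, j))
        elif both and only_j:
            out.nested.add((j, i))
        elif only_i and only_j:
            out.exclusive.add(frozenset((i, j)))
    return out


def constraints_to_clusters(constraints: ColonyConstraints,
                            assignment: dict[str, str]) -> ColonyConstraints:
    """Lift mutation-level colony constraints to cluster level.

    Pairs inside one cluster are dropped (exclusivity there is already a
    reported violation at mutation level)."""
    out = ColonyConstraints(n_colonies_used=constraints.n_colonies_used)
    for i, j in constraints.nested:
        ci, cj = assignment.get(i), assignment.get(j)
        if ci and cj and ci != cj:
            out.nested.add((ci, cj))
    for pair in constraints.exclusive:
        i, j = sorted(pair)
        ci, cj = assignment.get(i), assignment.get(j)
        if ci and cj and ci != cj:
            out.exclusive.add(frozenset((ci, cj)))
    out.violations = set(constraints.violations)
    return out


@dataclass
class CloneForestEstimate:
    """Selected clone forest with diagnostics."""

    parent: dict[str, str | None]  # cluster -> parent cluster (None = root)
    ccf: pd.DataFrame              # clusters x samples (centroids)
    score: float
    n_admissible: int
    slack: pd.DataFrame | None = None     # per (node, sample) sum-rule excess
    violations: list[str] = field(default_factory=list)
    unrelated_roots: dict[str, str] = field(default_factory=dict)

    @property
    def roots(self) -> list[str]:
        return sorted(c for c, p in self.parent.items() if p is None)

    def children(self, cid: str | None) -> list[str]:
        return sorted(c for c, p in self.parent.items() if p == cid)

    def ancestors(self, cid: str) -> list[str]:
        out = []
        cur = self.parent[cid]
        while cur is not None:
            out.append(cur)
            cur = self.parent[cur]
        return out

    def tree_of(self, root: str) -> set[str]:
        members = {root}
        frontier = [root]
        while frontier:
            nxt = []
            for c in frontier:
                kids = self.children(c)
                members.update(kids)
                nxt.extend(kids)
            frontier = nxt
        return members


def first_detection(centroids: pd.DataFrame, floor: float = 0.01) -> pd.Series:
    """First sample index at which each cluster's centroid CCF clears the
    floor; clusters never detected get the sample count (sorts last)."""
    n = centroids.shape[1]
    idx = {}
    for cid, row in centroids.iterrows():
        above = np.flatnonzero(row.to_numpy(dtype=float) > floor)
        idx[cid] = int(above[0]) if above.size else n
    return pd.Series(idx)


def _epsilon(pooled_se: np.ndarray, eps_floor: float) -> np.ndarray:
    return np.maximum(eps_floor, 2.0 * pooled_se)


def enumerate_forests(
    centroids: pd.DataFrame,
    centroid_se: pd.DataFrame | None = None,
    cluster_constraints: ColonyConstraints | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[dict[str, str | None]]:
    """All parent assignments satisfying the clonal constraints.

    ``centroids`` holds cluster CCFs (clusters x time-ordered samples);
    ``centroid_se`` their standard errors (zeros when omitted). Returns a
    deterministic, lexicographically sorted list of parent maps.
    """
    clusters = sorted(centroids.index)
    k = len(clusters)
    if k == 0:
        return []
    if k > config.max_clusters_exhaustive:
        raise CombinatorialLimitError(
            f"{k} clusters exceed the exhaustive cap of "
            f"{config.max_clusters_exhaustive}")
    C = centroids.loc[clusters].to_numpy(dtype=float)
    C = np.nan_to_num(C, nan=0.0)
    if centroid_se is None:
        S = np.zeros_like(C)
    else:
        S = np.nan_to_num(centroid_se.loc[clusters].to_numpy(dtype=float),
                          nan=0.0)
    detect = first_detection(centroids.loc[clusters]).to_numpy()
    cons = cluster_constraints or ColonyConstraints()
    nested = {(clusters.index(a), clusters.index(b))
              for a, b in cons.nested if a in clusters and b in clusters}
    exclusive = {frozenset((clusters.index(a), clusters.index(b)))
                 for pair in cons.exclusive
                 for a, b in [sorted(pair)] if a in clusters and b in clusters}

    # pigeonhole + temporal pre-screen of single edges
    allowed: list[list[int]] = []
    for child in range(k):
        opts = [-1]
        for par in range(k):
            if par == child:
                continue
            eps = _epsilon(np.sqrt(S[child] ** 2 + S[par] ** 2),
                           config.eps_floor)
            if np.all(C[child] <= C[par] + eps) and detect[par] <= detect[child]:
                opts.append(par)
        allowed.append(opts)

    results: list[tuple[int, ...]] = []
    parent_vec = [-2] * k

    def _creates_cycle(child: int, par: int) -> bool:
        cur = par
        while cur != -1:
            if cur == child:
                return True
            cur = parent_vec[cur] if parent_vec[cur] != -2 else -1
        return False

    def _on_same_path(i: int, j: int) -> bool:
        for a, b in ((i, j), (j, i)):
            cur = a
            while cur != -1 and parent_vec[cur] != -2:
                cur = parent_vec[cur]
                if cur == b:
                    return True
        return False

    def _recurse(child: int) -> None:
        if child == k:
            if _final_check():
                results.append(tuple(parent_vec))
            return
        for par in allowed[child]:
            if par != -1 and _creates_cycle(child, par):
                continue
            parent_vec[child] = par
            _recurse(child + 1)
            parent_vec[child] = -2

    def _final_check() -> bool:
        # sum rule per node and root bound
        kids: dict[int, list[int]] = {}
        for c, p in enumerate(parent_vec):
            kids.setdefault(p, []).append(c)
        for p, cs in kids.items():
            if p == -1:
                total = C[cs].sum(axis=0)
                eps = _epsilon(np.sqrt((S[cs] ** 2).sum(axis=0)),
                               config.eps_floor)
                if np.any(total > 1.0 + eps):
                    return False
            else:
                total = C[cs].sum(axis=0)
                eps = _epsilon(
                    np.sqrt((S[cs] ** 2).sum(axis=0) + S[p] ** 2),
                    config.eps_floor)
                if np.any(total > C[p] + eps):
                    return False
        # colony constraints
        for i, j in nested:
            if _is_ancestor(j, i):
                return False
        for pair in exclusive:
            i, j = sorted(pair)
            if _is_ancestor(i, j) or _is_ancestor(j, i):
                return False
        return True

    def _is_ancestor(a: int, b: int) -> bool:
        cur = parent_vec[b]
        while cur != -1:
            if cur == a:
                return True
            cur = parent_vec[cur]
        return False

    _recurse(0)
    results.sort()
    return [
        {clusters[c]: (None if p == -1 else clusters[p])
         for c, p in enumerate(vec)}
        for vec in results
    ]


def _forest_stats(parent: dict[str, str | None],
                  centroids: pd.DataFrame,
                  centroid_se: np.ndarray | pd.DataFrame | None,
                  config: PipelineConfig) -> tuple[float, pd.DataFrame]:
    clusters = sorted(parent)
    C = centroids.loc[clusters]
    if centroid_se is None:
        S = pd.DataFrame(0.0, index=C.index, columns=C.columns)
    else:
        S = pd.DataFrame(centroid_se).loc[clusters]
    slack_rows = {}
    penalty = 0.0
    for p in clusters:
        kids = sorted(c for c in clusters if parent[c] == p)
        if not kids:
            continue
        total = C.loc[kids].sum(axis=0)
        excess = (total - C.loc[p]).clip(lower=0.0)
        var = (S.loc[kids] ** 2).sum(axis=0) + S.loc[p] ** 2
        var = var.where(var > 0, 1e-6)
        penalty += float((excess ** 2 / var).sum())
        slack_rows[p] = excess
    roots = [c for c in clusters if parent[c] is None]
    branch_nodes = sum(
        1 for p in clusters
        if sum(1 for c in clusters if parent[c] == p) >= 2)
    score = (penalty + config.lambda_root * (len(roots) - 1)
             + config.mu_branch * branch_nodes)
    slack = pd.DataFrame(slack_rows).T if slack_rows else pd.DataFrame(
        columns=C.columns)
    return score, slack


def score_and_select(
    forests: list[dict[str, str | None]],
    centroids: pd.DataFrame,
    centroid_se: pd.DataFrame | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> CloneForestEstimate:
    """Pick the minimum-score forest.

    Score = squared sum-rule slack in pooled-se units, plus lambda per extra
    root and mu per branch node. Ties break deterministically: fewer roots,
    fewer branch nodes, then lexicographic parent vector.
    """
    if not forests:
        raise ValueError("no forests supplied; use best_violating_forest")
    ranked = []
    for parent in forests:
        score, slack = _forest_stats(parent, centroids, centroid_se, config)
        clusters = sorted(parent)
        n_roots = sum(1 for c in clusters if parent[c] is None)
        n_branch = sum(
            1 for p in clusters
            if sum(1 for c in clusters if parent[c] == p) >= 2)
        vec = tuple("" if parent[c] is None else parent[c] for c in clusters)
        ranked.append((score, n_roots, n_branch, vec, parent, slack))
    ranked.sort(key=lambda r: r[:4])
    score, _, _, _, parent, slack = ranked[0]
    return CloneForestEstimate(
        parent=dict(parent), ccf=centroids.loc[sorted(parent)],
        score=score, n_admissible=len(forests), slack=slack)


def best_violating_forest(
    centroids: pd.DataFrame,
    centroid_se: pd.DataFrame | None = None,
    cluster_constraints: ColonyConstraints | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> CloneForestEstimate:
    """Fallback when no forest satisfies every constraint.

    Clusters are taken in descending mean-CCF order; each attaches to the
    already-placed cluster (or root) that adds the least pigeonhole excess.
    The result is returned with an explicit violation table — the situation
    is reported, never silently repaired.
    """
    clusters = sorted(centroids.index)
    order = sorted(clusters,
                   key=lambda c: (-float(np.nanmean(centroids.loc[c])), c))
    C = centroids.fillna(0.0)
    parent: dict[str, str | None] = {}
    placed: list[str] = []
    for c in order:
        best, best_cost = None, float(np.maximum(
            C.loc[c] - 1.0, 0.0).sum())  # cost of making it a root (crude)
        for p in placed:
            cost = float(np.maximum(C.loc[c] - C.loc[p], 0.0).sum())
            if cost < best_cost - 1e-12:
                best, best_cost = p, cost
        parent[c] = best
        placed.append(c)
    score, slack = _forest_stats(parent, centroids, centroid_se, config)
    violations = []
    for c, p in parent.items():
        if p is None:
            continue
        eps = config.eps_floor
        excess = (C.loc[c] - C.loc[p]).clip(lower=0.0)
        if (excess > eps).any():
            violations.append(
                f"pigeonhole: {c} exceeds parent {p} by up to "
                f"{float(excess.max()):.3f}")
    cons = cluster_constraints or ColonyConstraints()
    for pair in cons.exclusive:
        violations.append(f"colony exclusivity unresolved: {sorted(pair)}")
    if not violations:
        violations.append("no admissible forest under sum/root constraints")
    return CloneForestEstimate(
        parent=parent, ccf=centroids.loc[clusters], score=score,
        n_admissible=0, slack=slack, violations=violations)


def detect_unrelated_clones(
    estimate: CloneForestEstimate,
    cluster_constraints: ColonyConstraints | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, str]:
    """Label every non-primary root with its evidence grade.

    The primary root is the earliest-detected (ties to the larger mean CCF)
    — the founding MDS clone. Grades, strongest first: ``colony-proven``
    (single-colony genotypes show mutual exclusivity with the primary tree),
    ``pigeonhole`` (the two roots' CCFs sum beyond 1 somewhere, so they
    cannot nest), ``topology-only`` (merely could not be attached).
    """
    roots = estimate.roots
    if len(roots) <= 1:
        estimate.unrelated_roots = {}
        return {}
    detect = first_detection(estimate.ccf)
    primary = min(roots, key=lambda r: (
        detect[r], -float(np.nanmean(estimate.ccf.loc[r])), r))
    primary_tree = estimate.tree_of(primary)
    cons = cluster_constraints or ColonyConstraints()
    out = {}
    for r in roots:
        if r == primary:
            continue
        tree = estimate.tree_of(r)
        colony_proof = any(
            (set(pair) & tree) and (set(pair) & primary_tree)
            for pair in cons.exclusive)
        if colony_proof:
            out[r] = "colony-proven"
            continue
        csum = estimate.ccf.loc[r].fillna(0) + estimate.ccf.loc[primary].fillna(0)
        if (csum > 1.0 + config.eps_floor).any():
            out[r] = "pigeonhole"
        else:
            out[r] = "topology-only"
    estimate.unrelated_roots = out
    return out


@dataclass(frozen=True)
class EvolutionPattern:
    kind: str  # single_clone | linear | branching
    unrelated_clones: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("single_clone", "linear", "branching"):
            raise ValueError(f"unknown pattern {self.kind!r}")


def classify_pattern(estimate: CloneForestEstimate) -> EvolutionPattern:
    """Evolution pattern of the primary tree.

    single_clone: one tree with one node; branching: some node of the
    primary tree has two or more children; otherwise linear. The unrelated
    flag reports extra roots (from detect_unrelated_clones when run, else
    from the root count)."""
    roots = estimate.roots
    detect = first_detection(estimate.ccf)
    primary = min(roots, key=lambda r: (
        detect[r], -float(np.nanmean(estimate.ccf.loc[r])), r))
    tree = estimate.tree_of(primary)
    unrelated = len(roots) > 1
    if len(tree) == 1 and len(estimate.parent) == 1:
        return EvolutionPattern("single_clone", unrelated)
    if len(tree) == 1:
        return EvolutionPattern("single_clone", unrelated)
    if any(len([c for c in tree if estimate.parent[c] == p]) >= 2
           for p in tree):
        return EvolutionPattern("branching", unrelated)
    return EvolutionPattern("linear", unrelated)


def clone_fractions(estimate: CloneForestEstimate) -> pd.DataFrame:
    """Exclusive clone fractions per timepoint (fishplot input).

    fraction(c, t) = CCF(c, t) - sum of children CCFs, clipped at 0; a final
    ``normal`` row holds 1 - sum of root CCFs."""
    C = estimate.ccf.fillna(0.0)
    rows = {}
    for c in sorted(estimate.parent):
        kids = estimate.children(c)
        frac = C.loc[c] - (C.loc[kids].sum(axis=0) if kids else 0.0)
        rows[c] = frac.clip(lower=0.0)
    rows["normal"] = (1.0 - C.loc[estimate.roots].sum(axis=0)).clip(lower=0.0)
    return pd.DataFrame(rows).T
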