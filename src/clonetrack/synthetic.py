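"""Ground-truthed synthetic longitudinal MDS cohorts.

The generator emulates the statistical structure of serial-sample clonal
surveillance in low-risk MDS: 2-8 samples over years, a handful of clones
carrying ~8-27 somatic mutations per patient arranged on a clone tree (or a
forest when an unrelated clone co-expands), del(5q)/monosomy/CN-LOH copy
number contexts, treatment windows that bottleneck the MDS tree while a
previously minor unrelated clone grows out, amplicon read counts at ~10,000x
and exome counts at ~110x with a per-alt-base substitution error, and
single-progenitor CFU-GEMM colony genotypes.

Everything is driven by one :class:`numpy.random.Generator`; fixing the seed
fixes every emitted byte.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ccf import CopyNumberState, expected_vaf
from .filters import BASES, CnaSegment

CONSEQUENCE_CLASSES = (
    "nonsynonymous SNV", "stopgain SNV", "frameshift indel",
    "inframe indel", "splice site",
)
# class weights emulate the observed alteration mix (nonsyn SNVs dominate)
_CONSEQUENCE_P = (0.82, 0.07, 0.05, 0.02, 0.04)

# strand-symmetric substitution classes; first two are the transitions.
SUBSTITUTION_CLASSES = (
    "G:C>A:T", "A:T>G:C", "G:C>T:A", "G:C>C:G", "A:T>C:G", "A:T>T:A",
)
# transition-heavy spectrum: ~65% transitions, G:C>A:T predominant
_SUBSTITUTION_P = (0.53, 0.12, 0.10, 0.08, 0.08, 0.09)

_CLASS_TO_PAIR = {
    "G:C>A:T": (("C", "T"), ("G", "A")),
    "A:T>G:C": (("A", "G"), ("T", "C")),
    "G:C>T:A": (("C", "A"), ("G", "T")),
    "G:C>C:G": (("C", "G"), ("G", "C")),
    "A:T>C:G": (("A", "C"), ("T", "G")),
    "A:T>T:A": (("A", "T"), ("T", "A")),
}

# copy-number contexts a clone may acquire; coordinates loosely follow the
# recurrent MDS lesions (hg19 scale), 0-based half-open.
CN_EVENTS = {
    "del5q": dict(chrom="5", start=30_000_000, end=150_000_000,
                  cn_total=1, cn_minor=0, is_cnloh=False,
                  reaches_telomere=False),
    "monosomy7": dict(chrom="7", start=0, end=159_000_000,
                      cn_total=1, cn_minor=0, is_cnloh=False,
                      reaches_telomere=True),
    "cnloh4q": dict(chrom="4", start=90_000_000, end=191_000_000,
                    cn_total=2, cn_minor=0, is_cnloh=True,
                    reaches_telomere=True),
}


def _load_driver_genes() -> tuple[str, ...]:
    path = Path(__file__).parent / "data" / "myeloid_drivers.txt"
    genes = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    return tuple(genes)


class InvalidConfigError(ValueError):
    pass


@dataclass
class TreatmentWindow:
    """Suppression of one root's whole tree inside [start, end] days."""

    start: float
    end: float
    factor: float
    target_root: int = 0  # index into the forest's root list

    def __post_init__(self) -> None:
        if not 0.0 < self.factor <= 1.0:
            raise InvalidConfigError("suppression factor must be in (0, 1]")
        if self.end < self.start:
            raise InvalidConfigError("window end before start")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_timepoints: int = 4
    times: tuple[float, ...] | None = None  # days; default spread over ~6 y
    depth_targeted: float = 10_000.0
    depth_wes: float = 110.0
    error_rate: float = 5e-4
    n_clones: int = 3
    topology: str = "random"  # single | linear | branching | random
    p_unrelated: float = 0.0
    n_driver_range: tuple[int, int] = (0, 1)     # per clone
    n_passenger_range: tuple[int, int] = (4, 6)  # per clone
    p_cn_event: float = 0.2
    treatment_windows: list[TreatmentWindow] = field(default_factory=list)
    contamination: float = 0.0  # tumour-in-germline fraction
    min_separation: float = 0.15  # pairwise clone CCF separation enforced
    min_clone_ccf: float = 0.15  # every clone must reach this somewhere
    n_colonies: int = 24
    p_mixed_colony: float = 0.0
    colony_depth: int = 200
    sex: str = "female"

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise InvalidConfigError("n_clones must be >= 1")
        if self.times is None:
            if self.n_timepoints < 1:
                raise InvalidConfigError("need at least one timepoint")
            self.times = tuple(
                np.linspace(0.0, 2200.0, self.n_timepoints).round(0))
        self.times = tuple(float(t) for t in self.times)
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise InvalidConfigError("times must be strictly increasing")
        self.n_timepoints = len(self.times)
        for p in (self.p_unrelated, self.p_cn_event, self.contamination,
                  self.p_mixed_colony):
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError("probabilities must lie in [0, 1]")
        if self.depth_targeted < 1 or self.depth_wes < 1:
            raise InvalidConfigError("depths must be >= 1")
        if self.topology not in ("single", "linear", "branching", "random"):
            raise InvalidConfigError(f"unknown topology {self.topology!r}")


@dataclass
class CloneNode:
    clone_id: str
    parent_id: str | None
    private_mutation_ids: list[str] = field(default_factory=list)
    cn_event: str | None = None  # key into CN_EVENTS


@dataclass
class CloneForest:
    """Rooted clone trees; more than one root means unrelated clones."""

    nodes: dict[str, CloneNode]

    def __post_init__(self) -> None:
        for node in self.nodes.values():
            if node.parent_id is not None and node.parent_id not in self.nodes:
                raise ValueError(f"dangling parent {node.parent_id}")
        # reject cycles by walking every node to a root
        for cid in self.nodes:
            seen = set()
            cur = cid
            while cur is not None:
                if cur in seen:
                    raise ValueError("parent pointers form a cycle")
                seen.add(cur)
                cur = self.nodes[cur].parent_id

    @property
    def roots(self) -> list[str]:
        return [c for c, n in sorted(self.nodes.items()) if n.parent_id is None]

    def children(self, clone_id: str) -> list[str]:
        return [c for c, n in sorted(self.nodes.items())
                if n.parent_id == clone_id]

    def root_path(self, clone_id: str) -> list[str]:
        """Ancestors from root down to (and including) the clone."""
        path = []
        cur = clone_id
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent_id
        return path[::-1]

    def root_of(self, clone_id: str) -> str:
        return self.root_path(clone_id)[0]

    def clone_of_mutation(self) -> dict[str, str]:
        out = {}
        for cid, node in self.nodes.items():
            for m in node.private_mutation_ids:
                if m in out:
                    raise ValueError(f"mutation {m} assigned twice")
                out[m] = cid
        return out

    def mutations_on_path(self, clone_id: str) -> list[str]:
        muts = []
        for cid in self.root_path(clone_id):
            muts.extend(self.nodes[cid].private_mutation_ids)
        return muts


@dataclass
class TrajectorySet:
    """Per-clone CCF (fraction of nucleated cells) at each sample time."""

    ccf: pd.DataFrame  # clones x timepoints (columns = times in days)

    def check_nesting(self, forest: CloneForest, atol: float = 1e-9) -> None:
        for cid in forest.nodes:
            kids = forest.children(cid)
            if kids:
                total = self.ccf.loc[kids].sum(axis=0)
                if (total > self.ccf.loc[cid] + atol).any():
                    raise ValueError(f"children of {cid} exceed parent CCF")
        if (self.ccf.loc[forest.roots].sum(axis=0) > 1.0 + atol).any():
            raise ValueError("root CCFs exceed 1")


@dataclass(frozen=True)
class SimulatedMutation:
    mutation_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    is_driver: bool
    clone_of_origin: str
    consequence: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref must differ from alt")
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence {self.consequence!r}")


def simulate_clone_forest(config: SimulationConfig,
                          rng: np.random.Generator) -> CloneForest:
    """Draw a clone tree (plus, with probability p_unrelated, an extra
    independent root carrying its own private mutations).

    Drivers come from a bundled myeloid gene panel, passengers get random
    labels. Topologies: single (one clone), linear (path), branching (some
    node has two children), random (uniform attachment).
    """
    if config.n_clones < 1:
        raise InvalidConfigError("n_clones must be >= 1")
    topology = config.topology
    if topology == "random":
        choices = ["single"] if config.n_clones == 1 else ["linear"]
        if config.n_clones >= 3:
            choices.append("branching")
        topology = str(rng.choice(choices))
    n = config.n_clones
    if topology == "single":
        n = 1
    parent: dict[int, int | None] = {0: None}
    for i in range(1, n):
        if topology == "linear":
            parent[i] = i - 1
        elif topology == "branching":
            if i == 1:
                parent[i] = 0
            elif i == 2:
                parent[i] = 0  # guarantee one branch point at the root
            else:
                parent[i] = int(rng.integers(0, i))
        else:
            parent[i] = int(rng.integers(0, i))

    drivers = list(_load_driver_genes())
    rng.shuffle(drivers)
    nodes: dict[str, CloneNode] = {}
    mut_counter = 0

    def _make_clone(idx: int, parent_label: str | None, tag: str) -> str:
        nonlocal mut_counter
        cid = f"{tag}{idx}"
        n_drv = int(rng.integers(config.n_driver_range[0],
                                 config.n_driver_range[1] + 1))
        n_psg = int(rng.integers(config.n_passenger_range[0],
                                 config.n_passenger_range[1] + 1))
        n_mut = max(n_drv + n_psg, 1)
        muts = [f"m{mut_counter + k:03d}" for k in range(n_mut)]
        mut_counter += n_mut
        cn = None
        if rng.random() < config.p_cn_event:
            cn = str(rng.choice(sorted(CN_EVENTS)))
        nodes[cid] = CloneNode(cid, parent_label, muts, cn_event=cn)
        return cid

    labels: dict[int, str] = {}
    for i in range(n):
        p_label = None if parent[i] is None else labels[parent[i]]
        labels[i] = _make_clone(i, p_label, "C")
    if rng.random() < config.p_unrelated:
        _make_clone(0, None, "U")
    forest = CloneForest(nodes)
    # attach driver gene labels later (simulate_mutations); forest only
    # carries structure + mutation ids
    return forest


def _logistic(t: np.ndarray, lo: float, hi: float, rate: float,
              t_mid: float) -> np.ndarray:
    return lo + (hi - lo) / (1.0 + np.exp(-rate * (t - t_mid)))


def simulate_trajectories(forest: CloneForest, config: SimulationConfig,
                          rng: np.random.Generator) -> TrajectorySet:
    """Logistic growth of each clone's fraction-within-parent; CCFs built
    top-down so the nesting invariant holds by construction.

    Roots get logistic curves of total-population fraction, jointly capped
    so they sum to <= 0.97 (the residue is normal haematopoiesis). Inside a
    treatment window the target root's whole tree is multiplied by the
    window's suppression factor; an unrelated root emulates outgrowth simply
    through its own late-rising curve. Sibling sets under a branch point are
    drawn with opposite growth directions (one waning, one expanding), the
    clonal-competition signature seen in serial MDS samples.
    """
    t = np.asarray(config.times, dtype=float)
    span = t[-1] - t[0] if len(t) > 1 else 1.0
    roots = forest.roots
    curves: dict[str, np.ndarray] = {}

    primary = roots[0]
    for i, rid in enumerate(roots):
        if rid == primary:
            lo = rng.uniform(0.25, 0.5)
            hi = rng.uniform(0.7, 0.95)
            rate = rng.uniform(2.0, 6.0) / max(span, 1.0)
            c = _logistic(t, lo, hi, rate, t_mid=t[0] + 0.35 * span)
        else:
            # unrelated clone: small early, expanding at some later phase
            lo = rng.uniform(0.005, 0.05)
            hi = rng.uniform(0.25, 0.75)
            rate = rng.uniform(4.0, 9.0) / max(span, 1.0)
            t_mid = t[0] + rng.uniform(0.4, 0.85) * span
            c = _logistic(t, lo, hi, rate, t_mid=t_mid)
        curves[rid] = c
    total = np.sum([curves[r] for r in roots], axis=0)
    scale = np.minimum(1.0, 0.97 / np.maximum(total, 1e-12))
    for rid in roots:
        curves[rid] = curves[rid] * scale
    for window in config.treatment_windows:
        if window.target_root >= len(roots):
            raise InvalidConfigError("treatment window targets missing root")
        rid = roots[window.target_root]
        mask = (t >= window.start) & (t <= window.end)
        curves[rid] = np.where(mask, curves[rid] * window.factor, curves[rid])

    ccf: dict[str, np.ndarray] = {}

    def _descend(cid: str, depth: int) -> None:
        kids = forest.children(cid)
        if not kids:
            return
        fracs = []
        for j, kid in enumerate(kids):
            # a lone successor clone overgrows its ancestor (linear
            # pattern); sibling pairs alternate directions so their
            # trajectories cross (clonal competition under a branch point).
            # Successive sweeps start later the deeper the clone sits.
            rising = (j % 2 == 1) if len(kids) > 1 else True
            if rising:
                lo, hi = rng.uniform(0.02, 0.12), rng.uniform(0.65, 0.92)
            else:
                lo, hi = rng.uniform(0.6, 0.92), rng.uniform(0.02, 0.12)
            rate = rng.uniform(5.0, 10.0) / max(span, 1.0)
            frac_mid = min(0.1 + 0.18 * depth + rng.uniform(0.0, 0.25), 0.9)
            t_mid = t[0] + frac_mid * span
            fracs.append(_logistic(t, lo, hi, rate, t_mid))
        total = np.sum(fracs, axis=0)
        scale = np.minimum(1.0, 0.98 / np.maximum(total, 1e-12))
        for kid, f in zip(kids, fracs):
            ccf[kid] = f * scale * ccf[cid]
            _descend(kid, depth + 1)

    for rid in roots:
        ccf[rid] = curves[rid]
        _descend(rid, 1)

    frame = pd.DataFrame({cid: ccf[cid] for cid in sorted(forest.nodes)},
                         index=t).T
    traj = TrajectorySet(ccf=frame)
    traj.check_nesting(forest)
    return traj


def _pairwise_separation(traj: TrajectorySet) -> float:
    c = traj.ccf.to_numpy()
    if len(c) < 2:
        return np.inf
    sep = np.inf
    for i in range(len(c)):
        for j in range(i + 1, len(c)):
            sep = min(sep, np.max(np.abs(c[i] - c[j])))
    return float(sep)


def simulate_mutations(forest: CloneForest, config: SimulationConfig,
                       rng: np.random.Generator) -> list[SimulatedMutation]:
    """Assign genomic coordinates, alleles, gene labels and consequence
    classes to the forest's mutations.

    Mutations of a clone carrying a copy-number event are placed inside the
    event's segment (the lesion and the mutations travel together); all
    other mutations land on unaffected chromosomes. Drivers draw labels from
    the bundled myeloid panel, passengers get random symbols.
    """
    drivers = list(_load_driver_genes())
    rng.shuffle(drivers)
    neutral_chroms = ["1", "2", "3", "6", "9", "11", "12", "17"]
    out: list[SimulatedMutation] = []
    taken_positions: set[tuple[str, int]] = set()
    for cid in sorted(forest.nodes):
        node = forest.nodes[cid]
        n_mut = len(node.private_mutation_ids)
        n_drv = min(int(rng.integers(config.n_driver_range[0],
                                     config.n_driver_range[1] + 1)), n_mut)
        for k, mid in enumerate(node.private_mutation_ids):
            is_driver = k < n_drv and bool(drivers)
            gene = drivers.pop() if is_driver else "".join(
                rng.choice(list(string.ascii_uppercase), size=5)) + str(
                    rng.integers(1, 10))
            consequence = str(rng.choice(CONSEQUENCE_CLASSES,
                                         p=_CONSEQUENCE_P))
            if node.cn_event is not None:
                ev = CN_EVENTS[node.cn_event]
                chrom = ev["chrom"]
                lo, hi = ev["start"] + 1, ev["end"]
            else:
                chrom = str(rng.choice(neutral_chroms))
                lo, hi = 1, 200_000_000
            pos = int(rng.integers(lo, hi + 1))
            while (chrom, pos) in taken_positions:
                pos = int(rng.integers(lo, hi + 1))
            taken_positions.add((chrom, pos))
            if "SNV" in consequence or consequence == "splice site":
                klass = str(rng.choice(SUBSTITUTION_CLASSES,
                                       p=_SUBSTITUTION_P))
                pair = _CLASS_TO_PAIR[klass][int(rng.integers(0, 2))]
                ref, alt = pair
            elif consequence == "frameshift indel":
                base = str(rng.choice(list(BASES)))
                ins = str(rng.choice(list(BASES)))
                ref, alt = (base, base + ins) if rng.random() < 0.5 else (
                    base + ins, base)
            else:  # inframe indel
                base = str(rng.choice(list(BASES)))
                tri = "".join(rng.choice(list(BASES), size=3))
                ref, alt = (base, base + tri) if rng.random() < 0.5 else (
                    base + tri, base)
            out.append(SimulatedMutation(
                mutation_id=mid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene=gene, is_driver=is_driver, clone_of_origin=cid,
                consequence=consequence))
    return out


def cn_state_of_mutation(mut: SimulatedMutation, forest: CloneForest,
                         sex: str = "female") -> CopyNumberState:
    """True copy-number state of a simulated mutation.

    A clone's own copy-number event applies to its private mutations: under
    a deletion the surviving allele is the mutated one (m=1, CN_t as in the
    event); under CN-LOH the mutated allele is duplicated (m=2).
    """
    node = forest.nodes[mut.clone_of_origin]
    male = str(sex).lower() in ("male", "m", "xy")
    n_p = 1 if (male and mut.chrom in ("X", "Y")) else 2
    if node.cn_event is None:
        return CopyNumberState(cn_total=2, multiplicity=1, normal_ploidy=n_p)
    ev = CN_EVENTS[node.cn_event]
    if ev["is_cnloh"]:
        return CopyNumberState(cn_total=2, multiplicity=2, normal_ploidy=n_p)
    return CopyNumberState(cn_total=ev["cn_total"], multiplicity=1,
                           normal_ploidy=n_p)


def simulate_read_counts(vafs: np.ndarray, depth_mean: float,
                         error_rate: float, rng: np.random.Generator,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Sequencing noise model: depth ~ Poisson(mean), alt ~ Binomial(depth,
    vaf + error*(1-vaf)). Returns (alt_counts, depths)."""
    vafs = np.asarray(vafs, dtype=float)
    if np.any((vafs < 0) | (vafs > 1)):
        raise ValueError("vafs must lie in [0, 1]")
    depths = rng.poisson(depth_mean, size=vafs.shape)
    p = vafs + error_rate * (1.0 - vafs)
    alts = rng.binomial(depths, p)
    return alts, depths


def simulate_null_locus_counts(n_loci: int, depth_mean: float,
                               error_rate: float, rng: np.random.Generator,
                               ) -> list[dict[str, int]]:
    """Mutation-free loci with full base composition.

    Each non-reference base accrues reads at the per-alt-base error rate
    (three independent binomials); the reference base takes the rest. The
    reference is fixed to 'A' without loss of generality.
    """
    out = []
    for _ in range(n_loci):
        depth = int(rng.poisson(depth_mean))
        errs = rng.binomial(depth, error_rate, size=3)
        while errs.sum() > depth:  # pathological only at absurd error rates
            errs = rng.binomial(depth, error_rate, size=3)
        counts = {"A": depth - int(errs.sum()), "C": int(errs[0]),
                  "G": int(errs[1]), "T": int(errs[2])}
        out.append(counts)
    return out


def simulate_colonies(forest: CloneForest, clone_ccf_at_t: pd.Series,
                      n_colonies: int, p_mixed: float,
                      rng: np.random.Generator, colony_depth: int = 200,
                      error_rate: float = 5e-4) -> pd.DataFrame:
    """Single-progenitor CFU-GEMM colony VAF table at one timepoint.

    Each colony's founder clone is drawn proportionally to exclusive clone
    fractions (cells in the clone but no descendant subclone), with the
    residual normal fraction founding mutation-free colonies. Mutations on
    the founder's root path read ~50% VAF; the rest read sequencing noise.
    With probability ``p_mixed`` two founders blend 50:50.

    Returns a long frame: colony_id, founder (truth), mutation_id, vaf.
    """
    if n_colonies < 1:
        raise InvalidConfigError("n_colonies must be >= 1")
    clones = sorted(forest.nodes)
    exclusive = {}
    for cid in clones:
        kids = forest.children(cid)
        excl = clone_ccf_at_t[cid] - sum(clone_ccf_at_t[k] for k in kids)
        exclusive[cid] = max(float(excl), 0.0)
    normal = max(1.0 - sum(clone_ccf_at_t[r] for r in forest.roots), 0.0)
    founders = clones + ["normal"]
    weights = np.array([exclusive[c] for c in clones] + [normal])
    if weights.sum() <= 0:
        raise InvalidConfigError("no cells available to found colonies")
    weights = weights / weights.sum()
    mutations = sorted(forest.clone_of_mutation())

    rows = []
    for i in range(n_colonies):
        founder = founders[int(rng.choice(len(founders), p=weights))]
        founder2 = None
        if rng.random() < p_mixed:
            founder2 = founders[int(rng.choice(len(founders), p=weights))]
        path = set() if founder == "normal" else set(
            forest.mutations_on_path(founder))
        path2 = None
        if founder2 is not None:
            path2 = set() if founder2 == "normal" else set(
                forest.mutations_on_path(founder2))
        for mid in mutations:
            p1 = 0.5 if mid in path else error_rate
            if path2 is None:
                p = p1
            else:
                p2 = 0.5 if mid in path2 else error_rate
                p = 0.5 * (p1 + p2)
            vaf = rng.binomial(colony_depth, p) / colony_depth
            label = founder if founder2 is None else f"{founder}+{founder2}"
            rows.append((f"col{i:03d}", label, mid, vaf))
    return pd.DataFrame(rows, columns=["colony_id", "founder",
                                       "mutation_id", "vaf"])


@dataclass
class PatientBundle:
    """One simulated patient: truth plus everything the pipeline consumes."""

    patient_id: str
    config: SimulationConfig
    forest: CloneForest
    trajectories: TrajectorySet
    mutations: list[SimulatedMutation]
    counts: pd.DataFrame      # sample_id, mutation_id, alt_count, depth
    sample_sheet: pd.DataFrame
    segments: list[CnaSegment]
    colonies: pd.DataFrame | None = None

    def variants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.mutation_id, m.chrom, m.pos, m.ref, m.alt, m.gene,
              int(m.is_driver), m.consequence) for m in self.mutations],
            columns=["mutation_id", "chrom", "pos", "ref", "alt", "gene",
                     "is_driver", "consequence"])

    def true_states(self) -> dict[str, CopyNumberState]:
        return {m.mutation_id: cn_state_of_mutation(m, self.forest,
                                                    self.config.sex)
                for m in self.mutations}

    def true_assignment(self) -> dict[str, str]:
        return {m.mutation_id: m.clone_of_origin for m in self.mutations}

    def true_parent_map(self) -> dict[str, str | None]:
        return {cid: n.parent_id for cid, n in self.forest.nodes.items()}


def simulate_patient(config: SimulationConfig,
                     patient_id: str = "SIM01",
                     max_tries: int = 500) -> PatientBundle:
    """End-to-end simulation of one patient.

    Trajectories are redrawn until every clone pair is separated by at
    least ``config.min_separation`` CCF in some sample and every clone
    reaches ``config.min_clone_ccf`` somewhere (a clone that never does
    would not have entered a validated mutation catalogue in the first
    place). The forest itself is redrawn periodically when a structure
    makes those conditions hard to satisfy; the retry count is bounded.
    """
    rng = np.random.default_rng(config.seed)

    def _ok(traj: TrajectorySet) -> bool:
        reaches = (traj.ccf.max(axis=1) >= config.min_clone_ccf).all()
        return bool(reaches) and (
            _pairwise_separation(traj) >= config.min_separation)

    forest = simulate_clone_forest(config, rng)
    traj = simulate_trajectories(forest, config, rng)
    tries = 1
    while not _ok(traj) and tries < max_tries:
        if tries % 60 == 0:
            forest = simulate_clone_forest(config, rng)
        traj = simulate_trajectories(forest, config, rng)
        tries += 1
    if not _ok(traj):
        raise RuntimeError("could not achieve requested clone separation")
    mutations = simulate_mutations(forest, config, rng)
    clone_of = forest.clone_of_mutation()

    times = list(config.times)
    sheet_rows = []
    count_rows = []
    for ti, t in enumerate(times):
        sid = f"{patient_id}_t{ti}"
        sheet_rows.append((patient_id, sid, "BM_MNC", t, "amplicon", ""))
        vafs = []
        for m in mutations:
            state = cn_state_of_mutation(m, forest, config.sex)
            ccf = float(traj.ccf.loc[clone_of[m.mutation_id]].iloc[ti])
            vafs.append(expected_vaf(ccf, state))
        alts, depths = simulate_read_counts(
            np.asarray(vafs), config.depth_targeted, config.error_rate, rng)
        for m, a, d in zip(mutations, alts, depths):
            count_rows.append((patient_id, sid, m.mutation_id, int(a), int(d)))
    # germline control (cultured T cells): tumour contamination + error only
    gl_id = f"{patient_id}_germline"
    sheet_rows.append((patient_id, gl_id, "T_cells", times[0], "amplicon", ""))
    gl_vafs = []
    for m in mutations:
        state = cn_state_of_mutation(m, forest, config.sex)
        ccf0 = float(traj.ccf.loc[clone_of[m.mutation_id]].iloc[0])
        gl_vafs.append(config.contamination * expected_vaf(ccf0, state))
    alts, depths = simulate_read_counts(
        np.asarray(gl_vafs), config.depth_targeted, config.error_rate, rng)
    for m, a, d in zip(mutations, alts, depths):
        count_rows.append((patient_id, gl_id, m.mutation_id, int(a), int(d)))

    counts = pd.DataFrame(count_rows, columns=[
        "patient", "sample_id", "mutation_id", "alt_count", "depth"])
    sheet = pd.DataFrame(sheet_rows, columns=[
        "patient", "sample_id", "tissue", "time_days", "platform",
        "treatment_label"])

    segments = []
    seen_events = set()
    for cid in sorted(forest.nodes):
        ev_name = forest.nodes[cid].cn_event
        if ev_name and ev_name not in seen_events:
            seen_events.add(ev_name)
            ev = CN_EVENTS[ev_name]
            segments.append(CnaSegment(
                chrom=ev["chrom"], start=ev["start"], end=ev["end"],
                cn_total=ev["cn_total"], cn_minor=ev["cn_minor"],
                is_cnloh=ev["is_cnloh"],
                reaches_telomere=ev["reaches_telomere"]))

    colonies = None
    if config.n_colonies > 0:
        colonies = simulate_colonies(
            forest, traj.ccf.iloc[:, -1], config.n_colonies,
            config.p_mixed_colony, rng, config.colony_depth,
            config.error_rate)
        colonies.insert(0, "patient", patient_id)
        colonies.insert(1, "time_days", times[-1])

    return PatientBundle(patient_id, config, forest, traj, mutations,
                         counts, sheet, segments, colonies)


# ---------------------------------------------------------------------------
# cohort serialisation

def write_cohort(bundle: PatientBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a patient bundle as plain-text files plus a ground-truth JSON.

    Files: counts.tsv (long read counts), samples.tsv, segments.tsv,
    colonies.tsv (when simulated), variants.tsv (mutation annotations) and
    truth.json (forest, trajectories, clone assignment). Re-reading
    reproduces the read counts exactly; bytes are a pure function of the
    simulation seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["counts"] = out / "counts.tsv"
    bundle.counts.to_csv(paths["counts"], sep="\t", index=False)
    paths["samples"] = out / "samples.tsv"
    bundle.sample_sheet.to_csv(paths["samples"], sep="\t", index=False)

    seg_frame = pd.DataFrame(
        [(s.chrom, s.start, s.end, s.cn_total, s.cn_minor,
          int(s.is_cnloh), int(s.reaches_telomere)) for s in bundle.segments],
        columns=["chrom", "start", "end", "cn_total", "cn_minor",
                 "is_cnloh", "reaches_telomere"])
    paths["segments"] = out / "segments.tsv"
    seg_frame.to_csv(paths["segments"], sep="\t", index=False)

    var_frame = pd.DataFrame(
        [(m.mutation_id, m.chrom, m.pos, m.ref, m.alt, m.gene,
          int(m.is_driver), m.consequence) for m in bundle.mutations],
        columns=["mutation_id", "chrom", "pos", "ref", "alt", "gene",
                 "is_driver", "consequence"])
    paths["variants"] = out / "variants.tsv"
    var_frame.to_csv(paths["variants"], sep="\t", index=False)

    if bundle.colonies is not None:
        paths["colonies"] = out / "colonies.tsv"
        bundle.colonies.to_csv(paths["colonies"], sep="\t", index=False)

    truth = {
        "patient_id": bundle.patient_id,
        "seed": bundle.config.seed,
        "times": list(bundle.config.times),
        "clones": {
            cid: {"parent": node.parent_id,
                  "mutations": list(node.private_mutation_ids),
                  "cn_event": node.cn_event}
            for cid, node in sorted(bundle.forest.nodes.items())},
        "ccf": {cid: [float(x) for x in bundle.trajectories.ccf.loc[cid]]
                for cid in sorted(bundle.forest.nodes)},
        "assignment": bundle.true_assignment(),
    }
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths


def read_cohort(in_dir: str | Path) -> dict[str, object]:
    """Read back a written cohort directory into plain frames + truth dict."""
    d = Path(in_dir)
    out: dict[str, object] = {
        "counts": pd.read_csv(d / "counts.tsv", sep="\t"),
        "samples": pd.read_csv(d / "samples.tsv", sep="\t"),
        "variants": pd.read_csv(d / "variants.tsv", sep="\t"),
    }
    seg_frame = pd.read_csv(d / "segments.tsv", sep="\t")
    out["segments"] = [
        CnaSegment(str(r.chrom), int(r.start), int(r.end), int(r.cn_total),
                   int(r.cn_minor), bool(r.is_cnloh),
                   bool(r.reaches_telomere))
        for r in seg_frame.itertuples()]
    if (d / "colonies.tsv").exists():
        out["colonies"] = pd.read_csv(d / "colonies.tsv", sep="\t")
    with open(d / "truth.json") as fh:
        out["truth"] = json.load(fh)
    return out
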