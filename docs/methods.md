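# Methods

## Problem and model

Serial sampling of a haematological neoplasm yields, for each somatic
mutation *i* and sample *s*, an alt read count and a depth. The quantity of
biological interest is the cancer cell fraction CCF — the fraction of
nucleated cells carrying the mutation — because mutations born in the same
clone share one CCF trajectory while mutations of different clones do not.
The pipeline is therefore: filter → convert VAF to CCF → cluster
trajectories → order clusters into a clone forest → classify the pattern.

### VAF ↔ CCF conversion

A cell population at CCF *c* carrying a mutation at multiplicity *m* on a
segment of tumour total copy number *CN*ₜ, mixed with normal cells of locus
ploidy *n*ₚ (1 on male X/Y, else 2), produces the expected VAF

    v = m·c / (nₚ·(1−c) + CNₜ·c)

and inversely c = nₚ·v / (m − v·(CNₜ − nₚ)). The model treats CCF as a
fraction of **all** nucleated cells; tumour purity is not a separate
parameter. Assumptions: one copy-number state per locus shared by all cells
that carry the mutation, and no subclonal copy-number heterogeneity at a
mutated locus. Under CN-LOH the multiplicity is ambiguous (mutation before
LOH → m = 2, after → m = 1); `choose_multiplicity` picks the binomial
maximum-likelihood value given candidate CCFs when counts are available and
defaults to m = 2 (the common somatic order) otherwise.

Uncertainties propagate by the delta method from the binomial VAF error:
se(c) = |dc/dv|·√(v(1−v)/depth); for het-diploid loci this is exactly
2·se(v).

### Detection floor and censored zeros

Entries below the 0.2% VAF detection cutoff become explicit CCF zeros
flagged `below_detection`. Their uncertainty is the CCF equivalent of the
floor itself (≈ 0.004 for a diploid het locus), not the binomial se at the
floor: an undetected mutation's true CCF lies anywhere below the floor, so
the censoring half-width is the honest scale. This keeps a mutation that
hovers at the floor in one sample from being split from its clone-mates
(z ≈ 3 artifacts), while a zero against any established clone still gives
z in the hundreds and correctly blocks merging.

### Trajectory clustering

Distance between mutations = worst-sample z: max over shared samples of
|c_i − c_j| / √(se_i² + se_j²). Clusters grow by average-linkage
agglomeration, halting when the smallest inter-cluster linkage reaches
z* = 3 (the conventional "statistically indistinguishable" bound; two
mutations co-cluster only when their trajectories agree everywhere). Ties
break on the smallest mutation id and rows are canonically sorted first, so
the output is independent of input order. The merge loop is written out in
the package (≈40 lines) because the stop-at-threshold semantics and the id
tie-break need to be exact; the linkage definition itself is standard.
Metric, linkage and z* are all exposed in `PipelineConfig`.

### Clone forest inference

With k clusters (k ≤ 12 enforced; longitudinal patients produce ≲8), every
parent-or-root assignment is enumerated and kept iff at every timepoint,
within tolerance ε:

* pigeonhole: CCF(child) ≤ CCF(parent) + ε;
* sum rule: Σ CCF(children) ≤ CCF(parent) + ε;
* root bound: Σ CCF(roots) ≤ 1 + ε;
* temporal precedence: the parent's first detection is no later than the
  child's;
* colony constraints: colony-proved exclusive pairs never share a root
  path and colony-proved ancestry is never inverted.

ε = max(0.05, 2·pooled centroid se) per comparison — it scales with depth
and keeps sparse exome-only timepoints from over-constraining. Exhaustive
enumeration (recursive, with pruning on the monotone constraints) was
chosen over MCMC or heuristic search for determinism and auditability; the
admissible set is typically small once trajectories are well separated.

Selection minimises score = Σ max(0, Σchildren − parent)²/se² + λ·(roots−1)
+ μ·(branch nodes) with λ = 1.0, μ = 0.25: parsimony prefers a single tree
and linear chains, but genuine crossing trajectories force branches and
colony exclusivity forces extra roots regardless of the penalties. Ties
break on fewer roots, fewer branch nodes, then the lexicographic parent
vector. If **no** forest is admissible, a greedy least-violating forest is
returned together with an explicit violation table — mirroring a manual
review workflow rather than failing silently.

Unrelated roots are graded by evidence: `colony-proven` (mutual exclusivity
in single-colony genotypes) > `pigeonhole` (two roots' CCFs sum beyond 1
somewhere, so they cannot nest) > `topology-only` (merely unattachable).

### Colony genotyping

A colony is positive for a mutation at VAF > 40%, negative below 5%, and
ambiguous (possibly mixed, excluded from constraints) in between. Over
unambiguous colonies, mutation pairs showing patterns {11,10} imply
ancestry, {10,01} without 11 imply exclusivity, and all three patterns are
reported as perfect-phylogeny violations.

## Filtering thresholds

All published thresholds are implemented with their exact wording's
strictness and exposed in `PipelineConfig`: Fisher exact (one-sided,
tumour-enriched; two-sided available) P ≤ 0.001; tumour VAF ≥ 0.07 in at
least one tumour sample; synonymous/SNP/incomplete-ORF exclusions;
deep-sequencing call at VAF ≥ 0.002 **and** variant base strictly
second-highest (a tie with another non-reference base is still called but
flagged); validation at ≥ 5 VAF points above germline; FISH cutoff
mean + 3 s.d. of control false positives; CNA segments kept above 5 Mb or
rescued by cancer-gene overlap, CN-LOH only above 10 Mb and telomeric,
IG/TCR focal changes and normal-variant matches dropped. The "5%
difference" is percentage points of VAF, not relative.

## Synthetic cohort generator

The generator emulates the study conditions, not generic tumours:

* 2–8 serial samples spanning years (default 4–5 over ~6 years);
* 1–5 clones per patient carrying ~4–7 mutations each (cohort totals in
  the 8–27 range, median ≈ 17), drivers drawn from a bundled myeloid gene
  panel, passengers with random labels;
* substitution spectrum ~65% transitions dominated by G:C→A:T, consequence
  mix dominated by nonsynonymous SNVs;
* recurrent copy-number contexts (del(5q), monosomy 7, telomeric 4q
  CN-LOH) acquired by single clones, with the clone's private mutations
  placed inside the lesion so each mutation has a single well-defined
  copy-number state;
* logistic growth of each clone's fraction-within-parent, composed
  top-down so the nesting invariant holds exactly by construction.
  A lone successor clone always expands (the linear
  successive-overgrowth pattern); sibling pairs under a branch point get
  opposite growth directions so their trajectories cross — the
  clonal-competition signature without which a non-crossing sibling pair
  is topologically indistinguishable from a chain;
* treatment windows multiply a chosen root's whole tree by a suppression
  factor (lenalidomide-like bottleneck); an unrelated root's outgrowth is
  produced by its own late-rising curve rather than by mechanistic
  competition;
* read counts: depth ~ Poisson(10,000) for amplicon / Poisson(110) for
  exome; alt ~ Binomial(depth, v + e·(1−v)) with per-alt-base error
  e = 5×10⁻⁴ (amplicon-platform-like, configurable); null loci also draw
  the two other non-reference bases so the second-highest-base rule is
  exercised;
* colonies: founder drawn ∝ exclusive clone fraction (plus residual
  normal), root-path mutations at Binomial(200, 0.5)/200, others at the
  error rate; optional 50:50 mixed colonies. Colony depth 200 is a
  generator choice.

Patients are redrawn until every clone pair is separated by ≥ 0.15 CCF in
some sample and every clone reaches CCF ≥ 0.15 somewhere — a clone that
never does would not have entered a validated mutation catalogue, so the
conditioning matches how real cohorts are ascertained.

What the generator does **not** emulate: subclonal copy-number states
within a mutation's carrier population, mapping/alignment artifacts,
amplification (PCR) errors correlated across samples, indel-specific error
profiles, and contamination structure beyond a single tumour-in-germline
fraction. Passing recovery tests therefore demonstrates correctness of the
inference given the stated noise model, not robustness to every artifact
of real sequencing.

## Numerical choices

* Pooled standard errors floor at 10⁻¹² to keep identical trajectories at
  distance 0 without dividing by zero.
* `vaf_to_ccf` flags overflow only beyond 1 + 3·se; values in [0,1] are
  never altered by clipping.
* First detection = first sample with centroid CCF > 0.01.
* Forest enumeration sorts results lexicographically; every tie-break in
  clustering and selection is deterministic, so fixed seeds fix every
  output byte.
* The exhaustive-enumeration cap (12 clusters) raises a documented error
  rather than falling back to a heuristic.

## Known limitations

* The CCF model assumes all carriers of a mutation share one copy-number
  state; a mutation spanning a subclonal CNA boundary will be mis-scaled.
* Temporal precedence uses observed first detection, which at very low
  depths can invert for a parent hovering at the floor.
* The parsimony score is an engineering proxy for "most probable"; when
  two admissible forests are slack-free and differ only in arrangement,
  the data genuinely cannot distinguish them and the tie-break (fewer
  roots, fewer branches) decides.
* With a single timepoint the sum rule is weak and many forests are
  admissible; the method is designed for ≥ 3–4 serial samples.
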