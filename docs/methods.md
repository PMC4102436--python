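# Methods

## Model and scope

The unit of analysis is a constraint-based metabolic model: metabolites,
reactions with signed stoichiometry and flux bounds, a designated biomass
reaction, and optional boolean gene–protein–reaction (GPR) rules. Flux
balance analysis (FBA) treats the network at steady state, **S·V = 0**,
maximizing biomass flux *f*<sub>BM</sub> subject to bounds. A *medium* is a
set of exchange metabolites whose uptake is allowed; allowed exchanges get
lower bound −M, all others 0. Secretion stays open for every exchange
regardless of the medium: only uptake is ever restricted, because the
minimal-environment count concerns consumed compounds only.

Sign convention throughout: negative exchange flux = uptake, positive =
secretion. Every exchange reaction must touch exactly one metabolite; a
violation is a hard validation error, as is a missing biomass reaction.

## The two-stage MILP

**Stage 1 (cardinality).** One binary ϑ<sub>i</sub> per counted exchange,
coupled by *f*<sub>i</sub> ≥ −M(1 − ϑ<sub>i</sub>); maximize Σϑ subject to
steady state, bounds, and *f*<sub>BM</sub> ≥ cutoff. The minimum number of
consumed metabolites is E − Σϑ\*.

**Stage 2 (canonical set).** All exchangeable metabolites are ranked 1..E
by ascending molar mass, ties broken by lexicographic metabolite id (the
tie rule makes the ordering reproducible across runs and machines). With
the constraint Σ(1 − ϑ) ≤ stage-1 optimum, minimize Σ rank<sub>i</sub>(1 −
ϑ<sub>i</sub>). Preferring light compounds singles out one canonical
minimal environment — the MINENV.

**Rank-sum tie refinement.** Distinct sets can tie on summed rank (ranks
{1, 4} and {2, 3} both sum to 5). A third solve pins the weighted sum at
its optimum and minimizes Σ 2^(E − rank<sub>i</sub>)·ϑ<sub>i</sub>, which
selects, among tied optima, the set whose sorted rank vector is
lexicographically smallest — i.e. ties always break toward the lightest
attainable compounds. The power-of-two weights are exact in double
precision up to E = 45 exchanges; beyond that the refinement is skipped
(equal-rank-sum degeneracy across different supports is the only case it
resolves, and the swap check below reports any residual mass-level
degeneracy explicitly).

**Post-solve hygiene.** ϑ values are rounded to {0, 1}; the extracted set
is re-tested by plain FBA and pruned to inclusion-minimality (members whose
removal keeps growth above the cutoff are dropped, heaviest rank first).
The MILP bounds the support; FBA verifies necessity. A final growth
re-check guards against integrality-tolerance leakage; its failure is
raised, never papered over.

**Catalogue preference.** The preferred-compound variant replaces the
stage-2 weights with rank<sub>i</sub> + B·[i ∉ catalogue], B = E² + 1 >
any attainable rank sum, so minimizing non-catalogue members strictly
dominates and molar rank breaks ties. With an empty or all-inclusive
catalogue this reduces exactly to the plain objective.

## Critical metabolites, swaps, knockout stability

A MINENV member is **critical** when closing its uptake alone — with every
other exchange open — drops the biomass optimum below the cutoff. On
enumerable fixtures this provably equals the intersection of all feasible
uptake sets (a feasible superset exists for every feasible set, so the
intersection over all feasible sets equals the intersection over
inclusion-minimal ones).

The **swap check** tests, for every MINENV member and every non-member of
identical molar mass (equal after rounding to 6 decimals), whether the
single exchange preserves growth; an empty report certifies the canonical
choice is non-degenerate for that model.

**Knockout stability** recomputes the MINENV under every single-gene
deletion (GPR semantics: AND = complex, OR = isozymes; reactions whose rule
evaluates false get bounds [0, 0]). Genes lethal on the all-open medium are
reported separately and excluded from the composition-/size-change ratios,
which are defined only over viable knockouts.

## Ecology analyses

Ecological distance between organisms is 1 − Jaccard of their
environment-membership sets; MINENV similarity is 100 × Jaccard of their
nutrient sets. `jaccard(∅, ∅)` is defined as 1 (identical sets).

- **Binned similarity curve**: unordered organism pairs are binned into
  equal-width ecological-distance bins (default 20) and the per-bin
  fraction of pairs at or above each similarity threshold is reported.
  Bins under a pair-count floor (default 1000) are flagged and excluded
  from the per-threshold Spearman correlation, which relates bin
  ecological *similarity* (1 − distance) to the ratio, so a positive rho
  means co-distributed organisms have similar nutritional needs.
- **Split-half distances**: per trial, two disjoint groups of an
  environment's members are drawn and the Jaccard distance between their
  aggregate (union) MINENVs is recorded; matched control trials draw both
  groups from strict non-members. Default 100 trials; group size defaults
  to half the membership.
- **Growth on aggregates**: per trial, the union of a random builder
  subset's MINENVs becomes the medium; held-out members (never builders)
  and an equal-size sample of non-members are FBA-tested on it. By
  medium-superset monotonicity, any tested organism whose own MINENV is
  contained in the aggregate is guaranteed to grow.
- **Containment test**: the model-free variant for curated media
  catalogues — growth means the organism's own medium is a subset of the
  builders' union.
- **Correlates**: Spearman rank correlation (average ranks on ties)
  between MINENV size and any organism covariate, over the shared
  organisms; per-organism pair scores are summarized by the arithmetic
  mean over all pairings.

All resampling funnels through one `numpy` Generator seeded per call;
every analysis is bit-reproducible given its seed.

## Synthetic fixtures and the enumeration oracle

Toy models consist of: biomass consuming 1–4 precursor compounds; per
precursor, one or more alternative external sources (exchange → transport →
conversion); optional hub compounds converting into several precursors at
once (nutrient "packing"); optional distractor imports that feed nothing.
Molar masses come from a fixed palette of plausible nutrient weights
(18–507 g/mol) with small deterministic offsets so unplanted ties are
rare; tests plant exact ties deliberately. Exchange counts are capped at
12 so the oracle can scan the full uptake-subset lattice (≤ 4096 subsets;
supersets of known-feasible sets are accepted without re-solving, by
monotonicity). The oracle returns the minimal feasible cardinality, every
feasible set at that cardinality, and the intersection of all feasible
sets (ground-truth criticals).

Communities: each of 10 environments owns a core drawn from a 60-nutrient
global pool (6 nutrients per core); each of 50 organisms joins 1–3
environments and draws each of its 3 precursor sources from its
environments' cores with probability `coupling`, else uniformly from the
pool. Nutrient ids are global, so MINENV sets are comparable across
organisms. Coupling 1 ties nutrition to co-occurrence by construction;
coupling 0 is the null model. These sizes are the package's reference
conditions for the recovery analyses.

What the toys do **not** emulate: SEED-scale networks (~10³ reactions),
secretion-mediated cross-feeding, cofactor/ion chemistry, redundant
pathway structure, or realistic GPR topology. Consequences worth knowing:
absolute growth-on-aggregate fractions are low (each toy organism needs
its exact nutrient set — there are no alternative assimilation routes), and
knockout change rates on dense-GPR toys (~25% composition) are far above
what a redundant real network shows; both are reported as measured, and
only the *contrasts* (inside > outside; coupled > null) are the claims the
tests assert. Passing recovery tests demonstrate the statistics detect
planted structure at these scales, not that real communities behave this
way.

## Numerical choices

- Solver: HiGHS for both LP (`linprog`) and MILP (`milp`);
  `mip_rel_gap = 0` so MILP optima are exact.
- M (uptake magnitude) defaults to 1000 flux units and is shared verbatim
  between the medium machinery and the MILP coupling constraints — the
  indicator logic is only valid if the two agree.
- Growth comparisons use cutoff − 1e-6 slack to absorb LP round-off at the
  boundary; the cutoff itself defaults to 0.1 absolute flux units, with a
  fraction-of-maximum alternative computed against the all-open medium.
- The LP is never infeasible for well-formed models (V = 0 is always
  admissible); infeasibility is reported as a model defect. Unbounded
  biomass is flagged as its own status and treated as growth.
- MILP time limit: 300 s per solve (configurable); hitting it raises a
  timeout error carrying incumbent and bound rather than silently
  returning a suboptimal set.
- Masses: explicit `molar_mass` annotations win over formulas; generic
  residue formulas (R-groups) raise rather than being assigned a guess.

## Problem sizes used by the shipped checks

The test suite verifies MILP-vs-enumeration agreement on 200 seeded toy
models with 3–10 exchanges (exact set equality, no tolerance), cutoff
monotonicity on the same fixtures over a five-point cutoff grid, and
coupling recovery on 50-organism/10-environment communities (one coupled
seed; twenty null seeds). `scripts/acceptance.py` re-measures the same
quantities at 100 oracle models, 50 monotonicity models, five coupled
communities and ten null communities, which keeps a full run in the
low minutes on one CPU.

## Known limitations

- Stage-1 witnesses are one optimal support among possibly many; only the
  stage-2 set is canonical.
- The lexicographic refinement is skipped above 45 exchanges (see above);
  real genome-scale models rely on mass-rank uniqueness plus the swap
  check instead.
- Molar ranks depend on the mass annotation source; models mixing
  annotated and formula-derived masses are ranked on the mixture.
- The bin-level Spearman of the similarity curve is noisy when few
  distance bins are occupied (small communities with coarse environment
  sets); the acceptance script averages it over five generated communities
  for that reason.
- `delete_gene` re-parses GPR strings per call; adequate for toys and
  single sweeps, not tuned for exhaustive double-knockout scans.
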