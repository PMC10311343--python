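# Methods

## Scope and data model

`splicewire` contextualizes a domain-resolved protein interaction prior: a
table of undirected domain–domain interactions (DDIs) in which every endpoint
is a (gene symbol, Pfam accession) pair annotated with the Ensembl exon and
transcript IDs that encode the domain. Protein–protein interactions (PPIs)
are the protein-level projection of the DDIs, and a PPI is treated as
functional only through at least one functional constituent DDI. An auxiliary
`PERTURBATION` node represents the upstream cause; every inferred path
originates there. Duplicate DDI rows (e.g. per-isoform rows of the same
domain pair) are collapsed to the canonical endpoint ordering with merged
exon/transcript lists; self-interactions (both domains on one protein) are
retained in the network but excluded from path search, since they cannot
mediate regulation between distinct proteins.

Root designation when no explicit roots are supplied: if the table carries an
optional `direction` annotation, roots are proteins with no annotated incoming
edge ("no upstream regulator"). On a fully undirected prior every non-TF
protein is a candidate root, and the size regularization of the selection
objective decides which roots are actually used. Perturbation links attach at
the protein level only — the root carries no domain.

## Skipped-domain calls

Evidence features are exon-level dPSI (clipped to [−1, 1]) or transcript-level
log2 fold changes, each with a p-value in (0, 1]. Features map to domains via
the prior's exon/transcript mappings; a feature matching several domains
contributes to each. Per domain, p-values are combined by Fisher's method —
the survival probability of \(X=-2\sum\ln p_i\) under \(\chi^2_{2k}\),
computed with `scipy.stats.chi2.sf` (p-values floored at 1e-300 before the
log) — and effects are averaged arithmetically, pooling exons and transcripts
into a single aggregation. A domain is **skipped** when the aggregated
p-value is ≤ the threshold (default 0.05, ties inclusive) *and* the mean
effect is negative: an included exon or up-regulated transcript cannot remove
a domain. Domains without any matched feature never appear in the skip table
— absence of evidence is not evidence of skipping. A stricter reading of the
multi-feature rule (every matched feature individually under the threshold)
is available as `strict_all_features`.

## TF activity and its permutation null

The TF score is the signed, √k-normalized sum of matched target statistics —
a deliberate simplification of regulon enrichment scoring that keeps the part
that matters downstream (a weight per TF) while the significance machinery is
implemented in full: the bipartite TF→target graph is randomized (default
1000 times), resampling each TF's matched targets without replacement from
the union of all regulon targets that carry a statistic, keeping the
regulation modes. Restricting the resampling universe to targets with
statistics keeps the observed and permuted scores on the same matched degree
k. The empirical p-value is two-sided with add-one smoothing,
\(p=(1+\#\{|s^{perm}|\ge|s^{obs}|\})/(n_{perm}+1)\), so it is never zero and
is bounded below by \(1/(n_{perm}+1)\). A comparison tolerance of 1e-9
relative absorbs summation-order jitter so exactly-tied nulls (e.g. flat
statistics) count as extreme and give p = 1. A global rewiring scheme
(permuting statistics across the target universe) is exposed as an
alternative null. The downstream objective uses only \(w_T=|s_T|\): the prior
carries no interaction signs, so the score's sign is not interpretable as
activation or inhibition.

## The selection ILP

Variables: binary \(y_P\) (protein), \(z_{P,m}\) (domain), \(u_{e,d}\)
(DDI e in orientation d), \(v_{q,d}\) (PPI q in orientation d), \(r_P\)
(perturbation link to candidate root), \(t_T\) (TF reached); integer
\(\mathrm{depth}_P\in[0,N]\) with N the protein count. Undirected prior edges
expand into two mutually exclusive directed candidates; a `direction`
annotation restricts the candidates to one orientation.

Constraints: (C1) \(z \le y\); (C2) \(u\) ≤ both endpoint \(z\); (C3)
\(v_{q,d}\le\sum_{e\in q}u_{e,d}\) and \(u_{e,d}\le v_{q,d}\) — a PPI is
selected exactly when a constituent DDI is; (C4) \(u_{e,ab}+u_{e,ba}\le1\),
likewise for v; (C5) rooted acyclicity — active roots sit at depth 0
(\(\mathrm{depth}_P \le N(1-r_P)\)), each selected directed PPI P→Q forces
\(\mathrm{depth}_Q\ge\mathrm{depth}_P+1-M(1-v)\) with \(M=N+1\), and every
selected protein needs an incoming selected PPI or an active perturbation
link (\(y_Q \le \sum_{in} v + r_Q\), r only on candidate roots, \(r\le y\));
(C6) \(t_T\le y_T\) and \(t_T\le\sum_{in} v\) — a TF counts as reached only
through an incoming interaction; (C7, hard mode) \(z_{P,m}=0\) for skipped
domains, which renders every DDI with a skipped endpoint non-functional. In
soft mode C7 is dropped and the objective charges
\(\beta\, s_{P,m} z_{P,m}\) per selected skipped domain, with
\(s_{P,m}=-\log_{10}(\text{aggregated } p)\) capped at 300. The penalty is
applied to domains that meet the skip call (threshold and negative effect):
this is what makes the soft optimum converge to the hard optimum as β grows.

Objective (maximized): significant-TF weights on reached TFs, minus α per
reached non-significant TF, minus λ per selected element, minus the soft
penalties. Defaults: λ = 0.01 (small enough that any TF worth reaching
outweighs a path of tens of elements, large enough to prune free riders);
α = half the median significant weight (penalizes detours through
non-significant TFs without dominating); β = λ (penalties on the
regularization scale) unless set explicitly. The empty network is always
feasible, so a solver "infeasible" status signals a modelling bug and is
surfaced as such.

Determinism and ties: the solver objective adds a secondary cost on edge
indices with a *total* budget of 1e-7 (`tie_eps`), preferring
lower-canonical-index edges among ties. The reported `objective_value` is
always recomputed from the pure objective terms of the selected elements, so
it is comparable across solvers and against the enumeration oracle at float
precision. The budget is deliberately far below any realistic gap between
distinct pure objective values. The default backend is HiGHS through
`scipy.optimize.milp`, run single-threaded with `mip_rel_gap` 0; a
`brute` backend (exhaustive enumeration, ≤12 DDIs) provides an independent
cross-check, and every returned solution is certified post hoc by
`validate_solution` (endpoint closure, PPI/DDI consistency, rooted
reachability, acyclicity, no skipped domain in hard mode). Instances export
to LP and MPS for cross-solver debugging.

## Solution pools, consensus, differencing

Diverse (near-)optimal solutions are enumerated by re-solving with a
Hamming-distance cut on the selected directed-DDI set plus active roots
(`min_hamming` = 1 is a plain no-good cut); enumeration stops at `k_max`, at
objective degradation beyond `objective_tolerance` (default 0: optimal-only
pools), or when the signature space is exhausted. The consensus network keeps
integer appearance counts per element, so weights are exact rationals
count/pool-size. Differencing splice-aware against splice-unaware consensus
networks is done on undirected DDIs (orientation exclusivity makes the
undirected count the sum over the two orientations); unaware-only edges with
a skipped endpoint are flagged `splice_abrogated`.

## Over-representation analysis

One-sided hypergeometric upper tail \(P(X\ge k)\) with population = the
background universe, successes = gene set ∩ universe, draws = network
proteins; scores are −log10(p). The default universe is the prior's protein
complement, because the inference can only ever select prior proteins. Raw
scores are reported (matching how benchmark score distributions are usually
compared); Benjamini–Hochberg adjustment is available for exploratory use.

## Synthetic scenarios: what they emulate, and what not

The generator produces the pipeline's *input level* — summary statistics, not
reads: a layered, rooted prior (1 root, 1–2 intermediate layers, a TF layer)
in which each TF has exactly one guaranteed root→TF path and no other
incoming edge; extra edges are sampled between consecutive layers at
`edge_density` 0.3 by default. Regulons hold 15 targets from a 150-gene
universe; true-TF targets get concordant statistics of magnitude ≈3.5±0.5
(sign matching the regulation mode, 80% activating), so the observed score
exceeds every degree-preserving randomization; background statistics are
standard normal. A decoy TF with noise-level targets exercises the α penalty.
Skip evidence is planted on the TF-side domain of the final path edge (then
upstream path domains for additional skips): 2 exon features with dPSI in
[−0.6, −0.3] and p between 1e-4 and ~3e-3, plus one transcript feature on
TF-layer domains; optional null evidence (p in [0.3, 0.9], small effects of
either sign) dresses non-planted domains. Everything derives from one seeded
`numpy` generator and file writes are ordered, so scenarios regenerate
byte-identically.

What passing tests on these scenarios shows: the selection machinery
correctly abrogates exactly the planted interactions, the permutation null
separates signal from decoys, and consensus/differencing bookkeeping is
exact. What they do not show: performance on realistic priors (tens of
thousands of interactions, hub proteins, correlated evidence, noisy dPSI
estimates near the threshold) or the biological validity of any particular
skip call — those depend on the upstream differential analyses. Verification
problem sizes (6–8 proteins per scenario, ≤8 DDIs for the
enumeration-oracle comparison, pools of ≤10) were chosen so that exhaustive
enumeration is exact and the whole suite re-runs in seconds; the ILP itself
has no such size assumptions.

## Numerical choices and degenerate inputs

- p-values of 0 are rejected at the evidence boundary; inside Fisher's
  aggregation a 1e-300 floor guards the logarithm.
- Skip-call ties at the threshold count as skipped (inclusive ≤).
- dPSI outside [−1, 1] is clipped, not rejected.
- A prior with no perturbation targets admits only the empty solution and
  logs a warning; a regulon with no matched targets is omitted with a
  warning; evidence matching no domain yields an empty (valid) skip table.
- Objective comparisons in pool enumeration use a 1e-9 slack so float noise
  cannot truncate or extend an optimal-only pool.

## Known limitations

- No sign/direction-of-regulation inference: the prior carries no
  activation/inhibition information, so edges are oriented by the
  optimization, not by mechanism.
- The TF scorer is a simplified regulon enrichment; the permutation null is
  faithful, but shadow/pleiotropy corrections of full enrichment frameworks
  are out of scope.
- Whether non-significant TFs may serve as unpenalized pass-through nodes is
  a modelling choice: only their inclusion as *reached terminals* is
  penalized here.
- No-good-cut pools guarantee distinctness, not maximal diversity; a minimum
  Hamming distance option provides stronger separation at the cost of
  completeness.
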