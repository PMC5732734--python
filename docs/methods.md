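# Methods

## The model

`netprior` ranks candidate disease genes by propagating disease risk over
a functionally weighted interaction network.

**Disease network.** Given a source interaction network (a generic edge
list, SIF, or STRING `protein.links` with a combined-score cut, 700 by
default for STRING input) and a set of seed genes with curated disease
evidence, the disease-related network is the subgraph induced by the
seeds present in the source network together with all of their direct
interactors. The induced subgraph keeps edges between two non-seed
interactors: the propagation needs candidate–candidate paths, and
dropping them would make every candidate a leaf. Seeds missing from the
interaction universe are reported and kept aside for cross-validation
bookkeeping; they are not nodes. Multi-hop (k > 1) expansion is out of
scope.

**Functional weights.** Nodes and edges are weighted by shared
annotation. Let `T(g)` be gene g's set of ontology terms (all three GO
aspects pooled; optionally closed over `is_a` ancestors when an OBO file
is supplied — `part_of` is deliberately not followed, keeping the closure
minimal and deterministic). The similarity used throughout is the Jaccard
index `J(A,B) = |A∩B| / |A∪B|` (0 when both sets are empty): it is the
simplest auditable set similarity, and it is isolated behind
`WeightingConfig` so information-content measures can be swapped in
later. Then

- edge weight: `w(h,g) = J(T(h), T(g))`,
- node weight: seeds get `w_s = 1` (known disease genes carry maximal
  initial risk); any other gene gets `w_g = max_s J(T(g), T(s))` over the
  seeds (a `mean-sim-to-seeds` variant averages instead).

Under the default `floor` policy every weight is clamped from below at
`epsilon_floor = 0.001`. The floor is a numerical guard, not a modelling
statement: a gene whose incident edges all weigh zero would have an
undefined transition column. The `zero` policy disables the clamp; the
transition builder then falls back to the isolated-node policy for
zero-weight columns.

**Transition matrix.** Risk transfers from gene h to a neighbor g with
probability proportional to the edge weight,

    q(g|h) = w(h,g) / Σ_{l ∈ neighbor(h)} w(h,l),

so each column of Q sums to 1 (column-stochastic). Note the denominator
sums h's own incident weights; a per-target denominator would not yield a
probability distribution over h's neighbors. Isolated nodes (no
neighbors, or zero total incident weight) get a self-loop `q(h|h) = 1` by
default so Q stays stochastic on disconnected inputs; an `error` policy
is available for callers who want such nodes to be fatal.

**Initial scores and propagation.** The initial risk vector is
weight-proportional over *all* network genes,

    d_g(0) = w_g / Σ_m w_m,

and risk is iterated with a restart:

    D(i+1) = (1 − β) · Q · D(i) + β · D(0),   β ∈ (0, 1), default 0.1.

β balances propagated (interaction-driven) against intrinsic
(annotation-driven) risk. The map is a contraction with factor (1 − β),
so it converges geometrically to the unique fixed point
`D* = β (I − (1−β)Q)⁻¹ D(0)`; iteration stops when successive iterates
differ by less than the tolerance (default 1e−9) in the L1 norm (the
natural norm for probability vectors; L∞ is available). The iteration cap
(10 000) can only bind on degenerate configurations — at β = 0.1 and
tolerance 1e−9 convergence needs at most ⌈log 1e−9 / log 0.9⌉ ≈ 197
steps.

A `seed_restricted` initial vector (mass on seeds only — the classic
random-walk-with-restart restart vector) is offered for comparison but is
not the default; the default keeps every gene's functional weight in
D(0).

**Numerical formulation.** The implementation iterates the increment
`Δ(i+1) = (1−β) Q Δ(i)` and accumulates `D(i+1) = D(i) + Δ(i+1)`. This is
algebraically identical to the recurrence above, but the convergence
residual ‖Δ‖ is obtained directly instead of subtracting two nearly equal
vectors, which would contaminate the residual with cancellation noise
near convergence. Summations over neighbors are performed in sorted node
order so results are bit-identical regardless of input edge order.

**Ranking.** Candidates are sorted by fixed-point score in descending
order; ties break lexicographically on the gene symbol for
reproducibility. With `include_seeds=False` (the default view) seeds are
removed before ranks are assigned.

## Evaluation

**LOOCV.** Each seed is held out in turn and re-ranked as if unknown.
Two protocols are implemented:

- `rebuild` (default): the disease network is rebuilt from the remaining
  seeds; the held-out gene enters, if at all, as an ordinary candidate
  recruited by the others. A fold whose held-out gene interacts with no
  remaining seed is recorded and excluded — such a gene could never be
  ranked by the method, and any other treatment leaks information.
- `fixed`: the network topology from the full seed set is kept and only
  node weights (hence D(0)) are rebuilt per fold. Every fold stays
  evaluable, but the protocol is optimistically biased: the held-out
  seed retains the neighborhood that only its own seed status pulled
  into the network, which measurably inflates the AUC even on
  signal-free data (pooled null AUC ≈ 0.67 versus ≈ 0.45 under
  `rebuild` on the synthetic null described below). `rebuild` is the
  default for exactly this reason.

**ROC/AUC from ranks.** Each fold is one positive with rank r in a pool
of size n (the held-out gene versus the n−1 candidates of its own fold).
Ranks are mapped to x = (r−1)/(n−1), the fraction of the fold's negatives
ranked above the positive; the ROC is TPR(t) = fraction of folds with
x ≤ t against FPR(t) = t, and the trapezoidal area equals the
fold-averaged Mann–Whitney statistic `mean((n−r)/(n−1))` exactly (each
fold weighted equally). Pool composition is recorded per fold for audit.

**Baselines.** Degree, weighted degree, and an unweighted
random-walk-with-restart (every node and edge weight 1, same β) are
provided; the latter doubles as the LOOCV baseline via
`weighting="uniform"`.

**β sweep.** `beta_sweep` evaluates a supplied metric (LOOCV AUC by
default usage) over a β grid and flags the argmax. On real disease
networks β = 0.1 is the conventional operating point; on the synthetic
benchmark the argmax lands elsewhere, which the sweep reports without
judgement.

## Enrichment

Over-representation of a top-k gene list is tested per term with the
upper-tail hypergeometric probability P(X ≥ k | N, K, n), adjusted by
Benjamini–Hochberg step-up, significant at adjusted P < 0.05. The
background defaults to the analyzed network's gene set — the pool the
ranking draws from — not the genome, and is configurable. A term is
flagged disease-related when it annotates at least one seed gene. This is
a plain hypergeometric test; DAVID's EASE-modified score is deliberately
not replicated.

## Synthetic benchmark

The generator emulates the two assumptions the method relies on: disease
genes cluster topologically and share function. It plants a
stochastic-block module of `module_size` genes (default 20) inside
`n_nodes` genes (default 200): within-module pairs get an edge with
probability `p_in = 0.3`, all other pairs with `p_out = 0.02`. Seeds
(default 10) are drawn uniformly from the module. Of `n_terms = 50`
synthetic terms, 20 % are module-specific; each module gene carries each
of them with probability `term_coherence = 0.8`, and every gene carries
each remaining background term with probability
`background_term_rate = 0.05`. All sampling is vectorized in a fixed
order (edges, seeds, module terms, background terms) from a single
`numpy` generator, so outputs are byte-identical across platforms for a
given `rng_seed` (default 42).

The matched null (`null_generate`) forces `p_in = p_out` and
`term_coherence = background_term_rate`, recording the override in the
provenance metadata; truth labels are still emitted. Null LOOCV excludes
the many folds whose held-out gene touches no remaining seed (~80 % at
`p_out = 0.02`) — an inherent property of a method that can only rank
genes inside the disease neighborhood — and the pooled AUC over the
surviving folds sits near 0.5.

What the generator does **not** emulate: scale-free degree structure and
study bias (real disease genes are better studied, hence better
annotated and better connected), annotation ontology structure (terms
are flat ids), overlapping disease modules, and edge confidence scores.
Passing the synthetic recovery test therefore demonstrates that the
machinery recovers a planted functional module under the stated noise
model, not that it reproduces performance on any real disease network.

## Design choices on genuinely open points

- **Similarity = Jaccard over pooled GO aspects.** An explicit stand-in
  where the weighting literature offers many choices; swappable behind
  `WeightingConfig`, with aspect pooling as the default combination rule.
- **Gene identifiers** are case-sensitive strings canonicalized only by
  whitespace stripping; no alias resolution.
- **Self-loops** in input edge lists are dropped (counted and warned);
  duplicate undirected pairs merge keeping the maximum score.
- **LOOCV pool** = the held-out gene plus all candidates of its fold's
  network.
- **Benchmark problem sizes** (200-gene networks, 20 null replicates, 50
  random oracle networks of 5–50 nodes) were chosen so the whole suite
  exercises every code path at desk scale; all scale linearly if larger
  instances are wanted.

## Known limitations

- Jaccard similarity treats all terms as equally informative; shallow,
  frequent terms dilute it. Information-content measures are the natural
  extension.
- The weight floor (0.001) injects a small uniform prior; on very sparsely
  annotated networks it dominates and the method degrades toward the
  unweighted walk.
- The rebuild LOOCV cannot evaluate seeds whose only network connection
  was their own neighborhood; their exclusion is reported but reduces
  fold counts on sparse networks.
- Enrichment against the network background is conservative when the
  network itself is already module-enriched (always true for a disease
  neighborhood); genome-wide backgrounds require supplying the background
  explicitly.
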