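# netprior

Disease-gene prioritization by risk propagation on functionally weighted
interaction networks, with leave-one-out cross-validation, rank-based
ROC/AUC, over-representation testing, and a synthetic planted-module
benchmark so the whole pipeline is testable without any database
downloads.

## Who it is for

Computational biologists who have (i) an interaction network — a generic
TSV/SIF edge list or STRING `protein.links` — (ii) a list of seed genes
with curated disease evidence, and (iii) gene functional annotations
(GO OBO + GAF, or a plain gene→term TSV), and who want a ranked list of
candidate disease genes with an honest cross-validated performance
estimate.

## The method

The disease-related network is the subgraph induced by the seed genes and
their direct interactors. Nodes and edges are weighted by functional
similarity (Jaccard index over annotation term sets): edge weight
`w(h,g) = J(T(h), T(g))`, node weight `w_g = max_s J(T(g), T(s))` over
seeds s, with seeds themselves at `w_s = 1`. Disease risk then diffuses
over the network:

    q(g|h)  = w(h,g) / Σ_{l∈neighbor(h)} w(h,l)      (column-stochastic Q)
    d_g(0)  = w_g / Σ_m w_m                          (initial risk, all genes)
    D(i+1)  = (1−β) · Q · D(i) + β · D(0)            (restart iteration)

with β = 0.1 and convergence when successive iterates differ by less than
1e−9 (L1). The iteration is a (1−β)-contraction and converges to
`D* = β(I−(1−β)Q)⁻¹D(0)`; candidates are ranked by `D*` in descending
order. Performance is estimated by leave-one-out cross-validation: each
seed is held out, the network and weights are rebuilt from the remaining
seeds, and the held-out gene's recovered rank feeds a rank-based ROC
whose area equals the Mann–Whitney statistic. See `docs/methods.md` for
the full model description, numerical choices, and limitations.

## Worked example

Generate a synthetic benchmark — a 200-gene network with a planted
20-gene disease module, 10 seed genes sampled from it, and coherent
annotations — then run the full pipeline:

```
netprior simulate --nodes 200 --module 20 --seeds-count 10 --rng 42 --out-prefix fixture/
netprior run --edges fixture/edges.tsv --seeds fixture/seeds.txt \
             --annotations fixture/annotations.tsv --out-dir results
```

`results/ranking.tsv` starts:

```
rank    gene    score           is_seed
1       G010    0.0972242373111 0
2       G013    0.0814790839816 0
3       G007    0.0566719117515 0
4       G002    0.0527183009056 0
5       G003    0.0423163414081 0
```

All top-ranked candidates (G002–G019 symbols below G020) are members of
the planted module — the prioritizer recovers the module from the seeds.
`results/provenance.json` records the run: the disease network has 55
nodes (10 seeds, 45 candidates) and 107 edges, propagation converged in
52 iterations, and `results/loocv.json` reports a leave-one-out AUC of
0.872 over 10 folds, i.e. a held-out disease gene is ranked above ~87 %
of candidates on average. `results/enrich.tsv` holds the
hypergeometric/Benjamini–Hochberg enrichment of the top-ranked genes
against the network background.

Each stage is also available separately (`build`, `weight`,
`prioritize`, `loocv`, `enrich`, `simulate`); `netprior --help` lists
them. The same functionality is importable:

```python
import netprior as npr

ds = npr.generate(npr.SyntheticSpec())           # planted benchmark
res = npr.loocv(ds.edges, ds.annotations, ds.seeds)
print(round(res.auc, 3), res.n_folds)            # 0.872 10
```

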