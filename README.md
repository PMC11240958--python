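# molnet — distance-based molecular similarity networks

`molnet` analyses a library of small molecules (its motivating use case is
the 1547 BACE-1 inhibitors distributed with DeepChem as `bace.csv`) as a
family of weighted networks. Each molecule is a node; edges are derived
from one of four inter-molecule dissimilarities:

* **Euclidean** distance between 12-component descriptor vectors
  (molecular mass, reference-normalised MMFF94 energy, Crippen cLogP and
  MR, geometric eccentricity, the three Kier kappa shape indices,
  synthetic-accessibility score, TPSA, and the Shannon entropies of the
  2D/3D autocorrelation vectors), `d(A,B) = (Σᵢ (aᵢ−bᵢ)²)^½`;
* **Tanimoto** distance on binary fingerprints, `d = 1 − T` with
  `T = A·B / (|A|² + |B|² − A·B)`;
* **Hamming** distance on the same fingerprints, `d = Σᵢ |aᵢ−bᵢ|`;
* **Levenshtein** (unit-cost edit) distance between SMILES strings.

Each dense distance matrix is mapped to similarities (`s = 1 − d/d_max` by
default) and sparsified with the **Triangulated Maximally Filtered Graph**
(TMFG): a greedy maximal-planar filter that keeps exactly `3n − 6` edges by
inserting each vertex into the triangular face it is most similar to. On
the filtered networks the package computes weighted degree, shortest
paths, betweenness, Burt constraint `Cᵢ = Σⱼ (p_ij + Σₖ p_ik p_kj)²`, and
eigenvector centrality `x = (1/λ) W x` (rescaled so the most central
molecule scores exactly 1). Communities are detected twice — by recursive
leading-eigenvector bisection of the modularity matrix
`B_ij = A_ij − k_i k_j / 2m` and by the Leiden algorithm optimising
modularity `Q = (1/2m) Σ_ij [A_ij − k_i k_j/2m] δ(c_i, c_j)` — and the two
partitions are compared with VOI, NMI, split–join distance, Rand index and
adjusted Rand index from a shared contingency table. Finally, descriptor
differences across the detected communities are tested per descriptor
with Kruskal–Wallis (location), Conover squared-ranks (variance) and
Gehan generalized-Wilcoxon (distribution) k-sample tests.

It is aimed at cheminformaticians and network scientists who want a
reproducible, fully tested version of this workflow, including a
planted-cluster synthetic generator so every stage can be exercised
without downloads.

## Worked example

```python
from molnet import run_full_pipeline

report = run_full_pipeline({
    "synthetic": {"sizes": (30, 30, 30), "seed": 7},  # 3 planted clusters
    "metrics": ["euclidean", "hamming"],
    "seed": 7,
})
sec = report["networks"]["hamming"]
print(sec["graph"])
print(sec["communities"]["leiden"])
print(sec["comparison"])
```

prints (exactly reproducible for this seed):

```
{'n': 90, 'edges': 264, 'is_planar': True, 'connected': True}
{'count': 3, 'sizes': [30, 30, 30], 'modularity': 0.6560012725178048}
{'VOI': 0.0, 'NMI': 1.0, 'SJD': 0, 'RI': 1.0, 'ARI': 1.0, ...}
```

The Hamming TMFG has `3·90 − 6 = 264` edges and is planar and connected,
as every TMFG must be. Both detection methods find exactly the three
planted 30-molecule clusters, so the five agreement metrics sit at their
identity values (VOI = 0, NMI = RI = ARI = 1, SJD = 0), and the planted
ARI recorded in `sec["planted_ari"]` is 1.0. On the Euclidean network of
the same molecules the two methods return finer 5-block partitions
(NMI ≈ 0.87 between them) — see `docs/methods.md` for why modularity
sub-divides geometric clusters on a planar filter. The descriptor test
battery in `sec["descriptor_tests"]` reports, e.g. for molecular mass
across the three Hamming communities, Kruskal–Wallis H = 79.1
(p ≈ 7·10⁻¹⁸): the planted clusters differ strongly in location but not
in spread (Conover p ≈ 0.29).

The same analysis runs from the shell:

```bash
molnet generate --sizes 30,30,30 --seed 7 --out syn.csv
molnet run --synthetic --metrics euclidean,hamming --seed 7 --out-dir out/
# real data: molnet run --csv bace.csv --seed 0 --out-dir out/
```

`out/report.json` holds the consolidated report; GraphML networks and
per-stage CSV tables are written alongside it.

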