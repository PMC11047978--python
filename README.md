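# pnnkit

Quantification of **perineuronal net (PNN) ultrastructure and synaptic
inputs** from fluorescence image stacks, for neuroscientists studying
extracellular-matrix plasticity in factorial (genotype × housing) designs.

Perineuronal nets are condensed extracellular-matrix lattices that enwrap
neuronal somata, visualised with the lectin WFA. At super-resolution the
net resolves into a mesh whose junction points ("nodes") carry structural
information; at confocal resolution, PNN-delineating ROIs support
densitometry of the net itself (WFA intensity, PV co-labelling) and of the
inhibitory/excitatory presynaptic puncta (VGAT / VGlut1) penetrating it.
`pnnkit` implements that entire analysis as a tested, reproducible
library, driven end-to-end by a seeded synthetic-data generator with
recorded ground truth.

## What it computes

**Mesh topology.** From a node cloud $\{x_i\} \subset \mathbb{R}^3$ (µm),
the proximity graph at threshold $t$ has edges
$\{(i,j) : \lVert x_i - x_j \rVert \le t\}$. Per PNN, five statistics at
the base threshold $t_0 = 0.7$ µm:

- $N$ — number of nodes,
- % connected — $100 \cdot |\{i : \deg_{t_0}(i) \ge 1\}| / N$,
- mean internode distance — mean edge length at $t_0$,
- mean degree — $2|E|/N$,
- **R95** — the smallest $t \in \{0.7, 0.75, \dots, 3.0\}$ µm with
  $\ge 95\,\%$ of nodes connected; flagged *unreached* if more than 5 % of
  nodes stay isolated at the sweep ceiling.

**Node detection.** Anisotropic Laplacian-of-Gaussian spot detection with
background-referenced intensity gating, Hessian-based ridge rejection
(mesh struts are elongated; nodes are not), greedy minimum-separation
suppression and sub-voxel parabolic refinement.

**Per-ROI densitometry.** Rolling-ball background subtraction; mean WFA
intensity over pixels whose centres fall inside each ROI polygon; PV+
classification against the out-of-ROI background (mean + 3 SD); puncta
detection à la *Analyze particles* (threshold → watershed split →
8-connected components → size filter), summarised per ROI as density
(count / area in µm²), mean size (µm²) and mean intensity (0–255).

**Group statistics.** Shapiro–Wilk per group gates between two-way ANOVA
(Type II) + Tukey HSD and Kruskal–Wallis (tie-corrected, df = 3) + Dunn's
z-tests with Holm adjustment, over the four TnC⁺/⁺/TnC⁻/⁻ × SE/EE cells at
$\alpha = 0.05$.

## Worked example

```python
from pnnkit import DetectParams, NodeSet, detect_nodes, summarize_topology
from pnnkit.synthetic import PnnStackParams, generate_pnn_stack

stack, truth = generate_pnn_stack(
    PnnStackParams(n_nodes=80, shell_radius=5.0, snr=10.0), seed=7)
nodes = detect_nodes(stack, DetectParams(min_separation_um=0.4))
print(len(nodes), "detected of", truth.n_nodes)

m = summarize_topology(nodes)
print(f"pct_connected={m.pct_connected:.1f}%  "
      f"mean_degree={m.mean_degree:.2f}  r95={m.r95:.2f} µm")
```

prints

```
80 detected of 80
pct_connected=52.5%  mean_degree=0.65  r95=1.30 µm
```

— all 80 rendered nodes are recovered (median localization error ≈ 20 nm
on this scene); at the 0.7 µm base threshold about half the nodes of this
relatively sparse demo net have a neighbour, and sweeping the threshold
to 1.30 µm connects 95 % of them. The scripts in `examples/`
walk through every stage (simulation, detection, topology, section
densitometry, group statistics, full pipeline) with printed output.

A thin CLI mirrors the stages:

```bash
pnnkit simulate stack --seed 7 --out demo/
pnnkit detect-nodes --stack demo/pnn_stack.tif --out demo/nodes.csv
pnnkit topology --nodes demo/nodes.csv --out demo/metrics.csv
pnnkit run-all --seed 2024 --out results/
```

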