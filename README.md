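# flowmotifs

Information-flow motif analysis of directed functional networks, built as a
reusable pipeline:

1. **Phase transfer entropy (PTE)** — pairwise directed information flow
   estimated from instantaneous-phase time series with histogram-binned
   probabilities and a data-driven prediction delay
   (`h = round(N_s · N_regions / N_sign_changes)`), averaged over all
   subject/epoch units; directed PTE (`dPTE = PTE_xy / (PTE_xy + PTE_yx)`)
   included.
2. **Threshold-interval network construction** — strict binarization
   `link(i→j) ⇔ PTE[i,j] > τ` over a principled interval: `τ_min` is the
   nearest-rank 30th percentile of the off-diagonal PTE values, `τ_max` the
   largest threshold at which the network is still weakly connected with no
   isolated nodes.  Network properties (uni/bi link counts, average degree,
   link density, assortativity) are reported per threshold.
3. **3-node motif census** — canonical motif ids (minimum over relabelings of
   the row-major 9-bit adjacency encoding; id 78 is the bi-directional 2-hop
   path), exhaustive induced census, degree- and mutuality-preserving
   link-switching null model, z-scores and three-criterion overexpression
   calls, apex-ratio and high-degree-node statistics.
4. **Motif-conductance spectral clustering** — motif adjacency matrices
   (node-disjoint co-participation counts), normalized motif Laplacian sweep
   cut with the `4·√(φ*)` approximation guarantee, link-resolved threshold
   sets (one removed link per threshold), aggregation of motif adjacencies
   over the interval, and a two-cluster partition plus the non-participant
   third group.
5. **Synthetic data with ground truth** — lag-coupled Kuramoto-style phase
   oscillators with configurable directed couplings, and planted two-level
   weight matrices with bidirectional hubs for end-to-end recovery tests.

## CLI

```bash
# simulate a coupled-phase ensemble (config is flat key=value; see RunConfig)
flowmotifs simulate --config cfg.txt --seed 3 --out-dir out/

# pairwise PTE matrix from the saved ensemble
flowmotifs pte --input out/phases --out out/pte.tsv

# threshold interval and a binarized network
flowmotifs threshold --input out/pte.tsv --auto-interval --tau 0.02 --out-dir out/

# motif census with null-model overexpression calls at one threshold
flowmotifs census --input out/pte.tsv --tau 0.02 --n-random 1000 --seed 7

# aggregated motif-conductance clustering (motif 78 by default)
flowmotifs cluster --input out/pte.tsv --ties group --out-dir out/

# everything end to end, with a JSON run report
flowmotifs run-all --config cfg.txt --seed 3 --out-dir out/
```

Example config file:

```
seed = 3
n_regions = 10
n_epochs = 4
n_samples = 512
n_random = 200
percentile = 0.30
ties = group
```

All artifacts are plain text (TSV matrices, edge lists, JSON reports) and are
byte-identical across reruns of the same config.

## Layout

```
src/flowmotifs/
  synthetic.py    phase-oscillator and planted-matrix generators
  pte.py          delay estimation, pairwise/matrix PTE, dPTE
  netbuild.py     thresholding, interval selection, network properties
  motifs.py       canonical ids, census, rewiring nulls, overexpression, apex
  clustering.py   motif adjacency, conductance, sweep cut, aggregation
  io.py           TSV/JSON/edge-list readers and writers
  pipeline.py     RunConfig and the full orchestrated run
  cli.py          click-based command line
tests/            pytest suite incl. brute-force oracles and acceptance tests
scripts/          acceptance.py
```
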