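# traitedge

Where do naturalized and invasive plant species sit in the multidimensional
functional trait space of the local communities they join? `traitedge`
implements the full analysis pipeline for that question on vegetation-plot
data:

- **Trait space** — log10 transformation and global z-scoring of species
  traits (max height, seed mass, leaf area, SLA, LDMC, flowering midpoint,
  flowering length, 2C genome size), plus a Gower dissimilarity alternative
  with the Podani ordinal extension (flowering midpoint) embedded via PCoA.
- **Per-plot statistics** — `D`, the mean Euclidean distance of each
  community fraction (native / naturalized / invasive) from the native
  centroid (an unweighted functional-dispersion analog), and `E`, the
  two-sample energy distance measuring the overlap of two fractions. Both
  come in cover-weighted variants (weights = √percentage cover).
- **Null models** — stratified random redraws of each fraction from the
  habitat species pool (native pool for comparisons against natives,
  naturalized pool for the naturalized-vs-invasive comparison), preserving
  fraction size, per-life-form counts and covers. Pool selection is
  uniform, frequency-weighted, or weighted by Beals co-occurrence
  probabilities. Reductions: ΔD = observed D − mean simulated D, and the
  empirical overlap probability p_E = (#{simulated E ≥ observed} + 1) /
  (n_sim + 1).
- **Habitat summaries** — paired Wilcoxon signed-rank tests of ΔD between
  fractions, Benjamini–Hochberg adjustment across the whole family, effect
  sizes r = z/√N with small/medium/large classes (0.3 / 0.5 boundaries).
- **Trait drivers** — a CART regression tree (greedy SSE splits, 10-fold CV
  with the 1-SE cost-complexity pruning rule, percent variance explained
  per split, surrogate splits at ≥90% agreement) relating ΔD to
  fraction-mean trait values.
- **Synthetic data** — a generator of habitat pools and invaded plots under
  `neutral`, `filtering` and `eots` (edge-of-trait-space) scenarios with
  controllable displacement of invasive trait means, so the whole pipeline
  is testable without any external data.

## CLI

Generate a synthetic dataset, then run the full analysis:

```bash
traitedge simulate --seed 1 --scenario eots --displacement 2 \
    --n-plots 200 --out synthetic/

traitedge run --plots synthetic/plots.csv --traits synthetic/traits.tsv \
    --registry synthetic/registry.csv --nsim 999 --seed 1 \
    --weighting beals --out results/
```

Outputs in `results/`: `plot_metrics.csv` (observed D/E per plot),
`null_results.csv` (ΔD and p_E per plot × comparison), `habitat_summary.csv`
(Wilcoxon z, BH-adjusted p, effect size r per habitat × contrast),
`tree_naturalized.json` / `tree_invasive.json` (driver trees) and
`manifest.json` (seed, config hash, counts).

Other flags: `--cover-weights` (√cover-weighted D/E),
`--distance gower_pcoa`, `--layer-split` (separate herb and phanerophyte
layers, for scrub/forest data), `--exclude-species NAME` (sensitivity
reruns), `--habitat-map FILE` (plot→habitat CSV if the plots file has no
habitat column), `--config FILE` (YAML mirroring all flags). A debugging
subcommand `traitedge metrics --plot-id ...` prints one plot's statistics.

Input formats: plots as long CSV (`plot_id, habitat, species, cover` with
covers in (0, 100]; a wide plot×species matrix is also accepted), traits as
TSV (`species` + the eight canonical trait columns), registry as CSV
(`species, status, life_form`) with status in {native, naturalized,
invasive} and life form in {macrophanerophyte, nanophanerophyte,
chamaephyte, herb, epiphyte}.

## Reproducibility

Every stochastic step is seeded. Null-model draws use per-plot generators
derived from the master seed and the plot id, so per-plot results do not
depend on processing order, and rerunning a configuration reproduces the
output files byte for byte.
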