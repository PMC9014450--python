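# spothet

Spot-level cell-fraction deconvolution and heterogeneous drug-response
screening for Visium-style spatial transcriptomics.

## The problem

A capture spot on a spatial transcriptomics array overlaps several cells,
so bulk per-spot expression confounds cell-type composition with cell-type
response. In tissues where the responding population is a small minority —
for example renin-producing juxtaglomerular (JG) cells at the glomerular
vascular pole of the kidney, which up-regulate *Ren* under angiotensin
receptor blockade, and the adjacent macula densa (TAL-2) cells, which
up-regulate *Ptgs2* — asking *which structures responded, and how
uniformly* requires attributing each spot's signal to the cell type of
interest first.

`spothet` implements that analysis end to end:

1. **QC + signature** — filter reference single cells (200–5,000 detected
   genes, < 30,000 UMIs, < 40% mitochondrial) and build a genes × types
   signature of mean counts-per-10k profiles.
2. **Deconvolution** — estimate per-spot fractions `f_j` by non-negative
   least squares under the linear mixing model `E[c_j] ∝ S f_j`, refined
   with fitted-mean inverse-variance reweighting.
3. **Fraction normalization** — attribute expression to the target type,
   `NC_ij = C_ij / F_j` over spots with `F_j ≥ 0.05`, followed by
   total-count log normalization `log(1 + 10^4 · v / Σv)`.
4. **Spatial context** — classify cortical spots by dominant sub-population
   score and test glomerulus adjacency of the minority group with Fisher's
   exact test on the hexagonal lattice.
5. **Heterogeneity screen** — rank genes by skewness `g1 = m3/m2^{3/2}`
   (top 5% among genes with mean > 0.01), test the response-gene
   distribution against a Gaussian null (one-sample KS), classify
   responding spots against a control-referenced threshold, select the
   top-25% *high-responding* spots per sample, and run Wilcoxon/BH
   differential expression for the high-responders.

A synthetic tissue generator (`spothet.simulate`) produces hex-lattice
kidney sections with zone bands (Cortex / OMOS / OMIS / IM), single-spot
glomeruli with planted podocyte/mesangial/JG composition, macula densa
spots adjacent to each glomerulus, and planted treatment effects — so
every stage is verifiable against ground truth. See `docs/methods.md` for
the model, defaults, and limitations.

## Worked example

```python
from spothet import (SimConfig, PipelineConfig, PipelineInputs,
                     make_reference, make_tissue, make_spot_counts, run_pipeline)

cfg = SimConfig(seed=1)                    # 3 Ctrl + 3 Losa sections, 40 glomeruli each
ref, labels = make_reference(cfg)          # 300 genes x 2,000 labelled cells
lattice, truth = make_tissue(cfg)          # 7,200 spots with planted truth
spots = make_spot_counts(lattice, truth, cfg)

result = run_pipeline(PipelineConfig(min_genes=100),
                      PipelineInputs(ref, labels, spots, lattice))

print(result.adjacency[["group", "adjacent", "not_adjacent", "fisher_p"]])
print("responder Fisher p:", result.responder_p)
gs = result.gene_stats.set_index("gene_id")
print(gs.loc[["Ren", "Rplp0"], ["mean", "skewness", "top_skew"]])
```

prints

```
   group  adjacent  not_adjacent      fisher_p
0  TAL-1       714           481  2.758243e-25
1  TAL-2       314            44  2.758243e-25
responder Fisher p: 3.0668218340965914e-07
             mean  skewness  top_skew
gene_id
Ren      4.149792  0.636976      True
Rplp0    5.296495 -0.078376      True
```

Reading it: macula densa (TAL-2-dominant) spots are strongly enriched next
to glomeruli (odds ratio far from 1, Fisher p ≈ 3e-25); treated sections
contain significantly more responding JG spots than controls (p ≈ 3e-7);
and the response gene *Ren* shows a long right tail across treated JG
spots (skewness 0.64, inside the top-5% flag set) while the housekeeping
analog *Rplp0* stays near-symmetric — the signature of a heterogeneous,
subset-driven response.

The same stages are scriptable from the shell:

```sh
spothet simulate --seed 1 --out data/
spothet run --seed 1 --out reports/
spothet --help         # qc, signature, deconvolve, normalize, spatial, heterogeneity, de
```

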