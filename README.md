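# nucleoquant

Quantification pipelines for three proteostasis readouts measured in
ageing and neurodegeneration studies:

1. **Nucleolar morphometry** — nucleolar size and number are biomarkers of
   ageing. From two-channel micrographs (DNA stain + nucleolar marker such
   as NCL/FBL, or FUrd for nascent rRNA), the package segments nuclei and
   their nucleoli and reports, per nucleus: nucleolus count, the size
   fold (total nucleolar area / nuclear area), the nucleolar *presence
   ratio* (mean marker intensity in nucleoli ÷ mean in the nucleoplasm),
   and integrated/median nucleolar intensities.
2. **polyQ aggregation scoring** — aggregated polyQ-EGFP forms bright foci
   that give a cell a "rough" texture. Cells are grown from nuclear seeds
   (seeded watershed on the EGFP channel), and aggregation is quantified
   by Haralick GLCM contrast `Σ (i−j)² P(i,j)`, by Laplacian-of-Gaussian
   focus counting, and by the S0/S1/S2 rule (0, 1–5, > 5 aggregates).
3. **Polysome-profile quantification** — from sucrose-gradient OD260
   traces, the profile is anchored at the 60S/80S valley (X = 0), min–max
   normalized in Y, rescaled to X ∈ [0, 100], and integrated into monosome
   and polysome fractions split at the monosome/disome valley; the
   reported statistic is the polysome/monosome (P/M) ratio, a proxy for
   ribosomal engagement.

A synthetic-data module generates ground-truthed micrographs and traces
(exact per-object truth tables), so every stage of the analysis is
verifiable without any external dataset. Shared reporting utilities cover
fold changes vs. a control condition, the luciferase refold-capacity
statistic (recovered ÷ non-shocked activity, per genotype), rank/Welch
group tests and Benjamini–Hochberg adjustment.

Intended users: cell biologists quantifying nucleolar state, polyQ
aggregation or translation from standard fluorescence micrographs (TIFF)
and gradient spectrometer exports (two-column text), and anyone needing a
scriptable, testable re-implementation of these CellProfiler-style
measurements.

## Worked example

```python
import nucleoquant as nq
from nucleoquant.nucleoli import measures_to_frame

# nucleolar morphometry on a ground-truthed synthetic scene
scene = nq.gen_nucleolar_scene(nq.NucleolarSceneSpec(n_nuclei=6, seed=42))
nuclei = nq.segment_nuclei(scene.image, "dna", min_area_px=200)
nucleoli = nq.segment_nucleoli(scene.image, "marker", nuclei)
df = measures_to_frame(nq.measure_nuclei(scene.image, "marker", nuclei, nucleoli))
print(df[["nucleus_id", "nucleolus_count", "size_fold", "presence_ratio"]]
      .round(3).to_string(index=False))

# polysome profile with a known polysome/monosome ratio of 2
trace, truth = nq.gen_polysome_trace(nq.standard_polysome_spec(2.0, seed=7))
quant, norm = nq.quantify_trace(trace)
print(f"true P/M = {truth['true_ratio']:.2f}, recovered P/M = {quant.pm_ratio:.3f}")
```

prints

```
 nucleus_id  nucleolus_count  size_fold  presence_ratio
          1                3      0.063           2.009
          2                1      0.028           2.003
          3                4      0.126           1.998
          4                2      0.074           2.000
          5                3      0.101           2.001
          6                3      0.076           2.004
true P/M = 2.00, recovered P/M = 2.051
```

Each row is one nucleus (labels in raster order): its nucleolus count, the
fraction of the nucleus covered by nucleoli, and the marker enrichment of
nucleoli over nucleoplasm — the scene was generated at enrichment 2.0, and
the measured presence ratios recover it to within ~0.5%. The trace example
recovers the constructed P/M ratio 2.0 within ~2.5%.

## Command line

```sh
nucleoquant simulate nucleoli --seed 4 --out sim/          # scene + truth JSON
nucleoquant nucleoli  --image sim/scene.tif --out out/     # per-nucleus CSV + QC overlay
nucleoquant aggregates --image scene.tif --out out/        # per-cell contrast/foci/score CSV
nucleoquant polysome  --manifest runs.csv --out out/       # P/M ratios + normalized traces + plot
nucleoquant report    --table values.csv --control WT --out out/
```

`runs.csv` lists `sample,condition,path`; channel maps for real TIFFs are
JSON files like `{"dna": 0, "marker": 1}` passed via `--channels`.

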