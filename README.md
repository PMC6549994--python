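# landmarkov

Scenario-led land-use/land-cover (LULC) change projection as a reusable,
tested pipeline:

1. **Change analysis** between two co-registered categorical rasters —
   cross-tabulation, per-class gains/losses/net change, Boolean transition
   masks, and polynomial trend surfaces of change intensity.
2. **Driver variables** — Euclidean distance transforms (dynamic variables),
   evidence-likelihood transformation of categorical layers, and Cramér's V
   screening (default threshold 0.15, ties dropped).
3. **Transition sub-models** — one multiclass single-hidden-layer MLP per
   origin class, trained on a stratified 10 000-pixel sample split half/half
   into training and validation, with backwards stepwise variable selection
   and per-pixel transition-potential rasters.
4. **Markov change demand** — transition probability matrix estimated from
   observed counts, rescaled to the projection horizon (principal fractional
   matrix power, with a documented linear fallback), optionally transformed
   by declarative scenario edits (`scale_cell`, `scale_diagonal`,
   `fix_row_identity` with donor compensation), then converted to per-class
   area demand.
5. **Allocation** — greedy ranked allocation of demand onto the map by
   transition potential, with deterministic seeded tie-breaking and explicit
   unmet-demand accounting; optional multi-step projection recomputing
   dynamic distance variables each step.
6. **Synthetic data** — autocorrelated categorical landscapes evolved under
   a known row-stochastic matrix with covariate-modulated transitions, so
   every stage is testable without external downloads.

Rasters are read/written as ESRI ASCII grids (the human-readable fixture
format) or single-band GeoTIFF (via `tifffile`, with ModelPixelScale/
ModelTiepoint and GDAL_NODATA tags). Inputs must already be co-registered;
reprojection and resampling are out of scope.

The printed transition matrices and the 20-value driver-screening table of a
published Wales 2007–2015 study are embedded in `landmarkov.datasets` as
validation fixtures; the scenario-edit arithmetic reproduces the published
ecosystem-conservation matrix cell-for-cell (one known 0.001 rounding
residue in conifer persistence is reported, not matched).

## Command-line interface

```bash
landmarkov change   --t1 t1.asc --t2 t2.asc --legend legend.csv --out out/
landmarkov drivers  --t1 t1.asc --t2 t2.asc --legend legend.csv \
                    --config drivers.conf --out out/
landmarkov train    --t1 t1.asc --t2 t2.asc --legend legend.csv \
                    --drivers alt=alt.asc --origin conifer \
                    --n 10000 --seed 7 --out model.json
landmarkov markov   --counts counts.csv --base-years 8 --target-years 15 \
                    --scenario ec.scn --out P_ec.csv
landmarkov project  --map t2.asc --legend legend.csv --models models/ \
                    --matrix P_ec.csv --drivers alt=alt.asc \
                    --steps 1 --seed 7 --out projected.asc
landmarkov simulate --seed 11 --out fixtures/
landmarkov run      --config study.conf
```

Exit codes: 0 success, 2 validation error, 3 stage failure.

Scenario files are plain text, one edit per line:

```
scale_cell conifer broadleaf 1.5 donor=diagonal
scale_diagonal mountain_heath_bog 1.5 donor=largest_offdiagonal
fix_row_identity broadleaf
```

`landmarkov run` takes a flat INI config (see
`tests/test_cli_pipeline.py::workspace` for a complete example) with
sections `[inputs]`, `[driver:<name>]`, `[screening]`, `[sampling]`,
`[mlp]`, `[markov]`, `[scenarios]`, `[output]`. A seed is required; every
default is echoed into `run_log.json`.

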