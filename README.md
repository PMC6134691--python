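# shapesearch

Retrieve candidate 3D biological shapes from a few 2D projection images.

`shapesearch` builds a redundancy-reduced library of 2D projection images
from 3D density maps and ranks library models against a handful of query
images:

1. **Volume normalization** — every map is resampled to a 100 Å cubic grid
   at 1 Å spacing and rescaled so its particle content occupies a common
   reference volume of 50³ Å³ (`D_new = D_old · D_ref / V_old^{1/3}`, with
   the particle volume read from a Gaussian-mixture model of the map).
2. **Shape similarity** — maps are summarized as 3D Gaussian mixtures;
   similarity is the analytic overlap correlation, maximized over rigid
   superposition.
3. **Deduplication** — pairwise CCs become distances `d = sqrt(1 − CC²)`,
   clustered with Ward's method applied to unsquared distances (R's
   `ward.D`); the tree is cut at the median merge height and each cluster's
   medoid represents it.
4. **Projection library** — 91 quasi-uniform view directions per
   representative (subdivided icosahedron, upper hemisphere), 64×64 px
   images.
5. **Retrieval** — each query image is aligned against every library image
   (exhaustive in-plane rotation + mirror, FFT translation search); per-row
   Z-scores, per-model top-10 sums, and a final standardized match score
   `T_n` rank the models.

Diagnostics include per-model PCC clustering of image similarity, classical
MDS of the image set, and 0.1-unit grid-cell summaries of the embedding.
A synthetic-shape generator (spheres, ellipsoids, cylinders, dumbbells,
L-blocks, bullets) makes the whole pipeline testable with no external data.

## CLI

```sh
# generate 20 synthetic maps in 4 families
shapesearch simulate --n 20 --families 4 --seed 7 --out maps/

# build a deduplicated projection library
shapesearch build-library --maps maps/ --gdfs 20 --n-images 91 \
    --cutoff median --seed 0 --out lib/

# rank library models against a query stack (MRCS + sibling TSV index)
shapesearch search --library lib/ --queries queries.mrcs --k 10 \
    --psi-step 2 --max-shift 10 --out report

# model dendrogram from the stored pairwise 3D CCs
shapesearch cluster --library lib/ --out dendrogram.tsv

# classical MDS of all library images + 0.1-unit cell summaries
shapesearch mds --library lib/ --out mds
```

`search` writes `report.tsv` (rank, model, `T_n`, `S_n`, per-image `X_i`)
and `report.json` (full provenance). All stochastic stages take explicit
seeds; identical flags reproduce identical outputs.

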