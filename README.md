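# ramanmix

Spectral unmixing of Raman hyperspectral images of plant cell walls.

Raman imaging of plant tissue yields thousands of spatially resolved
spectra in which the bands of cellulose, hemicelluloses, pectin, lignin and
cell contents overlap heavily. Spectral unmixing describes such an image
with a bilinear model **D = C Sᵀ**: every pixel spectrum is a non-negative
combination of a few *endmember* spectra **S** (approximate pure-component
signatures) weighted by abundances **C** (one concentration map per
endmember). This package is for spectroscopists and image analysts who
want to run and *compare* the three standard unmixing approaches on such
data under controlled conditions:

* **VCA** — vertex component analysis: sequential endmember extraction by
  orthogonal projections under the pure-pixel assumption, with
  closure-constrained (sum-to-one) abundances;
* **NMF** — non-negative matrix factorization with Euclidean cost and
  multiplicative updates, supporting missing-value masks and restarts;
* **MCR-ALS** — multivariate curve resolution by alternating exact
  non-negative least squares in both directions, with Euclidean-normalized
  spectra and optional rank-matched PCA (truncated SVD) noise filtering.

Around the solvers it provides the standard Raman pre-processing (spectral
cropping, cosmic-ray removal against spatial–spectral neighborhoods,
iterative order-3 polynomial baseline subtraction), model statistics
(lack of fit, explained variance, endmember correlation and matching, a
rank scree), a ground-truthed synthetic scene generator emulating spruce
cross-sections and Arabidopsis stem sections, and a CLI plus numbered
analysis scripts that chain everything into a reproducible comparison.

The model statistics follow

    LOF (%) = 100 · sqrt( Σᵢⱼ e²ᵢⱼ / Σᵢⱼ d²ᵢⱼ ),
    r² (%)  = 100 · ( 1 − Σᵢⱼ e²ᵢⱼ / Σᵢⱼ d²ᵢⱼ ),

so that r² = 100 − LOF²/100 when both are computed from the same residuals.

## Worked example

```python
import ramanmix as rm

# a 60x60 spruce-like map: lignin-rich cell corners/middle lamella, an
# orientation-enhanced S1 ring, a lignin+cellulose S2 wall, water lumina
scene = rm.make_scene("spruce", (60, 60), snr=25.0, seed=1)
D = scene.image.D

vca = rm.run_vca(D, rm.VcaOptions(rank=4, seed=1))
mcr = rm.mcr_als_fit(D, rm.McrOptions(rank=4, seed=1))

for name, res in [("VCA", vca), ("MCR-ALS", mcr)]:
    lof = rm.lack_of_fit(D, res.C, res.S)
    r2 = rm.variance_explained(D, res.C, res.S)
    perm, r, _ = rm.match_endmembers(scene.S_true, res.S)
    print(f"{name:8s} LOF {lof:6.3f}%  r2 {r2:7.4f}%  min matched r {min(r):.4f}")
```

prints

```
VCA      LOF  6.306%  r2 99.6024%  min matched r 0.9988
MCR-ALS  LOF  3.929%  r2 99.8457%  min matched r 1.0000
```

Both methods recover the four planted components almost perfectly (matched
spectral correlation ≥ 0.998), but VCA's lack of fit is higher: its
endmembers are actual pixel spectra and its abundances obey closure, while
MCR-ALS optimizes both factors freely — the systematic ordering the
comparison workflow is built to expose.

The same comparison is available from the shell:

```sh
ramanmix simulate --layout spruce --grid 60 60 --seed 1 --out scene/
ramanmix run --layout spruce --grid 60 60 --seed 1 \
    --method vca --method nmf --method mcr --method mcr_pca \
    --rank 4 --out run/
```

and as a narrative pipeline under `analysis/` (`01_simulate_scenes.py`,
`02_preprocess.py`, `03_compare_methods.py`, `04_benchmarks.py`), each of
which writes its tables under `results/`.

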