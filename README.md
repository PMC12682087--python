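# psfpercept

Tools for predicting perceived image quality through multifocal contact-lens
optics: compute geometric-optics point-spread functions (PSFs) from wavefront
data, and quantify the agreement between computed ("objective") and drawn
("subjective") PSFs with feature-consensus statistics, nonmetric
multidimensional scaling, Procrustes congruence, and an exact matching-task
null.

No raw study data are bundled; a seeded synthetic-data module emulates every
input (lens power profiles, pupils, wavefronts, surrogate drawings, Likert
responses, similarity ratings) with planted structure so every analysis stage
can be validated by recovery.

## Modules

| Module | What it does |
| --- | --- |
| `psfpercept.optics` | Pupil sampling, Zernike / power-profile wavefronts, ray-slope fields, ray-intersection PSF histograms, raster rendering |
| `psfpercept.agreement` | Likert consensus vectors (strict >50% rule), Yule's Q, Phi, Cohen's kappa, mutual information, study summaries |
| `psfpercept.mds` | Reverse-scaled dissimilarities, nonmetric SMACOF (own PAVA), Kruskal stress-1, Shepard data, dimension scans, permutation tests, rater bootstrap regions, random-start studies |
| `psfpercept.procrustes` | Similarity-transform alignment, congruence coefficient, distance-based configuration correlation |
| `psfpercept.matching` | Exact rencontres/derangement null for one-to-one image matching (rational arithmetic) |
| `psfpercept.synth` | Seeded generators for all of the above, plus a normalized-cross-correlation matcher |
| `psfpercept.design` | Questionnaire and comparison-grid builders |
| `psfpercept.io` / `psfpercept.cli` | CSV/TSV/PGM/JSON round-trip formats and the command-line pipeline |

Unit conventions: pupil coordinates mm, optical path difference µm, ray
angles radians, PSF axes arcmin. Zernike coefficients use OSA/ANSI single
indexing with normalized polynomials.

## CLI

```bash
psfpercept synthesize --seed 7 --out study/          # full synthetic fixture set
psfpercept psf --zernike-json wavefront.json --out psf_out   # wavefront -> PSF
psfpercept agreement --likert-csv study/likert.csv --out agreement.json
psfpercept mds --similarity-csv study/similarity.csv --block D2G \
    --ndim 3 --seed 1 --out-prefix out/d2g
psfpercept procrustes --ref-coords out/d2d_coords.tsv \
    --target-coords out/g2g_coords.tsv --out procrustes.json
psfpercept match-test --n 15 --correct 10
psfpercept run --seed 7 --out report/                # synthesize + all stages
```

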