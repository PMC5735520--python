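# facematch

Evaluation pipeline for face-matching over a labelled image database
("facebase"): leave-one-out top-k retrieval, a random-ranking null model,
Yates-corrected goodness-of-fit, and software-vs-clinician diagnostic
concordance (McNemar's test, Cohen's kappa). A seeded synthetic generator
stands in for the proprietary matcher and the original photographs, and
shipped fixtures of published table cells allow every printed statistic to
be recomputed exactly from its printed inputs.

## What it does

- **facebase** — CSV-manifest data model for labelled images (image id,
  individual id, syndrome cohort or `CONTROL`, entry stage) with an
  optional unit-norm embedding matrix (CSV or `.npy`).
- **synthetic** — seeded generators: a three-level Gaussian hierarchy of
  embeddings (cohort prototype → individual → image, controls from the
  zero-centred marginal), clinician score tables, and parametric grayscale
  face sketches. The default layout emulates a staged 10-cohort database
  of 3145 / 3432 / 3681 images.
- **descriptor** — baseline low-resolution frequency-domain embedding
  (resize → equalize → 2-D DCT → low-frequency block, DC dropped,
  L2-normalised) plus cosine similarity.
- **retrieval** — leave-one-out ranking of every syndrome image against
  the rest of the database; all images of the test individual are
  withheld so same-person duplicates can never match. Flags record a
  same-cohort image in the top 1 / 5 / 10.
- **null_model** — expected top-k match counts under uniformly random
  ranking: hypergeometric-tail closed form `1 − C(M−m,k)/C(M,k)` plus a
  Monte-Carlo simulation cross-check.
- **match_stats** — 1-df chi-square goodness-of-fit with Yates'
  continuity correction over observed vs expected (match, no-match) pairs.
- **concordance** — paired 2×2 tables of software vs clinician-panel
  calls (two-of-three or all-three raters scoring "definitely"),
  McNemar's test without continuity correction, Cohen's kappa.
- **reference** — fixture CSVs of published table cells and verification
  that every printed chi-square, McNemar statistic, p-value and kappa
  recomputes from its printed inputs to 2 decimal places.

## CLI

```sh
facematch generate --out db --d 64 --seed 1     # synthetic facebase + ratings
facematch evaluate --manifest db/manifest.csv --embeddings db/embeddings.npy \
    --out flags.csv                             # per-test-image top-k flags
facematch expected --manifest db/manifest.csv --out expected.csv
facematch match-table --manifest db/manifest.csv --embeddings db/embeddings.npy \
    --out table.csv                             # observed vs expected + GoF
facematch concordance --manifest db/manifest.csv --embeddings db/embeddings.npy \
    --ratings db/ratings.csv --k 5 --out conc.csv
facematch embed --manifest imgs.csv --out emb.csv   # DCT descriptor on images
facematch verify-reference                      # recompute published statistics
facematch run --config run.yaml                 # full pipeline
```

A minimal `run.yaml`:

```yaml
seed: 1
output_dir: out
generator:
  reference_layout: true   # staged 10-cohort, 3681-image layout
  d: 64
  sigma_b: 1.0
rating_model:
  p_definite: 0.5
  p_possible: 0.25
```

Each run writes `match_table.csv`, six concordance CSVs
({top-1,5,10} × {two-of-three, all-three}), and `run_log.json` with the
seed and config hash; reruns with the same config are byte-identical.

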