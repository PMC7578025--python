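# pdxscreen

Analysis pipeline for high-throughput drug viability screens on
PDX-derived tumor cells: raw 384-well plate luminescence → fraction-affected
normalization → robust cascade dose–response fits (4PL with linear
fallback) → AUC drug profiles → assay QC (Z′, minimum significance ratio)
→ bidirectional hierarchical clustering with drug activity classes →
subtype-selectivity ANOVA → ssGSEA pathway scoring → pharmaco-genomic and
pharmaco-transcriptomic association screens.

A synthetic-data generator (`pdxscreen.synthgen`) produces complete screens
with planted ground truth — true dose–response curves, subtype labels,
mutation calls, and an expression matrix with pathway modules whose
activity correlates with planted drug sensitivities — so every downstream
stage is testable without external data.

## Modules

| Module | Role |
| --- | --- |
| `pdxscreen.synthgen` | Synthetic plates, expression, gene sets, labels with planted truth |
| `pdxscreen.platecore` | Plate CSV I/O, FA normalization, Z′ / MSR / ΔΔCt QC |
| `pdxscreen.doseresp` | IRLS 4PL ∕ linear cascade fits, clipped AUC, IC50 |
| `pdxscreen.profiles` | AUC matrix, biclustering, activity classes, enrichment, concordance |
| `pdxscreen.selectivity` | Per-drug subtype ANOVA; mutation association with Sidak correction |
| `pdxscreen.pathways` | GMT I/O, ssGSEA scoring, drug–feature correlation screen |

## CLI

Each pipeline stage is a subcommand of `pdxscreen`:

```sh
pdxscreen simulate  --out-dir sim --seed 1
pdxscreen normalize --plates sim/plates.csv --out normalized.tsv
pdxscreen fit       --normalized normalized.tsv --dose-min 0.1 --dose-max 10 --out fits.tsv
pdxscreen matrix    --fits fits.tsv --out auc.tsv
pdxscreen qc        --plates sim/plates.csv --normalized normalized.tsv --out qc/
pdxscreen cluster   --auc auc.tsv --subtypes sim/subtypes.tsv --k 3 --out clusters/
pdxscreen selectivity --auc auc.tsv --subtypes sim/subtypes.tsv --exclude IM,UNS --alpha 0.05 --out selectivity.tsv
pdxscreen pgx       --auc auc.tsv --mutations sim/mutations.tsv --gene TP53 --out pgx.tsv
pdxscreen ssgsea    --expr sim/expression.tsv --gmt sim/gene_sets.gmt --alpha 0.25 --out scores.tsv
pdxscreen correlate --auc auc.tsv --drug D014 --features scores.tsv --rmin 0.70 --out corr.tsv
pdxscreen concordance --expr expr.tsv --groups groups.tsv --ntop 1000 --out conc.tsv
```

Plate CSV dialect: `plate_barcode, well (A01..P24), role {DMSO, POSCON,
DRUG, EMPTY}, drug_id, dose_uM, replicate, rlu`. The model id is encoded
in the barcode as `<model>-<plate number>`.

## Tests

```sh
python -m pytest -q tests/
```

The suite covers unit behavior, invariants (property tests via
hypothesis), and independent-oracle equivalence: 4PL fits against a dense
grid search, analytic AUC against adaptive quadrature, ssGSEA against a
brute-force cumulative-sum evaluation, and ANOVA p-values against label
permutation. `tests/test_acceptance.py` holds the acceptance criteria
(QC reproduction, oracle equivalence, planted-effect recovery, and
statistical calibration). The optional external-data checks run only when
`PDXSCREEN_EXTERNAL_DATA` points at a directory with the deposited
`auc.tsv`, `tpm.tsv` and `subtypes.tsv` frames.

## Notes on method choices

* FA = 1 − (RLU / median on-plate DMSO RLU); FA is clipped to [0, 1] only
  when integrating fitted curves, never at normalization.
* The cascade falls back from 4PL to a linear fit in log10 dose when IRLS
  fails to converge, the design-limited Jacobian rank is deficient, or
  the Hill slope pins at a bound without beating the linear RMSE.
* AUC is the exact analytic integral of the clipped fitted curve over the
  log10 dose range, normalized to [0, 1].
* Z′ uses the standard three-sigma separation formula on raw control RLU;
  MSR is `10 ** (2 * sqrt(2) * s)` with `s` the SD of replicate log10
  potencies.
* ssGSEA uses descending rank weighting with exponent `alpha = 0.25`
  (exposed as a flag) and no final range normalization; scores are
  z-normalized per pathway across samples.
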