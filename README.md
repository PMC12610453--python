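# mirpanel

Analysis toolkit for 96-well qPCR miRNA panels: delta-Ct / delta-delta-Ct
differential expression with Welch inference and Benjamini–Hochberg FDR
control, post hoc power and minimal-detectable-effect-size (MDES) analysis
under Bonferroni and BH-effective alpha policies, validated-target
convergence counting with hypergeometric over-representation, and
cross-platform log2-fold-change sign concordance. A synthetic-data module
emulates the statistical structure of a 60-sample, 84-target panel
(delta-Ct SD ≈ 1.8, groups 40/20 and 7/33, Ct LOD 35, three housekeeping
references) so the entire pipeline runs and is testable fully offline.

## Quick start

A zero-configuration, study-shaped synthetic run:

```bash
mirpanel run --seed 42 --out-dir results/
```

writes differential-expression tables for both contrasts
(`de_cancer_vs_healthy.tsv`, `de_pole_vs_wildtype.tsv` — the POLE contrast
is computed strictly within cancer samples), the MDES table and power
curves, per-direction convergence rankings and enrichment tables, a
concordance report against a synthetic external DE table, and a
`manifest.json` with a sha256 per artifact (identical config + seed gives
identical hashes).

Individual stages:

```bash
mirpanel simulate --seed 7 --out-dir synthetic/
mirpanel de --ct synthetic/ct_table.tsv --layout synthetic/layout.tsv \
            --meta synthetic/sample_meta.tsv --contrast cancer_vs_healthy \
            --out de.tsv
mirpanel power --sd 1.8 --n-a 40 --n-b 20 --m 84 --alpha 0.05 \
               --power 0.8 --power 0.9 --de de.tsv --out mdes.tsv
mirpanel targets --interactions snapshot.tsv --de de.tsv --direction up \
                 --functional-only --top-k 20
mirpanel concord --panel-de de.tsv --external-de external.tsv
mirpanel run --config run.yaml        # YAML or JSON config
```

All file I/O is plain delimited text (TSV by default, CSV accepted by
extension for inputs); writes round-trip at full float precision.

## Library layout

| module | contents |
| --- | --- |
| `mirpanel.panel_io` | `PanelLayout`, `CtTable`, `SampleMeta`; Ct/metadata/layout readers, TSV writers |
| `mirpanel.synthetic_data` | `SimConfig`, `EffectSpec`, `simulate_panel`, `default_study_config`, snapshot fixtures |
| `mirpanel.diffexpr` | `normalize_delta_ct`, `welch_test`, `bh_adjust`, `run_contrast`, `covariate_adjustment` |
| `mirpanel.power_mdes` | `representative_sd`, `estimate_pi0`, `effective_alpha`, `power_two_sample_t`, `mdes_solve`, `mdes_report` |
| `mirpanel.targets_net` | `load_interactions`, `convergence_counts`, `hypergeom_enrich` |
| `mirpanel.concordance` | `match_mirna_names`, `concordance_report` |
| `mirpanel.pipeline` | `RunConfig`, `run_pipeline` |

Conventions: log2 fold regulation = −ΔΔCt (positive = up in the first-named
group); significance = |log2 fold regulation| > 1 and FDR < 0.05; the BH
family per contrast is the set of assays actually tested (≥2 values per
group); MDES inverts the two-sided noncentral-t power function (pooled df
by default) with a BH-effective alpha 0.05·(1−π0) floored at 0.05/m.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (MDES value
reproduction, BH-effective internal consistency, oracle equivalence against
independent references, null-panel FDR control, planted-effect recovery,
power sanity). One assertion — the ≥95% unique-call rate for a single
planted effect — is known to fail by design of BH at q = 0.05 (the measured
rate is ~92%, the theoretical ceiling ~90%); everything else is green.

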