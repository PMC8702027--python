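# sedscreen

Integrated bioactivity–chemistry screening of contaminated sediments.

After disasters such as hurricanes, redistributed sediments can expose
populations to complex chemical mixtures, and targeted chemical
analysis (e.g. the 16 EPA priority PAHs) may miss much of the hazard.
`sedscreen` implements, end to end, the analysis that turns in vitro
concentration–response screens of sediment extracts plus PAH chemistry
into risk-management quantities:

1. **Points of departure (POD)** — each sample × endpoint
   dilution–response series, scaled to vehicle controls, is fit with a
   four-parameter logistic `f(x) = bottom + (top − bottom)/(1 +
   10^{h(m − log₁₀x)})`; the POD is the smallest tested dilution at
   which the fitted curve exits the vehicle band (mean ± 1 SD).
2. **ToxPi integration** — PODs are inversely scaled per endpoint to
   [0, 1] (highest POD → 0, lowest → 1), aggregated to cell-type and
   overall scores, ranked and clustered.
3. **Spatial statistics** — Mantel permutation tests (Pearson
   correlation of pairwise geographic distances vs squared feature
   differences, 10,000 permutations, Benjamini–Hochberg adjustment) and
   ordinary kriging with a spherical semivariogram on log-transformed
   values.
4. **Cross-prediction** — leave-one-out cross-validated multivariate
   ridge regression with a single shared penalty, predicting the
   bioactivity matrix from chemistry and vice versa, with per-feature
   prediction significance.
5. **Risk screening** — hazard index `HI = Σ Cᵢ/SLⁿᶜᵢ` and cancer risk
   `CR = Σ Cᵢ/SLᶜᵃᵢ` (cases per million) per sample under recreational
   sediment and residential soil scenarios, with alkylated homologs
   summed into parents.
6. **Remediation comparison** — the traditional goal (HI ≤ 1, CR ≤ 1
   per million ⇒ dilution factor max(HI, CR, 1)) versus the
   bioactivity goal (≤ 10% of endpoints active ⇒ the 10th-percentile
   POD), with residual risk/bioactivity under each.

A first-class synthetic-study generator (`sedscreen.synth`) emulates a
46-sample three-region coastal survey with 34 endpoints in 5 human cell
types and 40 analytes, planting a spatially autocorrelated latent
contamination field, chemistry-driven and non-PAH-driven bioactivity,
and exporting the analytic ground truth for recovery testing.  See
`docs/methods.md` for the models, defaults and their rationale.

The packaged screening-level table is **illustrative only**; supply
authoritative values (`load_tox_params`) for real assessments.

## Worked example

```python
import sedscreen as ss

study = ss.generate_study(ss.default_design(), seed=1)   # synthetic survey
pods  = ss.fit_pods(study["plates"])                     # 46 x 34 curve fits
tox   = ss.toxpi_from_pods(pods)                         # ToxPi scores + ranks
risks = ss.risk_table(study["chemistry"])                # HI / CR per scenario
rem   = ss.remediation_table(pods, risks)                # goal comparison

print(tox["overall"].idxmax(),
      round(float(tox["overall"].max()), 3))
print(round(float((risks.query("scenario=='residential_soil'").CR > 1).mean()), 2))
print(round(float((rem.residual_fraction_active_after_traditional > 0.1).mean()), 2),
      round(float(rem.residual_cr_after_bioactivity.max()), 2))
```

prints

```
HSC-06 0.684
0.48
1.0 0.07
```

i.e. the top-ranked (most bioactive) sample lies in the Houston Ship
Channel cluster; about half the samples exceed a 1-per-million PAH cancer
risk at baseline; after chemistry-based remediation **all** samples
still show bioactivity in more than 10% of endpoints, while after
bioactivity-based remediation the largest residual cancer risk is 0.07
per million — cleanup based on reducing bioactivity is protective
against the measured chemical risk, but not the converse.

The same pipeline runs from the shell:

```
sedscreen run-all --seed 1 --out results/
sedscreen fit-pods --plates plates.csv --out pods.csv
sedscreen mantel --sites sites.csv --features chemistry.csv
sedscreen krige --sites sites.csv --features chemistry.csv --feature total_pah
```

`run-all` writes the full set of CSV tables (sites, chemistry, plates,
pods, toxpi, mantel, kriged grids, cross-predictions, risk,
remediation, region summary) plus a checksummed `manifest.json`;
outputs are byte-identical across reruns with the same seed and
configuration.

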