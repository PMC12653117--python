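# meadowdiv

Multi-dimensional diversity assessment of grassland insect communities.

`meadowdiv` is for community ecologists (and anyone analysing incidence
matrices — the machinery applies equally to microbiome presence/absence
data) who want to compare community structure across experimental
treatments along four complementary axes:

1. **Alpha diversity** per sampling unit and trophic guild:
   Margalef richness `MR = (S − 1)/ln N`, Shannon–Wiener
   `H′ = −Σᵢ pᵢ ln pᵢ`, Pielou evenness `J = H′/ln S`, and Simpson
   diversity `D = 1 − Σᵢ pᵢ²`.
2. **Multi-order zeta diversity** — the expected number of species shared
   by *i* sites. For a species occupying *o* of *n* units the exact
   expectation is combinatorial:
   `ζᵢ = Σₛ C(oₛ, i) / C(n, i)`.
   ζ₁ is mean per-site richness, ζ₂ the mean number of species shared by
   site pairs, and so on. The decline curve and the consecutive ratios
   `ζᵢ₊₁/ζᵢ` separate turnover driven by rare species (fast decline,
   ratios falling toward 0) from communities knit together by widespread
   species (ratios near 1). A permutation test compares decline curves
   between strata.
3. **Dark diversity** via Beals smoothing: the probability of species *j*
   at unit *k* is
   `P_kj = (1/S′ₖ) Σ_{i present at k, i≠j} M_ij / n_i`,
   with co-occurrence counts `M_ij` and occurrence frequencies `n_i`
   estimated from a reference pool. A species absent at a unit whose
   probability exceeds a per-species threshold (a low quantile of its
   values at occupied units) belongs to the unit's dark diversity.
   Summaries: per species `PDD = ND/NP` (dark occurrences over
   species-pool occurrences) and per unit the Community Completeness
   Index `CCI = SR/(SR + PR)` (observed richness over observed-plus-dark
   richness).
4. **Assumption-gated treatment comparison**: Shapiro–Wilk and
   Brown–Forsythe Levene checks route each response to one-way ANOVA +
   Tukey HSD or Kruskal–Wallis + Dunn (Holm-adjusted), summarised as a
   compact letter display.

A synthetic-community generator reproduces the sampling design
(4 treatments × 3 plots × 4 transects, 88 species in 4 guilds) with
controllable occupancy structure and *planted* dark diversity — a known
fraction of suitable occurrences is deleted after generation — so every
stage of the pipeline can be validated against ground truth.

## Worked example

```python
import meadowdiv as md

cm, guilds, truth = md.simulate_community(md.SyntheticDesign(seed=7))
print(md.composition_summary(cm).to_string(index=False))
```

```
treatment  total  share_pct
       FE   4674      39.29
       GC   1018       8.56
       FR   5159      43.37
       CK   1045       8.78
```

The grazing-exclusion (FE) and reseeding (FR) treatments are simulated
as widespread-dominated and carry most individuals; the planted-grass
(GC) and grazed-control (CK) treatments are rare-dominated. Zeta decline
makes that structure visible:

```python
fe = cm.select_units([u for u in cm.unit_ids if cm.metadata.loc[u, "treatment"] == "FE"])
dec = md.zeta_decline(md.to_incidence(fe), max_order=5, sd=False)
print(dec.zeta.round(2), md.zeta_ratios(dec).round(3))
```

```
FE zeta: [54.33 34.59 22.61 15.12 10.3 ] ratios: [0.637 0.654 0.669 0.681]
CK zeta: [11.75  2.47  0.6   0.16  0.04] ratios: [0.21  0.245 0.271 0.27 ]
```

FE retains two-thirds of its shared species with every added site; in CK
shared species collapse almost immediately — the signature of
rare-species turnover. The dark-diversity machinery recovers the planted
withheld occurrences far above the chance rate on never-suitable
absences:

```python
res = md.dark_diversity(cm, level="transect", q=0.01)
print(md.evaluate_dark_recovery(truth, res))
```

```
{'n_withheld': 131, 'sensitivity': 0.664, 'precision': 0.227,
 'flag_rate_eligible_absences': 0.582, 'flag_rate_ineligible_absences': 0.139}
```

66% of the deleted occurrences are flagged as dark, versus a 14% flag
rate on absences of species outside the treatment's species pool.

The full pipeline (composition → alpha → zeta → dark → comparison, with
a JSON run manifest) runs from one config:

```bash
meadowdiv simulate --seed 7 --outdir sim
meadowdiv run-all --config config.yaml --seed 7
```

Subcommands `alpha`, `zeta`, `dark` and `compare` expose the individual
stages on any CSV community matrix + metadata + guild table.

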