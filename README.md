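# diaflav

Glycosylated-flavonoid profiling from LC-MS runs acquired with
data-independent acquisition (DIA, a.k.a. MS<sup>E</sup>/AIF): alternating
low-energy scans that see intact precursors (MS¹) and high-energy all-ion
scans that see their fragments (MS²), with no precursor isolation.

The central idea is to run the *same* feature-detection chain — mass
detection, EIC building, local-minimum peak resolving, ¹³C de-isotoping,
cross-sample alignment, gap filling — independently on both channels, and
then re-link fragment features to precursor features by co-elution and
chromatographic peak shape. Each linked pair yields a neutral loss

&nbsp;&nbsp;&nbsp;&nbsp;ΔM = *m/z*(MS¹) − *m/z*(MS²)

that is looked up in a glycosyl-loss dictionary (hexose 162.0528 Da,
pentose 132.0423, deoxyhexose 146.0579, acylated and composite losses,
…). Two cleavage families are modelled on the deprotonated basis:

* **O-glycosides** release the intact sugar, giving the even-electron
  aglycone [Agly − H]⁻ (heterolytic) or the radical anion [Agly − 2H]˙⁻
  one hydrogen atom (1.007825 Da) lower (homolytic — the departing glycosyl
  then carries the extra hydrogen, so the expected loss is sugar + 1.0078).
* **C-glycosides** never release the bare aglycone; cross-ring cleavage
  leaves a +42.0106 Da (C₂H₂O, "etenol") or +72.0211 Da (C₃H₄O₂) residue
  per sugar on the fragment (losses of 120/90/60 Da per hexosyl/pentosyl
  unit).

The final call names the aglycone, the bond type and the sugar —
e.g. `Quercetin O-hexoside` — deliberately *not* the attachment position,
which fragmentation m/z alone cannot support.

Who this is for: natural-product / metabolomics researchers who have
negative-mode DIA runs (mzML) and curated compound lists, and want
reproducible flavonoid backbone profiles, flavone:flavonol ratios and
database-overlap summaries without vendor software.

## Worked example

Everything is testable offline through the synthetic-cohort generator,
which spikes known glycosides as co-eluting Gaussian precursor/fragment
pairs (with isotope satellites, m/z jitter and a noise floor) into
alternating-scan DIA runs:

```python
from diaflav import chemcore, cli, synthgen

runs, truth = synthgen.make_cohort(n_spikes=20, n_samples=3, seed=7)
result = cli.run_pipeline(
    runs,
    synthgen.cohort_compound_db(truth),   # MS1 database (neutral masses)
    chemcore.build_fragment_db(),         # MS2 in-silico aglycone fragments
)
print(result["annotation_table"].head(4).to_string(index=False))
report = synthgen.truth_compare(truth, result["glycosides"])
print("recall", report["recall"], "precision", report["precision"])
```

prints (abridged columns):

```
 rt_min   ms1_mz   ms2_mz aglycone_fragment  neutral_loss bond                     call
   1.50 415.1034 268.0377  Apigenin [M-H].-       147.066    O Apigenin O-deoxyhexoside
   2.93 431.0984 268.0377  Apigenin [M-H].-       163.061    O      Apigenin O-hexoside
   2.93 431.0984 269.0455   Apigenin [M-H]-       162.053    O      Apigenin O-hexoside
   1.50 415.1034 269.0456   Apigenin [M-H]-       146.058    O Apigenin O-deoxyhexoside
recall 1.0 precision 1.0
```

Reading row 2: an MS² feature at *m/z* 268.0377 matched the homolytic
radical apigenin fragment, co-eluted at 2.93 min with an MS¹ feature at
431.0984, and the 163.061 Da loss equals hexose + one hydrogen atom — an
apigenin O-hexoside. Row 3 is the heterolytic confirmation of the same
compound (loss 162.053, the intact hexose). All 20 spiked glycosides were
recovered with the correct aglycone, bond type and sugar.

The same chain is available from the shell:

```bash
diaflav simulate --out-dir sim --n-spikes 20 --n-samples 3 --seed 7
diaflav build-db --out fragments.csv
diaflav run sim/S1.mzML sim/S2.mzML sim/S3.mzML \
    --compounds sim/compounds.csv --fragments fragments.csv --out-dir results
```

which writes the feature tables, the annotation CSV, BPI chromatograms,
the sample-correlation heatmap and the backbone stacked-bar figure.

## Layout

| module | role |
| --- | --- |
| `diaflav.chemcore` | formulas, monoisotopic masses, adducts, ppm errors, O-/C-glycoside fragment rules, sugar-loss dictionary |
| `diaflav.dbio` | mzML reader/writer, compound & fragment database CSVs, feature tables |
| `diaflav.featdet` | EICs, peak resolving, de-isotoping, join alignment, gap filling (identical at MS¹/MS²) |
| `diaflav.annotate` | database search, precursor–fragment linking, sugar assignment, Jaccard isomer scoring |
| `diaflav.profile_report` | flavone:flavonol ratio, correlation heatmap, Venn counts, backbone stacks |
| `diaflav.synthgen` | synthetic DIA cohorts with ground truth |
| `diaflav.cli` | `diaflav` command-line tool and `run_pipeline` |

See `docs/methods.md` for the model, parameter defaults and limitations.
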