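# focalstage

Quantification and **focal staging of amyloid-PET scans**: regional SUVR
aggregation, direct-comparison Centiloid (dcCL) scaling, data-driven regional
positivity cutoffs, and the group-comparison statistics used to characterize
participants whose scans show *focally* increased amyloid uptake at
*subthreshold global* amyloid levels.

## Who this is for

Neuroimaging groups working with ^18^F-florbetaben (FBB) and
^18^F-flutemetamol (FMM) amyloid PET across the cognitive continuum
(cognitively unimpaired, amnestic MCI, dementia). A global SUVR cutoff labels
a scan "amyloid-negative" even when one or two regions are clearly involved;
this package implements the quantitative staging scheme that separates those
cases out and the statistics that test whether they differ clinically.

## The method

1. **Regional SUVR** — lateralized AAL volumes of interest are pooled
   (volume-weighted) into ten composite regions: frontal, lateral temporal,
   parietal, cingulate and striatum, left and right. Uptake is referenced to
   the whole cerebellum. A global cortical SUVR is computed over all
   non-striatal VOIs.

2. **Centiloid conversion** — per-ligand anchor means place SUVR on the
   common dcCL scale:

   `CL = 100 · (SUVR_ind − SUVR_YC-0) / (SUVR_ADCI-100 − SUVR_YC-0)`

   where `SUVR_YC-0` is the mean of amyloid-negative young controls (0 CL)
   and `SUVR_ADCI-100` the mean of a typical amyloid-positive cognitively
   impaired anchor group (100 CL). Global positivity is `CL ≥ 25.11` by
   default (a ROC/Youden-derived cutoff; 20 and 40 CL are supported
   sensitivity settings).

3. **Regional cutoffs** — per ligand and per region, an iterative outlier
   method run on a cognitively unimpaired reference sample: repeatedly drop
   values outside the Tukey inner fences `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`
   until none are removed, then set `cutoff = 1.025 × max(retained)`
   (the retained maximum plus 2.5% of itself).

4. **Staging** — each scan gets ten regional flags (`SUVR > cutoff`) and a
   group: `G−F−` (global- and focal-negative), `G−F+` (global-negative with
   ≥ 1 involved region), `G+` (global-positive); the subtype distinguishes
   focal (1–9 regions) from whole-brain (all 10) involvement.

5. **Statistics** — chi-square, ANOVA / age-adjusted ANCOVA with Tukey
   post hoc comparisons, Mann–Whitney, Jonckheere–Terpstra trend tests,
   participant-bootstrap comparison of lobar involvement frequencies, and an
   AIC comparison of the G/F grouping against dcCL bands
   (negative / subthreshold / positive).

A `synthetic` module generates two-ligand cohorts with planted group
structure (burden gradients by diagnosis, lobar spreading order
parietal > frontal ≈ temporal > cingulate > striatum, group effects on
cognition and morphometry) so the whole pipeline is testable end to end;
see `docs/methods.md` for the generative model and its limits.

## Worked example

```python
from focalstage import GeneratorConfig, generate_cohort, stage_generated_cohort
from focalstage import compare_groups, involvement_frequency_bootstrap

sim = generate_cohort(GeneratorConfig(n_participants=900, seed=42))
staged = stage_generated_cohort(sim)   # cutoffs + calibration + staging
print("group counts:", staged.summary)

fmm = staged.cutoffs_by_ligand["FMM"]
print("FMM parietal_left cutoff: %.3f SUVR (from %d CU scans, %d outlier passes)"
      % (fmm.cutoff("parietal_left"), fmm.reference_n,
         len(fmm.per_region["parietal_left"].iterations)))

table = staged.table()
res = compare_groups(table, "svlt", "ancova_age")
print("SVLT ANCOVA (age-adjusted): F = %.1f, p = %.2e" % (res.statistic, res.p_value))

focal = [r for r in staged.results if r.subtype == "focal"]
boot = involvement_frequency_bootstrap(focal, n_resamples=1000, seed=42)
print("lobar involvement among focal scans:",
      {k: round(v, 2) for k, v in boot.frequencies.items()})
```

Output:

```
group counts: {'G-F-': 306, 'G-F+': 81, 'G+': 513}
FMM parietal_left cutoff: 1.239 SUVR (from 202 CU scans, 4 outlier passes)
SVLT ANCOVA (age-adjusted): F = 210.2, p = 1.41e-75
lobar involvement among focal scans: {'frontal': 0.66, 'lateral_temporal': 0.66, 'parietal': 0.69, 'cingulate': 0.6, 'striatum': 0.28}
```

Reading the numbers: roughly a third of the cohort is fully
amyloid-negative, a small minority (here 9%) shows focal involvement below
the 25.11 CL global cutoff, and the rest are global-positive. The FMM
parietal cutoff of 1.239 SUVR came out of four Tukey-fence passes over a
202-scan unimpaired reference. Verbal memory (SVLT delayed recall) differs
strongly across the three groups after adjusting for age, and among
focally-involved scans the parietal lobe is involved most often and the
striatum least — the planted cortical-first spreading order.

The same steps are available from the shell:

```bash
focalstage simulate --n 900 --seed 42 --out-dir data/
focalstage derive-cutoffs --ligand FMM --input data/cu_profiles.csv --out cutoffs_FMM.json
focalstage classify --profiles data/profiles.csv --anchors data/anchors.csv \
    --cutoffs cutoffs_FBB.json --cutoffs cutoffs_FMM.json --out staging.csv
focalstage analyze --staging staging.csv --cohort data/cohort.csv --out report.json
```

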