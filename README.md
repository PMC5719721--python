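# plaquekit

Serial intravascular-ultrasound virtual-histology (IVUS-VH) plaque analysis:
per-frame morphometry and tissue composition, six-category plaque phenotype
classification, the Liverpool Active Plaque Score (LAPS), landmark-based
co-registration of baseline and follow-up pullbacks into 5-mm vessel
segments, phenotype-transition / thin-cap-fibroatheroma (TCFA) fate
analysis, and two-group (diabetic vs non-diabetic) statistics — together
with a calibrated synthetic cohort generator so the whole pipeline is
testable end to end without clinical data.

## Who this is for

Researchers analysing serial IVUS-VH pullback tables: one row per
cross-sectional frame carrying the lumen and external-elastic-membrane
(EEM) cross-sectional areas (CSA, mm²), the four VH tissue-component areas
— fibrous (F), fibro-fatty (FF), necrotic core (NC), dense calcium (DC) —
and the arc (degrees) over which necrotic core abuts the lumen.  Image
segmentation and VH tissue classification are upstream of this package;
frame tables, landmark pairs and group labels are its inputs.

## The quantities it computes

Per frame set (segment or pullback), percent atheroma volume

    PAV = 100 × Σ(EEM_area − Lumen_area) / Σ EEM_area .

Per frame, a phenotype from the threshold cascade (all thresholds
configurable): plaque burden < 40% → **NL** (no lesion); NC ≥ 10% of
characterized tissue with an NC–lumen contact arc ≥ 30° → **TCFA**
candidate; NC ≥ 10% without contact → **ThCFA**; DC ≥ 10% → **FcP**;
FF ≥ 15% → **PIT**; otherwise **FP**.  A TCFA label requires three
consecutive candidate frames; each 5-mm segment is labeled by the most
advanced phenotype among its frames (NL < PIT < FP < FcP < ThCFA < TCFA),
and a confirmed candidate run straddling a segment boundary marks every
segment it touches as TCFA.

Per frame, the Liverpool Active Plaque Score

    LAPS = −2.149 + 0.68 × NC/DC + 3.39 × MLA
           + 5.1 × [remodeling index > 1.05] + 3.7 × [VH-TCFA] ,

where the MLA term uses the frame's lumen CSA, NC/DC is capped for
calcium-free frames, and the remodeling index comes from the enclosing
segment.  Segment LAPS is the maximum frame LAPS; pullback LAPS is the
mean over segments.

Between timepoints, each segment pair yields change scores (Δ plaque CSA,
Δ PAV, Δ LAPS, Δ composition), a phenotype transition, and a TCFA fate:
*persistent* (TCFA→TCFA), *healed* (TCFA→other), *new* (other→TCFA).
Group contrasts use Welch's t / Mann–Whitney / Fisher's exact tests plus a
patient-random-intercept mixed model that corrects for the clustering of
segments within patients.

## Worked example

```python
import plaquekit as pk

cohort = pk.generate_cohort(seed=7)        # 17 DM + 44 non-DM patients
result = pk.run_study(cohort, seed=7)

pat = result.patients
for g in ("DM", "non_DM"):
    sub = pat[pat.group == g]
    seg = result.segments[result.segments.group == g]
    fates = result.fates[g]
    share = pk.group_phenotype_share(seg, pk.Phenotype.TCFA, "baseline")
    print(f"{g}: {len(sub)} patients, {len(seg)} segments")
    print(f"  delta plaque area  {seg.delta_plaque_csa_mm2.mean():+.2f} mm^2")
    print(f"  delta PAV          {seg.delta_pav_pct.mean():+.2f} %")
    print(f"  delta pullback LAPS {sub.delta_pullback_laps.mean():+.2f}")
    print(f"  TCFA segments at baseline: {share.count}/{share.total} ({share.percent}%)")
    print(f"  new TCFA rate {100*fates.new_rate:.1f}%  persistent {100*fates.persistent_rate:.1f}%")
```

prints

```
DM: 17 patients, 221 segments
  delta plaque area  +0.35 mm^2
  delta PAV          +1.12 %
  delta pullback LAPS +0.28
  TCFA segments at baseline: 106/221 (48.0%)
  new TCFA rate 21.7%  persistent 83.0%
non_DM: 44 patients, 629 segments
  delta plaque area  -0.48 mm^2
  delta PAV          -1.40 %
  delta pullback LAPS -0.94
  TCFA segments at baseline: 271/629 (43.1%)
  new TCFA rate 13.1%  persistent 72.7%
```

The synthetic diabetic group progresses (plaque area, PAV and LAPS all
increase over the year) while the non-diabetic group regresses, and new
TCFAs arise more often in the diabetic group — the effect structure the
generator is calibrated to.  `result.group_stats` holds the full
variable-by-variable comparison table (means ± SD per group, test used,
p-value, and the mixed-model p for segment-level changes).

The same workflow is available from a shell:

```sh
plaquekit synth --seed 7 --out cohort/          # write frame tables + manifest
plaquekit validate cohort/cohort.yaml
plaquekit analyze cohort/cohort.yaml --out results/
plaquekit report results/
```

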