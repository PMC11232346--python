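# autoplan

Automated rotational-IMRT treatment planning for cervical-cancer
external-beam radiotherapy, exercised end-to-end on synthetic pelvic
phantoms.

Manual inverse planning for cervical cancer is slow and planner-dependent:
the target (PTV) is large (≈ 1350 cc) and overlaps heavily with bladder,
rectum and bowel.  This package implements a script-style automated
workflow for that problem — the kind a physicist would drive from a TPS
scripting console — as a self-contained, desk-scale pipeline:

1. **Auxiliary structures**: rings at 0–5/5–10/10–20/20–30 mm around the
   PTV, and an iterative 0.5 mm PTV-contraction loop that caps each OAR's
   overlap with the effective target (bladder and rectum ≤ 45 % of organ
   volume, bowel bag ≤ 110 cc), yielding `oar-ptv` subtraction structures
   and the effective target `PTV_new`.
2. **Optimization**: a built-in 25-row objective template (Max/Min Dose,
   Max/Min DVH, Max gEUD penalties; the bowel-helper row's volume parameter
   is `floor(100·195/V_bag)` % per patient) drives projected-gradient
   fluence optimization — two rounds of 100 iterations — against a
   simplified beamlet dose engine (36 coplanar angles, exponential
   attenuation, Gaussian lateral kernel, 3 mm dose grid).
3. **Normalization**: the dose is rescaled so the 50.4 Gy prescription
   covers exactly 95 % of the PTV.
4. **Evaluation**: DVH statistics (D_x%, V_xGy, D_0.03cc, D_mean), the
   homogeneity index HI = (D₂% − D₉₈%)/D₅₀%, conformity index
   CI = TV²/(V_PTV·V_TVP), gradient indices GI_x = V_x/V_TVP, and an
   11-row hard/soft protocol constraint table.
5. **Statistics**: paired plan comparison via the exact two-sided Wilcoxon
   signed-rank test, and linear regression of OAR mean dose (gEUD, a = 1)
   on PTV overlap.

Phantoms are generated to match published cohort statistics (PTV volume
1347.45 ± 179.28 cc; bladder/rectum in-PTV overlap 37 ± 11 % / 52 ± 13 %;
bowel-bag overlap 115.79 ± 52.09 cc), so every stage is testable without
patient data.  See `docs/methods.md` for the models and their assumptions.

## Worked example

```python
from autoplan import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=7))
rep = result.report
print("contraction steps:", rep["preprocessing"]["contraction_steps"])
print("achieved overlaps:", {k: round(v, 1)
      for k, v in rep["preprocessing"]["achieved_overlaps"].items()})
print("HI %.3f  CI %.3f" % (rep["metrics"]["HI"], rep["metrics"]["CI"]))
for c in rep["metrics"]["constraints"]:
    print(f"{c['label']:28s} {c['value']:8.2f}  "
          f"{'PASS' if c['passed'] else 'FAIL'} ({c['type']})")
```

prints (seed 7, default settings; ≈ 3 minutes on one CPU):

```
contraction steps: {'bladder': 10, 'rectum': 10, 'bowel bag': 0}
achieved overlaps: {'bladder_overlap_pct': 43.0, 'rectum_overlap_pct': 44.8, 'bowelbag_overlap_cc': 70.2}
HI 0.149  CI 0.940
PTV D_max <= 115%              108.60  PASS (hard)
PTV D_max <= 110%              108.60  PASS (soft)
PTV V_presc >= 95%              95.00  PASS (soft)
bladder V_50Gy < 50%            42.14  PASS (hard)
bladder V_40Gy < 60%            54.10  PASS (soft)
rectum V_50Gy < 50%             38.53  PASS (hard)
rectum V_40Gy < 60%             57.08  PASS (soft)
bowel bag V_45Gy < 195 cc       97.10  PASS (hard)
femoral head V_50Gy < 5%         0.00  PASS (hard)
kidney D_mean < 15 Gy            5.20  PASS (hard)
kidney D_mean < 10 Gy            5.20  PASS (soft)
```

This phantom drew bladder and rectum overlaps above the 45 % cap, so both
loops ran 10 × 0.5 mm contraction steps (landing at 43.0 % and 44.8 %); the
bowel-bag overlap was already under 110 cc.  After optimization and
normalization every protocol row passes.  A cohort run
(`autoplan run --cohort 30 ...` or `pipeline.run_cohort`) produces the
per-case metrics table that `compare_plans` and the Wilcoxon machinery
consume.

The same workflow is available from the shell:

```bash
autoplan generate-phantom --seed 0 --out case/          # masks + manifest (NIfTI + JSON)
autoplan preprocess --case case/manifest.json --out aux/
autoplan run --seed 0 --out plan0/                      # end-to-end, writes report.json
autoplan evaluate --plan-dir plan0/ --out metrics/
```

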