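# astigvec

Power-vector analysis of corneal astigmatism for cataract-surgery method
comparison: Jackson-coefficient algebra, vertex-distance transport of
manifest refractions, surgically induced astigmatism (SIA) modeling,
ocular residual astigmatism (ORA), cohort-level statistics, and a
synthetic cohort generator.

## The problem

Automated keratometry (AK, e.g. from an optical biometer) measures only
the anterior corneal surface; ray-traced total corneal refractive power
(TCRP, from Scheimpflug tomography, averaged over a 3- or 4-mm
pupil-centred zone) accounts for both surfaces. In corneas with high
irregularity the two disagree, and picking the wrong one leads to
residual astigmatism after toric-IOL or incisional correction. This
package implements the analysis used to quantify that disagreement and
to ask which keratometry better predicts postoperative refractive
astigmatism.

## The core math

An astigmatism of cylinder C (positive-cylinder convention) with flat
meridian A is decomposed into Jackson coefficients:

    J0  = (C/2) cos 2A
    J45 = (C/2) sin 2A

Doubling the angle turns the 180°-periodic meridian into an ordinary
vector direction, so the discrepancy between two measurements is the
Euclidean distance

    Δ = sqrt(ΔJ0² + ΔJ45²)

A manifest refraction at vertex distance d (12 mm by default) is moved
to the corneal plane meridian by meridian with Fc = F / (1 − d·F). The
ORA for a keratometry K and postoperative refraction RA is
|pv(K) − (pv(RA_c) + pv(SIA))|, evaluated under assumed SIA magnitudes
of 0, 0.20 and 0.40 D (variants RA, RA1, RA2) for a temporal clear
corneal incision flattening the horizontal meridian: a 0.40 D SIA is
exactly (J0, J45) = (0.20, 0).

Eyes are classified with-the-rule (steep meridian within 45–135°) vs
against-the-rule, and split into low/high corneal-irregularity groups at
the cohort median IR and at mean + 2 SD. Log-linear OLS relates ln(IR)
to age and irregular astigmatism, and ln(Δ) to age, IR and AK magnitude.

## Worked example

```python
from astigvec import (SimulationParams, generate_cohort, analyze_cohort)

cohort = generate_cohort(SimulationParams(n=2000, seed=1))
report = analyze_cohort(cohort)
print(report.per_eye["delta_tcrp3_ak"].mean())   # 0.4174684747032103
t5 = report.tables["table5_paired_ora"]
print(t5[t5["variant"] == "RA2"][["comparison", "mean_ak", "mean_tcrp", "p_value"]])
```

prints (high-irregularity subgroup, mean + 2 SD grouping, n = 88):

```
    comparison  mean_ak  mean_tcrp   p_value
2  AK_vs_TCRP3  0.69531   0.298443  0.000007
5  AK_vs_TCRP4  0.69531   0.317244  0.000002
```

The mean TCRP3–AK discrepancy is ≈0.42 D, and in highly irregular
corneas the ORA computed from ray-traced keratometry (≈0.30 D) is far
below the ORA computed from automated keratometry (≈0.70 D): TCRP is
the better predictor of postoperative astigmatism there, which is how
the synthetic cohort is constructed.

The same pipeline runs from the shell:

```
astigvec simulate --config configs/default_simulation.yaml --out cohort.csv --seed 1
astigvec analyze --in cohort.csv --out report/ --sia 0,0.20,0.40 --vertex-mm 12
astigvec ora --in cohort.csv --out ora.csv
```

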