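# rbedose

Variable-RBE weighted dose, heart-substructure dosimetry and
acute-coronary-event (ACE) risk estimation for breast intensity-modulated
proton therapy (IMPT).

## The problem

Clinical proton therapy assumes a constant relative biological effectiveness
(RBE) of 1.1, but the RBE rises where protons slow down: the dose-averaged
linear energy transfer (LETd) climbs steeply at the end of range, a few
millimetres beyond the target. For left-sided breast or chest-wall treatment
with en-face beams, the heart sits immediately distal to the clinical target
volume (CTV), exactly where this end-of-range LET elevation lands — so a
constant RBE of 1.1 systematically underestimates the biological dose to the
heart, and with it the radiation-induced cardiac risk.

`rbedose` quantifies that underestimate. Given voxel grids of physical dose
*D* (Gy) and LETd (keV/μm) plus structure masks (heart, ventricles, left
anterior descending artery (LAD), CTV), it computes RBE-weighted dose under
four schemes:

* **constant 1.1** — the clinical comparator, RBE ≡ 1.1;
* **McMahon linear fit** — RBE = 1 + 0.055·LETd;
* **McNamara** — linear-quadratic (LQ) model with
  RBE<sub>max</sub> = 0.99064 + 0.35605·LETd/(α/β) and
  RBE<sub>min</sub> = 1.1012 − 0.0038703·√(α/β)·LETd;
* **Wedenberg** — LQ model with RBE<sub>max</sub> = 1 + 0.434·LETd/(α/β) and
  RBE<sub>min</sub> = 1.

For the LQ models the dose-dependent RBE per fraction dose *d* is

RBE(d, LETd) = [ √( (α/β)² + 4·d·(α/β)·RBE<sub>max</sub> + 4·d²·RBE<sub>min</sub>² ) − α/β ] / (2d)

with α/β = 3 Gy for late-responding heart tissue by default. Cardiac risk
follows the Darby linear no-threshold model: the ACE rate rises 7.4% per Gy
of mean heart dose (MHD) over a 4.5% baseline (women treated at 50, attained
age 80, no preexisting risk factors):

total risk = 4.5% · (1 + 0.074 · MHD),  excess risk = 4.5% · 0.074 · MHD.

The package also provides DVH metrics (mean dose, Vx, Dxcc), LETd histograms
with dose cutoffs, line profiles, a 3-D gamma index (2%/2 mm) for dose-grid
benchmarking, Wilcoxon signed-rank cohort comparisons, and a seedable
synthetic distal-edge phantom cohort so the whole pipeline runs without any
patient data.

## Worked example

```python
from rbedose import (PhantomSpec, generate_case, model_spec, rbe_field,
                     mean_dose, ace_risk)

spec = PhantomSpec()              # 60^3 grid at 2 mm, heart 8 mm past the target
case = generate_case(spec, seed=1)
heart = case.mask("heart")

for name in ("constant_1p1", "mcmahon_linear", "mcnamara", "wedenberg"):
    weighted = rbe_field(case, model_spec(name)).weighted_dose
    mhd = mean_dose(weighted, heart)
    risk = ace_risk(mhd)
    print(f"{name:15s} MHD = {mhd:5.2f} GyRBE   excess ACE risk = {risk.excess_risk_pct:.2f}%")
```

prints

```
constant_1p1    MHD =  0.37 GyRBE   excess ACE risk = 0.12%
mcmahon_linear  MHD =  0.48 GyRBE   excess ACE risk = 0.16%
mcnamara        MHD =  0.61 GyRBE   excess ACE risk = 0.20%
wedenberg       MHD =  0.67 GyRBE   excess ACE risk = 0.22%
```

The phantom's heart intercepts the distal falloff where LETd has risen to
~8 keV/μm, so every variable-RBE model predicts a higher biological heart
dose than the constant 1.1 — here up to ~80% higher MHD under the Wedenberg
model, and a proportionally larger excess ACE risk.

The same analysis is available from the shell:

```bash
rbedose run --n 20 --seed 7 --out results/
```

writes `metrics.csv` (per patient × structure × model), `risk.csv`,
`table1.csv` (cohort medians and ranges), `stats.csv` (signed-rank tests of
each variable-RBE MHD against the constant-1.1 MHD), `gamma.csv` and
`manifest.csv`. Individual stages are exposed as
`rbedose synth|weight|metrics|gamma|risk|report`.

Case bundles on disk are plain MetaImage volumes (`dose.mhd`, `letd.mhd`,
`mask_<name>.mhd`) plus a `plan.txt` key=value file — see
`docs/methods.md` for conventions and model details.

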