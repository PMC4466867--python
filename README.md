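# dcefit

Quantitative analysis of dynamic contrast-enhanced MRI (DCE-MRI) for
preclinical and clinical studies: parametric relaxometry maps, conversion of
dynamic signal to contrast-agent concentration, arterial input function
(AIF) handling, voxelwise tracer-kinetic model fitting with data-driven
nested model selection, goodness-of-fit statistics, and a Monte-Carlo
harness for validating the whole chain on synthetic data.

## Who it is for

Researchers fitting pharmacokinetic models to dynamic T1-weighted MRI —
tumour permeability imaging, blood-brain-barrier studies — who need an
open, scriptable pipeline from raw image series (NIfTI, Analyze, DICOM) to
parameter maps and comparison tables, with every statistical choice
inspectable.

## The models

All tissue models map the arterial plasma concentration C_a(t) to the
tissue concentration C(t):

| model | parameters | form |
|---|---|---|
| steady-state | v | C = v·C_a |
| Patlak | K<sup>trans</sup>, v_p | C = v_p·C_a + K<sup>trans</sup>∫C_a |
| Tofts | K<sup>trans</sup>, v_e | C = K<sup>trans</sup>·C_a ∗ e^(−k_ep t), k_ep = K<sup>trans</sup>/v_e |
| extended Tofts | K<sup>trans</sup>, v_e, v_p | Tofts + v_p·C_a |
| 2CXM | K<sup>trans</sup>, v_e, v_p, F_p | two-compartment exchange, bi-exponential impulse response |
| tissue uptake | K<sup>trans</sup>, v_p, F_p | 2CXM without backflux |
| FXR (shutter speed) | K<sup>trans</sup>, v_e, τ_i | Tofts kinetics seen through finite transcytolemmal water exchange (signal domain) |

Nested model selection fits Model 0 (no enhancement), then promotes through
steady-state → Patlak → extended Tofts, accepting each additional parameter
only when a sequential F-test gives p < 0.05.  Fit quality can be compared
across (also non-nested) models with AIC/AICc, FMI/FRI information
fractions, and 95 % prediction bounds; parameter-recovery agreement is
summarised with Lin's concordance correlation coefficient (CCC).

Relaxometry supports variable-flip-angle T1 (linearised and nonlinear SPGR
fits), mono-exponential T2/T2*, and ADC mapping.  The Parker population AIF
is built in; raw AIFs can be extracted from an arterial ROI, fitted with a
bi-exponential, or averaged across subjects.

## Worked example

Fit the nested hierarchy to one noisy synthetic curve:

```python
import numpy as np
from dcefit.aif import parker_aif
from dcefit.kinetic_models import evaluate_model
from dcefit.fitting_selection import nested_model_fit

t = np.arange(0, 10 + 1e-9, 0.5 / 60)          # 10 min at 0.5 s, in minutes
aif = parker_aif(t, onset_min=1.0)             # population AIF, bolus at 60 s
truth = evaluate_model("ex_tofts", dict(ktrans=0.35, ve=0.1, vp=0.1), aif).conc
rng = np.random.default_rng(0)
data = truth + rng.normal(0, 0.02, truth.shape)

sel = nested_model_fit(t, data, aif)
print(sel.selected_model, sel.selected_index)
print({k: round(v, 4) for k, v in sel.fit.params.items()})
print([f"{p:.3g}" for p in sel.p_values])
```

prints

```
ex_tofts 3
{'ktrans': 0.3365, 've': 0.0973, 'vp': 0.1014}
['0', '6.53e-54', '0']
```

The walk promoted three times (each p ≪ 0.05), landing on the extended
Tofts model that generated the data, and recovered K<sup>trans</sup> = 0.35 min⁻¹,
v_e = 0.10 and v_p = 0.10 to within the noise.

The same machinery is available from the shell:

```bash
dcefit --output-dir out relaxfit vfa.nii.gz --kind t1_vfa --method nlls \
       --control-values 12,24,36,48,60 --tr 200
dcefit --output-dir out prep dyn.nii.gz --t1map out/t1_vfa_map.nii.gz \
       --r1 3.3 --baseline 0:30 --frame-interval 2 --fa 35 --tr 25
dcefit --output-dir out aif --mode roi --conc out/concentration.npz --roi artery.nii.gz
dcefit --output-dir out nested out/concentration.npz --aif out/aif_roi.csv
dcefit --output-dir out compare out/concentration.npz --aif out/aif_roi.csv --roi tissue.nii.gz
```

Each stage writes NIfTI maps (or CSV tables) plus a plain-text run report
naming its inputs, configuration digest and seed.

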