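# dynapet

Desk-scale simulation and quantification laboratory for **low-dose
dynamic PET**: how far can the injected dose be reduced before kinetic
parameters degrade, and how much does learned frame-by-frame denoising
buy back?

The package is aimed at PET physicists and methods researchers who want
a fully controlled, seconds-to-minutes sandbox for questions that
normally require list-mode patient data: it simulates 4D tracer images
from compartment-model kinetics on a multi-organ phantom, emulates dose
reduction by binomial thinning of Poisson counts, denoises frames with a
bank of count-level-matched residual attention U-Nets trained on a
static late-uptake image, and quantifies the impact on time-activity
curves (TACs), compartmental parameters, and parametric images.

## The models at its core

Tissue kinetics follow the standard compartment models. For an
irreversible tracer (FDG-like), the two-tissue model with k₄ = 0 gives
the net influx rate

    Ki = K1·k3 / (k2 + k3)        [ml·min⁻¹·cm⁻³]

and for a reversible tracer (glutamine-tracer-like), the one-tissue
model gives the total volume of distribution

    VT = K1 / k2                  [ml·cm⁻³].

The measured curve is (1−vB)·CT + vB·Cb with fractional blood volume vB
and blood delay, both fitted. Graphical analyses provide the same macro
parameters voxelwise: the Patlak plot (CT/Cp vs ∫Cp/Cp, slope = Ki,
t\* = 25 min) and the Logan plot (∫CT/CT vs ∫Cp/CT, slope = VT,
t\* = 2 min). Dose reduction is modelled as binomial thinning of
acquired counts; variability via Poisson bootstrap replicates; the
denoiser bank routes each frame to the network whose training count
level is log-nearest to the frame's own total counts.

See `docs/methods.md` for assumptions, parameter defaults, and
limitations.

## Worked example

Simulate a 60-min dynamic scan of the built-in phantom at 1/10 dose,
then fit the thalamus with the irreversible two-tissue model:

```python
import numpy as np
from dynapet.frames import TAC, roi_extract
from dynapet.kinetics import FitOptions, fit_compartment
from dynapet.phantom import simulate_noisy_dynamic

noisy, clean, masks, cp = simulate_noisy_dynamic(
    "small", "fdg_60min", seed=42, dose_factor=0.1)
tac = roi_extract(noisy, masks["thalamus"])
fit = fit_compartment(tac, cp, "2tcm_irr",
                      FitOptions(delay_grid_s=np.arange(-6, 7, 2.0)),
                      schedule=noisy.schedule)
truth = 0.10 * 0.062 / (0.13 + 0.062)   # phantom ground truth
print(f"fitted Ki = {fit.macro:.4f}  (truth {truth:.4f}, "
      f"bias {100 * (fit.macro / truth - 1):+.1f}%)")
```

which prints

```
fitted Ki = 0.0324  (truth 0.0323, bias +0.2%)
```

— at 1/10 dose the thalamus ROI fit recovers the ground-truth influx
rate to within a fraction of a percent; shrinking the dose or the region makes
the bias and its replicate-to-replicate spread grow, which is exactly
the regime the denoiser bank targets.

The same pipeline is scriptable from the shell:

```bash
dynapet schedule fdg_60min                 # 39 frames, 3600 s
dynapet simulate --phantom small --dose 0.1 --seed 42 --out run/
dynapet roi-tac --in run/dynamic.nii.gz --mask run/mask_thalamus.nii.gz \
        --out thalamus.csv
dynapet fit --tac thalamus.csv --if run/input_function.csv \
        --model 2tcm-irr --out fit.json
dynapet patlak --in run/dynamic.nii.gz --if run/input_function.csv \
        --tstar 25 --out patlak/
```

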