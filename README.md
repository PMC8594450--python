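# iqtask — task-based image-quality assessment of super-resolution

`iqtask` is a fully simulated test bed for a question that traditional
image-quality metrics cannot answer: does deep-learning super-resolution
(SR) preserve the *task-relevant* information in a medical image? It
implements, end to end:

* **Phantoms** — clustered lumpy backgrounds (CLB) emulating mammographic
  texture, Rayleigh two-point/line discrimination signals, and synthetic
  microcalcification (MC) cluster maps inserted multiplicatively,
  `f1 = fb(1 + c·sMC)`;
* **Imaging** — Gaussian-blur / downsample degradation with mixed
  scaled-Poisson + Gaussian noise, producing paired HR/LR ensembles;
* **Super-resolution** — a small trainable CNN (9×9 first layer, 5×5
  hidden layers) mapping LR images to SR estimates, on a deterministic
  numpy training engine;
* **Numerical observers** — Hotelling (`w = K⁻¹Δf̄`), regularized
  Hotelling via a truncated pseudoinverse (`σ_P ≥ λσ_1`), the 60-channel
  Gabor channelized Hotelling observer, and learned residual-CNN observers
  approximating the ideal observer;
* **Evaluation** — ensemble MSE / PSNR / SSIM, Mann–Whitney AUC with
  DeLong confidence intervals, and experiment drivers sweeping signal
  length, SR network depth, and observer capacity / training-set size.

The core scientific point the package lets you demonstrate on your own
machine: SR reliably improves MSE/PSNR/SSIM, yet — consistent with the
data-processing inequality — it cannot raise the performance of a strong
observer, and only helps observers that are starved of capacity or data.

Intended users: researchers in objective image-quality assessment and
image-restoration evaluation who want a controlled, reproducible
simulation study rather than a clinical dataset.

## Worked example

Simulate the Rayleigh discrimination task at the default calibrated
configuration, then compare a Gabor channelized Hotelling observer on HR
and LR images:

```python
from iqtask import stream_rng
from iqtask.config import load_config
from iqtask.imaging import build_task_ensembles
from iqtask.metrics import iq_metrics, delong_ci
from iqtask.observers import (GaborChannelSpec, apply_linear,
                              build_gabor_matrix, cho_template)

cfg = load_config()                       # Rayleigh-task defaults
hr, lr = build_task_ensembles(
    "rayleigh", 400, stream_rng(cfg.master_seed, "clb"),
    clb=cfg.clb_params(), noise=cfg.noise_spec(),
    signal_spec=cfg.signal_spec(), signal_lengths=[5, 6, 7, 8, 9],
)
print(f"LR vs HR ensemble MSE: {iq_metrics(hr, lr, peak=1.0).ensemble_mse:.4f}")

fit_hr, test_hr = hr.split(400)
fit_lr, test_lr = lr.split(400)
channels = build_gabor_matrix(GaborChannelSpec(grid_size=64))
for name, fit, test in (("HR", fit_hr, test_hr), ("LR", fit_lr, test_lr)):
    f0, f1 = fit.images[fit.labels == 0], fit.images[fit.labels == 1]
    roc = delong_ci(apply_linear(cho_template(channels, (f0, f1), crop=64), test))
    print(f"Gabor CHO on {name}: AUC {roc.auc:.3f}  "
          f"95% CI [{roc.ci_low:.3f}, {roc.ci_high:.3f}]")
```

Output (about a minute on one CPU):

```
LR vs HR ensemble MSE: 0.4374
Gabor CHO on HR: AUC 0.891  95% CI [0.859, 0.924]
Gabor CHO on LR: AUC 0.799  95% CI [0.756, 0.843]
```

The ensemble MSE sits at the calibrated fidelity level of the LR
simulation, and the blur costs the linear observer about nine points of
AUC — the task-information loss that SR post-processing cannot restore.

A command-line interface mirrors the library
(`iqtask simulate|fixtures|observer|train|evaluate|sweep`); see
`iqtask --help`. Model and experiment details are in
[docs/methods.md](docs/methods.md).

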