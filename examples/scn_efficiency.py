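"""Structural covariance networks: group contrast in global efficiency.

Builds per-group SCNs from age-residualized regional thickness (every
image is one observation), thresholds the correlation matrix at tau = 0.5,
and reports global efficiency with an SD band from rebuilding the network
on random 80% subsamples of the images.
"""

from cemorph import group_contrast, simulate_study
from cemorph.synthetic import default_study_config

config, models = default_study_config()
dl_models = [m for m in models if m.method == "DL"]
truth, measured = simulate_study(config, dl_models)

contrast = group_contrast(measured, tau_star=0.5, reps=100, seed=0, methods=["DL"])
print(contrast.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    "\nGlobal efficiency (0 = edgeless, 1 = complete) of the thresholded "
    "covariance graph; band_sd is one SD over 100 subsample rebuilds.  The "
    "PPMS group shows stronger structural covariance, hence higher "
    "efficiency at the same threshold."
)
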