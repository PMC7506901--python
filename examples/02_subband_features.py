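"""Extract the three sub-band feature families from CSP-projected signals.

Shows how each extractor sees the same projected trials: CSP-Wavelet takes
(energy, std) of db4 DWT sub-bands intersecting 8-30 Hz, CSP-WPD does the
same on the uniform packet tiling, and CSP-FB takes log-variance in ten
overlapping 4 Hz Butterworth bands.  Feature counts follow P = 4mB,
4mB' and 2mB'' respectively.
"""

from cspdecode import (
    BandPassSpec,
    SyntheticConfig,
    bandpass_epochs,
    compute_class_covariances,
    extract_csp_fb,
    extract_csp_wavelet,
    extract_csp_wpd,
    generate_epochs,
    make_filter_bank,
    plan_wavelet,
    project,
    solve_csp,
)

epochs, _ = generate_epochs(SyntheticConfig(n_trials_per_class=20, seed=4))
filt = bandpass_epochs(epochs, BandPassSpec(8.0, 30.0, order=6))
bank = solve_csp(compute_class_covariances(filt), m=3)
proj = project(filt, bank)
print(f"projected trials: {proj.data.shape} (trials x 2m x samples)")

dwt_plan = plan_wavelet(epochs.fs, "dwt")
print(f"\nDWT plan at {epochs.fs:g} Hz: {dwt_plan.levels} levels, retained "
      f"sub-bands {dwt_plan.selected_intervals()} Hz")
feats = extract_csp_wavelet(proj, dwt_plan)
print(f"CSP-Wavelet features: {feats.values.shape}, first columns "
      f"{feats.feature_names[:4]}")

wpd_plan = plan_wavelet(epochs.fs, "wpd")
print(f"\nWPD plan: retained packet bands {wpd_plan.selected_intervals()} Hz")
feats = extract_csp_wpd(proj, wpd_plan)
print(f"CSP-WPD features: {feats.values.shape}")

fb = make_filter_bank(8, 30, 4, 2)
print(f"\nfilter bank: {fb.n_bands} bands, {fb.bands[0]} ... {fb.bands[-1]} Hz")
feats = extract_csp_fb(proj, fb)
print(f"CSP-FB features: {feats.values.shape}, first columns "
      f"{feats.feature_names[:3]}")
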