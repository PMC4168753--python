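"""Transient duration is proportional to probe contact time.

Generates a low-load cohort spanning contact times 0.1-2.0 s, measures
contact time from the force curves and FWHM duration from the corrected
traces, and fits the line relating them.  The generator is calibrated
to duration = 0.98 x contact_time + 0.60 s.
"""

import numpy as np

from mechanoca.studies import duration_vs_contact_study

rng = np.random.default_rng(20140711)
fit, points = duration_vs_contact_study(rng, n_per_level=17)

print(f"n = {len(points)} stimulations")
print(f"duration = {fit.slope:.3f} x contact_time + {fit.intercept:.3f} s")
print(f"standard errors: slope {fit.slope_se:.3f}, intercept {fit.intercept_se:.3f}")
print(f"R^2 = {fit.r_squared:.3f}")
print()
print("The slope near 1 means each extra second the probe stays on the cell")
print("adds about one second to the calcium transient; the intercept is the")
print("minimal response duration for the briefest touch.")
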