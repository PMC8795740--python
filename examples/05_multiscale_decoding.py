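"""Maximum-likelihood position decoding from nested grid scales.

Poisson spike counts from modules with periods 10, 6.7, 4.4, 3.0 m are
fused coarse-to-fine; each finer scale multiplies precision.
"""

import numpy as np

from hippocan import GridModule, decode_multiscale, sample_poisson_rates

rng = np.random.default_rng(0)
periods = [10.0 / 1.5**m for m in range(4)]
modules = [GridModule.regular(p, 30) for p in periods]
x_true = np.array([1.8, -2.4])

counts = [sample_poisson_rates(m, x_true, 1.0, seed=rng) for m in modules]
for n_scales in (1, 2, 3, 4):
    est = decode_multiscale(counts[:n_scales], modules[:n_scales])
    err = np.linalg.norm(est.estimate - x_true)
    print(f"{n_scales} scale(s): estimate {np.round(est.estimate, 3)}, "
          f"error {err * 100:.1f} cm")
# The error drops roughly geometrically with each added scale: the coarse
# module fixes the branch, the fine modules sharpen the estimate.
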