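"""Pointwise group comparison and scan-rescan variability.

A patient group with a 10-mm CSA deficit is compared to controls with
Welch t-tests at every millimetre (Bonferroni over tested points), and
repeat-scan pairs estimate the per-point measurement variability.
"""

import numpy as np

from hippoprof import Profile, group_pointwise_test, scan_rescan_variability

rng = np.random.default_rng(9)
grid = np.arange(0.0, 47.0)
mu = 55.0 + 25.0 * np.exp(-0.5 * ((grid - 33.0) / 6.0) ** 2) \
    - 40.0 * np.exp(-0.5 * (grid / 6.0) ** 2)
band = (grid >= 20) & (grid < 30)


def cohort(n, deficit=0.0):
    return [Profile(grid, np.clip(mu - deficit * band
                                  + rng.normal(0, 5.0, len(grid)), 0.01, None),
                    modality="csa") for _ in range(n)]


res = group_pointwise_test(cohort(30), cohort(30, deficit=12.0), alpha=0.01)
sig = res.grid[res.significant]
print(f"{res.n_tests} points tested at p < 0.01/{res.n_tests}; "
      f"significant at {sig.min():.0f}-{sig.max():.0f} mm "
      f"(implanted deficit spans 20-29 mm)")
print(f"fraction of profile significantly smaller: "
      f"{100 * res.fraction_significant:.1f}%")

pairs = []
for _ in range(20):
    truth = mu + rng.normal(0, 5.0)
    pairs.append((Profile(grid, truth + rng.normal(0, 2.0, len(grid)),
                          modality="csa"),
                  Profile(grid, truth + rng.normal(0, 2.0, len(grid)),
                          modality="csa")))
rescan = scan_rescan_variability(pairs)
print(f"scan-rescan sd ~ {rescan.sigma.mean():.2f} mm^2 per point "
      f"(expected 2.0 x sqrt(2) = {2 * np.sqrt(2):.2f} for iid noise sd 2); "
      f"a fraction of the between-subject sigma of 5")
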