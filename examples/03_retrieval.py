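"""End-to-end inversion: simulate a water body, retrieve (a, b, xi).

Generates Monte Carlo triple-FOV molecular signals for the L2 water and
inverts them with the iterative retrieval, printing the recovered profiles
and their RMSRD against the known truth.
"""

import numpy as np

from oceanhsrl import (
    LidarConfig,
    ScenarioSpec,
    iterate_retrieval,
    make_profile,
    rmsrd,
    simulate_mc,
)

cfg = LidarConfig()
truth = make_profile(ScenarioSpec.preset("L2", depth_max=20.0))
print(f"truth: a={truth.a[0]}, b={truth.b[0]}, xi={truth.xi[0]} (L2, homogeneous)")

signals = simulate_mc(truth, cfg, n_photons=2_000_000, seed=42)
result = iterate_retrieval(signals, cfg)
print(result.summary())

m = len(result.iop)
print(f"usable depth: {result.iop.depths[-1]:.1f} m ({m} bins, narrow-FOV "
      "dynamic range cut)")
for p in ("a", "b", "xi"):
    got = getattr(result.iop, p)
    want = getattr(truth, p)[:m]
    print(f"  {p:2s}: retrieved median {np.median(got):.4f} vs truth {want[0]:.4f}"
          f"   RMSRD {rmsrd(got, want):.2f}%")
print("The absorption coefficient is pinned by the wide-FOV channel; the")
print("(b, xi) pair rests on the FOV-differential multiple scattering and")
print("carries larger uncertainties, especially in turbid water.")
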