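"""Standard vs functional-liver-sparing plan for one synthetic patient.

The sparing plan adds a "parallel organ" objective on the FLV and raises
its weight along a geometric ladder until PTV coverage would fall below
the optimal tolerance (D95% >= 95% of prescription).  A well-behaved
result drops the FLV mean dose substantially while coverage and OAR doses
stay essentially unchanged.
"""

import liverspare as ls

config = ls.RunConfig(
    n_patients=1,
    base_seed=3,
    phantom=ls.PhantomConfig(grid_shape=(96, 96, 20), gtv_radius_mm=10.0),
    n_beams=9,
    max_iter=80,
    sparing_max_steps=5,
)
run = ls.run_patient(config, 0)

print(f"prescription: {run.standard.rx_gy:.0f} Gy "
      f"(sparing weight reached {run.sparing.meta.get('sparing_weight')})")
print(f"{'metric':>22s} {'standard':>9s} {'sparing':>9s}")
for key in ("ptv_d95_gy", "ptv_d99_gy", "flv_mean_gy", "liver_gtv_mean_gy",
            "liver_v10gy_lt_percent"):
    print(f"{key:>22s} {run.metrics_standard[key]:9.2f} {run.metrics_sparing[key]:9.2f}")
# flv_mean_gy is the headline number: the sparing arm should be lower while
# ptv_d95_gy stays above 0.95 x prescription in both arms.
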