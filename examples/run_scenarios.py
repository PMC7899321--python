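"""Compare annual productivity under four reservoir management scenarios.

Runs 20 replicate 50-year simulations (35 females/year) per scenario with
synthetic hydrographs and prints grand means of the four annual summary
metrics.  Expect roughly: early fill ~1.06 independent young/female,
late fill ~1.40, zero flooding ~1.49 — the gap is driven almost entirely
by post-fledging survival on inundated territories.
"""

import numpy as np

from renestsim import load_params, run_replicates

params, site = load_params()
root = np.random.SeedSequence(1)

print(f"{'scenario':<14} {'nest_succ':>9} {'breed_succ':>10} {'fledglings':>10} {'independent':>11}")
for kind, seq in zip(("long_term", "early_fill", "late_fill", "zero_flooding"), root.spawn(4)):
    runs = run_replicates(kind, params, site, n_replicates=20, seed_seq=seq)
    gm = {m: np.mean([r.metric(m).mean() for r in runs])
          for m in ("nest_success", "breeding_success", "fledging_success", "productivity")}
    print(f"{kind:<14} {gm['nest_success']:>9.3f} {gm['breeding_success']:>10.3f} "
          f"{gm['fledging_success']:>10.2f} {gm['productivity']:>11.2f}")

print("\nindependent = young surviving the 21-day post-fledging dependence period, per female")
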