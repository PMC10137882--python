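"""Compare SAR and mSAR on the synthetic ten-function benchmark suite.

Builds the suite with seeded synthetic shift/rotation data (the official
competition data files are not bundled, so absolute values are specific
to this synthetic instance) and runs both optimizers a few times on two
representative functions.
"""

import numpy as np

from msar import Bounds, SarConfig, make_suite, run_msar, run_sar, run_std

DIM, RUNS, SEED = 10, 5, 1
suite = {fn.id: fn for fn in make_suite(dim=DIM, seed=SEED)}
bounds = Bounds.cube(-100.0, 100.0, DIM)

print(f"dim={DIM}, {RUNS} runs each, minimizing (short runs for illustration)")
print("function  algo   mean best      std          target f*")
for fid in ("F1", "F4"):
    fn = suite[fid]
    for name, runner in (("sar", run_sar), ("msar", run_msar)):
        bests = []
        for r in range(RUNS):
            cfg = SarConfig(pop_size=30, max_iters=150, sense="minimize",
                            seed=SEED + 1000 * r)
            bests.append(runner(fn, bounds, cfg).best_fitness)
        print(f"  {fid:4s}   {name:4s}  {np.mean(bests):12.4e} {run_std(bests):12.4e}"
              f"   {fn.f_star}")

# f* is the value at the planted optimum; the gap between the mean best
# and f* measures how close each optimizer gets within the budget, and
# the STD across runs measures its stability.
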