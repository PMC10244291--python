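"""Frequency locking: the Devil's staircase of average duration.

With a 40-kyr forcing of amplitude alpha = 0.003, the asymptotic cycle
duration D locks onto integer multiples of the forcing period while the
internal period T0 sweeps up smoothly with gamma. (~1 min)
"""

import calcalk as ck

p = ck.TABLE_DEFAULTS
fast = ck.SolverSettings(rel_tol=1e-9, abs_tol=1e-12)
grid = [0.06, 0.085, 0.105]

res = ck.staircase(p, grid, alpha=0.003, horizon=3e7, settings=fast)
df = res.to_dataframe().round({"T0": 1, "D": 1, "lock_residual": 1})
print(df.to_string(index=False))
print("-> D sits on 1x, 2x, 3x the 40-kyr forcing period (lock_n) even as"
      " T0 varies smoothly: frequency locking")
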