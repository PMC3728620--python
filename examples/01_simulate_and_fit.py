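"""Simulate a single vGlut-pHluorin response and fit its decay.

A 25 AP, 10 Hz train is delivered to one cell with the shipped 37C
defaults; the post-stimulus fluorescence decay is fitted with the
standard offset single-exponential protocol.
"""

from phendo import (
    calibrate_defaults,
    cell_from_config,
    fit_config_for,
    fit_exp_offset,
    simulate_trace,
    single_burst,
)

cfg = calibrate_defaults()["37C"]
cell = cell_from_config(cfg)
protocol = single_burst(25, 10.0)

trace = simulate_trace(cell, protocol, seed=7)
fit = fit_exp_offset(trace, burst_index=0, cfg=fit_config_for("37C"))

print(f"peak dF            : {trace.dF.max():.1f} vesicle units")
print(f"fitted tau         : {fit.tau:.2f} s (SE {fit.tau_se:.2f})")
print(f"fit window         : {fit.window[0]:.1f} - {fit.window[1]:.1f} s")
print(f"adjusted R^2       : {fit.adj_r2:.4f}")
print(f"converged          : {fit.converged}")
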