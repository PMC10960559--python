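"""Confidence interval and z-test for coskewness on one 'scan'.

Simulates a single scan-length recording (T = 1200 samples) with strong
third-order connectivity, then quantifies the estimate's uncertainty with
the block bootstrap (L = 10 consecutive samples per block, preserving the
signals' autocorrelation).  For contrast it also shows the independent
(column-wise) bootstrap, whose standard error is too small on
autocorrelated data and would inflate false-positive rates.
"""

from hoconn import BootstrapConfig, bootstrap, generative as g, measure_statistic

params = g.ARParams(n=3, psi=1.0, innovation=g.SkewNormalSpec(3.0), tau=2.0, r=0.4)
ts = g.simulate(params, T=1200, seed=7)
stat = measure_statistic("coskewness", ("R1", "R2", "R3"))

print(f"true coskewness: {g.true_coskewness(params):+.4f}")
for scheme in ("block", "independent"):
    cfg = BootstrapConfig(scheme=scheme, block_length=10, n_boot=1000, seed=11)
    res = bootstrap(ts, stat, cfg)
    print(
        f"{scheme:>12} bootstrap: estimate {res.estimate:+.4f}  se {res.se:.4f}  "
        f"95% CI [{res.ci[0]:+.4f}, {res.ci[1]:+.4f}]  p = {res.p_value:.2e}"
    )
print()
print("The independent scheme's smaller SE is an artifact of ignoring")
print("autocorrelation; the block bootstrap is the calibrated choice.")
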