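"""Simulate coupled regional signals and recover their connectivity.

Builds a 3-region autoregressive model whose shared skew-normal innovation
creates genuine third-order structure, simulates a long recording, and
compares every plug-in estimate against the model's closed-form ground
truth.  The second- and third-order estimates agree with the closed forms
to about two decimals at this length.  The fourth-order run uses nu = 5
Student-t innovations, where the estimators converge slowly and sit
somewhat below the truth even at T = 2,000,000 — the same heavy-tail
behaviour that makes single-scan fourth-order inference hard.
"""

import hoconn
from hoconn import generative as g

params = g.ARParams(n=3, psi=1.0, innovation=g.SkewNormalSpec(3.0), tau=2.0, r=0.4)
ts = g.simulate(params, T=200_000, seed=1)
gt = g.ground_truth(params)

corr = hoconn.correlation2(ts, "R1", "R2")
cosk = hoconn.coskewness(ts, "R1", "R2", "R3")

print(f"pairwise correlation  estimate {corr.value:+.4f}   truth {gt.pair_correlation:+.4f}")
print(f"coskewness            estimate {cosk.value:+.4f}   truth {gt.coskewness:+.4f}")

# fourth-order structure needs heavy tails: same model with t innovations
params4 = g.ARParams(n=4, psi=1.0, innovation=g.StudentTSpec(5), tau=2.0, r=0.4)
ts4 = g.simulate(params4, T=2_000_000, seed=2)
gt4 = g.ground_truth(params4)

kurt = hoconn.cokurtosis(ts4, "R1", "R2", "R3", "R4")
edge = hoconn.edge_connectivity_corrected(ts4, ("R1", "R2"), ("R3", "R4"))

print(f"cokurtosis            estimate {kurt.value:+.4f}   truth {gt4.cokurtosis:+.4f}")
print(f"corrected edge conn.  estimate {edge.value:+.4f}   truth {gt4.edge_corrected:+.4f}")
print()
print("The coskewness/cokurtosis are the normalized third/fourth cumulants:")
print("nonzero values mean the regions share structure beyond their covariances.")
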