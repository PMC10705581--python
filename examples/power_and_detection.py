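"""Conditional power and detection probability as the signal grows.

Simulates three true groups of 50 whose means differ by ±delta on the last
half of the features, clusters each replicate into K=3, and reports (i) the
detection probability — how often the randomly chosen tested pair of
estimated clusters coincides exactly with two true groups — and (ii) the
conditional power — how often the selective test rejects given detection.
The tested feature is uniform over all features, so roughly half the tests
target a feature with no signal and the power plateau is about 1/2.
"""

from postclust import SimulationConfig, power_experiment

print(f"{'method':8s} {'delta':>5s} {'detection':>9s} {'cond.power':>10s}")
for method in ("average", "kmeans"):
    for delta in (3.0, 6.0):
        cfg = SimulationConfig(n=150, q=10, rho=0.4, delta=delta,
                               design="power3", M=80, alpha=0.05, seed=11, K=3)
        res = power_experiment(cfg, method)
        print(f"{method:8s} {delta:5.1f} {res.detection_probability:9.3f} "
              f"{res.conditional_power:10.3f}")
print(
    "\nDetection and conditional power both rise with delta; average-linkage\n"
    "clustering recovers these spherical groups more reliably than a single\n"
    "seeded k-means run, which sometimes lands in a split/merged optimum."
)
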