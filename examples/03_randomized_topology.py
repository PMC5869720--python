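"""How much does the topology matter?  True vs randomized networks.

Runs the replicated benchmark twice per replicate: once with the true
topology (degree-normalized weights) and once with a degree-preserving
randomization (link-target swaps + sign flips).  The collapse of accuracy
under randomization shows the predictive signal lives in the wiring, not
in the degree sequence.
"""

import sigflow as sf

df = sf.run_benchmark(
    sf.GeneratorSpec(seed=0),
    n_replicates=10,
    arms=("true", "random"),
    seed=7,
)
summary = df.groupby("arm")["mean_accuracy"].agg(["mean", "median", "std"])
print("mean accuracy per replicate, summarized over 10 replicates:")
print(summary.round(3).to_string())
gap = summary.loc["true", "mean"] - summary.loc["random", "mean"]
print(
    f"\ntrue topology leads by {100 * gap:.1f} percentage points;"
    "\nthe randomized arm sits near chance (~0.5-0.6), so degree structure"
    "\nalone carries little of the predictive power"
)
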