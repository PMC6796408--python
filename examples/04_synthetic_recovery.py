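"""Generate synthetic per-subject data and check parameter recovery.

Records are simulated structurally from the fitted solution (latents,
disturbances and measurement errors drawn from their estimated Gaussians),
optionally coarsened to reproduce the binary sexual-assault and 3-level
smoking margins, then summarized to moments and refitted.
"""

import cardiosem as cs

study = cs.fit_study(compute_se=False)
cm = study.result.compiled

coarsen = cs.CoarsenSpec(
    binary={"ASA": 88 / 227},
    ordinal={"SMOKE": (75 / 227, 68 / 227, 84 / 227)},
)
ds = cs.generate(cm, study.result.theta, n=227, seed=11, coarsen=coarsen)
print(f"simulated {ds.n} records; coarsening: {ds.coarsening}")
print(f"ASA prevalence: {ds.records['ASA'].mean():.3f} (target 0.388)")
print()

rep = cs.recovery_experiment(
    study.model, study.result.theta, n_list=[500, 5000],
    replicates=3, seed=11, moments=study.moments,
    standardize=cs.ABUSE_INDICATORS,
)
rep["rel_bias"] = rep.bias.abs() / rep.scale
rep["rel_rmse"] = rep.rmse / rep.scale
summary = rep.groupby("n")[["rel_bias", "rel_rmse"]].mean()
print("mean |bias| and RMSE relative to each parameter's natural scale:")
print(summary.round(4).to_string())
print()
print("RMSE shrinking roughly like 1/sqrt(n) confirms the engine recovers")
print("the generating parameters from its own data.")
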