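"""The continuous-variable workflow.

Instead of vegetation categories, the environment is a smooth gradient
(e.g. temperature). The variable is discretized into equal-width intervals;
each trait bin predicts the midpoint of its modal interval (the
maximum-likelihood estimate under the discretized distribution). The same
reconstruction machinery then returns continuous estimates at fossil sites.
"""
from scipy import stats

from ecometrica import (
    fit_continuous,
    model_diagnostics,
    reconstruct_env,
    summarize_traits_by_point,
)
from ecometrica.plots import plot_continuous_space
from ecometrica.synthetic import WorldConfig, generate_fossils, generate_world

config = WorldConfig(env_kind="continuous", n_points=800, n_fossils=20, seed=7)
ranges, traits, points = generate_world(config)
summaries = summarize_traits_by_point(points, traits, ranges)
fossils = generate_fossils(config, ranges, traits, points, summaries=summaries)

model = fit_continuous(summaries, "env", bins1=15, bins2=15)
diag = model_diagnostics(model)
print(f"training Pearson r (observed vs predicted): {diag['pearson_r']:.3f}")
print(f"anomaly mean {diag['anomaly_mean']:.3f}, SD {diag['anomaly_sd']:.3f}")

recon = reconstruct_env(fossils, model)
r = stats.pearsonr(fossils["true_env"], recon["prediction"]).statistic
print(f"fossil reconstruction: r = {r:.3f} between true and estimated values")

plot_continuous_space(model, recon, path="continuous_space.png")
print("wrote continuous_space.png")
# Predictions are bounded by the training environmental range: the model
# cannot extrapolate beyond conditions represented in the modern data.
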