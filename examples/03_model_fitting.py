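"""Ask which random-graph model best fits a network's wiring patterns.

Generates a uniform-random (ER) network, then measures its GCD-11
distance (Euclidean distance between graphlet correlation matrices) to
replicas drawn from the ER and geometric (GEO) models, with a
Mann–Whitney U test comparing real-to-model against model-to-model
distances.
"""

from icell.null_models import ModelParams, fit_models, generate_model

real = generate_model(ModelParams(model="ER", n=300, density=0.03, seed=42))
real.layer_label = "data"

result = fit_models(real, models=["ER", "GEO"], reps=10, seed=0)
print("model  mean GCD-11   sd      MWU p     rejected")
for name, fit in result.fits.items():
    print(
        f"{name:6s} {fit.mean_distance:10.3f} {fit.sd_distance:7.3f} "
        f"{fit.mwu_p:9.3g} {'yes' if fit.rejected else 'no':>8s}"
    )
print("-> the ER model sits much closer to the data (small mean GCD-11);")
print("   the geometric model's wiring patterns are far away.")
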