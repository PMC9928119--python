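"""Select phenotype-predictive regions with the cross-validated lasso.

Fits the L1-penalized logistic model (penalty chosen by stratified 5-fold
CV with the one-standard-error rule), reports the sparse candidate list,
then reruns with the top candidate omitted — the fallback when a candidate
fails wet-lab validation — which surfaces its correlated proxy.
"""

from mavenpy import accuracy, fit_lasso_cv, refit_excluding, synthetic

matrix, phenotypes, truth = synthetic.simulate_matrix(synthetic.default_config(seed=0))
print(f"planted causal effect: {truth.causal_effects}")

model = fit_lasso_cv(matrix, phenotypes, seed=0)
print(f"\nCV-selected penalty lambda = {model.lam:.4f}")
print(f"selected regions: {model.selected_regions}")
print(f"top region (largest |coefficient|): {model.top_region}")
print(f"training accuracy: {accuracy(model, matrix, phenotypes):.2f}")

dropped = refit_excluding(matrix, phenotypes, [model.top_region], seed=0)
print(f"\nafter omitting {model.top_region}: top region becomes "
      f"{dropped.top_region}")
print("The r~0.8 proxy inherits the association once the causal region's")
print("column is gone — exactly why a single lasso hit should be read as")
print("'this region or something tightly correlated with it'.")
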