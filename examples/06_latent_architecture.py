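"""Latent architecture: PCA, parallel analysis, weighted total importance.

Decomposes the 52 scored items of a linked cohort, retains components by
parallel analysis, fits both prediction models (illusion magnitude and
metacognitive efficiency) and projects their feature importances onto the
components.  The signature pattern: one component loaded in both models,
the other two each dominant in exactly one.
"""

import numpy as np

import ponzometa as pm

spec = pm.CohortSpec.linked(seed=1234)
trials, sheets, _ = pm.simulate_study(spec)
est = pm.subject_estimates(trials)
wide = est.pivot(index="subject_id", columns="condition")
targets = {
    "illusion magnitude (d' diff)":
        (wide[("d_prime", "depth")] - wide[("d_prime", "control")]).to_numpy(),
    "metacognitive efficiency (log M-ratio)":
        wide[("log_m_ratio", "control")].to_numpy(),
}

scored = [pm.score_ratings(s) for s in sheets]
X = np.stack([s.values for s in scored])
words = scored[0].words
Xs, _, _, _ = pm.standardize(X, item_names=words)

res = pm.pca_svd(Xs, words)
k = pm.parallel_analysis(X, n_random=1000, quantile=0.95, seed=0)
print(f"components retained by parallel analysis: {k}")
print(f"variance proportions: "
      f"{np.round(res.explained_variance_ratio[:k], 3).tolist()}")

for label, y in targets.items():
    ok = np.isfinite(y)
    ys = (y[ok] - y[ok].mean()) / y[ok].std()
    fit = pm.relaxed_fit(Xs[ok], ys, item_names=words)
    W = pm.weighted_total_importance(fit.importance, res.loadings[:, :k], words)
    print(f"\n{label}")
    print(f"  selected items          : {len(fit.selected)}")
    print(f"  weighted importance/PC  : {np.round(W, 3).tolist()}")
print()
print("Larger |weighted importance| = the model draws more on that latent")
print("rating dimension; compare the two rows to see shared vs specific use.")
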