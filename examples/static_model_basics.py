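"""Build a static coupling-tuning-latent model, check its exact Gaussian
moments against simulation, and evaluate the data likelihood.

The model: a target unit coupled to N non-target units, all tuned to an
M-dimensional stimulus, with one shared latent factor standing in for
unobserved activity.
"""

import numpy as np

import cotula as ct

rng = np.random.default_rng(0)
N, M, K = 4, 3, 1

params = ct.StaticParams(
    a=np.array([0.4, 0.0, 0.3, 0.0]),        # sparse coupling
    b=np.array([0.8, 0.0, 0.5]),             # sparse tuning
    B_not=rng.normal(0.5, 0.1, (M, N)),      # non-target tuning
    l=np.array([0.4]), L_not=np.full((1, N), 0.4),
    psi=0.8, Psi_not=np.full(N, 0.8),
)

x = np.array([1.0, 0.0, -1.0])
mean, cov = ct.joint_moments(params, x)
print("conditional mean of (y_i, y_not, z) for one stimulus:")
print(np.round(mean, 3))

prec = ct.precision_matrix(params)
err = np.max(np.abs(cov @ prec - np.eye(1 + N + K)))
print(f"covariance times closed-form precision deviates from I by {err:.2e}")

data = ct.generate_static(params, 50_000, seed=1)
emp_var = np.var(data.y)
print(f"simulated target variance {emp_var:.3f} vs analytic {cov[0, 0] + (params.b + params.B_not @ params.a) @ (params.b + params.B_not @ params.a):.3f}")
print("  (analytic = conditional variance + stimulus-driven variance for a standard-normal stimulus)")

ll = ct.marginal_loglik(params, data.subset(np.arange(1000)))
print(f"marginal log-likelihood of 1000 trials (latent integrated out): {ll:.1f}")
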