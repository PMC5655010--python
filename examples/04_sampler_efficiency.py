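"""Tailored proposals vs random-walk Metropolis on a DTI voxel.

Runs the tailored Metropolis-within-Gibbs sampler and two random-walk
baselines on the same synthetic voxel and compares inefficiency factors
IF = 1 + 2 sum_k rho_k (lower is better; IF = 1 is an independent sampler).
"""

import numpy as np

from ricianreg import (
    MCMCConfig,
    NoiseModel,
    fit_voxel,
    inefficiency_factor,
    make_multishell_scheme,
    run_rwm_voxel,
    simulate_dti_voxel,
)

scheme = make_multishell_scheme((16, 16, 16, 16))
D = np.diag([1.7e-3, 3e-4, 3e-4])
y, _, _ = simulate_dti_voxel(D, 1.0, scheme, NoiseModel("rician"),
                             alpha0=float(np.log(0.0025)), seed=5)
model = NoiseModel("rician")

runs = {
    "tailored": fit_voxel(y, scheme, model,
                          MCMCConfig(n_iter=2500, n_burnin=500, seed=6)),
    "rwm cI": run_rwm_voxel(y, scheme, model,
                            MCMCConfig(n_iter=2500, n_burnin=500, seed=6,
                                       sampler="rwm_identity")),
    "rwm -cH^-1": run_rwm_voxel(y, scheme, model,
                                MCMCConfig(n_iter=2500, n_burnin=500, seed=6,
                                           sampler="rwm_hessian")),
}

print(f"{'parameter':10s}" + "".join(f"{k:>14s}" for k in runs))
rows = [("ln S0", lambda d: d.beta0)]
rows += [(f"omega{j + 1}", lambda d, j=j: d.extras["omega"][:, j]) for j in range(6)]
rows += [("alpha0", lambda d: d.alpha0)]
for name, get in rows:
    ifs = [inefficiency_factor(get(d)) for d in runs.values()]
    print(f"{name:10s}" + "".join(f"{v:14.1f}" for v in ifs))
# the tailored sampler's IF stays near 1 (almost independent draws); the
# random-walk chains need tens to hundreds of times more iterations for the
# same Monte-Carlo precision
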