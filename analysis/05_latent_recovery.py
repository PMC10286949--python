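"""Latent-state recovery over the 16-set generating-parameter grid.

For every parameter set: simulate a session, refit by maximum likelihood,
re-estimate the choice-conditioned latent states under the fitted
parameters, and score them against the estimates under the generating
parameters (squared Pearson correlation across trials).  The R^2 against the
single realized latent trajectory is reported alongside for reference.
"""

import json
from itertools import product
from pathlib import Path

from bmbu.design import build_schedule, schedule_table
from bmbu.fitting import FitConfig
from bmbu.latents import recovery_test
from bmbu.observer import ObserverParams
from bmbu.synth import DEFAULT_PARAM_RANGES

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

design = schedule_table(build_schedule(n_runs=8, seed=3))
names = ("mu0", "sigma0", "sigma_m", "kappa")
grid = [
    ObserverParams(**dict(zip(names, combo)))
    for combo in product(*[DEFAULT_PARAM_RANGES[k] for k in names])
]
report = recovery_test(
    design, grid, FitConfig(n_starts=100, n_top=20, seed=0), n_sim=20_000, seed=7
)
report.per_set.to_csv(OUT / "recovery_per_set.tsv", sep="\t", index=False)
(OUT / "recovery_summary.json").write_text(
    json.dumps(
        {"mean_r2": report.mean_r2, "n_sets": len(grid), "failed": report.failed_sets},
        indent=2,
    )
)
print(f"{len(grid)}-set grid, {len(report.failed_sets)} failed fits")
for var in ("b", "s", "v"):
    print(f"  mean R^2({var}) = {report.mean_r2[var]:.3f}")
print(
    "reference: R^2 against the realized (single-draw) boundary trajectory "
    f"averages {report.per_set['r2_realized_b'].mean():.3f} -- bounded by "
    "trial-wise retrieval noise, not by the estimation procedure"
)
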