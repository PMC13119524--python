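"""Shared fixtures for the phagesteer test suite."""

from __future__ import annotations

import numpy as np
import pytest

import phagesteer as ps

#: The three late-dosing multi-phage arms compared throughout the study.
LATE_ARMS = {
    "t2_first": ps.TreatmentSpec("sequential", "T2", "late", "LAMBDA", 12),
    "cocktail": ps.TreatmentSpec("cocktail", "BOTH", "late", "BOTH", 12),
    "lam_first": ps.TreatmentSpec("sequential", "LAMBDA", "late", "T2", 12),
}


@pytest.fixture(scope="session")
def default_params() -> ps.SimParams:
    return ps.SimParams()


def analytic_params(**overrides) -> ps.SimParams:
    """Parameters for closed-form tests: no mutation, no refuge, no decay."""
    base = dict(
        mutations={},
        refuge_cells=0.0,
        decay={"T2": 0.0, "LAMBDA": 0.0},
        dormant_on=0.0,
        dormant_off=0.0,
        deterministic=True,
    )
    base.update(overrides)
    return ps.SimParams(**base)


@pytest.fixture(scope="session")
def steering_runs(default_params):
    """The follow-up-scale steering experiment: three late-dosing arms at 12
    replicate populations each, repeated over 50 independent seeds.

    Returns, per arm, a (50, 12) array of per-population mean 14-day OD600
    values and a matching array of the first day on which cross-resistant
    genotypes exceeded 50% frequency (inf = never).
    """
    n_seeds, n_reps = 50, 12
    out = {}
    for arm, spec in LATE_ARMS.items():
        mean_od = np.empty((n_seeds, n_reps))
        xr_day = np.empty((n_seeds, n_reps))
        for seed in range(n_seeds):
            for k in range(n_reps):
                traj = ps.run_population(
                    spec,
                    default_params,
                    seed=seed,
                    population_id=f"{arm}_s{seed}_r{k + 1}",
                )
                mean_od[seed, k] = traj.mean_od()
                day = ps.first_majority_day(traj)
                xr_day[seed, k] = np.inf if day is None else day
        out[arm] = {"mean_od": mean_od, "xr_day": xr_day}
    return out
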