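"""End-to-end parameter recovery: the package's self-verification loop.

A reference model (the toy engine at known ground-truth parameters)
supplies noisy <dU>_alpha targets; the fit starts from deliberately wrong
parameters and must recover the truth by trust-radius Newton-Raphson on
the regularised objective, re-simulating at every iteration.

This is a scaled-down scenario (24 solvent particles, short chains) so it
finishes in seconds; the full canonical scenario lives in
fegrad.fixtures.canonical_scenario and takes a few minutes.
"""

import numpy as np

from fegrad import ParameterSpace, Species, ThermoState, build_solvation_box
from fegrad.alchemy import AlphaSchedule, CoupledPotential, FitGrid, \
    SamplerConfig, Stage
from fegrad.fixtures import RecoveryScenario, recovery_experiment
from fegrad.optimizer import TrustConfig

solute = Species("solute", sigma=0.45, epsilon=1.5, charge=0.0, role="solute")
solvent = Species("solvent", sigma=0.42, epsilon=0.8, charge=0.0)
system = build_solvation_box(solute, {solvent: 24}, L=2.2, r_c=0.9,
                             seed=3, tether_k=10.0)
space = ParameterSpace.create(
    names=("solute.sigma", "solute.epsilon", "solute.charge"),
    kinds=("sigma", "epsilon", "charge"),
    K0=(0.45, 1.5, 0.0), t=(0.05, 1.5, 0.1),
    frozen=(True, False, True))

sampler = SamplerConfig(seed=0, n_equil=2000, n_steps=40000, save_every=200)
scenario = RecoveryScenario(
    name="mini-demo", space=space, system=system, state=ThermoState(),
    fit_grids=(FitGrid(CoupledPotential(mode="linear", stage="vdw"),
                       np.array([0.5, 0.75, 1.0]), sampler),),
    schedule=AlphaSchedule((Stage(CoupledPotential(mode="softcore",
                                                   stage="vdw"),
                                  np.linspace(0, 1, 5), sampler),)),
    perturbation={"solute.epsilon": 0.4},   # start +0.6 kJ/mol too high
    seed_ref=100, seed_fit=200, n_repeat=2)

report = recovery_experiment(scenario, TrustConfig(max_iterations=8))
print(report.summary())

# "recovered" should move from the perturbed start towards the truth and
# the objective should drop well below its starting value; with this tiny
# box the remaining gap is statistical, as the +/- uncertainty shows.
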