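"""Charged-solute hydration free energies: corrections and budgets.

Raw charging free energies from periodic simulations with approximate
electrostatics are methodology-dependent; standard totals need the
A+B+D continuum corrections, the C1 summation-scheme correction and the
standard-state term.  The package ships the published budget table and
re-assembles any row; correction *gradients* (for fitting charged
solutes) come from central differences on alpha-scaled parameters.
"""

import numpy as np

from fegrad import (BornWignerProvider, ParameterSpace, correction_gradient,
                    load_reference_budgets, standard_state_term)
from fegrad.charged import assemble_budget_row

print(f"standard-state term at 298.15 K, 1 atm: "
      f"{standard_state_term():.2f} kJ/mol\n")

df = load_reference_budgets()
row = df[(df.system == "ARG") & (df.force_field == "SIRAH1")].iloc[0]
budget = assemble_budget_row(row)
print("ARG / SIRAH 1.0 hydration free-energy budget (kJ/mol):")
for name, value in budget.addends().items():
    print(f"  {name:>14s}: {value:8.1f}")

# Correction gradients for a fit: Born+Wigner stand-in provider, charge
# scaled by alpha in [0.4, 1.0] as the parameters are grown in.
space = ParameterSpace.create(("ion.charge",), ("charge",), (1.0,))
provider = BornWignerProvider()
table = correction_gradient(
    lambda K: provider.dg_abd(q=K[0], radius=0.3, box_edge=2.5,
                              eps_model=65.0, eps_exp=78.4),
    space, np.array([0.4, 0.7, 1.0]))
print("\nd(dG_ABD)/dq at alpha-scaled charge (kJ/mol/e):")
for _, r in table.iterrows():
    print(f"  alpha = {r['alpha']:.1f}: {r['dcor_ion.charge']:8.2f}")

# The derivative grows as alpha^2 because the Born and Wigner terms are
# quadratic in the scaled charge alpha*q.
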