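"""Model assessment and the constrained/unconstrained gain statistic.

Evaluates docked models of a toy complex by ligand and interface RMSD
(acceptable = ligand RMSD < 10 A and interface RMSD < 4 A), then
recomputes the aggregate gain table from the packaged benchmark counts of
28 complexes: total acceptable constrained models divided by total
unconstrained, per docking setting and retention level.
"""

import numpy as np

from condock import (
    constraints_from_contacts,
    evaluate_model,
    gain_table,
    order_partners,
    run_constrained_docking,
)
from condock.synthetic import ToyComplexSpec, make_toy_complex

sa, sb, contacts = make_toy_complex(ToyComplexSpec(seed=2))
constraints = constraints_from_contacts([sorted(contacts.pairs)[0]])
run = run_constrained_docking(sa, sb, constraints, models_per_constraint=5)

receptor, ligand = order_partners(sa, sb)
print("model assessment against the true complex:")
n_acceptable = 0
for m in run.models[constraints[0].id]:
    moved = m.apply(sb)
    result = evaluate_model(receptor, moved, receptor, ligand)
    n_acceptable += result.acceptable
    print(f"  score {m.score:5d}  lrmsd {result.ligand_rmsd:5.2f} A  "
          f"irmsd {result.interface_rmsd:5.2f} A  "
          f"{'ACCEPTABLE' if result.acceptable else 'rejected'}")
print(f"{n_acceptable}/{len(run.models[constraints[0].id])} acceptable\n")

table = gain_table()
print("benchmark gain (acceptable constrained / unconstrained totals):")
print(table["gain"].round(2).to_string())
print(f"\nmean gain {table.attrs['mean']:.1f} (sd {table.attrs['sd']:.1f}): "
      "constraint-guided filtering roughly doubles the acceptable models "
      "surviving the geometric search")
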