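"""Rigid-body docking pruned by a predicted contact constraint.

Docks the two partners of a toy complex twice: unconstrained, and
constrained by one true residue contact. The constraint prunes the
translational search to a small ball around the contact geometry, and the
retained models include placements close to the true pose.
"""

import numpy as np

from condock import constraints_from_contacts, run_constrained_docking
from condock.docking import DockingConfig
from condock.synthetic import ToyComplexSpec, make_toy_complex

sa, sb, contacts = make_toy_complex(ToyComplexSpec(seed=2))
true_pair = sorted(contacts.pairs)[0]
print(f"constraining predicted contact {true_pair[0]} -- {true_pair[1]} "
      "(max distance 8 A = 5 A criterion + 3 A slack)")

constraints = constraints_from_contacts([true_pair], max_dist=8.0)
run_c = run_constrained_docking(sa, sb, constraints, models_per_constraint=10)
run_u = run_constrained_docking(
    sa, sb, None, config=DockingConfig(top_k_unconstrained=5)
)

scanned_c = sum(v for (c, _), v in run_c.translations_scored.items())
scanned_u = sum(v for (c, _), v in run_u.translations_scored.items())
print(f"translations scanned: {scanned_c} constrained vs {scanned_u} "
      f"unconstrained ({scanned_u / scanned_c:.0f}x pruning)")

print("\ntop constrained models (translation distance from true pose, A):")
for m in run_c.models[constraints[0].id]:
    print(f"  score {m.score:5d}   |t - t_true| = "
          f"{np.linalg.norm(m.translation):.2f}")
print("\ntop unconstrained models:")
for m in run_u.models[None]:
    print(f"  score {m.score:5d}   |t - t_true| = "
          f"{np.linalg.norm(m.translation):.2f}")
print("\nthe generated complex is already posed, so the true translation "
      "is zero; small distances mean the pose was recovered")
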