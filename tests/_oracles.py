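"""Independent brute-force oracles used by the tests.

The steady-state oracle solves N v(x) = 0 by root-finding, with the
conserved moieties (left null space of the free-species stoichiometry)
pinned to their initial values — without that constraint the root set is a
continuum indexed by the pool sizes.
"""

import numpy as np
from scipy.optimize import root

from cbckit.model_core import stoichiometry_matrix


def free_indices(model):
    sm = stoichiometry_matrix(model)
    return sm, [i for i, sid in enumerate(sm.species_ids)
                if not sm.clamped[i] and not model.get_species(sid).accumulator]


def brute_force_steady_state(model, x0_free, base, free, sm):
    """Root-find N v = 0 from x0_free with conserved pools fixed at base."""
    a = sm.matrix[free, :]
    u, s, _ = np.linalg.svd(a)
    rank = int(np.sum(s > 1e-10 * s[0]))
    w = u[:, rank:]  # left null space: the conserved moiety directions

    def residual(x):
        y = base.copy()
        y[free] = x
        state = dict(zip(sm.species_ids, y))
        rates = np.array([r.rate_law.evaluate(state, model.parameters)
                          for r in model.reactions])
        return a @ rates + w @ (w.T @ (x - base[free]))

    return root(residual, x0_free, method="hybr")
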