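"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the pruning recursion: the likelihood is a plain
sum over all joint ancestral-state assignments, and expected substitution
flows are accumulated by explicit enumeration of the rate matrix.
"""

import itertools

import numpy as np


def brute_force_loglik(tree, tip_states, rate_matrix_of, pi, nstates):
    """Log-likelihood by summation over all internal-node state assignments.

    tip_states: dict tip name -> list of state indices per site (-1 missing);
    rate_matrix_of: node -> RateMatrix for the branch above the node.
    """
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    tips = [n for n in nodes if n.is_leaf]
    nsites = len(next(iter(tip_states.values())))
    P = {id(n): rate_matrix_of(n).transition_probs(n.length) for n in nodes if not n.is_root}
    total = 0.0
    for site in range(nsites):
        site_lik = 0.0
        for combo in itertools.product(range(nstates), repeat=len(internal)):
            state = {id(n): s for n, s in zip(internal, combo)}
            ok = True
            for tip in tips:
                s = tip_states[tip.name][site]
                state[id(tip)] = s
            lik = pi[state[id(tree.root)]]
            for n in nodes:
                if n.is_root:
                    continue
                s_child = state[id(n)]
                s_parent = state[id(n.parent)]
                if s_child == -1:  # missing tip: marginalize
                    continue
                lik *= P[id(n)][s_parent, s_child]
            site_lik += lik
        total += np.log(site_lik)
    return total


def expected_flows(rate_matrix, syn_mask_pairs):
    """Synonymous vs nonsynonymous substitution flow by explicit enumeration.

    syn_mask_pairs: callable (i, j) -> True if the i->j change is synonymous.
    Returns (synonymous flow, total flow) of pi_i * Q_ij over i != j.
    """
    Q, pi = rate_matrix.Q, rate_matrix.pi
    syn = tot = 0.0
    n = Q.shape[0]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            f = pi[i] * Q[i, j]
            tot += f
            if syn_mask_pairs(i, j):
                syn += f
    return syn, tot
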