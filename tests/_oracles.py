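"""Independent oracles shared by the unit and acceptance tests.

These deliberately avoid the code paths they check: likelihoods by
exhaustive enumeration over internal-state assignments, mass properties
by rejection-sampling Monte Carlo, QP optimality by feasible-point
sampling in the constraint null space.
"""

from __future__ import annotations

import itertools

import numpy as np

from bipedsim.asr import CharacterData, DatedTree, MkModelSpec, transition_matrices


def enumeration_loglik(tree: DatedTree, data: CharacterData, spec: MkModelSpec,
                       rates) -> float:
    """Brute-force Mk likelihood: sum over every internal-node state
    assignment of the product of branch transition probabilities."""
    k = spec.n_states
    Q = spec.rate_matrix(np.asarray(rates, dtype=float))
    P = transition_matrices(Q, tree.branch_lengths)
    internals = [i for i in range(tree.n_nodes) if tree.children[i]]
    tip_w = {i: data.weights[tree.labels[i]] for i in tree.tip_indices}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        like = 1.0 / k  # flat root prior
        for i in internals:
            for c in tree.children[i]:
                if tree.children[c]:
                    like *= P[c][amap[i], amap[c]]
                else:
                    like *= float(P[c][amap[i]] @ tip_w[c])
        total += like
    return float(np.log(total))


def enumeration_marginals(tree: DatedTree, data: CharacterData,
                          spec: MkModelSpec, rates) -> dict[int, np.ndarray]:
    """Marginal internal-node state probabilities by enumeration."""
    k = spec.n_states
    Q = spec.rate_matrix(np.asarray(rates, dtype=float))
    P = transition_matrices(Q, tree.branch_lengths)
    internals = [i for i in range(tree.n_nodes) if tree.children[i]]
    tip_w = {i: data.weights[tree.labels[i]] for i in tree.tip_indices}
    mass = {i: np.zeros(k) for i in internals}
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        like = 1.0 / k
        for i in internals:
            for c in tree.children[i]:
                if tree.children[c]:
                    like *= P[c][amap[i], amap[c]]
                else:
                    like *= float(P[c][amap[i]] @ tip_w[c])
        for i in internals:
            mass[i][amap[i]] += like
    return {i: m / m.sum() for i, m in mass.items()}


def convex_hull_monte_carlo(vertices: np.ndarray, density: float,
                            n_samples: int, rng: np.random.Generator):
    """Mass and COM of a convex polyhedron by rejection sampling inside
    its bounding box, using the hull's half-space representation."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(vertices)
    lo, hi = vertices.min(axis=0), vertices.max(axis=0)
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    # hull.equations: A x + b <= 0 inside
    inside = np.all(pts @ hull.equations[:, :3].T
                    + hull.equations[:, 3] <= 1e-12, axis=1)
    box_volume = float(np.prod(hi - lo))
    volume = box_volume * inside.mean()
    com = pts[inside].mean(axis=0)
    return volume * density, com


def sample_feasible_points(matrix: np.ndarray, b: np.ndarray, x_feasible,
                           lower, upper, n_samples: int,
                           rng: np.random.Generator,
                           scale: float = 0.5) -> np.ndarray:
    """Random points satisfying matrix @ x = b within the bounds,
    generated in the constraint null space around a feasible point."""
    from scipy.linalg import null_space

    N = null_space(matrix)
    c = rng.uniform(-scale, scale, size=(n_samples, N.shape[1]))
    pts = np.asarray(x_feasible)[None, :] + c @ N.T
    ok = np.all((pts >= lower - 1e-12) & (pts <= upper + 1e-12), axis=1)
    return pts[ok]
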