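"""Maximum-likelihood ancestral-state reconstruction of discrete
locomotor mode (Mk models) on time-calibrated trees.

A continuous-time Markov chain with k states (k = 2: quadrupedal,
bipedal; k = 3: quadrupedal, facultatively bipedal, bipedal) evolves
along a rooted tree with branch lengths in Myr.  Rate structures:
``ER`` (one shared rate), ``ARD`` (all k(k-1) rates different) and
``ordered`` (k = 3 with direct quadrupedal <-> bipedal transitions
forbidden, q02 = q20 = 0).  Tip likelihoods are weight vectors, so taxa
of uncertain mode enter with flat priors (0.5/0.5 or 1/3 each).
Likelihoods use Felsenstein pruning with matrix exponentials per branch;
model choice uses AIC = 2p - 2 lnL; node states are marginal
probabilities under the ML rates.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

MIN_BRANCH_LENGTH = 0.1  # Myr floor for zero-length dating artefacts

STATE_NAMES = {2: ("quadrupedal", "bipedal"),
               3: ("quadrupedal", "facultative", "bipedal")}


class DatedTree:
    """A rooted, time-calibrated tree in postorder arrays.

    Tips need not be contemporaneous (fossil tips make the tree
    non-ultrametric).  Zero or missing branch lengths are floored at
    `min_branch_length` (root edge excepted).
    """

    def __init__(self, tree: dendropy.Tree,
                 min_branch_length: float = MIN_BRANCH_LENGTH) -> None:
        self._dendropy = tree
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.children: list[list[int]] = []
        self.branch_lengths = np.zeros(self.n_nodes)
        self.labels: list[str] = []
        self.floored_branches = 0
        for i, nd in enumerate(nodes):
            self.children.append([index[id(c)] for c in nd.child_nodes()])
            length = nd.edge.length
            if nd.parent_node is None:
                length = 0.0
            elif length is None or length <= 0:
                length = min_branch_length
                self.floored_branches += 1
            self.branch_lengths[i] = length
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("every tip must carry a unique label")
                self.labels.append(nd.taxon.label)
            else:
                self.labels.append("")
        self.tip_indices = [i for i, ch in enumerate(self.children) if not ch]
        self.root = self.n_nodes - 1
        tips = [self.labels[i] for i in self.tip_indices]
        if len(set(tips)) != len(tips):
            raise ValueError("tip labels must be unique")

    @classmethod
    def from_newick(cls, newick: str,
                    min_branch_length: float = MIN_BRANCH_LENGTH) -> "DatedTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"tip labels must be unique: {exc}") from exc
        return cls(tree, min_branch_length)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    def newick(self) -> str:
        return self._dendropy.as_string(schema="newick").strip()

    def annotated_newick(self, node_probs: dict[int, np.ndarray]) -> str:
        """Newick with per-internal-node marginal probabilities as
        comment annotations."""
        tree = self._dendropy.clone(depth=1)
        nodes = list(tree.postorder_node_iter())
        for i, nd in enumerate(nodes):
            if nd.is_leaf() or i not in node_probs:
                continue
            probs = ",".join(f"{p:.4f}" for p in node_probs[i])
            nd.annotations.add_new("state_probs", probs)
        return tree.as_string(schema="newick", suppress_annotations=False).strip()


@dataclass
class CharacterData:
    """Tip state weights: label -> length-k vector (resolved tips are
    one-hot; ambiguous tips get a flat 1/k vector)."""

    n_states: int
    weights: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for label, w in self.weights.items():
            w = np.asarray(w, dtype=float).reshape(self.n_states)
            if np.any(w < 0) or w.sum() > 1 + 1e-9 or w.sum() <= 0:
                raise ValueError(f"tip {label!r}: weights must be non-negative "
                                 "and sum to at most 1")
            clean[label] = w
        self.weights = clean

    @classmethod
    def from_states(cls, states: dict[str, int | str],
                    n_states: int) -> "CharacterData":
        """Build from integer states; the string 'ambiguous' yields a
        flat prior (0.5 each for k = 2, 0.333 each for k = 3)."""
        weights = {}
        for label, s in states.items():
            if isinstance(s, str) and s.lower().startswith("ambig"):
                weights[label] = np.full(n_states, 1.0 / n_states)
            else:
                w = np.zeros(n_states)
                w[int(s)] = 1.0
                weights[label] = w
        return cls(n_states, weights)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for label in sorted(self.weights):
            h.update(label.encode())
            h.update(np.round(self.weights[label], 12).tobytes())
        return h.hexdigest()[:16]


@dataclass
class MkModelSpec:
    """Mk rate structure: ER, ARD, or ordered (3-state chain)."""

    n_states: int
    structure: str = "ER"  # ER | ARD | ordered

    def __post_init__(self) -> None:
        if self.n_states not in (2, 3):
            raise ValueError("n_states must be 2 or 3")
        if self.structure not in ("ER", "ARD", "ordered"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.structure == "ordered" and self.n_states != 3:
            raise ValueError("the ordered model requires 3 states")

    @property
    def n_free_rates(self) -> int:
        if self.structure == "ER":
            return 1
        if self.structure == "ARD":
            return self.n_states * (self.n_states - 1)
        return 4  # ordered: q01, q10, q12, q21

    def rate_parameter_names(self) -> list[str]:
        k = self.n_states
        if self.structure == "ER":
            return ["q"]
        pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
        if self.structure == "ordered":
            pairs = [(i, j) for i, j in pairs if abs(i - j) == 1]
        return [f"q{i}{j}" for i, j in pairs]

    def rate_matrix(self, rates: np.ndarray) -> np.ndarray:
        rates = np.asarray(rates, dtype=float).reshape(self.n_free_rates)
        if np.any(rates < 0):
            raise ValueError("rates must be non-negative")
        k = self.n_states
        Q = np.zeros((k, k))
        if self.structure == "ER":
            Q[:] = rates[0]
        else:
            for name, r in zip(self.rate_parameter_names(), rates):
                i, j = int(name[1]), int(name[2])
                Q[i, j] = r
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


def transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) = exp(Qt) for every branch length, via eigendecomposition
    with a scaling-and-squaring (scipy expm) fallback for defective Q."""
    lengths = np.asarray(lengths, dtype=float)
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e8:
            E = np.exp(np.multiply.outer(lengths, w))  # n x k
            P = np.einsum("ij,nj,jl->nil", V, E, Vinv)
            P = np.real_if_close(P, tol=1e6)
            if np.isrealobj(P) or np.abs(np.imag(P)).max() < 1e-12:
                return np.real(P)
    except np.linalg.LinAlgError:
        pass
    return np.array([expm(Q * t) for t in lengths])


def _tip_partials(tree: DatedTree, data: CharacterData, k: int) -> np.ndarray:
    partials = np.ones((tree.n_nodes, k))
    for i in tree.tip_indices:
        label = tree.labels[i]
        if label not in data.weights:
            raise KeyError(f"tip {label!r} missing from the character data")
        partials[i] = data.weights[label]
    return partials


def mk_loglik(tree: DatedTree, data: CharacterData, spec: MkModelSpec,
              rates: np.ndarray, root_prior: str = "flat") -> float:
    """Log-likelihood by Felsenstein pruning (scaled partials)."""
    k = spec.n_states
    if data.n_states != k:
        raise ValueError("character data and model state counts differ")
    Q = spec.rate_matrix(rates)
    P = transition_matrices(Q, tree.branch_lengths)
    partials = _tip_partials(tree, data, k)
    log_scale = 0.0
    for i in range(tree.n_nodes):
        if not tree.children[i]:
            continue
        L = np.ones(k)
        for c in tree.children[i]:
            L = L * (P[c] @ partials[c])
        s = L.max()
        if s <= 0:
            return -np.inf
        partials[i] = L / s
        log_scale += np.log(s)
    prior = _root_prior(Q, k, root_prior)
    like = float(prior @ partials[tree.root])
    if like <= 0:
        return -np.inf
    return float(np.log(like) + log_scale)


def _root_prior(Q: np.ndarray, k: int, kind: str) -> np.ndarray:
    if kind == "flat":
        return np.full(k, 1.0 / k)
    if kind == "stationary":
        w, V = np.linalg.eig(Q.T)
        v = np.real(V[:, np.argmin(np.abs(w))])
        v = np.abs(v)
        return v / v.sum()
    raise ValueError(f"unknown root prior {kind!r}")


@dataclass
class MkFit:
    spec: MkModelSpec
    rates: np.ndarray
    log_likelihood: float
    aic: float
    root_prior: str = "flat"
    data_fingerprint: str = ""
    n_starts_converged: int = 0

    def rate_table(self) -> dict[str, float]:
        return dict(zip(self.spec.rate_parameter_names(), self.rates))


class FitError(RuntimeError):
    pass


def fit_mk(tree: DatedTree, data: CharacterData, spec: MkModelSpec,
           seed: int = 0, n_starts: int = 5, root_prior: str = "flat",
           log_rate_bounds: tuple = (-8.0, 4.0)) -> MkFit:
    """ML rates by bounded L-BFGS-B in log-rate space with seeded
    multistarts; AIC = 2p - 2 lnL.  Deterministic given the seed."""
    p = spec.n_free_rates
    rng = np.random.default_rng(seed)
    lo, hi = log_rate_bounds
    # one heuristic start (about one expected change over the whole tree)
    # plus jittered starts spread across the log-rate box, so at least one
    # start lands near the informative rate regime on any tree scale
    centre = np.log(max(1.0 / max(tree.total_length, 1e-9), 1e-6))
    starts = [np.clip(np.full(p, centre), lo + 0.5, hi - 0.5)]
    for v in np.linspace(lo + 1.5, hi - 1.5, n_starts - 1):
        starts.append(np.clip(v + rng.uniform(-0.5, 0.5, size=p),
                              lo + 0.1, hi - 0.1))

    def nll(logr):
        return -mk_loglik(tree, data, spec, np.exp(logr), root_prior)

    best, best_val, converged = None, np.inf, 0
    for x0 in starts:
        res = minimize(nll, np.clip(x0, *log_rate_bounds), method="L-BFGS-B",
                       bounds=[log_rate_bounds] * p,
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10})
        if np.isfinite(res.fun):
            converged += 1
            if res.fun < best_val:
                best, best_val = res.x, float(res.fun)
    if best is None:
        raise FitError(f"all {n_starts} optimizer starts failed for "
                       f"{spec.structure} (k={spec.n_states})")
    lnl = -best_val
    return MkFit(spec, np.exp(best), lnl, 2.0 * p - 2.0 * lnl, root_prior,
                 data.fingerprint(), converged)


def marginal_states(tree: DatedTree, data: CharacterData, spec: MkModelSpec,
                    rates: np.ndarray,
                    root_prior: str = "flat") -> dict[int, np.ndarray]:
    """Marginal state probabilities for every node (rerooting-style
    inside/outside recursion, valid for non-reversible rate matrices).

    Returns node index -> probability vector (sums to 1); tips included
    (resolved tips are their observed states, ambiguous tips their
    posterior weights).
    """
    k = spec.n_states
    Q = spec.rate_matrix(rates)
    P = transition_matrices(Q, tree.branch_lengths)
    down = _tip_partials(tree, data, k)  # conditional likelihood below node
    for i in range(tree.n_nodes):
        if tree.children[i]:
            L = np.ones(k)
            for c in tree.children[i]:
                L = L * (P[c] @ down[c])
            m = L.max()
            down[i] = L / (m if m > 0 else 1.0)

    prior = _root_prior(Q, k, root_prior)
    up = np.ones((tree.n_nodes, k))  # likelihood of everything outside
    up[tree.root] = prior
    order = list(range(tree.n_nodes))[::-1]  # preorder (reverse postorder)
    for i in order:
        for c in tree.children[i]:
            sib = np.ones(k)
            for b in tree.children[i]:
                if b != c:
                    sib = sib * (P[b] @ down[b])
            contrib = up[i] * sib  # at the parent node, state-indexed
            up[c] = contrib @ P[c]  # sum_parent contrib_p * P_c[p, child]
            m = up[c].max()
            if m > 0:
                up[c] /= m

    out = {}
    for i in range(tree.n_nodes):
        post = up[i] * down[i]
        out[i] = post / post.sum()
    return out


def compare_models(fits: list[MkFit]) -> pd.DataFrame:
    """Rank fits on the same data by ascending AIC; delta-AIC < 2 is
    flagged a tie, with the fewer-parameter model listed first."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) != 1:
        raise ValueError("fits were made on different tree/character data")
    rows = sorted(fits, key=lambda f: (f.aic, f.spec.n_free_rates))
    best_aic = rows[0].aic
    # within the tie band around the best model, prefer fewer parameters
    tied = [f for f in rows if f.aic - best_aic < 2.0]
    rest = [f for f in rows if f.aic - best_aic >= 2.0]
    rows = sorted(tied, key=lambda f: (f.spec.n_free_rates, f.aic)) + rest
    frame = pd.DataFrame([{
        "model": f"{f.spec.structure}_k{f.spec.n_states}",
        "n_free_rates": f.spec.n_free_rates,
        "log_likelihood": f.log_likelihood,
        "aic": f.aic,
        "delta_aic": f.aic - best_aic,
        "tie_with_best": bool(0 < f.aic - best_aic < 2.0),
    } for f in rows])
    return frame
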