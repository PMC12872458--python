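"""Felsenstein pruning likelihood with discrete gamma rates, plus
coordinate-wise branch-length optimization.

The engine works on an indexed copy of the tree: nodes in postorder,
conditional likelihoods stored per (rate category, site, state) with a
shared per-site log-scale to stay finite on large trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from ._alphabet import N_STATES, encode_sequence
from .msa import Alignment
from .substitution import SubstitutionModel

LOG_ZERO_SENTINEL = -1e9
MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 20.0

DEFAULT_ALPHA_GRID = (0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 5.0)


class _Engine:
    def __init__(self, tree: dendropy.Tree, aln: Alignment, model: SubstitutionModel):
        self.model = model
        self.rates = model.category_rates()
        self.ncat = len(self.rates)
        self.pi = model.frequencies

        seq_by_id = dict(zip(aln.ids, aln.seqs))
        self.nsites = aln.n_sites

        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.t = np.zeros(n)
        self.is_leaf = np.zeros(n, dtype=bool)
        self.leaf_codes: list[np.ndarray | None] = [None] * n
        for i, node in enumerate(self.nodes):
            for ch in node.child_nodes():
                self.children[i].append(self.index[id(ch)])
            if node.parent_node is not None:
                bl = node.edge.length
                if bl is None:
                    bl = 0.0
                if not np.isfinite(bl) or bl < 0:
                    raise ValueError("branch lengths must be finite and >= 0")
                self.t[i] = bl
            if node.is_leaf():
                self.is_leaf[i] = True
                label = node.taxon.label
                if label not in seq_by_id:
                    raise ValueError(f"leaf {label!r} missing from alignment")
                self.leaf_codes[i] = encode_sequence(seq_by_id[label])
        self.root = n - 1

        # per-node arrays
        self.P = [None] * n  # (ncat, 20, 20)
        self.D = [None] * n  # (ncat, nsites, 20) conditionals below node
        self.sD = [None] * n  # (nsites,) log-scale of D
        for i in range(n):
            if i != self.root:
                self._set_branch(i, self.t[i])

    # ------------------------------------------------------------ primitives

    def _set_branch(self, i: int, t: float) -> None:
        self.t[i] = t
        self.P[i] = np.stack(
            [self.model.transition_matrix(t * r) for r in self.rates]
        )

    def _leaf_conditional(self, i: int) -> np.ndarray:
        codes = self.leaf_codes[i]
        D = np.zeros((self.nsites, N_STATES))
        obs = codes >= 0
        D[obs, codes[obs]] = 1.0
        D[~obs, :] = 1.0  # gap / ambiguity: missing data
        return np.broadcast_to(D, (self.ncat, self.nsites, N_STATES)).copy()

    def _update_D(self, i: int) -> None:
        """Recompute conditionals at node i from its (current) children."""
        if self.is_leaf[i]:
            self.D[i] = self._leaf_conditional(i)
            self.sD[i] = np.zeros(self.nsites)
            return
        prod = np.ones((self.ncat, self.nsites, N_STATES))
        scale = np.zeros(self.nsites)
        for c in self.children[i]:
            # message from child c: D_c @ P_c^T, per category
            M = np.einsum("kse,kie->ksi", self.D[c], self.P[c])
            prod *= M
            scale += self.sD[c]
        m = prod.max(axis=(0, 2))
        safe = np.where(m > 0, m, 1.0)
        prod /= safe[None, :, None]
        self.D[i] = prod
        self.sD[i] = scale + np.log(safe)

    def full_postorder_update(self) -> None:
        for i in range(len(self.nodes)):
            self._update_D(i)

    def site_loglik(self) -> np.ndarray:
        self.full_postorder_update()
        L = np.einsum("ksi,i->ks", self.D[self.root], self.pi).mean(axis=0)
        with np.errstate(divide="ignore"):
            ll = np.log(L) + self.sD[self.root]
        return np.maximum(np.nan_to_num(ll, nan=LOG_ZERO_SENTINEL), LOG_ZERO_SENTINEL)

    def total_loglik(self) -> float:
        return float(self.site_loglik().sum())

    # ---------------------------------------------------------- optimization

    def _optimize_edge(self, E: np.ndarray, eS: np.ndarray, i: int) -> None:
        """Brent on one branch with the rest of the tree pre-contracted
        into the model's eigenbasis, so each evaluation is one matvec:
        L_s(t) = (1/ncat) sum_k sum_j G_ksj exp(lam_j t r_k)."""
        right, left, lam = self.model._right, self.model._left, self.model._evals
        G = np.matmul(E, right) * np.matmul(self.D[i], left.T)
        # flatten (cat, state) so each evaluation is one matvec
        G2 = np.ascontiguousarray(G.transpose(1, 0, 2).reshape(self.nsites, -1))
        const = eS + self.sD[i]
        rates = self.rates
        ncat = self.ncat

        def loglik(t: float) -> float:
            expd = np.exp(lam[None, :] * (t * rates)[:, None]).ravel()
            total = G2 @ expd
            ok = total > 0
            ll = np.full(total.shape, LOG_ZERO_SENTINEL)
            ll[ok] = np.log(total[ok] / ncat) + const[ok]
            return float(ll.sum())

        current = loglik(self.t[i])
        res = minimize_scalar(
            lambda t: -loglik(t),
            bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
            method="bounded",
            options={"xatol": 1e-5, "maxiter": 60},
        )
        best_t, best_ll = float(res.x), -res.fun
        # snap onto the lower bound when it is at least as good (Brent
        # stops within xatol of the boundary otherwise)
        if loglik(MIN_BRANCH_LENGTH) >= best_ll:
            best_t, best_ll = MIN_BRANCH_LENGTH, loglik(MIN_BRANCH_LENGTH)
        if best_ll > current:
            self._set_branch(i, best_t)

    def _smooth(self, u: int, H: np.ndarray, hS: np.ndarray) -> None:
        """Optimize every edge below u once, depth-first, keeping all
        conditional vectors exact at the moment each edge is optimized."""
        kids = self.children[u]
        for v in kids:
            prod = H.copy()
            eS = hS.copy()
            for w in kids:
                if w == v:
                    continue
                M = np.einsum("kse,kie->ksi", self.D[w], self.P[w])
                prod *= M
                eS = eS + self.sD[w]
            m = prod.max(axis=(0, 2))
            safe = np.where(m > 0, m, 1.0)
            prod /= safe[None, :, None]
            eS = eS + np.log(safe)

            self._optimize_edge(prod, eS, v)

            if not self.is_leaf[v]:
                Hv = np.einsum("ksi,kij->ksj", prod, self.P[v])
                self._smooth(v, Hv, eS)
                self._update_D(v)  # subtree edges changed

    def _root_loglik(self) -> float:
        """Total log-likelihood assuming children of the root are current."""
        self._update_D(self.root)
        L = np.einsum("ksi,i->ks", self.D[self.root], self.pi).mean(axis=0)
        ok = L > 0
        ll = np.full(L.shape, LOG_ZERO_SENTINEL)
        ll[ok] = np.log(L[ok]) + self.sD[self.root][ok]
        return float(ll.sum())

    def smoothing_round(self, refresh: bool = True) -> float:
        if refresh:
            self.full_postorder_update()
        H = np.broadcast_to(
            self.pi, (self.ncat, self.nsites, N_STATES)
        ).copy()
        self._smooth(self.root, H, np.zeros(self.nsites))
        return self._root_loglik()

    def write_lengths(self, tree: dendropy.Tree) -> None:
        for node in tree.postorder_node_iter():
            i = self.index[id(node)]
            if i != self.root:
                node.edge.length = float(self.t[i])


# ------------------------------------------------------------------- public


def site_loglik(
    tree: dendropy.Tree, alignment: Alignment, model: SubstitutionModel
) -> np.ndarray:
    """Per-site log-likelihood of the alignment on the tree.

    Gamma categories carry equal weight; impossible sites are clamped to
    the -1e9 sentinel rather than -inf.
    """
    return _Engine(tree, alignment, model).site_loglik()


def total_loglik(
    tree: dendropy.Tree, alignment: Alignment, model: SubstitutionModel
) -> float:
    return float(site_loglik(tree, alignment, model).sum())


@dataclass
class OptimizeResult:
    tree: dendropy.Tree
    loglik: float
    site_logliks: np.ndarray
    n_rounds: int
    converged: bool
    trace: list[float]


def optimize_branch_lengths(
    tree: dendropy.Tree,
    alignment: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-2,
    max_rounds: int = 5,
) -> OptimizeResult:
    """Coordinate-wise branch-length optimization (Brent per edge).

    Edges are visited depth-first with conditional vectors kept exact, so
    the total log-likelihood never decreases.  Stops when a full round
    improves by less than ``tol`` or after ``max_rounds``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    work = tree.clone(depth=1)
    engine = _Engine(work, alignment, model)
    ll = engine.total_loglik()
    trace = [ll]
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        # conditionals are already current: total_loglik refreshed them
        # initially and each smoothing round keeps them exact
        new_ll = engine.smoothing_round(refresh=False)
        trace.append(new_ll)
        if new_ll - ll < tol:
            ll = max(ll, new_ll)
            converged = True
            break
        ll = new_ll
    engine.write_lengths(work)
    return OptimizeResult(
        tree=work,
        loglik=ll,
        site_logliks=engine.site_loglik(),
        n_rounds=rounds,
        converged=converged,
        trace=trace,
    )


def estimate_gamma_alpha(
    tree: dendropy.Tree,
    alignment: Alignment,
    model: SubstitutionModel,
    grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
) -> float:
    """Pick the gamma shape from a grid by total log-likelihood on the tree."""
    if not grid:
        raise ValueError("alpha grid must be non-empty")
    scores = [
        total_loglik(tree, alignment, model.with_alpha(a)) for a in grid
    ]
    return float(grid[int(np.argmax(scores))])
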