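"""Phylogenetic likelihood on a fixed topology.

Felsenstein pruning with site-pattern compression and per-node scaling,
maximum-likelihood fitting of branch lengths and model parameters (HKY85
with global / branch-class / per-branch kappa; MG94xHKY85 with global,
branch-class or partition-specific omega), pairwise ML distances,
likelihood-ratio tests and nonparametric bootstrap of branch lengths.

Branch lengths are optimized coordinate-wise (bounded Brent on each branch,
using outside/inside conditional-likelihood arrays so one branch move costs
a single matrix product) interleaved with bounded quasi-Newton updates of
the global parameters in log space; convergence is declared when a full
round improves the log-likelihood by less than a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .gene_model import CodonAlignment
from .phylo import Node, Tree
from .subst_models import (
    CODON_INDEX,
    HKYParams,
    MG94Params,
    NUC_INDEX,
    RateMatrix,
    decompose_sn,
    decompose_titv,
    hky_matrix,
    mg94_matrix,
    position_frequencies,
)

__all__ = [
    "FitResult",
    "LRTResult",
    "PairwiseResult",
    "DataError",
    "NestingError",
    "loglik",
    "loglik_hky",
    "loglik_mg94",
    "fit_hky",
    "fit_mg94",
    "pairwise_ml",
    "pairwise_hky",
    "lrt",
    "bootstrap_branches",
]

MIN_BL = 1e-9
MAX_BL = 20.0
LOG_PARAM_BOUNDS = (np.log(1e-4), np.log(1e3))
DEFAULT_CLASS = "all"


class DataError(ValueError):
    pass


class NestingError(ValueError):
    pass


@dataclass
class FitResult:
    tree: Tree
    params: dict
    lnL: float
    n_params: int
    converged: bool
    model: object = None  # HKYParams / MG94Params at the optimum

    def branch_lengths(self) -> dict[frozenset, float]:
        cm = self.tree.clade_map()
        return {k: n.length for k, n in cm.items() if not n.is_root}


@dataclass
class LRTResult:
    lnL0: float
    lnL1: float
    df: int
    statistic: float
    p_value: float


@dataclass
class PairwiseResult:
    t: float
    kappa: float
    lnL: float
    omega: Optional[float] = None
    dS: Optional[float] = None
    dN: Optional[float] = None
    TI: Optional[float] = None
    TV: Optional[float] = None
    saturated: bool = False


# --------------------------------------------------------------------------
# data encoding
# --------------------------------------------------------------------------


class Partition:
    """Compressed site patterns for one data partition."""

    def __init__(self, taxa: Sequence[str], states: np.ndarray, nstates: int):
        # states: (ntaxa, nsites) ints, -1 = missing
        patterns, weights = np.unique(states, axis=1, return_counts=True)
        self.taxa = list(taxa)
        self.patterns = patterns
        self.weights = weights.astype(float)
        self.nstates = nstates
        self.npat = patterns.shape[1]
        self._tip_partials: dict[str, np.ndarray] = {}
        eye = np.eye(nstates)
        for k, taxon in enumerate(self.taxa):
            col = patterns[k]
            part = np.ones((self.npat, nstates))
            obs = col >= 0
            part[obs] = eye[col[obs]]
            self._tip_partials[taxon] = part

    def tip_partial(self, name: str) -> np.ndarray:
        try:
            return self._tip_partials[name]
        except KeyError:
            raise DataError(f"taxon {name!r} missing from alignment") from None

    @property
    def nsites(self) -> float:
        return float(self.weights.sum())


def encode_nucleotides(rows: Mapping[str, str]) -> Partition:
    taxa = sorted(rows)
    lengths = {len(rows[t]) for t in taxa}
    if len(lengths) != 1:
        raise DataError("aligned sequences differ in length")
    states = np.full((len(taxa), lengths.pop()), -1, dtype=np.int64)
    for k, taxon in enumerate(taxa):
        for i, c in enumerate(rows[taxon].upper()):
            states[k, i] = NUC_INDEX.get(c, -1)
    return Partition(taxa, states, 4)


def encode_codons(aln: CodonAlignment) -> Partition:
    states = np.full((len(aln.taxa), aln.ncodons), -1, dtype=np.int64)
    for k, row in enumerate(aln.rows):
        for i, codon in enumerate(row):
            states[k, i] = CODON_INDEX.get(codon.upper(), -1)
    return Partition(aln.taxa, states, 61)


def _check_taxa(tree: Tree, part: Partition) -> None:
    tips = set(tree.leaf_names())
    if tips != set(part.taxa):
        raise DataError(
            f"tree tips and alignment taxa differ: "
            f"{sorted(tips ^ set(part.taxa))}"
        )


# --------------------------------------------------------------------------
# pruning
# --------------------------------------------------------------------------


def _down_arrays(tree: Tree, part: Partition, P_of: Mapping[int, np.ndarray]):
    """Post-order conditional likelihoods with per-node scaling.

    Returns (down, msg, logsc) where msg[v] = P_v @ down[v] is the message a
    non-root node sends to its parent and logsc[v] accumulates the log of the
    scalers applied within v's subtree.
    """
    nn = max(n.index for n in tree.postorder()) + 1
    down = [None] * nn
    msg = [None] * nn
    logsc = [np.zeros(part.npat)] * nn
    for node in tree.postorder():
        if node.is_leaf:
            d = part.tip_partial(node.name)
            ls = np.zeros(part.npat)
        else:
            d = np.ones((part.npat, part.nstates))
            ls = np.zeros(part.npat)
            for child in node.children:
                d = d * msg[child.index]
                ls = ls + logsc[child.index]
            scale = d.max(axis=1)
            scale[scale == 0.0] = 1.0
            d = d / scale[:, None]
            ls = ls + np.log(scale)
        down[node.index] = d
        logsc[node.index] = ls
        if not node.is_root:
            msg[node.index] = d @ P_of[node.index].T
    return down, msg, logsc


def _loglik_parts(
    tree: Tree, parts_data, pi_list
) -> float:
    """Sum of partition log-likelihoods; parts_data = [(part, P_of), ...]."""
    total = 0.0
    for (part, P_of), pi in zip(parts_data, pi_list):
        down, _, logsc = _down_arrays(tree, part, P_of)
        root = tree.root
        site = down[root.index] @ pi
        with np.errstate(divide="ignore"):
            lw = np.log(site) + logsc[root.index]
        total += float(np.dot(part.weights, lw))
    return total


def _out_arrays(tree: Tree, part: Partition, P_of, msg, logsc, pi):
    """Pre-order outside arrays: out[v][k] = P(data outside subtree(v) and
    root prior | state k at parent(v)), scaled, with log-scalers lout[v]."""
    nn = max(n.index for n in tree.postorder()) + 1
    out = [None] * nn
    lout = [None] * nn
    for node in tree.preorder():
        if node.is_root:
            base = np.tile(pi, (part.npat, 1))
            lbase = np.zeros(part.npat)
        else:
            base = out[node.index] @ P_of[node.index]
            lbase = lout[node.index]
            scale = base.max(axis=1)
            scale[scale == 0.0] = 1.0
            base = base / scale[:, None]
            lbase = lbase + np.log(scale)
        for child in node.children:
            o = base.copy()
            lo = lbase.copy()
            for sib in node.children:
                if sib is child:
                    continue
                o = o * msg[sib.index]
                lo = lo + logsc[sib.index]
            scale = o.max(axis=1)
            scale[scale == 0.0] = 1.0
            out[child.index] = o / scale[:, None]
            lout[child.index] = lo + np.log(scale)
    return out, lout


# --------------------------------------------------------------------------
# model wrappers: build per-branch P matrices
# --------------------------------------------------------------------------


def _branch_class(node: Node) -> str:
    return node.klass or DEFAULT_CLASS


class _BranchModel:
    """Per-branch rate matrices from class-level generators (or per-branch
    kappa for the HKY 'local parameters' mode)."""

    def __init__(
        self,
        matrices_by_class: Mapping[str, RateMatrix],
        per_branch: Optional[Mapping[int, RateMatrix]] = None,
    ):
        self.by_class = dict(matrices_by_class)
        self.per_branch = dict(per_branch or {})

    def matrix(self, node: Node) -> RateMatrix:
        if node.index in self.per_branch:
            return self.per_branch[node.index]
        try:
            return self.by_class[_branch_class(node)]
        except KeyError:
            raise DataError(
                f"no rate matrix for branch class {_branch_class(node)!r}"
            ) from None

    def P_of(self, tree: Tree) -> dict[int, np.ndarray]:
        return {
            n.index: self.matrix(n).transition_probs(n.length)
            for n in tree.branches()
        }

    @property
    def pi(self) -> np.ndarray:
        return next(iter(self.by_class.values())).pi


def _hky_branch_model(tree: Tree, params: HKYParams) -> _BranchModel:
    classes = {_branch_class(n) for n in tree.branches()}
    if params.per_branch_kappa:
        km = dict(params.per_branch_kappa)
        cm = tree.clade_map()
        per_branch = {}
        for key, kap in km.items():
            node = cm[frozenset(key)] if not isinstance(key, Node) else key
            per_branch[node.index] = hky_matrix(params, kappa=kap)
        base = hky_matrix(params)
        return _BranchModel({c: base for c in classes}, per_branch)
    base = hky_matrix(params)
    return _BranchModel({c: base for c in classes})


def _mg94_branch_model(tree: Tree, params: MG94Params) -> _BranchModel:
    classes = {_branch_class(n) for n in tree.branches()}
    mats = {}
    for c in classes:
        label = c if c in params.omega_by_class else DEFAULT_CLASS
        mats[c] = mg94_matrix(params, label)
    return _BranchModel(mats)


# --------------------------------------------------------------------------
# public log-likelihoods
# --------------------------------------------------------------------------


def loglik_hky(tree: Tree, rows: Mapping[str, str], params: HKYParams) -> float:
    part = encode_nucleotides(rows)
    _check_taxa(tree, part)
    bm = _hky_branch_model(tree, params)
    return _loglik_parts(tree, [(part, bm.P_of(tree))], [bm.pi])


def loglik_mg94(tree: Tree, aln: CodonAlignment, params: MG94Params) -> float:
    part = encode_codons(aln)
    _check_taxa(tree, part)
    bm = _mg94_branch_model(tree, params)
    return _loglik_parts(tree, [(part, bm.P_of(tree))], [bm.pi])


def loglik(tree: Tree, alignment, model) -> float:
    """Dispatch on the parameter object: HKYParams expects a mapping of
    aligned nucleotide rows, MG94Params a CodonAlignment."""
    if isinstance(model, HKYParams):
        return loglik_hky(tree, alignment, model)
    if isinstance(model, MG94Params):
        return loglik_mg94(tree, alignment, model)
    raise TypeError(f"unsupported model {type(model).__name__}")


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


class _FitProblem:
    """Shared-branch-length likelihood over one or more data partitions."""

    def __init__(self, tree: Tree, partitions, builder, theta0, bounds, names):
        # builder(theta) -> list[_BranchModel], one per partition
        self.tree = tree
        self.partitions = partitions
        self.builder = builder
        self.theta = np.asarray(theta0, dtype=float)
        self.bounds = bounds
        self.names = names

    def loglik(self, theta=None) -> float:
        theta = self.theta if theta is None else theta
        models = self.builder(theta)
        parts = [(p, m.P_of(self.tree)) for p, m in zip(self.partitions, models)]
        return _loglik_parts(self.tree, parts, [m.pi for m in models])

    def optimize_theta(self) -> float:
        if len(self.theta) == 0:
            return self.loglik()
        res = minimize(
            lambda th: -self.loglik(th),
            self.theta,
            method="L-BFGS-B",
            bounds=self.bounds,
            options=dict(maxiter=200, ftol=1e-12),
        )
        self.theta = res.x
        return -res.fun

    def sweep_branches(self) -> float:
        """One round of bounded-Brent updates on every branch length."""
        models = self.builder(self.theta)
        for node in self.tree.branches():
            edge_data = []
            for part, bm in zip(self.partitions, models):
                P_of = bm.P_of(self.tree)
                down, msg, logsc = _down_arrays(self.tree, part, P_of)
                out, lout = _out_arrays(self.tree, part, P_of, msg, logsc, bm.pi)
                edge_data.append(
                    (
                        part,
                        bm.matrix(node),
                        down[node.index],
                        logsc[node.index],
                        out[node.index],
                        lout[node.index],
                    )
                )

            def neg_edge(t: float) -> float:
                total = 0.0
                for part, rm, D, ld, O, lo in edge_data:
                    P = rm.transition_probs(t)
                    site = np.einsum("pk,kj,pj->p", O, P, D)
                    with np.errstate(divide="ignore"):
                        lw = np.log(site) + ld + lo
                    total += float(np.dot(part.weights, lw))
                return -total

            res = minimize_scalar(
                neg_edge,
                bounds=(MIN_BL, MAX_BL),
                method="bounded",
                options=dict(xatol=1e-8),
            )
            if -res.fun >= -neg_edge(node.length):
                node.length = float(res.x)
        return self.loglik()

    def run(self, max_rounds: int = 50, tol: float = 1e-8):
        last = -np.inf
        converged = False
        lnL = self.loglik()
        for _ in range(max_rounds):
            self.sweep_branches()
            lnL = self.optimize_theta()
            if abs(lnL - last) < tol:
                converged = True
                break
            last = lnL
        return lnL, converged


def _sanitize_lengths(tree: Tree) -> None:
    """Bring starting branch lengths onto the substitutions/site scale.

    Input topologies may carry time-scaled lengths (e.g. a chronogram in My);
    starting a fit there parks every P(t) at stationarity and strands the
    optimizer, so overlong trees are shrunk and all lengths clipped into the
    search box."""
    mx = max((n.length for n in tree.branches()), default=0.0)
    if mx > 5.0:
        scale = 0.5 / mx
        for n in tree.branches():
            n.length *= scale
    for n in tree.branches():
        n.length = min(max(n.length, 1e-6), MAX_BL)


def _empirical_pi(rows: Mapping[str, str]) -> np.ndarray:
    counts = np.zeros(4)
    for seq in rows.values():
        for c in seq.upper():
            k = NUC_INDEX.get(c)
            if k is not None:
                counts[k] += 1
    if counts.sum() == 0:
        raise DataError("no unambiguous bases in alignment")
    return counts / counts.sum()


def fit_hky(
    tree: Tree,
    rows: Mapping[str, str],
    kappa_mode: str = "global",
    pi: Optional[np.ndarray] = None,
    partition_rows: Optional[Sequence[Mapping[str, str]]] = None,
    max_rounds: int = 50,
    tol: float = 1e-8,
) -> FitResult:
    """ML fit of the HKY85 model on a fixed topology.

    kappa_mode: 'global' (one kappa), 'by_class' (one kappa per branch-class
    label on the tree), 'per_branch' (HyPhy-style local parameters: each
    branch gets its own kappa and length), or 'by_region' (one kappa per
    entry of ``partition_rows``, branch lengths shared across partitions
    with a free per-partition rate multiplier for every partition after the
    first).
    """
    work = tree.copy()
    _sanitize_lengths(work)
    if partition_rows is None:
        partition_rows = [rows]
    parts = [encode_nucleotides(r) for r in partition_rows]
    for p in parts:
        _check_taxa(work, p)
    pi = _empirical_pi(rows) if pi is None else np.asarray(pi, float)
    classes = sorted({_branch_class(n) for n in work.branches()})

    if kappa_mode == "per_branch":
        return _fit_hky_local(work, parts[0], pi, max_rounds, tol)

    if kappa_mode == "global":
        names = ["kappa"]
    elif kappa_mode == "by_class":
        names = [f"kappa:{c}" for c in classes]
    elif kappa_mode == "by_region":
        names = [f"kappa:part{i}" for i in range(len(parts))]
    else:
        raise ValueError(f"unknown kappa_mode {kappa_mode!r}")
    # free rate multiplier for partitions beyond the first
    names += [f"rate:part{i}" for i in range(1, len(parts))]

    def builder(theta):
        vals = dict(zip(names, np.exp(theta)))
        models = []
        for i in range(len(parts)):
            if kappa_mode == "global":
                kap = {c: vals["kappa"] for c in classes}
            elif kappa_mode == "by_class":
                kap = {c: vals[f"kappa:{c}"] for c in classes}
            else:
                kap = {c: vals[f"kappa:part{i}"] for c in classes}
            base = HKYParams(kappa=2.0, pi=pi)
            mult = vals.get(f"rate:part{i}", 1.0)
            mats = {
                c: _scaled_matrix(hky_matrix(base, kappa=kap[c]), mult)
                for c in classes
            }
            models.append(_BranchModel(mats))
        return models

    theta0 = np.zeros(len(names)) + np.log(2.0)
    theta0[[n.startswith("rate:") for n in names]] = 0.0
    problem = _FitProblem(
        work, parts, builder, theta0,
        [LOG_PARAM_BOUNDS] * len(names), names,
    )
    lnL, converged = problem.run(max_rounds, tol)
    vals = dict(zip(names, np.exp(problem.theta)))
    kappas = {k.split(":", 1)[1]: v for k, v in vals.items() if k.startswith("kappa:")}
    params = {
        "pi": pi,
        "kappa": vals.get("kappa", kappas or None),
        "rate_multipliers": {
            k.split(":", 1)[1]: v for k, v in vals.items() if k.startswith("rate:")
        },
    }
    n_params = len(names) + len(work.branches())
    model = HKYParams(
        kappa=vals.get("kappa", next(iter(kappas.values()), 2.0)), pi=pi
    )
    return FitResult(work, params, lnL, n_params, converged, model)


def _scaled_matrix(rm: RateMatrix, mult: float) -> RateMatrix:
    if mult == 1.0:
        return rm
    return RateMatrix(rm.Q * mult, rm.pi)


def _fit_hky_local(tree, part, pi, max_rounds, tol) -> FitResult:
    """HyPhy-style local HKY fit: per-branch (t, kappa)."""
    kappas = {n.index: 2.0 for n in tree.branches()}

    def model() -> _BranchModel:
        base = HKYParams(kappa=2.0, pi=pi)
        per_branch = {
            i: hky_matrix(base, kappa=k) for i, k in kappas.items()
        }
        return _BranchModel({DEFAULT_CLASS: hky_matrix(base)}, per_branch)

    def full_lnL() -> float:
        bm = model()
        return _loglik_parts(tree, [(part, bm.P_of(tree))], [bm.pi])

    last = -np.inf
    converged = False
    base_params = HKYParams(kappa=2.0, pi=pi)
    for _ in range(max_rounds):
        for node in tree.branches():
            bm = model()
            P_of = bm.P_of(tree)
            down, msg, logsc = _down_arrays(tree, part, P_of)
            out, lout = _out_arrays(tree, part, P_of, msg, logsc, bm.pi)
            D, ld = down[node.index], logsc[node.index]
            O, lo = out[node.index], lout[node.index]

            def neg(tk) -> float:
                t, logk = tk
                rm = hky_matrix(base_params, kappa=float(np.exp(logk)))
                P = rm.transition_probs(t)
                site = np.einsum("pk,kj,pj->p", O, P, D)
                with np.errstate(divide="ignore"):
                    lw = np.log(site) + ld + lo
                return -float(np.dot(part.weights, lw))

            res = minimize(
                neg,
                [max(node.length, 1e-4), np.log(kappas[node.index])],
                method="L-BFGS-B",
                bounds=[(MIN_BL, MAX_BL), LOG_PARAM_BOUNDS],
            )
            if res.fun <= neg([node.length, np.log(kappas[node.index])]):
                node.length = float(res.x[0])
                kappas[node.index] = float(np.exp(res.x[1]))
        lnL = full_lnL()
        if abs(lnL - last) < tol:
            converged = True
            break
        last = lnL
    cm = {n.index: n for n in tree.branches()}
    kap_by_clade = {
        tree.clade_key(cm[i]): k for i, k in kappas.items()
    }
    params = {"pi": pi, "kappa_by_branch": kap_by_clade}
    n_params = 2 * len(tree.branches())
    model_out = HKYParams(kappa=2.0, pi=pi, per_branch_kappa=kap_by_clade)
    return FitResult(tree, params, lnL, n_params, converged, model_out)


def fit_mg94(
    tree: Tree,
    aln: CodonAlignment,
    omega_mode: str = "global",
    pos_freqs: Optional[np.ndarray] = None,
    max_rounds: int = 50,
    tol: float = 1e-8,
) -> FitResult:
    """ML fit of MG94xHKY85 with shared kappa and F3x4 frequencies.

    omega_mode: 'global' (one dN/dS), 'by_class' (one per branch-class
    label), or 'by_region' (partitioned fit over the alignment's SC/IR
    partition: shared branch lengths and kappa, one omega per region plus a
    free region rate multiplier).
    """
    work = tree.copy()
    _sanitize_lengths(work)
    if pos_freqs is None:
        pos_freqs = position_frequencies(aln.rows)
    classes = sorted({_branch_class(n) for n in work.branches()})

    if omega_mode == "by_region":
        if aln.partition is None:
            raise DataError("by_region fit requires a partitioned alignment")
        labels = sorted(set(aln.partition))
        sub = [aln.subset_partition(lab) for lab in labels]
        parts = [encode_codons(s) for s in sub]
        names = [f"kappa"] + [f"omega:{lab}" for lab in labels]
        names += [f"rate:{lab}" for lab in labels[1:]]

        def builder(theta):
            vals = dict(zip(names, np.exp(theta)))
            models = []
            for i, lab in enumerate(labels):
                mp = MG94Params(
                    kappa=vals["kappa"],
                    omega_by_class={c: vals[f"omega:{lab}"] for c in classes},
                    pos_freqs=pos_freqs,
                )
                mats = {
                    c: _scaled_matrix(mg94_matrix(mp, c), vals.get(f"rate:{lab}", 1.0))
                    for c in classes
                }
                models.append(_BranchModel(mats))
            return models

        theta0 = np.concatenate(
            [[np.log(2.0)], np.full(len(labels), np.log(0.2)), np.zeros(len(labels) - 1)]
        )
    else:
        parts = [encode_codons(aln)]
        if omega_mode == "global":
            omega_names = ["omega"]
        elif omega_mode == "by_class":
            omega_names = [f"omega:{c}" for c in classes]
        else:
            raise ValueError(f"unknown omega_mode {omega_mode!r}")
        names = ["kappa"] + omega_names

        def builder(theta):
            vals = dict(zip(names, np.exp(theta)))
            if omega_mode == "global":
                omegas = {c: vals["omega"] for c in classes}
            else:
                omegas = {c: vals[f"omega:{c}"] for c in classes}
            mp = MG94Params(
                kappa=vals["kappa"], omega_by_class=omegas, pos_freqs=pos_freqs
            )
            return [_BranchModel({c: mg94_matrix(mp, c) for c in classes})]

        theta0 = np.concatenate([[np.log(2.0)], np.full(len(names) - 1, np.log(0.2))])

    for p in parts:
        _check_taxa(work, p)
    problem = _FitProblem(
        work, parts, builder, theta0, [LOG_PARAM_BOUNDS] * len(names), names
    )
    lnL, converged = problem.run(max_rounds, tol)
    vals = dict(zip(names, np.exp(problem.theta)))
    omegas = {k.split(":", 1)[1]: v for k, v in vals.items() if k.startswith("omega:")}
    params = {
        "kappa": vals["kappa"],
        "omega": vals.get("omega", omegas or None),
        "pos_freqs": pos_freqs,
        "rate_multipliers": {
            k.split(":", 1)[1]: v for k, v in vals.items() if k.startswith("rate:")
        },
    }
    if omega_mode == "global":
        omega_by_class = {c: vals["omega"] for c in classes}
    elif omega_mode == "by_class":
        omega_by_class = {c: omegas[c] for c in classes}
    else:
        omega_by_class = dict(omegas)
    model = MG94Params(
        kappa=vals["kappa"], omega_by_class=omega_by_class, pos_freqs=pos_freqs
    )
    n_params = len(names) + len(work.branches())
    return FitResult(work, params, lnL, n_params, converged, model)


# --------------------------------------------------------------------------
# pairwise maximum likelihood
# --------------------------------------------------------------------------


def _pair_counts(a: str, b: str, index: Mapping[str, int], width: int):
    if len(a) != len(b):
        raise DataError("pairwise sequences differ in length")
    n = len(index)
    counts = np.zeros((n, n))
    for i in range(0, len(a), width):
        x = index.get(a[i : i + width].upper())
        y = index.get(b[i : i + width].upper())
        if x is not None and y is not None:
            counts[x, y] += 1
    return counts


def pairwise_ml(
    cds_a: str,
    cds_b: str,
    pos_freqs: Optional[np.ndarray] = None,
) -> PairwiseResult:
    """codeml-style pairwise codon ML (runmode=-2 analogue): optimize
    (t, kappa, omega) on the two-sequence tree, return dS/dN."""
    rows = [
        [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)],
        [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)],
    ]
    if pos_freqs is None:
        pos_freqs = position_frequencies(rows)
    counts = _pair_counts(cds_a, cds_b, CODON_INDEX, 3)

    def build(kappa, omega):
        return mg94_matrix(
            MG94Params(kappa=kappa, omega_by_class={"all": omega}, pos_freqs=pos_freqs),
            "all",
        )

    def neg(x):
        t, kap, om = np.exp(x)
        rm = build(kap, om)
        P = rm.transition_probs(t)
        with np.errstate(divide="ignore"):
            M = np.log(np.maximum(rm.pi[:, None] * P, 1e-300))
        return -float((counts * M).sum())

    identical = np.allclose(counts, np.diag(np.diag(counts)))
    x0 = np.log([max(0.05, 1e-3), 2.0, 0.2])
    res = minimize(
        neg,
        x0,
        method="L-BFGS-B",
        bounds=[(np.log(MIN_BL), np.log(MAX_BL)), LOG_PARAM_BOUNDS, LOG_PARAM_BOUNDS],
    )
    t, kap, om = np.exp(res.x)
    if identical:
        t = 0.0
    mp = MG94Params(kappa=kap, omega_by_class={"all": om}, pos_freqs=pos_freqs)
    ds, dn = decompose_sn(mp, "all", t)
    return PairwiseResult(
        t=float(t),
        kappa=float(kap),
        omega=float(om),
        dS=float(ds),
        dN=float(dn),
        lnL=-float(res.fun),
        saturated=bool(t > 0.98 * MAX_BL),
    )


def pairwise_hky(
    seq_a: str, seq_b: str, pi: Optional[np.ndarray] = None
) -> PairwiseResult:
    """Pairwise HKY85 ML: optimize (t, kappa), return expected TI/TV per site."""
    if pi is None:
        pi = _empirical_pi({"a": seq_a, "b": seq_b})
    counts = _pair_counts(seq_a, seq_b, NUC_INDEX, 1)
    base = HKYParams(kappa=2.0, pi=pi)

    def neg(x):
        t, kap = np.exp(x)
        rm = hky_matrix(base, kappa=kap)
        P = rm.transition_probs(t)
        with np.errstate(divide="ignore"):
            M = np.log(np.maximum(rm.pi[:, None] * P, 1e-300))
        return -float((counts * M).sum())

    identical = np.allclose(counts, np.diag(np.diag(counts)))
    res = minimize(
        neg,
        np.log([0.05, 2.0]),
        method="L-BFGS-B",
        bounds=[(np.log(MIN_BL), np.log(MAX_BL)), LOG_PARAM_BOUNDS],
    )
    t, kap = np.exp(res.x)
    if identical:
        t = 0.0
    ti, tv = decompose_titv(base, float(t), kappa=float(kap))
    return PairwiseResult(
        t=float(t),
        kappa=float(kap),
        TI=float(ti),
        TV=float(tv),
        lnL=-float(res.fun),
        saturated=bool(t > 0.98 * MAX_BL),
    )


# --------------------------------------------------------------------------
# likelihood-ratio test
# --------------------------------------------------------------------------


def lrt(fit0, fit1, df: int, tolerance: float = 1e-6) -> LRTResult:
    """Chi-square LRT of nested fits (fit0 nested in fit1)."""
    lnL0 = fit0.lnL if hasattr(fit0, "lnL") else float(fit0)
    lnL1 = fit1.lnL if hasattr(fit1, "lnL") else float(fit1)
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnL1 - lnL0)
    if stat < -2.0 * tolerance * max(1.0, abs(lnL0)):
        raise NestingError(
            f"alternative lnL {lnL1:.6f} below null {lnL0:.6f}: models not nested "
            f"or optimization failed"
        )
    stat = max(stat, 0.0)
    return LRTResult(lnL0, lnL1, df, stat, float(chi2.sf(stat, df)))


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------


def bootstrap_branches(
    aln: CodonAlignment,
    tree: Tree,
    model: MG94Params,
    n_reps: int = 100,
    seed: int = 0,
    max_rounds: int = 8,
) -> dict[frozenset, float]:
    """Column-resampling bootstrap SEs of branch lengths.

    Codon columns are resampled with replacement; branch lengths are refit
    per replicate with the model parameters held at their estimates; the SE
    is the sample standard deviation over replicates, keyed by the branch's
    descendant-tip set.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    keys = [tree.clade_key(n) for n in tree.branches()]
    samples = {k: [] for k in keys}
    classes = sorted({_branch_class(n) for n in tree.branches()})
    for _ in range(n_reps):
        idx = rng.integers(0, aln.ncodons, size=aln.ncodons)
        rows = [[row[i] for i in idx] for row in aln.rows]
        part = encode_codons(CodonAlignment(aln.taxa, rows))
        work = tree.copy()

        def builder(_theta):
            return [_BranchModel({c: mg94_matrix(model, c if c in model.omega_by_class else DEFAULT_CLASS) for c in classes})]

        problem = _FitProblem(work, [part], builder, np.zeros(0), [], [])
        problem.run(max_rounds=max_rounds, tol=1e-6)
        cm = work.clade_map()
        for k in keys:
            samples[k].append(cm[k].length)
    return {k: float(np.std(v, ddof=1)) for k, v in samples.items()}
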