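"""HKY85 nucleotide and MG94xHKY85 codon substitution models.

Both models are time-reversible continuous-time Markov chains. The codon
model lives on the 61 sense codons of the bacterial/plastid genetic code
(NCBI translation table 11); a single-nucleotide change is weighted by the
target nucleotide's position-specific frequency (F3x4), multiplied by the
transition/transversion ratio kappa when the change is a transition and by
omega (dN/dS) when it is nonsynonymous. Generators are normalized to one
expected substitution per site per unit branch length, so branch lengths are
in substitutions/site.

Branch lengths decompose into synonymous/nonsynonymous components (dS, dN;
codeml's mutational-opportunity convention, so dN/dS recovers omega exactly)
and, for the nucleotide model, into expected transitions and transversions
per site (TI, TV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "NUCS",
    "CODONS",
    "CODON_INDEX",
    "STOP_CODONS",
    "GENETIC_CODE",
    "HKYParams",
    "MG94Params",
    "RateMatrix",
    "ModelParameterError",
    "hky_matrix",
    "mg94_matrix",
    "transition_probs",
    "f3x4_frequencies",
    "position_frequencies",
    "codon_freqs_from_positions",
    "decompose_sn",
    "decompose_titv",
    "translate_codon",
    "is_transition",
]

NUCS = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

def _codon_table() -> dict[str, str]:
    # NCBI translation table 11 (bacterial/archaeal/plant plastid), taken from
    # Biopython.  Its codon->amino-acid map equals the standard code; it
    # differs only in allowed initiators, which do not matter for rate models.
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    t11 = unambiguous_dna_by_id[11]
    table = dict(t11.forward_table)
    for stop in t11.stop_codons:
        table[stop] = "*"
    return table


GENETIC_CODE: dict[str, str] = _codon_table()
STOP_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa == "*"))
CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
N_CODONS = len(CODONS)  # 61

_FREQ_FLOOR = 1e-10


class ModelParameterError(ValueError):
    pass


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon.upper()]


def is_transition(a: str, b: str) -> bool:
    """Purine<->purine or pyrimidine<->pyrimidine interchange."""
    return {a, b} in ({"A", "G"}, {"C", "T"})


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass
class HKYParams:
    kappa: float = 2.0
    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    per_branch_kappa: Optional[Mapping[object, float]] = None

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        _check_kappa(self.kappa)
        _check_simplex(self.pi, 4)


@dataclass
class MG94Params:
    """Codon-model parameters: kappa shared, omega per branch class.

    ``pos_freqs`` is the 3x4 matrix of position-specific nucleotide
    frequencies (rows sum to 1); the 61-codon equilibrium vector is the F3x4
    product measure renormalized over sense codons.
    """

    kappa: float
    omega_by_class: Mapping[str, float]
    pos_freqs: np.ndarray = field(
        default_factory=lambda: np.full((3, 4), 0.25)
    )

    def __post_init__(self):
        _check_kappa(self.kappa)
        for label, omega in self.omega_by_class.items():
            if not (omega >= 0.0 and np.isfinite(omega)):
                raise ModelParameterError(f"omega for class {label!r} must be >= 0")
        self.pos_freqs = _floor_positions(np.asarray(self.pos_freqs, dtype=float))

    @property
    def codon_freqs(self) -> np.ndarray:
        return codon_freqs_from_positions(self.pos_freqs)


def _check_kappa(kappa: float) -> None:
    if not (kappa > 0 and np.isfinite(kappa)):
        raise ModelParameterError("kappa must be finite and > 0")


def _check_simplex(v: np.ndarray, n: int) -> None:
    if v.shape != (n,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-8:
        raise ModelParameterError(f"frequency vector must be length {n}, >= 0, sum 1")


def _floor_positions(pos: np.ndarray) -> np.ndarray:
    if pos.shape != (3, 4):
        raise ModelParameterError("pos_freqs must be 3x4")
    if np.any(pos < 0):
        raise ModelParameterError("pos_freqs must be >= 0")
    pos = np.maximum(pos, _FREQ_FLOOR)
    return pos / pos.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# rate matrices
# --------------------------------------------------------------------------


class RateMatrix:
    """Normalized reversible generator with a cached spectral decomposition.

    P(t) = exp(Qt) is computed through the symmetric similarity transform
    S = D^{1/2} Q D^{-1/2} (D = diag(pi)), which is numerically stable for
    reversible Q; a scaling-and-squaring expm fallback guards near-degenerate
    frequency vectors.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = np.asarray(Q, dtype=float)
        self.pi = np.asarray(pi, dtype=float)
        self.scale = float(-np.sum(self.pi * np.diag(self.Q)))
        self._decompose()

    def _decompose(self) -> None:
        sq = np.sqrt(self.pi)
        try:
            S = (sq[:, None] * self.Q) / sq[None, :]
            S = 0.5 * (S + S.T)
            w, V = np.linalg.eigh(S)
            self.eigvals = w
            self._left = V / sq[:, None]  # D^{-1/2} V
            self._right = V.T * sq[None, :]  # V^T D^{1/2}
            self._sym_ok = True
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate guard
            self._sym_ok = False

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]

    def transition_probs(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length t must be >= 0")
        if not self._sym_ok:  # pragma: no cover - degenerate guard
            from scipy.linalg import expm

            return expm(self.Q * t)
        P = (self._left * np.exp(self.eigvals * t)) @ self._right
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def hky_matrix(params: HKYParams, kappa: Optional[float] = None) -> RateMatrix:
    """HKY85 generator, normalized to one expected substitution/site/unit t."""
    kappa = params.kappa if kappa is None else kappa
    _check_kappa(kappa)
    pi = params.pi
    Q = np.zeros((4, 4))
    for i, a in enumerate(NUCS):
        for j, b in enumerate(NUCS):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if is_transition(a, b) else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.sum(pi * np.diag(Q))
    Q /= mu
    return RateMatrix(Q, pi)


# single-nucleotide codon neighbourhood, computed once
def _codon_moves():
    moves = []  # (i, j, position, target_nt_index, transition?, synonymous?)
    for i, ci in enumerate(CODONS):
        for pos in range(3):
            for nt in NUCS:
                if nt == ci[pos]:
                    continue
                cj = ci[:pos] + nt + ci[pos + 1 :]
                j = CODON_INDEX.get(cj)
                if j is None:  # stop codon target
                    continue
                moves.append(
                    (
                        i,
                        j,
                        pos,
                        NUC_INDEX[nt],
                        is_transition(ci[pos], nt),
                        GENETIC_CODE[ci] == GENETIC_CODE[cj],
                    )
                )
    return (
        np.array([m[0] for m in moves], dtype=int),
        np.array([m[1] for m in moves], dtype=int),
        np.array([m[2] for m in moves], dtype=int),
        np.array([m[3] for m in moves], dtype=int),
        np.array([m[4] for m in moves], dtype=bool),
        np.array([m[5] for m in moves], dtype=bool),
    )


_MOV_I, _MOV_J, _MOV_POS, _MOV_NT, _MOV_TI, _MOV_SYN = _codon_moves()


def codon_freqs_from_positions(pos_freqs: np.ndarray) -> np.ndarray:
    """F3x4 codon equilibrium: product of positional frequencies over the 61
    sense codons, renormalized to sum 1."""
    pos = _floor_positions(np.asarray(pos_freqs, dtype=float))
    freqs = np.empty(N_CODONS)
    for i, codon in enumerate(CODONS):
        freqs[i] = pos[0, NUC_INDEX[codon[0]]] * pos[1, NUC_INDEX[codon[1]]] * pos[2, NUC_INDEX[codon[2]]]
    return freqs / freqs.sum()


def mg94_matrix(params: MG94Params, class_label: str) -> RateMatrix:
    """MG94xHKY85 codon generator for one branch class."""
    if class_label not in params.omega_by_class:
        raise ModelParameterError(f"unknown branch class {class_label!r}")
    omega = params.omega_by_class[class_label]
    return _mg94_q(params.kappa, omega, params.pos_freqs)


def _mg94_q(kappa: float, omega: float, pos_freqs: np.ndarray) -> RateMatrix:
    pos = _floor_positions(pos_freqs)
    rates = pos[_MOV_POS, _MOV_NT].copy()
    rates[_MOV_TI] *= kappa
    rates[~_MOV_SYN] *= omega
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[_MOV_I, _MOV_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    pi = codon_freqs_from_positions(pos)
    mu = -np.sum(pi * np.diag(Q))
    Q /= mu
    return RateMatrix(Q, pi)


def transition_probs(Q: RateMatrix, t: float) -> np.ndarray:
    return Q.transition_probs(t)


# --------------------------------------------------------------------------
# empirical frequencies
# --------------------------------------------------------------------------


def position_frequencies(codon_rows: Sequence[Sequence[str]]) -> np.ndarray:
    """Position-specific nucleotide frequencies from codon rows (gaps and
    ambiguous bases ignored)."""
    counts = np.zeros((3, 4))
    for row in codon_rows:
        for codon in row:
            for pos, nt in enumerate(codon.upper()):
                k = NUC_INDEX.get(nt)
                if k is not None:
                    counts[pos, k] += 1
    if counts.sum() == 0:
        raise ValueError("empty codon alignment: no unambiguous bases")
    return _floor_positions(counts / counts.sum(axis=1, keepdims=True))


def f3x4_frequencies(codon_rows: Sequence[Sequence[str]]) -> np.ndarray:
    """F3x4 codon frequency vector (codeml CodonFreq=2) from a codon alignment."""
    return codon_freqs_from_positions(position_frequencies(codon_rows))


# --------------------------------------------------------------------------
# branch-length decompositions
# --------------------------------------------------------------------------


def decompose_sn(params: MG94Params, class_label: str, t: float) -> tuple[float, float]:
    """Split a codon branch length into (dS, dN).

    The expected synonymous/nonsynonymous substitution flows of the class
    generator are divided by the neutral (omega=1) flow proportions, i.e. by
    the proportions of synonymous and nonsynonymous mutational opportunity,
    so that dN/dS equals the class omega exactly.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if class_label not in params.omega_by_class:
        raise ModelParameterError(f"unknown branch class {class_label!r}")
    rho_s = _syn_flow(params.kappa, params.omega_by_class[class_label], params.pos_freqs)
    p_s = _syn_flow(params.kappa, 1.0, params.pos_freqs)
    ds = t * rho_s / p_s
    dn = t * (1.0 - rho_s) / (1.0 - p_s)
    return ds, dn


def _syn_flow(kappa: float, omega: float, pos_freqs: np.ndarray) -> float:
    """Fraction of the (normalized) substitution flow that is synonymous."""
    rm = _mg94_q(kappa, omega, pos_freqs)
    flow = rm.pi[_MOV_I] * rm.Q[_MOV_I, _MOV_J]
    total = flow.sum()
    return float(flow[_MOV_SYN].sum() / total)


def decompose_titv(
    params: HKYParams, t: float, kappa: Optional[float] = None
) -> tuple[float, float]:
    """Split a nucleotide branch length into expected (TI, TV) per site."""
    if t < 0:
        raise ValueError("t must be >= 0")
    rm = hky_matrix(params, kappa=kappa)
    ti_share = 0.0
    for i, a in enumerate(NUCS):
        for j, b in enumerate(NUCS):
            if i != j and is_transition(a, b):
                ti_share += rm.pi[i] * rm.Q[i, j]
    # Q is normalized, so total flow is 1 and ti_share is the TI fraction
    return t * ti_share, t * (1.0 - ti_share)
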