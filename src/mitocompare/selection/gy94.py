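"""Goldman–Yang codon substitution machinery.

The GY94 rate matrix between sense codons i≠j differing at exactly one
position is

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

zero for multi-step changes, with the diagonal closing rows to zero.
Codon frequencies pi come from F3x4 (position-specific nucleotide
frequencies, renormalized over sense codons).  The chain is reversible,
so transition probabilities are computed by a symmetrized
eigendecomposition, which is also what makes mixture likelihoods and
exact simulation cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..genetic_code import VERTEBRATE_MITO, GeneticCode

_NT_INDEX = {"T": 0, "C": 1, "A": 2, "G": 3}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class CodonStructure:
    """Cached single-step structure of a genetic code's sense codons."""

    code: GeneticCode
    codons: tuple[str, ...]
    index: dict
    diff: np.ndarray      # bool (n, n): exactly one differing position
    transition: np.ndarray  # bool: that difference is a transition
    synonymous: np.ndarray  # bool: same amino acid
    nt_pos: np.ndarray    # (n, 3) nucleotide index per codon position


_STRUCT_CACHE: dict[int, CodonStructure] = {}


def structure(code: GeneticCode = VERTEBRATE_MITO) -> CodonStructure:
    if code.table_id in _STRUCT_CACHE:
        return _STRUCT_CACHE[code.table_id]
    codons = code.sense_codons
    n = len(codons)
    diff = np.zeros((n, n), dtype=bool)
    ts = np.zeros((n, n), dtype=bool)
    syn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            diff[i, j] = True
            ts[i, j] = diffs[0] in _TRANSITIONS
            syn[i, j] = code.codon_to_aa[ci] == code.codon_to_aa[cj]
    nt_pos = np.array(
        [[_NT_INDEX[ch] for ch in c] for c in codons], dtype=int
    )
    st = CodonStructure(
        code=code, codons=codons, index={c: k for k, c in enumerate(codons)},
        diff=diff, transition=ts, synonymous=syn, nt_pos=nt_pos,
    )
    _STRUCT_CACHE[code.table_id] = st
    return st


def f3x4_frequencies(
    sequences: list[str], code: GeneticCode = VERTEBRATE_MITO,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """F3x4 equilibrium codon frequencies from aligned coding sequences.

    Nucleotide frequencies are tallied per codon position over all
    unambiguous codons (gaps skipped); stop codons are removed and the
    vector renormalized.  A small pseudocount keeps every sense codon
    reachable.
    """
    counts = np.full((3, 4), pseudocount)
    for s in sequences:
        s = s.upper().replace("U", "T")
        for i in range(len(s) // 3):
            codon = s[3 * i: 3 * i + 3]
            if any(ch not in "ACGT" for ch in codon):
                continue
            for pos, ch in enumerate(codon):
                counts[pos, _NT_INDEX[ch]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    st = structure(code)
    pi = (
        freqs[0, st.nt_pos[:, 0]]
        * freqs[1, st.nt_pos[:, 1]]
        * freqs[2, st.nt_pos[:, 2]]
    )
    return pi / pi.sum()


def pi_from_nt_freqs(
    nt_freqs: dict[str, float], code: GeneticCode = VERTEBRATE_MITO
) -> np.ndarray:
    """Sense-codon frequencies from one set of nucleotide frequencies
    applied to all three positions (an F1x4-style prior for simulation)."""
    st = structure(code)
    f = np.array([nt_freqs[b] for b in ("T", "C", "A", "G")], dtype=float)
    f = f / f.sum()
    pi = f[st.nt_pos[:, 0]] * f[st.nt_pos[:, 1]] * f[st.nt_pos[:, 2]]
    return pi / pi.sum()


def rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, st: CodonStructure
) -> tuple[np.ndarray, float]:
    """Unscaled GY94 generator and its mean rate −Σ pi_i q_ii."""
    Q = np.where(st.diff, pi[None, :], 0.0)
    Q = Q * np.where(st.transition, kappa, 1.0)
    Q = Q * np.where(st.diff & ~st.synonymous, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float(np.dot(pi, np.diag(Q)))
    return Q, rate


@dataclass(frozen=True)
class SpectralQ:
    """Eigendecomposition of a reversible generator: P(t) = L e^{Λt} R."""

    left: np.ndarray
    lam: np.ndarray
    right: np.ndarray

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.lam * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        return P


def decompose(Q: np.ndarray, pi: np.ndarray) -> SpectralQ:
    d = np.sqrt(np.maximum(pi, 1e-300))
    B = Q * (d[:, None] / d[None, :])
    B = 0.5 * (B + B.T)  # symmetrize against roundoff
    lam, U = np.linalg.eigh(B)
    return SpectralQ(left=U / d[:, None], lam=lam, right=(U * d[:, None]).T)
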