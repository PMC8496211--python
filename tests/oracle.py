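"""Independent brute-force oracle for the forward engine.

Enumerates every uni-hit local state path explicitly (entry match state,
exit match state, and all match/insert/delete moves in between) and sums raw
path odds.  Shares no code with the dynamic-programming implementation; only
feasible for tiny profiles (M <= 3) and short sequences (length <= 4).
"""

from __future__ import annotations

import math

import numpy as np

from orthohunt.io import AMINO_INDEX, ProfileHMM


def brute_force_bitscore(hmm: ProfileHMM, residues: str) -> float:
    L, M = len(residues), hmm.M
    x = [AMINO_INDEX[c] for c in residues]
    bg = hmm.background
    me = np.exp(hmm.match_emissions)
    ie = np.exp(hmm.insert_emissions)
    with np.errstate(over="ignore"):
        t = np.exp(hmm.transitions)
    t = np.nan_to_num(t, posinf=0.0)

    modds = me / bg[None, :]
    iodds = ie / bg[None, :]
    p = L / (L + 2.0)
    q = 2.0 / (L + 2.0)
    entry = 2.0 / (M * (M + 1.0))
    total = 0.0

    def from_match(node: int, i: int, odds: float) -> None:
        """At match state `node` (0-based) having just emitted residue i."""
        nonlocal total
        total += odds * p ** (L - 1 - i)  # exit here; trailing flank loops
        if node < M - 1:
            if i + 1 < L:
                from_match(node + 1, i + 1, odds * t[node, 0] * modds[node + 1, x[i + 1]])
                from_insert(node, i + 1, odds * t[node, 1] * iodds[node, x[i + 1]])
            from_delete(node + 1, i, odds * t[node, 2])

    def from_insert(node: int, i: int, odds: float) -> None:
        if i + 1 < L:
            if node < M - 1:
                from_match(node + 1, i + 1, odds * t[node, 3] * modds[node + 1, x[i + 1]])
            from_insert(node, i + 1, odds * t[node, 4] * iodds[node, x[i + 1]])

    def from_delete(node: int, i: int, odds: float) -> None:
        if node < M - 1 and i + 1 < L:
            from_match(node + 1, i + 1, odds * t[node, 5] * modds[node + 1, x[i + 1]])
        if node < M - 1:
            from_delete(node + 1, i, odds * t[node, 6])

    for i0 in range(L):  # first aligned residue
        for k in range(M):  # entry match state
            from_match(k, i0, entry * p ** i0 * modds[k, x[i0]])

    null_length = (L / (L + 1.0)) ** L * (1.0 / (L + 1.0))
    return math.log2(total * q * q / null_length)


def random_reduced_profile(M: int, rng: np.random.Generator) -> ProfileHMM:
    """A random tiny profile whose emissions concentrate on a 3-letter
    sub-alphabet {A, C, D}; transitions are proper per node."""
    match = np.full((M, 20), 0.06 / 17.0)
    insert = np.full((M, 20), 0.06 / 17.0)
    match[:, :3] = rng.dirichlet([1.0, 1.0, 1.0], size=M) * 0.94
    insert[:, :3] = rng.dirichlet([1.0, 1.0, 1.0], size=M) * 0.94
    trans = np.empty((M, 7))
    for k in range(M):
        mm, mi, md = rng.dirichlet([4.0, 1.0, 1.0])
        im, ii = rng.dirichlet([3.0, 1.0])
        dm, dd = rng.dirichlet([3.0, 1.0])
        trans[k] = [mm, mi, md, im, ii, dm, dd]
    trans[M - 1, 2] = 0.0  # no delete past the last node
    trans[M - 1, 6] = 0.0
    trans[M - 1, 5] = 1.0
    with np.errstate(divide="ignore"):
        log_trans = np.log(trans)
    return ProfileHMM(
        name=f"reduced{M}",
        match_emissions=np.log(match),
        insert_emissions=np.log(insert),
        transitions=log_trans,
        background=np.full(20, 0.05),
    )


def reduced_sequences(max_len: int = 4, alphabet: str = "ACD"):
    """Every sequence over the reduced alphabet up to ``max_len``."""
    seqs = [""]
    for _ in range(max_len):
        seqs = [s + a for s in seqs for a in alphabet]
        yield from seqs
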