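"""Independent brute-force oracles for the semi-Markov decoder.

Everything here works from the raw model probability tables with plain
Python loops and exhaustive enumeration of legal segmentations -- no code is
shared with the dynamic program under test beyond the model containers.
"""

from __future__ import annotations

import math

import numpy as np

from nuchmm.model import MAX_LINKER, NUC_LEN, TrainedModel, encode_sequence

__all__ = [
    "enumerate_placements", "oracle_log_nucleosome", "oracle_log_linker",
    "oracle_decode",
]


def enumerate_placements(n: int) -> list[list[int]]:
    """All legal sets of 0-based nucleosome start positions for an n-bp
    query: initial/final linkers of observed length 0..500, interior linkers
    of length 1..500, nucleosomes of exactly 147 bp."""
    out: list[list[int]] = [[]]

    def rec(prefix: list[int], next_min: int, first: bool) -> None:
        for s in range(next_min, n - NUC_LEN + 1):
            if first:
                if s > MAX_LINKER:
                    break
            elif s - next_min + 1 > MAX_LINKER:
                break
            placement = prefix + [s]
            if n - (s + NUC_LEN) <= MAX_LINKER:
                out.append(placement)
            rec(placement, s + NUC_LEN + 1, False)

    rec([], 0, True)
    return out


def oracle_log_nucleosome(codes: np.ndarray, s: int,
                          model: TrainedModel) -> float:
    nuc = model.nucleosome
    idx = 0
    for j in range(4):
        idx = idx * 4 + int(codes[s + j])
    total = math.log(nuc.freqN4[idx]) if nuc.freqN4[idx] > 0 else -math.inf
    for t in range(5, NUC_LEN + 1):
        ctx = 0
        for j in range(t - 5, t - 1):
            ctx = ctx * 4 + int(codes[s + j])
        p = nuc.tranN4[t - 5][ctx][int(codes[s + t - 1])]
        total += math.log(p) if p > 0 else -math.inf
    return total


def oracle_log_linker(codes: np.ndarray, a: int, b: int,
                      model: TrainedModel) -> float:
    link = model.linker
    tables = (link.tranL, link.tranL2, link.tranL3)
    p = link.freqL[int(codes[a])]
    total = math.log(p) if p > 0 else -math.inf
    for i in range(a + 1, b + 1):
        order = min(i - a, 4)
        ctx = 0
        for j in range(i - order, i):
            ctx = ctx * 4 + int(codes[j])
        table = link.tranL4 if order == 4 else tables[order - 1]
        p = table[ctx][int(codes[i])]
        total += math.log(p) if p > 0 else -math.inf
    return total


def _placement_score(codes, placement, model, logS, logPd, linker_cache):
    n = codes.shape[0]

    def linker(a: int, b: int) -> float:
        if (a, b) not in linker_cache:
            linker_cache[(a, b)] = oracle_log_linker(codes, a, b, model)
        return linker_cache[(a, b)]

    if not placement:
        return linker(0, n - 1)
    total = 0.0
    d0 = placement[0]
    total += logS[d0] + (linker(0, d0 - 1) if d0 else 0.0)
    prev_end = None
    for s in placement:
        if prev_end is not None:
            d = s - prev_end - 1
            total += logPd[d - 1] + linker(prev_end + 1, s - 1)
        total += oracle_log_nucleosome(codes, s, model)
        prev_end = s + NUC_LEN - 1
    df = n - 1 - prev_end
    total += logS[df] + (linker(prev_end + 1, n - 1) if df else 0.0)
    return total


def oracle_decode(seq: str, model: TrainedModel):
    """Exhaustive-enumeration decode of a short query.

    Returns (viterbi score, viterbi placement starts, total log-likelihood,
    pdyad vector, expected nucleosome count).
    """
    codes = encode_sequence(seq)
    n = codes.shape[0]
    s_arr = model.duration.survival()
    with np.errstate(divide="ignore"):
        logS = np.log(s_arr)
        logPd = np.log(model.duration.Pd)
    cache: dict = {}
    placements = enumerate_placements(n)
    scores = np.array([
        _placement_score(codes, p, model, logS, logPd, cache)
        for p in placements])
    best_i = int(np.argmax(scores))
    m = scores.max()
    z = float(m + np.log(np.exp(scores - m).sum()))
    pdyad = np.zeros(n)
    expected = 0.0
    for p, sc in zip(placements, scores):
        w = math.exp(sc - z)
        expected += w * len(p)
        for s in p:
            pdyad[s + 73] += w
    return float(scores[best_i]), placements[best_i], z, pdyad, expected


def placement_score(seq: str, placement: list[int],
                    model: TrainedModel) -> float:
    """Score one explicit placement (for checking the DP's returned path)."""
    codes = encode_sequence(seq)
    s_arr = model.duration.survival()
    with np.errstate(divide="ignore"):
        logS = np.log(s_arr)
        logPd = np.log(model.duration.Pd)
    return _placement_score(codes, placement, model, logS, logPd, {})
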