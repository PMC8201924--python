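"""Semi-Markov decoding over alternating nucleosome/linker states.

The generative model alternates a nucleosome state of fixed 147-bp duration
(emission: freqN4 + time-dependent tranN4) with a linker state whose duration
d is drawn from Pd on 1..500 bp (emission: the order-ramp linker chain).
State alternation is strict; two nucleosomes cannot touch because Pd's
support starts at 1 bp.

Boundary convention: the query may begin and end mid-linker.  An initial
linker of observed length d carries the survival weight S(d) = sum_{k>=d}
Pd(k) (S(0)=1: the query may start exactly at a nucleosome edge), and
symmetrically for the final linker.  Nucleosomes are never truncated, so a
query shorter than 147 bp decodes as all-linker.  A linker spanning the
whole query is truncated at both ends and carries duration weight 1 (no
duration boundary is observed), which guarantees a legal path for any input.

All dynamic programming is in natural-log space with max-shifted
log-sum-exp; time O(n * 500), memory O(n).  N bases are scored uniformly
(log 1/4) under both states so that decoding is defined on any input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .affinity import LinkerScorer, NucleosomeScorer, compute_hba, _as_codes
from .model import DYAD_OFFSET, MAX_LINKER, NUC_LEN, TrainedModel

_NEG_INF = -np.inf


def _lse(v: np.ndarray) -> float:
    m = np.max(v)
    if m == _NEG_INF:
        return _NEG_INF
    return float(m + np.log(np.sum(np.exp(v - m))))


class _Decoder:
    """Shared precomputation for Viterbi and forward-backward on one query."""

    def __init__(self, codes: np.ndarray, model: TrainedModel):
        self.codes = codes
        self.n = n = codes.shape[0]
        self.model = model
        self.lsc = LinkerScorer(codes, model.linker, n_policy="uniform")
        if n >= NUC_LEN:
            nsc = NucleosomeScorer(codes, model.nucleosome, n_policy="uniform")
            self.nuc = nsc.window_scores(np.arange(n - NUC_LEN + 1))
        else:
            self.nuc = np.empty(0)
        with np.errstate(divide="ignore"):
            self.logPd = np.log(model.duration.Pd)
            self.logS = np.log(model.duration.survival())

    # -- helpers -------------------------------------------------------------

    def _linker_end_scores(self, j: int, prev: np.ndarray) -> np.ndarray:
        """Candidate scores for an L segment ending at j, ordered so that the
        first maximum is the latest segment start: interior durations
        d = 1..dmax ascending, then the initial truncated linker [0, j]."""
        dmax = min(MAX_LINKER, j - NUC_LEN + 1)
        if dmax >= 1:
            ds = np.arange(1, dmax + 1)
            interior = (prev[j - ds] + self.logPd[ds - 1]
                        + self.lsc.score(j - ds + 1, j))
        else:
            interior = np.empty(0)
        if j + 1 <= MAX_LINKER:
            init = self.logS[j + 1] + float(self.lsc.score(0, j))
            return np.concatenate([interior, [init]])
        return interior

    def _final_candidates(self, vn: np.ndarray) -> np.ndarray:
        """Termination scores: final linker of observed length d = 0..dmax
        after the last nucleosome (ascending d), then the all-linker path."""
        n = self.n
        cands = []
        dmax = min(MAX_LINKER, n - NUC_LEN)
        for d in range(0, max(dmax, 0) + 1):
            e = n - 1 - d
            if e < NUC_LEN - 1 or vn[e] == _NEG_INF:
                cands.append(_NEG_INF)
                continue
            tail = 0.0 if d == 0 else float(self.lsc.score(n - d, n - 1))
            cands.append(vn[e] + self.logS[d] + tail)
        cands.append(float(self.lsc.score(0, n - 1)))  # doubly truncated L
        return np.asarray(cands)

    # -- Viterbi -------------------------------------------------------------

    def viterbi(self) -> tuple[str, float]:
        n = self.n
        if n < NUC_LEN:
            return "L" * n, float(self.lsc.score(0, n - 1))
        vn = np.full(n, _NEG_INF)
        lend = np.full(n, _NEG_INF)
        lbp = np.full(n, -1, dtype=np.int64)   # chosen d; 0 = initial linker
        for j in range(n):
            cands = self._linker_end_scores(j, vn)
            if cands.size:
                k = int(np.argmax(cands))
                lend[j] = cands[k]
                dmax = min(MAX_LINKER, j - NUC_LEN + 1)
                n_interior = max(dmax, 0)
                lbp[j] = k + 1 if k < n_interior else 0
            if j >= NUC_LEN - 1:
                prev = 0.0 if j == NUC_LEN - 1 else lend[j - NUC_LEN]
                vn[j] = self.nuc[j - NUC_LEN + 1] + prev

        cands = self._final_candidates(vn)
        k = int(np.argmax(cands))
        score = float(cands[k])
        states = np.full(n, "L", dtype="<U1")
        if k < cands.size - 1:                  # path contains nucleosomes
            e = n - 1 - k                       # end of last N run
            while True:
                states[e - NUC_LEN + 1 : e + 1] = "N"
                le = e - NUC_LEN                # end of preceding L segment
                if le < 0:
                    break                       # initial linker of length 0
                d = int(lbp[le])
                if d == 0:
                    break                       # initial truncated linker
                e = le - d                      # end of preceding N run
        return "".join(states), score

    # -- forward-backward ----------------------------------------------------

    def posterior(self) -> tuple[np.ndarray, float]:
        n = self.n
        pdyad = np.zeros(n)
        if n < NUC_LEN:
            return pdyad, float(self.lsc.score(0, n - 1))
        an = np.full(n, _NEG_INF)
        al = np.full(n, _NEG_INF)
        for j in range(n):
            cands = self._linker_end_scores(j, an)
            if cands.size:
                al[j] = _lse(cands)
            if j >= NUC_LEN - 1:
                prev = 0.0 if j == NUC_LEN - 1 else al[j - NUC_LEN]
                an[j] = self.nuc[j - NUC_LEN + 1] + prev
        z = _lse(self._final_candidates(an))

        bn = np.full(n, _NEG_INF)
        for e in range(n - 1, NUC_LEN - 2, -1):
            cands = []
            d_final = n - 1 - e
            if d_final <= MAX_LINKER:
                tail = 0.0 if d_final == 0 else float(
                    self.lsc.score(e + 1, n - 1))
                cands.append(self.logS[d_final] + tail)
            dmax = min(MAX_LINKER, n - e - NUC_LEN - 1)
            if dmax >= 1:
                ds = np.arange(1, dmax + 1)
                interior = (self.logPd[ds - 1]
                            + self.lsc.score(e + 1, e + ds)
                            + self.nuc[e + ds + 1]
                            + bn[e + ds + NUC_LEN])
                cands.append(interior)
            bn[e] = _lse(np.hstack(cands)) if cands else _NEG_INF

        starts = np.arange(n - NUC_LEN + 1)
        before = np.where(starts == 0, 0.0, al[starts - 1])
        logp = before + self.nuc[starts] + bn[starts + NUC_LEN - 1] - z
        pdyad[starts + DYAD_OFFSET] = np.exp(np.clip(logp, None, 0.0))
        return pdyad, z


def viterbi(query, model: TrainedModel) -> tuple[str, float]:
    """Maximum-probability segmentation: per-position state string over
    {'N','L'} plus the path's log score."""
    return _Decoder(_as_codes(query), model).viterbi()


def forward_backward(query, model: TrainedModel) -> tuple[np.ndarray, float]:
    """Posterior dyad probabilities and the total log-likelihood."""
    return _Decoder(_as_codes(query), model).posterior()


def occupancy_from_pdyad(pdyad: np.ndarray) -> np.ndarray:
    """occupancy(i) = sum of pdyad within +/-73 bp, truncated at the ends."""
    return np.convolve(pdyad, np.ones(NUC_LEN), mode="same")


@dataclass
class PredictionTrack:
    """Per-position prediction results for one query sequence."""

    pdyad: np.ndarray
    occupancy: np.ndarray
    viterbi_state: str              # 'N'/'L' per position
    hba: np.ndarray                 # NaN where undefined
    loglik: float
    viterbi_logscore: float
    query_id: str = "query"
    extras: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.pdyad.shape[0]

    def viterbi_binary(self) -> np.ndarray:
        return np.frombuffer(self.viterbi_state.encode(), dtype="S1") == b"N"

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("pos\tpdyad\toccup\tviterbi\thba\n")
            vit = self.viterbi_binary().astype(int)
            for i in range(self.n):
                hba = "NA" if np.isnan(self.hba[i]) else f"{self.hba[i]:.6g}"
                fh.write(f"{i + 1}\t{self.pdyad[i]:.6g}\t"
                         f"{self.occupancy[i]:.6g}\t{vit[i]}\t{hba}\n")


def predict(query, model: TrainedModel, smooth_hba: bool = False,
            query_id: str = "query") -> PredictionTrack:
    """Decode one query: Viterbi path, posterior dyad/occupancy tracks and
    the HBA profile (raw by default; 55-bp smoothed on request)."""
    codes = _as_codes(query)
    dec = _Decoder(codes, model)
    path, vscore = dec.viterbi()
    pdyad, loglik = dec.posterior()
    hba = compute_hba(codes, model,
                      mode="smoothed55" if smooth_hba else "raw")
    return PredictionTrack(
        pdyad=pdyad,
        occupancy=occupancy_from_pdyad(pdyad),
        viterbi_state=path,
        hba=hba.scores,
        loglik=loglik,
        viterbi_logscore=vscore,
        query_id=query_id,
    )
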