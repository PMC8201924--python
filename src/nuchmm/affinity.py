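"""Histone binding affinity (HBA) and 13-segment local HBA scoring.

HBA for the 147-bp window centered at dyad i is the natural-log likelihood
ratio

    a_i = log P_N(x[i-73..i+73]) - log G_L(x[i-73..i+73] | 147)

where P_N chains freqN4 with the position-specific tranN4 tables and G_L is
the linker chain with its order ramp (freqL, tranL, tranL2, tranL3, then
tranL4 for every later base).  Local HBA applies the same ratio to each of
the thirteen overlapping nucleosomal subsegments A-M, starting the
nucleosome-side chain from the segment's own joint 4-mer table (freqN4S) and
the linker-side chain fresh from freqL.

Scores are reported at the dyad coordinate; dyads whose window overlaps an N
are undefined (NaN) by default.  HBA negativity on its own carries no
meaning, since nucleosome and linker training sequences never overlap; no
function here thresholds HBA at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .model import (DYAD_OFFSET, NUC_LEN, SEGMENT_IDS, SEGMENTS, LinkerModel,
                    NucleosomeModel, TrainedModel, encode_sequence)

Mode = Literal["raw", "centered", "smoothed55"]
NPolicy = Literal["missing", "uniform"]

_LOG_QUARTER = float(np.log(0.25))


def _safe_log(a: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(a)


def _as_codes(query) -> np.ndarray:
    if isinstance(query, np.ndarray):
        return query
    return encode_sequence(str(query))


class LinkerScorer:
    """Per-position linker log-terms for one encoded sequence, supporting
    O(1) scoring of any subinterval under the order-ramp chain.

    Terms touching an N base are replaced by log(1/4) under the "uniform"
    policy and by 0 under "missing"; in the latter case callers must mask
    windows overlapping N via :meth:`window_has_n` (the scores themselves
    are meaningless there).
    """

    def __init__(self, codes: np.ndarray, model: LinkerModel,
                 n_policy: NPolicy = "missing"):
        self.n = n = codes.shape[0]
        self.codes = codes
        fill = 0.0 if n_policy == "missing" else _LOG_QUARTER
        lf, lt1 = _safe_log(model.freqL), _safe_log(model.tranL)
        lt2, lt3 = _safe_log(model.tranL2), _safe_log(model.tranL3)
        lt4 = _safe_log(model.tranL4)
        isn = codes == 4
        safe = np.where(isn, 0, codes).astype(np.int64)
        self._ncum = np.concatenate([[0], np.cumsum(isn)])

        def ctx(k: int) -> tuple[np.ndarray, np.ndarray]:
            # k-mer index ending at each position >= k-1, plus N flag
            idx = np.zeros(n, dtype=np.int64)
            bad = np.zeros(n, dtype=bool)
            for j in range(k):
                idx += np.roll(safe, j) * 4 ** j
                bad |= np.roll(isn, j)
            return idx, bad

        self.t1 = np.where(isn, fill, lf[safe])
        self.t2 = np.where(isn | np.roll(isn, 1), fill,
                           lt1[np.roll(safe, 1), safe])
        c2, b2 = ctx(2)
        self.t3 = np.where(isn | np.roll(b2, 1), fill,
                           lt2[np.roll(c2, 1), safe])
        c3, b3 = ctx(3)
        self.t4 = np.where(isn | np.roll(b3, 1), fill,
                           lt3[np.roll(c3, 1), safe])
        c4, b4 = ctx(4)
        t5 = np.where(isn | np.roll(b4, 1), fill, lt4[np.roll(c4, 1), safe])
        self.cum5 = np.concatenate([[0.0], np.cumsum(t5)])  # cum5[i+1]=sum t5[0..i]

    def window_has_n(self, starts, length) -> np.ndarray:
        starts = np.asarray(starts, dtype=np.int64)
        return (self._ncum[starts + length] - self._ncum[starts]) > 0

    def score(self, start, end):
        """log G_L of codes[start..end] (0-based inclusive); vectorized."""
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        length = end - start + 1
        s = self.t1[start]
        s = s + np.where(length >= 2, self.t2[np.minimum(start + 1, end)], 0.0)
        s = s + np.where(length >= 3, self.t3[np.minimum(start + 2, end)], 0.0)
        s = s + np.where(length >= 4, self.t4[np.minimum(start + 3, end)], 0.0)
        tail = self.cum5[end + 1] - self.cum5[np.minimum(start + 4, end + 1)]
        return s + np.where(length >= 5, tail, 0.0)


class NucleosomeScorer:
    """Position-specific nucleosome log-terms for one encoded sequence."""

    def __init__(self, codes: np.ndarray, model: NucleosomeModel,
                 n_policy: NPolicy = "missing"):
        self.n = n = codes.shape[0]
        self.model = model
        self.fill = 0.0 if n_policy == "missing" else _LOG_QUARTER
        self.lfreq = _safe_log(model.freqN4)
        self.ltran = _safe_log(model.tranN4)
        self.lsegs = _safe_log(model.freqN4S)
        isn = codes == 4
        safe = np.where(isn, 0, codes).astype(np.int64)
        self.safe = safe
        # 4-mer index ending at i (i >= 3), with flag for N contamination
        idx = np.zeros(n, dtype=np.int64)
        bad = np.zeros(n, dtype=bool)
        for j in range(4):
            idx += np.roll(safe, j) * 4 ** j
            bad |= np.roll(isn, j)
        self.ctx4 = idx
        self.bad4 = bad
        self.isn = isn
        # number of N within any window: prefix sums
        self._ncum = np.concatenate([[0], np.cumsum(isn)])

    def window_has_n(self, starts: np.ndarray, length: int) -> np.ndarray:
        return (self._ncum[starts + length] - self._ncum[starts]) > 0

    def chain(self, starts: np.ndarray, p: int, q: int,
              start_table: np.ndarray) -> np.ndarray:
        """log prob of nucleosomal positions p..q (1-based within the 147-bp
        frame) for windows beginning at each 0-based ``starts``; the first
        4-mer uses ``start_table`` (log, 256) and later bases use tranN4.
        Under the "missing" policy, windows overlapping N must be masked by
        the caller (via :meth:`window_has_n`)."""
        a = starts + p - 1
        out = np.where(self.bad4[a + 3], self.fill * 4.0,
                       start_table[self.ctx4[a + 3]])
        for t in range(p + 4, q + 1):
            pos = starts + t - 1
            term = np.where(self.bad4[pos - 1] | self.isn[pos], self.fill,
                            self.ltran[t - 5][self.ctx4[pos - 1], self.safe[pos]])
            out = out + term
        return out

    def window_scores(self, starts: np.ndarray) -> np.ndarray:
        """log P_N of the full 147-bp windows at each start."""
        return self.chain(starts, 1, NUC_LEN, self.lfreq)


def prob_nucleosome(seq147, model: NucleosomeModel | TrainedModel,
                    n_policy: NPolicy = "missing") -> float:
    """log P_N of a single 147-bp sequence."""
    if isinstance(model, TrainedModel):
        model = model.nucleosome
    codes = _as_codes(seq147)
    if codes.shape[0] != NUC_LEN:
        raise ValueError(f"expected 147 bp, got {codes.shape[0]}")
    if n_policy == "missing" and (codes == 4).any():
        return float("nan")
    scorer = NucleosomeScorer(codes, model, n_policy)
    return float(scorer.window_scores(np.array([0]))[0])


def prob_linker(seq, model: LinkerModel | TrainedModel,
                n_policy: NPolicy = "missing") -> float:
    """log G_L of a sequence of any length >= 1 under the order ramp."""
    if isinstance(model, TrainedModel):
        model = model.linker
    codes = _as_codes(seq)
    if codes.shape[0] < 1:
        raise ValueError("empty sequence")
    if n_policy == "missing" and (codes == 4).any():
        return float("nan")
    scorer = LinkerScorer(codes, model, n_policy)
    return float(scorer.score(0, codes.shape[0] - 1))


@dataclass
class HBAProfile:
    """Per-position HBA a_i; NaN where undefined (ends, N overlap)."""

    scores: np.ndarray     # length n, 1-based position i at scores[i-1]
    mode: Mode = "raw"

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.scores)

    def positions(self) -> np.ndarray:
        return np.arange(1, self.n + 1)


@dataclass
class LocalHBAProfile:
    """Thirteen per-position local HBA tracks (rows ordered A..M)."""

    scores: np.ndarray     # (13, n)
    segment_ids: tuple[str, ...] = SEGMENT_IDS

    @property
    def n(self) -> int:
        return self.scores.shape[1]

    def track(self, segment: str) -> np.ndarray:
        return self.scores[self.segment_ids.index(segment)]


def _raw_hba(codes: np.ndarray, model: TrainedModel,
             n_policy: NPolicy = "missing") -> np.ndarray:
    n = codes.shape[0]
    scores = np.full(n, np.nan)
    if n < NUC_LEN:
        return scores
    starts = np.arange(n - NUC_LEN + 1)
    nsc = NucleosomeScorer(codes, model.nucleosome, n_policy)
    lsc = LinkerScorer(codes, model.linker, n_policy)
    vals = nsc.window_scores(starts) - lsc.score(starts, starts + NUC_LEN - 1)
    if n_policy == "missing":
        vals = np.where(nsc.window_has_n(starts, NUC_LEN), np.nan, vals)
    scores[starts + DYAD_OFFSET] = vals
    return scores


def _smooth55(scores: np.ndarray) -> np.ndarray:
    """Centered 55-bp moving average over defined values."""
    defined = ~np.isnan(scores)
    filled = np.where(defined, scores, 0.0)
    kernel = np.ones(55)
    sums = np.convolve(filled, kernel, mode="same")
    counts = np.convolve(defined.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[~defined] = np.nan
    return out


def compute_hba(query, model: TrainedModel, mode: Mode = "raw",
                n_policy: NPolicy = "missing") -> HBAProfile:
    """HBA profile of a query; empty (all-NaN) with a warning if < 147 bp."""
    codes = _as_codes(query)
    if codes.shape[0] < NUC_LEN:
        import warnings
        warnings.warn("query shorter than 147 bp: empty HBA profile",
                      stacklevel=2)
    scores = _raw_hba(codes, model, n_policy)
    if mode == "centered":
        if np.any(~np.isnan(scores)):
            scores = scores - np.nanmean(scores)
    elif mode == "smoothed55":
        scores = _smooth55(scores)
    elif mode != "raw":
        raise ValueError(f"unknown mode {mode!r}")
    return HBAProfile(scores=scores, mode=mode)


def compute_local_hba(query, model: TrainedModel,
                      n_policy: NPolicy = "missing") -> LocalHBAProfile:
    """Local HBA tracks for segments A-M, aligned to the window dyad."""
    codes = _as_codes(query)
    n = codes.shape[0]
    out = np.full((len(SEGMENTS), n), np.nan)
    if n < NUC_LEN:
        return LocalHBAProfile(scores=out)
    starts = np.arange(n - NUC_LEN + 1)
    nsc = NucleosomeScorer(codes, model.nucleosome, n_policy)
    lsc = LinkerScorer(codes, model.linker, n_policy)
    for k, (seg, (p, q)) in enumerate(SEGMENTS.items()):
        num = nsc.chain(starts, p, q, nsc.lsegs[k])
        den = lsc.score(starts + p - 1, starts + q - 1)
        vals = num - den
        if n_policy == "missing":
            seg_has_n = nsc.window_has_n(starts + p - 1, q - p + 1)
            vals = np.where(seg_has_n, np.nan, vals)
        out[k, starts + DYAD_OFFSET] = vals
    return LocalHBAProfile(scores=out)
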