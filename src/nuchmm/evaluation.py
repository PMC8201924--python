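"""Accuracy protocol: Viterbi-dyad matching against reference dyad maps.

A predicted nucleosome is one maximal 147-bp N run on the Viterbi path; its
dyad is the run start + 73.  Matching is many-to-one: each predicted dyad is
judged independently against its nearest reference dyad on the same
chromosome, with the matching window w widened stepwise (a prediction matches
at window w when the nearest reference dyad is within +/- w bp).  The
matching rate is therefore non-decreasing in w by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model import DYAD_OFFSET, NUC_LEN
from .seqio import DyadMap


def _as_chrom_dict(dyads) -> dict[str, np.ndarray]:
    if isinstance(dyads, DyadMap):
        return dyads.by_chrom()
    if isinstance(dyads, dict):
        return {c: np.sort(np.asarray(v, dtype=np.int64))
                for c, v in dyads.items()}
    return {"": np.sort(np.asarray(dyads, dtype=np.int64))}


def viterbi_dyads(track_or_states) -> np.ndarray:
    """1-based dyad coordinates of the N runs on a Viterbi path."""
    states = getattr(track_or_states, "viterbi_state", track_or_states)
    arr = np.frombuffer(str(states).encode(), dtype="S1") == b"N"
    if not arr.any():
        return np.empty(0, dtype=np.int64)
    d = np.diff(arr.astype(np.int8))
    run_starts = np.flatnonzero(d == 1) + 1
    if arr[0]:
        run_starts = np.concatenate([[0], run_starts])
    return run_starts + DYAD_OFFSET + 1   # 1-based dyad = start + 73 (+1)


def nearest_distances(pred, ref) -> np.ndarray:
    """|predicted dyad - nearest reference dyad|, matched per chromosome."""
    pred_d, ref_d = _as_chrom_dict(pred), _as_chrom_dict(ref)
    out = []
    for chrom, p in pred_d.items():
        r = ref_d.get(chrom)
        if r is None or r.size == 0:
            raise ValueError(f"no reference dyads for chromosome {chrom!r}")
        idx = np.searchsorted(r, p)
        left = r[np.clip(idx - 1, 0, r.size - 1)]
        right = r[np.clip(idx, 0, r.size - 1)]
        out.append(np.minimum(np.abs(p - left), np.abs(p - right)))
    if not out:
        raise ValueError("no predicted dyads")
    return np.concatenate(out)


def match_rate(pred, ref, w: int) -> float:
    """Fraction of predicted dyads within +/- w bp of the nearest reference
    dyad, pooled over chromosomes."""
    d = nearest_distances(pred, ref)
    if d.size == 0:
        raise ValueError("no predicted dyads")
    return float(np.mean(d <= w))


def match_curve(pred, ref, max_window: int = 9) -> np.ndarray:
    """Matching rates for w = 0..max_window (non-decreasing)."""
    d = nearest_distances(pred, ref)
    if d.size == 0:
        raise ValueError("no predicted dyads")
    return np.array([np.mean(d <= w) for w in range(max_window + 1)])


def distance_histogram(pred, ref, max_d: int = 10) -> np.ndarray:
    """Fractions of predictions at each distance 0..max_d from the nearest
    reference dyad, plus one overflow bin (length max_d + 2)."""
    d = nearest_distances(pred, ref)
    clipped = np.minimum(d, max_d + 1)
    counts = np.bincount(clipped, minlength=max_d + 2)
    return counts / d.size


def enrichment(unique_rate: float, redundant_rate: float,
               n_unique: int, n_redundant: int) -> float:
    """Fold enrichment of unique nucleosomes among matched predictions over
    their share of the reference map:
    (unique_rate / redundant_rate) / (n_unique / n_redundant)."""
    if min(unique_rate, redundant_rate, n_unique, n_redundant) <= 0:
        raise ValueError("all enrichment inputs must be positive")
    return (unique_rate / redundant_rate) / (n_unique / n_redundant)


def nucleosome_density(genome_length: int, n_nucleosomes: int) -> float:
    """Base pairs per nucleosome."""
    if n_nucleosomes <= 0:
        raise ValueError("need at least one nucleosome")
    return genome_length / n_nucleosomes


def percent(part: float, whole: float) -> float:
    return 100.0 * part / whole


def nonrepresentative_fraction(unique_rate: float,
                               redundant_rate: float) -> float:
    """Share of Viterbi nucleosomes matching redundant-but-not-unique
    reference nucleosomes (rates in %, unique dyads are a subset of the
    redundant map)."""
    return redundant_rate - unique_rate


def target_select_count(genome_length: int, target_density: float) -> int:
    """Number of top-scoring dyads to keep for a target bp-per-nucleosome
    density: floor(genome_length / target_density), at least 1."""
    return max(1, math.floor(genome_length / target_density))


def select_top_by_density(redundant: DyadMap, genome_length: int,
                          target_density: float) -> DyadMap:
    """Keep the :func:`target_select_count` highest-scoring dyads; ties
    broken by (chrom, pos) for determinism."""
    k = target_select_count(genome_length, target_density)
    if k >= len(redundant.records):
        if k > len(redundant.records):
            warnings.warn(
                f"requested {k} records but only {len(redundant.records)} "
                "available; keeping all", stacklevel=2)
        kept = list(redundant.records)
    else:
        ranked = sorted(redundant.records,
                        key=lambda r: (-r.score, r.chrom, r.pos))
        kept = ranked[:k]
    return DyadMap(kept, category="redundant")


def at_frequency_profile(seqs: list[str], window: int = NUC_LEN) -> np.ndarray:
    """Mean A/T fraction of the ``window``-bp sequence centered at each
    position, averaged over equal-length aligned windows; NaN where the
    window does not fit."""
    if not seqs:
        raise ValueError("empty input")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned windows must have equal length")
    from .model import encode_sequence
    mat = np.stack([encode_sequence(s) for s in seqs])
    at = ((mat == 0) | (mat == 3)).astype(np.float64)
    cum = np.concatenate([np.zeros((at.shape[0], 1)), np.cumsum(at, axis=1)],
                         axis=1)
    out = np.full(length, np.nan)
    flank = (window - 1) // 2
    centers = np.arange(flank, length - (window - flank - 1))
    win_at = (cum[:, centers + window - flank] - cum[:, centers - flank])
    out[centers] = win_at.mean(axis=0) / window
    return out


@dataclass
class AlignedProfile:
    offsets: np.ndarray
    mean: np.ndarray
    counts: np.ndarray


def aligned_average_profile(profiles: list[np.ndarray],
                            anchors: list[int]) -> AlignedProfile:
    """Positionwise mean of profiles aligned at their anchor indices
    (0-based), ignoring missing values; reports per-offset contributor
    counts."""
    if not profiles:
        raise ValueError("empty input")
    if len(profiles) != len(anchors):
        raise ValueError("one anchor per profile required")
    lo = min(-a for a in anchors)
    hi = max(len(p) - 1 - a for p, a in zip(profiles, anchors))
    offsets = np.arange(lo, hi + 1)
    sums = np.zeros(offsets.size)
    counts = np.zeros(offsets.size)
    for p, a in zip(profiles, anchors):
        p = np.asarray(p, dtype=np.float64)
        start = -a - lo
        seg = slice(start, start + p.size)
        ok = ~np.isnan(p)
        sums[seg][ok] += p[ok]
        counts[seg][ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    mean[counts == 0] = np.nan
    return AlignedProfile(offsets=offsets, mean=mean, counts=counts)
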