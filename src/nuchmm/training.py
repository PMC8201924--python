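"""Estimate duration-HMM parameters from a genome plus a unique dyad map.

The training data are defined by coverage: genomic regions covered by the
147-bp footprints of the unique dyads are nucleosome regions, the uncovered
complement (including chromosome-end flanks) are linker regions.  Dyads
within 73 bp of a chromosome end are dropped; regions containing N are
dropped after the coverage partition is formed.  Linker *lengths* of
1-500 bp feed the duration law Pd; linker *sequences* of 7-500 bp feed the
linker Markov chain.

Position-specific nucleosome transition tables (tranN4) and Pd are smoothed
with a 3-window simple moving average; trailing by default (the value at t
averages t-2, t-1, t, with shortened windows at the left boundary), with a
centered variant available.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Literal, Sequence

import numpy as np

from .model import (DYAD_OFFSET, MAX_LINKER, NUC_LEN, SEGMENTS, DurationModel,
                    LinkerModel, NucleosomeModel, TrainedModel,
                    encode_sequence)

SmaMode = Literal["trailing", "centered"]

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)


@dataclass
class TrainConfig:
    pseudocount: bool = True
    smoothing: bool = True
    sma: SmaMode = "trailing"
    augment_revcomp: bool = False


def moving_average_3(x: np.ndarray, mode: SmaMode = "trailing",
                     axis: int = 0) -> np.ndarray:
    """3-window simple moving average along ``axis`` with shortened windows
    at the boundaries (no wrap, no NA)."""
    x = np.moveaxis(np.asarray(x, dtype=np.float64), axis, 0)
    out = np.empty_like(x)
    if mode == "trailing":
        out[0] = x[0]
        if x.shape[0] > 1:
            out[1] = (x[0] + x[1]) / 2.0
        if x.shape[0] > 2:
            out[2:] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    elif mode == "centered":
        out[:] = x
        if x.shape[0] > 1:
            out[0] = (x[0] + x[1]) / 2.0
            out[-1] = (x[-2] + x[-1]) / 2.0
        if x.shape[0] > 2:
            out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    else:
        raise ValueError(f"unknown SMA mode {mode!r}")
    return np.moveaxis(out, 0, axis)


def _normalize_rows(counts: np.ndarray) -> np.ndarray:
    """Row-normalize; all-zero rows become uniform (they carry no data and
    are never visited when scoring the sequences they were estimated from)."""
    counts = counts.astype(np.float64)
    sums = counts.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / sums
    return np.where(sums > 0, probs, 1.0 / counts.shape[-1])


def _encode_regions(seqs: Sequence[str]) -> list[np.ndarray]:
    return [encode_sequence(s) for s in seqs]


# ---------------------------------------------------------------------------
# region extraction
# ---------------------------------------------------------------------------

def extract_nucleosome_regions(genome, dyads, stats: dict | None = None
                               ) -> list[str]:
    """147-bp plus-strand footprint sequences of retained unique dyads.

    Drops dyads within 73 bp of a chromosome end, then footprints containing
    N.  ``stats`` (if given) is filled with retained/dropped counts.
    """
    if dyads.category != "unique":
        raise ValueError("nucleosome training requires a unique dyad map")
    lengths = genome.lengths
    kept: list[str] = []
    n_end = n_n = 0
    for rec in dyads.records:
        if rec.chrom not in lengths:
            raise KeyError(f"dyad on unknown chromosome {rec.chrom!r}")
        n = lengths[rec.chrom]
        if rec.pos <= DYAD_OFFSET or rec.pos > n - DYAD_OFFSET:
            n_end += 1
            continue
        seq = genome.records[rec.chrom][rec.pos - DYAD_OFFSET - 1 :
                                        rec.pos + DYAD_OFFSET]
        if "N" in seq:
            n_n += 1
            continue
        kept.append(seq)
    if stats is not None:
        stats.update(n_dyads=len(dyads.records), n_dropped_end=n_end,
                     n_dropped_N=n_n, n_nucleosomes=len(kept))
    if not kept:
        raise ValueError("no usable nucleosome regions after filtering")
    return kept


def retained_footprints(genome, dyads) -> dict[str, list[tuple[int, int]]]:
    """End-rule-retained footprints per chromosome (1-based inclusive).

    Footprints containing N still count as covered for the purpose of the
    nucleosome/linker coverage partition; the N filter applies to the
    extracted region sequences only.
    """
    lengths = genome.lengths
    out: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    for rec in dyads.records:
        n = lengths[rec.chrom]
        if DYAD_OFFSET < rec.pos <= n - DYAD_OFFSET:
            out[rec.chrom].append(rec.footprint)
    return out


def extract_linker_regions(genome, dyads, stats: dict | None = None
                           ) -> list[tuple[str, int]]:
    """Maximal uncovered intervals per chromosome as (sequence, length).

    Coverage is the union of retained footprints; chromosome-end flanks count
    as linkers.  Intervals containing N are dropped.
    """
    footprints = retained_footprints(genome, dyads)
    linkers: list[tuple[str, int]] = []
    n_n = 0
    for chrom, length in genome.lengths.items():
        intervals: list[tuple[int, int]] = []
        cursor = 1
        for lo, hi in sorted(footprints.get(chrom, [])):
            if lo > cursor:
                intervals.append((cursor, lo - 1))
            cursor = max(cursor, hi + 1)
        if cursor <= length:
            intervals.append((cursor, length))
        for lo, hi in intervals:
            seq = genome.records[chrom][lo - 1 : hi]
            if "N" in seq:
                n_n += 1
                continue
            linkers.append((seq, hi - lo + 1))
    if stats is not None:
        stats.update(n_linkers=len(linkers), n_linkers_dropped_N=n_n)
    return linkers


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

def estimate_duration(linker_lengths: Sequence[int], smoothing: bool = True,
                      sma: SmaMode = "trailing") -> DurationModel:
    """Pd over 1..500 bp: empirical histogram, optional 3-window SMA,
    renormalized.  Lengths outside 1..500 are excluded."""
    lengths = np.asarray(linker_lengths, dtype=np.int64)
    lengths = lengths[(lengths >= 1) & (lengths <= MAX_LINKER)]
    if lengths.size == 0:
        raise ValueError("no linker lengths in 1..500 bp")
    hist = np.bincount(lengths - 1, minlength=MAX_LINKER).astype(np.float64)
    pd_ = hist / hist.sum()
    if smoothing:
        pd_ = moving_average_3(pd_, mode=sma)
        pd_ = pd_ / pd_.sum()
    return DurationModel(Pd=pd_)


def _kmer_transition_counts(codes_list: list[np.ndarray], k: int,
                            pseudocount: bool) -> np.ndarray:
    """(4**k, 4) counts of (context k-mer, next base) pooled over sequences."""
    counts = np.zeros(4 ** k * 4, dtype=np.float64)
    for codes in codes_list:
        n = codes.shape[0]
        if n < k + 1:
            continue
        idx = np.zeros(n - k, dtype=np.int64)
        for j in range(k):
            idx = idx * 4 + codes[j : n - k + j]
        flat = idx * 4 + codes[k:]
        counts += np.bincount(flat, minlength=counts.shape[0])
    counts = counts.reshape(4 ** k, 4)
    if pseudocount:
        counts += 1.0
    return counts


def estimate_linker_model(linker_seqs: Sequence[str],
                          pseudocount: bool = True) -> LinkerModel:
    """Order-0 through order-4 linker chain from linkers of 7-500 bp."""
    retained = [s for s in linker_seqs if 7 <= len(s) <= MAX_LINKER]
    if not retained:
        raise ValueError("no linker sequences of 7-500 bp")
    codes_list = _encode_regions(retained)
    for i, codes in enumerate(codes_list):
        if (codes > 3).any():
            raise ValueError(f"linker sequence {i} contains N")
    base_counts = np.zeros(4, dtype=np.float64)
    for codes in codes_list:
        base_counts += np.bincount(codes, minlength=4)
    if pseudocount:
        base_counts += 1.0
    return LinkerModel(
        freqL=base_counts / base_counts.sum(),
        tranL=_normalize_rows(_kmer_transition_counts(codes_list, 1, pseudocount)),
        tranL2=_normalize_rows(_kmer_transition_counts(codes_list, 2, pseudocount)),
        tranL3=_normalize_rows(_kmer_transition_counts(codes_list, 3, pseudocount)),
        tranL4=_normalize_rows(_kmer_transition_counts(codes_list, 4, pseudocount)),
    )


def estimate_nucleosome_model(nuc_seqs: Sequence[str],
                              pseudocount: bool = True,
                              smoothing: bool = True,
                              sma: SmaMode = "trailing") -> NucleosomeModel:
    """freqN4, position-specific tranN4 (t = 5..147) and the thirteen
    segment-start 4-mer tables from 147-bp nucleosome sequences.

    The fitted model carries ``context_counts_`` (143, 256), the raw number
    of times each context was observed at each position.
    """
    mat = np.empty((len(nuc_seqs), NUC_LEN), dtype=np.int8)
    for i, s in enumerate(nuc_seqs):
        if len(s) != NUC_LEN:
            raise ValueError(f"sequence {i} has length {len(s)}, expected 147")
        codes = encode_sequence(s)
        if (codes > 3).any():
            raise ValueError(f"sequence {i} contains N")
        mat[i] = codes
    m64 = mat.astype(np.int64)
    # overlapping 4-mer index starting at each column 0..143
    ctx = (m64[:, :-3] * 64 + m64[:, 1:-2] * 16 + m64[:, 2:-1] * 4 + m64[:, 3:])

    freq4 = np.bincount(ctx[:, 0], minlength=256).astype(np.float64)
    if pseudocount:
        freq4 += 1.0
    freqN4 = freq4 / freq4.sum()

    # counts over (t, context, base) for t = 5..147
    t_idx = np.arange(NUC_LEN - 4, dtype=np.int64)
    flat = (t_idx[None, :] * 1024 + ctx[:, : NUC_LEN - 4] * 4 + m64[:, 4:])
    counts = np.bincount(flat.ravel(), minlength=(NUC_LEN - 4) * 1024)
    counts = counts.reshape(NUC_LEN - 4, 256, 4).astype(np.float64)
    context_counts = counts.sum(axis=2)
    if pseudocount:
        counts += 1.0
    tranN4 = _normalize_rows(counts)
    if smoothing:
        tranN4 = _normalize_rows(moving_average_3(tranN4, mode=sma, axis=0))

    seg_tables = np.empty((len(SEGMENTS), 256), dtype=np.float64)
    for k, (start, _end) in enumerate(SEGMENTS.values()):
        tab = np.bincount(ctx[:, start - 1], minlength=256).astype(np.float64)
        if pseudocount:
            tab += 1.0
        seg_tables[k] = tab / tab.sum()

    model = NucleosomeModel(freqN4=freqN4, tranN4=tranN4, freqN4S=seg_tables)
    model.context_counts_ = context_counts  # type: ignore[attr-defined]
    return model


def _revcomp_codes(seq: str) -> str:
    from .model import decode_sequence
    return decode_sequence(_COMPLEMENT[encode_sequence(seq)][::-1])


def train(genome, unique_dyads, config: TrainConfig | None = None
          ) -> TrainedModel:
    """Full training pipeline; deterministic given inputs and config."""
    config = config or TrainConfig()
    if len(unique_dyads) == 0:
        raise ValueError("empty dyad map")
    stats: dict = {}
    nuc_seqs = extract_nucleosome_regions(genome, unique_dyads, stats)
    linkers = extract_linker_regions(genome, unique_dyads, stats)
    linker_seqs = [s for s, _ in linkers]
    linker_lengths = [d for _, d in linkers]
    if config.augment_revcomp:
        nuc_seqs = nuc_seqs + [_revcomp_codes(s) for s in nuc_seqs]
        linker_seqs = linker_seqs + [_revcomp_codes(s) for s in linker_seqs]
    model = TrainedModel(
        nucleosome=estimate_nucleosome_model(
            nuc_seqs, pseudocount=config.pseudocount,
            smoothing=config.smoothing, sma=config.sma),
        linker=estimate_linker_model(linker_seqs,
                                     pseudocount=config.pseudocount),
        duration=estimate_duration(linker_lengths,
                                   smoothing=config.smoothing,
                                   sma=config.sma),
        provenance={
            "chromosomes": genome.lengths,
            "config": asdict(config),
            **stats,
            "n_linkers_for_sequence_model": sum(
                1 for s in linker_seqs if 7 <= len(s) <= MAX_LINKER),
        },
    )
    model.validate()
    return model
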