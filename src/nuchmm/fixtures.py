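"""Synthetic genomes and dyad maps drawn from known model parameters.

The generator emulates the alternating-renewal process the duration HMM
assumes: linker length d ~ Pd, linker bases from the linker chain, then a
147-bp nucleosome from freqN4 + tranN4, recording every completed dyad.  It
produces clean data by design -- no mapping noise, no missed or spurious
dyads, no repeats, no chemical-cleavage bias -- so parameter-recovery and
match-rate results on fixtures bound what the method can do when its own
assumptions hold, not its accuracy on real chromatin.

``divergence`` in [0, 1] controls the statistical distance between the
nucleosome and linker emission laws: 0 makes them identical (HBA identically
zero), 1 gives disjoint preferred bases (G/C-favoring nucleosomes with a
10-bp rotational modulation vs A/T-rich linkers).  All sampling flows through
one numpy default_rng seeded from the spec, so outputs are a pure function of
(seed, spec).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .model import (MAX_LINKER, NUC_LEN, SEGMENTS, DurationModel, LinkerModel,
                    NucleosomeModel, TrainedModel, decode_sequence)
from .seqio import DyadMap, DyadRecord, GenomeSequence


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    genome_length: int = 100_000
    divergence: float = 0.5
    duration_mean: float = 25.0      # mean linker length, bp
    duration_disp: float = 3.0       # negative-binomial dispersion r
    time_dependence: bool = True


def _nbinom_duration(mean: float, disp: float) -> DurationModel:
    p = disp / (disp + mean - 1.0)   # support shifted to start at 1 bp
    pmf = stats.nbinom.pmf(np.arange(MAX_LINKER), disp, p)
    return DurationModel(Pd=pmf / pmf.sum())


def _rows(base: np.ndarray, n_rows: int, lam: float,
          rng: np.random.Generator) -> np.ndarray:
    """Conditional table whose rows jitter around ``base``; exactly ``base``
    at divergence 0."""
    jitter = lam * 0.05 * rng.standard_normal((n_rows, 4))
    rows = np.clip(base[None, :] + jitter, 1e-4, None)
    return rows / rows.sum(axis=1, keepdims=True)


def _joint4(pos_laws: np.ndarray) -> np.ndarray:
    """Joint 4-mer law as the product of four per-position base laws."""
    out = np.einsum("i,j,k,l->ijkl", *pos_laws).reshape(256)
    return out / out.sum()


def random_model(spec: FixtureSpec) -> TrainedModel:
    """A valid TrainedModel whose nucleosome-vs-linker divergence scales with
    ``spec.divergence``; divergence 0 yields identical emission laws."""
    lam = float(spec.divergence)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    u = np.full(4, 0.25)

    # linker: A/T-rich i.i.d. target with context jitter
    q_link = np.array([0.35, 0.15, 0.15, 0.35])
    p_link = u + lam * (q_link - u)
    linker = LinkerModel(
        freqL=p_link,
        tranL=_rows(p_link, 4, lam, rng),
        tranL2=_rows(p_link, 16, lam, rng),
        tranL3=_rows(p_link, 64, lam, rng),
        tranL4=_rows(p_link, 256, lam, rng),
    )

    # nucleosome: G/C-favoring per-position laws, optionally with a 10-bp
    # rotational modulation of the A/T share across the footprint
    t = np.arange(1, NUC_LEN + 1)
    if spec.time_dependence:
        at_share = 0.5 - lam * (0.1 + 0.1 * np.cos(2 * np.pi * (t - 74) / 10))
    else:
        at_share = np.full(NUC_LEN, 0.5 - 0.2 * lam)
    pos_laws = np.stack([at_share / 2, (1 - at_share) / 2,
                         (1 - at_share) / 2, at_share / 2], axis=1)
    tranN4 = np.stack([_rows(pos_laws[tt - 1], 256, lam, rng)
                       for tt in range(5, NUC_LEN + 1)])
    freqN4S = np.stack([_joint4(pos_laws[p - 1 : p + 3])
                        for p, _q in SEGMENTS.values()])
    nucleosome = NucleosomeModel(freqN4=_joint4(pos_laws[0:4]),
                                 tranN4=tranN4, freqN4S=freqN4S)

    model = TrainedModel(
        nucleosome=nucleosome,
        linker=linker,
        duration=_nbinom_duration(spec.duration_mean, spec.duration_disp),
        provenance={"source": "synthetic", "spec": asdict(spec)},
    )
    model.validate()
    return model


def _sample_rows(rng: np.random.Generator, rows: np.ndarray) -> np.ndarray:
    """One categorical draw per row of a (k, 4) probability matrix."""
    cum = np.cumsum(rows, axis=1)
    u = rng.random(rows.shape[0])
    return np.minimum((cum < u[:, None]).sum(axis=1), 3).astype(np.int64)


def sample_nucleosomes(rng: np.random.Generator, model: TrainedModel,
                       k: int) -> np.ndarray:
    """(k, 147) encoded nucleosome sequences from freqN4 + tranN4."""
    nuc = model.nucleosome
    out = np.empty((k, NUC_LEN), dtype=np.int64)
    first = rng.choice(256, size=k, p=nuc.freqN4)
    for j in range(4):
        out[:, 3 - j] = first % 4
        first //= 4
    ctx = (out[:, 0] * 64 + out[:, 1] * 16 + out[:, 2] * 4 + out[:, 3])
    for t in range(5, NUC_LEN + 1):
        base = _sample_rows(rng, nuc.tranN4[t - 5][ctx])
        out[:, t - 1] = base
        ctx = (ctx % 64) * 4 + base
    return out


def sample_linkers(rng: np.random.Generator, model: TrainedModel,
                   k: int) -> list[np.ndarray]:
    """k encoded linkers, lengths ~ Pd, bases from the order-ramp chain."""
    link, pd_ = model.linker, model.duration.Pd
    lengths = rng.choice(np.arange(1, MAX_LINKER + 1), size=k, p=pd_)
    lmax = int(lengths.max())
    mat = np.zeros((k, lmax), dtype=np.int64)
    ctx = np.zeros(k, dtype=np.int64)
    for t in range(lmax):
        if t == 0:
            rows = np.broadcast_to(link.freqL, (k, 4))
        elif t == 1:
            rows = link.tranL[mat[:, 0]]
        elif t == 2:
            rows = link.tranL2[ctx]
        elif t == 3:
            rows = link.tranL3[ctx]
        else:
            rows = link.tranL4[ctx]
        base = _sample_rows(rng, rows)
        mat[:, t] = base
        ctx = (ctx % (4 ** 3)) * 4 + base if t >= 3 else ctx * 4 + base
    return [mat[i, : lengths[i]] for i in range(k)]


def simulate(model: TrainedModel, spec: FixtureSpec,
             chrom: str = "chrS") -> tuple[GenomeSequence, DyadMap]:
    """Alternating linker/nucleosome simulation up to ``genome_length`` bp.

    The truth map holds every completed nucleosome's dyad (score 1.0); a
    final segment truncated at the chromosome end is discarded.
    """
    rng = np.random.default_rng([spec.seed, spec.genome_length])
    target = spec.genome_length
    mean_cycle = NUC_LEN + float(
        model.duration.Pd @ np.arange(1, MAX_LINKER + 1))
    pieces: list[np.ndarray] = []
    dyads: list[int] = []
    total = 0
    while total < target:
        k = max(16, int((target - total) / mean_cycle * 1.1) + 4)
        linkers = sample_linkers(rng, model, k)
        nucs = sample_nucleosomes(rng, model, k)
        for i in range(k):
            pieces.append(linkers[i])
            total += linkers[i].shape[0]
            pieces.append(nucs[i])
            dyads.append(total + 74)   # 1-based dyad of this nucleosome
            total += NUC_LEN
            if total >= target:
                break
    codes = np.concatenate(pieces)[:target]
    truth = [DyadRecord(chrom, d, 1.0) for d in dyads if d + 73 <= target]
    genome = GenomeSequence({chrom: decode_sequence(codes.astype(np.int8))})
    return genome, DyadMap(truth, category="unique")


# -- hand-built models for closed-form checks --------------------------------

def iid_model(p_nuc, p_link, Pd: np.ndarray | None = None) -> TrainedModel:
    """Model whose nucleosome and linker laws are i.i.d. with the given base
    probabilities (order (A,C,G,T)); useful for closed-form affinity checks."""
    p_nuc = np.asarray(p_nuc, dtype=np.float64)
    p_link = np.asarray(p_link, dtype=np.float64)
    pos_laws = np.tile(p_nuc, (NUC_LEN, 1))
    nucleosome = NucleosomeModel(
        freqN4=_joint4(pos_laws[0:4]),
        tranN4=np.tile(p_nuc, (NUC_LEN - 4, 256, 1)),
        freqN4S=np.stack([_joint4(pos_laws[p - 1 : p + 3])
                          for p, _q in SEGMENTS.values()]),
    )
    linker = LinkerModel(
        freqL=p_link,
        tranL=np.tile(p_link, (4, 1)),
        tranL2=np.tile(p_link, (16, 1)),
        tranL3=np.tile(p_link, (64, 1)),
        tranL4=np.tile(p_link, (256, 1)),
    )
    if Pd is None:
        duration = _nbinom_duration(25.0, 3.0)
    else:
        duration = DurationModel(Pd=np.asarray(Pd, dtype=np.float64))
    model = TrainedModel(nucleosome=nucleosome, linker=linker,
                         duration=duration,
                         provenance={"source": "synthetic-iid"})
    model.validate()
    return model


def uniform_model(Pd: np.ndarray | None = None) -> TrainedModel:
    return iid_model([0.25] * 4, [0.25] * 4, Pd)


# -- recovery metrics ---------------------------------------------------------

def tranN4_recovery_tv(estimated: NucleosomeModel, truth: NucleosomeModel,
                       weights: np.ndarray) -> float:
    """Count-weighted mean per-row total-variation distance between estimated
    and generating tranN4 tables; ``weights`` are observed context counts
    (143, 256)."""
    tv = 0.5 * np.abs(estimated.tranN4 - truth.tranN4).sum(axis=2)
    return float((tv * weights).sum() / weights.sum())


def pd_recovery_tv(estimated: DurationModel, truth: DurationModel) -> float:
    return float(0.5 * np.abs(estimated.Pd - truth.Pd).sum())
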