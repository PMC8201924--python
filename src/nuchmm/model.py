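"""Trained parameter containers for the nucleosome/linker duration HMM.

The model has three blocks:

* :class:`NucleosomeModel` -- a time-dependent 4th-order Markov chain over the
  147 nucleosomal positions: ``freqN4`` is the joint law of the 4-mer at
  positions 1-4, ``tranN4[t]`` (t = 5..147) are position-specific conditional
  tables P(base at t | preceding 4-mer), and ``freqN4S`` holds thirteen joint
  4-mer laws, one per subsegment start, used for local affinity scoring.
* :class:`LinkerModel` -- a homogeneous 4th-order chain with an order ramp
  (``freqL``, ``tranL`` .. ``tranL4``) so that sequences of any length >= 1
  can be scored.
* :class:`DurationModel` -- ``Pd``, the linker-length distribution on 1..500 bp.

Bases are encoded A=0, C=1, G=2, T=3, N=4.  A k-mer index is the base-4
little-to-big expansion ``b1*4**(k-1) + ... + bk`` of its encoded bases.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

BASES = "ACGT"
N_CODE = 4
NUC_LEN = 147
DYAD_OFFSET = 73  # dyad is nucleosomal position 74 (1-based)
MAX_LINKER = 500

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _ENCODE[ord(_b)] = _i if _b != "N" else N_CODE
    _ENCODE[ord(_b.lower())] = _i if _b != "N" else N_CODE

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# Nucleosomal subsegments A..M (1-based inclusive positions within the 147-mer).
# Each 20-21 bp segment spans two superhelical-location contact sites; the odd
# segments {A,C,E,G,I,K,M} tile the footprint exactly.
SEGMENTS: dict[str, tuple[int, int]] = {
    "A": (1, 21), "B": (12, 31), "C": (22, 42), "D": (33, 52),
    "E": (43, 63), "F": (54, 73), "G": (64, 84), "H": (75, 94),
    "I": (85, 105), "J": (96, 115), "K": (106, 126), "L": (117, 136),
    "M": (127, 147),
}
SEGMENT_IDS = tuple(SEGMENTS)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A=0,C=1,G=2,T=3,N=4).

    Raises ``ValueError`` naming the first offending character if the string
    contains anything outside {A,C,G,T,N} (case-insensitive).
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if (codes < 0).any():
        i = int(np.argmax(codes < 0))
        raise ValueError(f"illegal base {seq[i]!r} at position {i + 1}")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def _check_rows(a: np.ndarray, name: str, atol: float = 1e-9) -> None:
    sums = a.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=atol):
        raise ValueError(f"{name}: conditional rows must sum to 1")
    if (a < 0).any():
        raise ValueError(f"{name}: negative probability")


@dataclass
class NucleosomeModel:
    freqN4: np.ndarray          # (256,)
    tranN4: np.ndarray          # (143, 256, 4), tranN4[t-5] for t in 5..147
    freqN4S: np.ndarray         # (13, 256), row order A..M

    def validate(self) -> None:
        if self.freqN4.shape != (256,) or self.tranN4.shape != (143, 256, 4) \
                or self.freqN4S.shape != (13, 256):
            raise ValueError("nucleosome model has wrong dimensions")
        if not np.isclose(self.freqN4.sum(), 1.0, atol=1e-9):
            raise ValueError("freqN4 must sum to 1")
        _check_rows(self.tranN4, "tranN4")
        if not np.allclose(self.freqN4S.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("freqN4S tables must sum to 1")


@dataclass
class LinkerModel:
    freqL: np.ndarray           # (4,)
    tranL: np.ndarray           # (4, 4)
    tranL2: np.ndarray          # (16, 4)
    tranL3: np.ndarray          # (64, 4)
    tranL4: np.ndarray          # (256, 4)

    def validate(self) -> None:
        for name in ("freqL", "tranL", "tranL2", "tranL3", "tranL4"):
            a = getattr(self, name)
            if a.shape[-1] != 4:
                raise ValueError(f"{name}: wrong shape")
        if not np.isclose(self.freqL.sum(), 1.0, atol=1e-9):
            raise ValueError("freqL must sum to 1")
        for name in ("tranL", "tranL2", "tranL3", "tranL4"):
            _check_rows(getattr(self, name), name)


@dataclass
class DurationModel:
    Pd: np.ndarray              # (500,), Pd[d-1] = P(linker length = d)

    def validate(self) -> None:
        if self.Pd.shape != (MAX_LINKER,):
            raise ValueError("Pd must have support 1..500")
        if (self.Pd < 0).any() or not np.isclose(self.Pd.sum(), 1.0, atol=1e-9):
            raise ValueError("Pd must be a probability distribution")

    def survival(self) -> np.ndarray:
        """S[d] = P(length >= d) for d = 0..500, with S[0] = 1."""
        s = np.concatenate([[1.0], self.Pd[::-1].cumsum()[::-1]])
        s[0] = 1.0
        return s


@dataclass
class TrainedModel:
    nucleosome: NucleosomeModel
    linker: LinkerModel
    duration: DurationModel
    provenance: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        self.nucleosome.validate()
        self.linker.validate()
        self.duration.validate()

    # -- serialization ------------------------------------------------------

    _ARRAYS = (
        ("nucleosome", "freqN4"), ("nucleosome", "tranN4"),
        ("nucleosome", "freqN4S"),
        ("linker", "freqL"), ("linker", "tranL"), ("linker", "tranL2"),
        ("linker", "tranL3"), ("linker", "tranL4"),
        ("duration", "Pd"),
    )

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"format": "nuchmm-model", "version": 1,
                               "provenance": self.provenance}
        for block, name in self._ARRAYS:
            out[name] = getattr(getattr(self, block), name).tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TrainedModel":
        if d.get("format") != "nuchmm-model":
            raise ValueError("not a nuchmm model file")
        g = {name: np.asarray(d[name], dtype=np.float64)
             for _, name in cls._ARRAYS}
        m = cls(
            nucleosome=NucleosomeModel(g["freqN4"], g["tranN4"], g["freqN4S"]),
            linker=LinkerModel(g["freqL"], g["tranL"], g["tranL2"],
                               g["tranL3"], g["tranL4"]),
            duration=DurationModel(g["Pd"]),
            provenance=d.get("provenance", {}),
        )
        m.validate()
        return m

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def checksum(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
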