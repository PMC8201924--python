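"""Paired wild-type / edited prediction of mutation effects on positioning.

An edit is a replacement of ``ref`` (possibly empty, for a pure insertion) by
``alt`` (possibly empty, for a deletion) starting at a 1-based position of a
plain query window.  Both sequences are decoded with the same model and the
occupancy change is reported in the wild-type coordinate frame; positions
created by an insertion exist only in the edited frame and are reported
separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dhmm import PredictionTrack, predict
from .model import TrainedModel, encode_sequence


@dataclass(frozen=True)
class EditSpec:
    position: int          # 1-based insertion point / replacement start
    ref: str = ""          # replaced substring ("" = pure insertion)
    alt: str = ""          # inserted string ("" = pure deletion)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("edit position must be >= 1")
        if self.alt:
            codes = encode_sequence(self.alt)
            if (codes > 3).any():
                raise ValueError("alt must be over {A,C,G,T}")

    @property
    def shift(self) -> int:
        return len(self.alt) - len(self.ref)


def apply_edit(seq: str, edit: EditSpec) -> str:
    """Replace ``edit.ref`` with ``edit.alt`` at ``edit.position``; for an
    empty ref the alt is inserted so that it occupies positions
    ``position .. position+len(alt)-1`` of the result."""
    i = edit.position - 1
    found = seq[i : i + len(edit.ref)]
    if found != edit.ref:
        raise ValueError(
            f"ref mismatch at position {edit.position}: expected "
            f"{edit.ref!r}, found {found!r}")
    return seq[:i] + edit.alt + seq[i + len(edit.ref):]


@dataclass
class PairedPrediction:
    wildtype: PredictionTrack
    edited: PredictionTrack
    edit: EditSpec

    def map_position(self, wt_pos: int) -> int | None:
        """Edited-frame coordinate of a wild-type position; None inside the
        replaced region.  The map is monotone."""
        if wt_pos < self.edit.position:
            return wt_pos
        if wt_pos < self.edit.position + len(self.edit.ref):
            return None
        return wt_pos + self.edit.shift

    def inserted_positions(self) -> np.ndarray:
        """Edited-frame positions occupied by the inserted alt string."""
        return np.arange(self.edit.position,
                         self.edit.position + len(self.edit.alt))

    def delta_occupancy(self) -> np.ndarray:
        """Edited minus wild-type occupancy over wild-type coordinates;
        NaN inside the replaced region."""
        n = self.wildtype.n
        delta = np.full(n, np.nan)
        pos = np.arange(1, n + 1)
        before = pos < self.edit.position
        after = pos >= self.edit.position + len(self.edit.ref)
        delta[before] = (self.edited.occupancy[pos[before] - 1]
                         - self.wildtype.occupancy[pos[before] - 1])
        mapped = pos[after] + self.edit.shift
        delta[after] = (self.edited.occupancy[mapped - 1]
                        - self.wildtype.occupancy[pos[after] - 1])
        return delta

    def to_tsv(self, path: str | Path) -> None:
        """Paired table over wild-type coordinates (edited values aligned via
        the coordinate map; NA where a wild-type position was replaced)."""
        delta = self.delta_occupancy()
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("wt_pos\ted_pos\twt_occup\ted_occup\tdelta_occup\t"
                     "wt_pdyad\ted_pdyad\n")
            for i in range(self.wildtype.n):
                ed = self.map_position(i + 1)
                wt_occ = self.wildtype.occupancy[i]
                wt_pd = self.wildtype.pdyad[i]
                if ed is None:
                    fh.write(f"{i + 1}\tNA\t{wt_occ:.6g}\tNA\tNA\t"
                             f"{wt_pd:.6g}\tNA\n")
                else:
                    fh.write(
                        f"{i + 1}\t{ed}\t{wt_occ:.6g}\t"
                        f"{self.edited.occupancy[ed - 1]:.6g}\t"
                        f"{delta[i]:.6g}\t{wt_pd:.6g}\t"
                        f"{self.edited.pdyad[ed - 1]:.6g}\n")


def predict_edit(wt_seq: str, edit: EditSpec, model: TrainedModel,
                 **options) -> PairedPrediction:
    """Decode the wild-type and edited sequences and pair the tracks."""
    ed_seq = apply_edit(wt_seq, edit)
    return PairedPrediction(
        wildtype=predict(wt_seq, model, query_id="wildtype", **options),
        edited=predict(ed_seq, model, query_id="edited", **options),
        edit=edit,
    )
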