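"""The siRMSD statistic.

siRMSD quantifies how far the nucleobases of a chemically modified guide
strand have moved from their positions in the unmodified strand, both posed
on AGO2 in the same frame:

    siRMSD (Å) = sqrt( (1/K) * Σ_i δ_i² )

where δ_i is the distance between equivalent nucleobase heavy atoms of the
modified and unmodified structures and K the number of paired atoms.  Only
nucleobase atoms enter the statistic — sugar and phosphate atoms are
excluded even when present.

For a modification at guide position N, the statistic is evaluated over
windows drawn from {N−1, N, N+1}.  Three combination modes are provided for
multi-nucleotide windows:

* ``POOLED`` (default): one siRMSD over the union of the window's atoms
  (units stay Å; reduces exactly to the single-nucleotide statistic).
* ``SUM_RMSD``: sum of the per-nucleotide siRMSD values (Å).
* ``SUM_MSD``: sum of the per-nucleotide mean squared distances (Å²).

The three modes are monotone transforms of one another only in special
cases, so the choice matters for cross-study comparison; all remain
selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PairingError
from .structures import (
    AtomPairing,
    StructureModel,
    heavy_atom_selection,
    pair_by_name,
)

SEED_POSITIONS = range(2, 9)  # guide nucleotides 2-8, 1-based from the 5' end


class CombinationMode(str, Enum):
    POOLED = "pooled"
    SUM_RMSD = "sum_rmsd"
    SUM_MSD = "sum_msd"


#: All window combinations evaluated in a profile scan, as offset tuples
#: relative to the modified position N, with their conventional labels.
WINDOW_COMBINATIONS: tuple[tuple[str, tuple[int, ...]], ...] = (
    ("N-1", (-1,)),
    ("N", (0,)),
    ("N+1", (1,)),
    ("N-1/N", (-1, 0)),
    ("N-1/N+1", (-1, 1)),
    ("N/N+1", (0, 1)),
    ("N-1/N/N+1", (-1, 0, 1)),
)

_COMBINATION_BY_LABEL = {label: offsets for label, offsets in WINDOW_COMBINATIONS}


@dataclass(frozen=True)
class WindowSpec:
    """A window around modified position N: a non-empty subset of {N−1, N, N+1}."""

    N: int
    members: tuple[int, ...]  # absolute guide positions, sorted

    def __post_init__(self) -> None:
        members = tuple(sorted(set(self.members)))
        object.__setattr__(self, "members", members)
        if not members:
            raise ValueError("window must have at least one member")
        allowed = {self.N - 1, self.N, self.N + 1}
        if not set(members) <= allowed:
            raise ValueError(
                f"window members {members} must be a subset of "
                f"{{N-1, N, N+1}} = {sorted(allowed)}")
        if any(p < 1 for p in members):
            raise ValueError("window members must be >= 1")

    @classmethod
    def from_offsets(cls, N: int, offsets: Iterable[int]) -> "WindowSpec":
        return cls(N, tuple(N + o for o in offsets))

    @classmethod
    def from_label(cls, N: int, label: str) -> "WindowSpec":
        """Build from a combination label such as ``"N-1/N/N+1"``."""
        key = label.strip().upper().replace(" ", "")
        if key not in _COMBINATION_BY_LABEL:
            raise ValueError(
                f"unknown window label {label!r}; expected one of "
                f"{[l for l, _ in WINDOW_COMBINATIONS]}")
        return cls.from_offsets(N, _COMBINATION_BY_LABEL[key])

    @property
    def label(self) -> str:
        offsets = tuple(p - self.N for p in self.members)
        for label, combo in WINDOW_COMBINATIONS:
            if tuple(sorted(combo)) == offsets:
                return label
        return "/".join(f"N{o:+d}" if o else "N" for o in offsets)


@dataclass
class SiRmsdResult:
    """siRMSD of one window: the value, atom count, and per-nucleotide breakdown."""

    window: WindowSpec
    mode: CombinationMode
    value: float  # Å (Å² for SUM_MSD)
    K: int
    per_nucleotide: dict[int, float]  # position -> single-nucleotide siRMSD (Å)
    per_nucleotide_K: dict[int, int]

    def to_dict(self) -> dict:
        return {
            "N": self.window.N,
            "window": self.window.label,
            "mode": self.mode.value,
            "value": self.value,
            "K": self.K,
            "per_nucleotide": {str(k): v for k, v in self.per_nucleotide.items()},
        }


def sirmsd_single(pairing: AtomPairing) -> float:
    """sqrt of the mean squared per-atom distance of a pairing."""
    if pairing.K < 1:
        raise PairingError("siRMSD of an empty pairing is undefined")
    deltas = pairing.deltas
    return float(math.sqrt(float(np.mean(deltas ** 2))))


def sirmsd_window(
    modified: StructureModel,
    unmodified: StructureModel,
    window: WindowSpec,
    mode: CombinationMode = CombinationMode.POOLED,
    superpose: bool = False,
) -> SiRmsdResult:
    """Evaluate siRMSD over a window of nucleobases.

    Every member position must be present in both models with a complete
    nucleobase heavy-atom set.
    """
    mode = CombinationMode(mode)
    for pos in window.members:
        if not (modified.has_position(pos) and unmodified.has_position(pos)):
            raise PairingError(
                f"window member position {pos} absent from "
                f"{'modified' if not modified.has_position(pos) else 'unmodified'} model")
    per_nt: dict[int, float] = {}
    per_nt_K: dict[int, int] = {}
    sq_sums: dict[int, float] = {}
    for pos in window.members:
        selection = heavy_atom_selection(unmodified, [pos])
        pairing = pair_by_name(modified, unmodified, selection, superpose=superpose)
        per_nt[pos] = sirmsd_single(pairing)
        per_nt_K[pos] = pairing.K
        sq_sums[pos] = float(np.sum(pairing.deltas ** 2))

    K = sum(per_nt_K.values())
    if mode is CombinationMode.POOLED:
        value = math.sqrt(sum(sq_sums.values()) / K)
    elif mode is CombinationMode.SUM_RMSD:
        value = sum(per_nt.values())
    else:  # SUM_MSD
        value = sum(sq_sums[p] / per_nt_K[p] for p in window.members)
    return SiRmsdResult(window, mode, float(value), K, per_nt, per_nt_K)


def profile_scan(
    model_pairs: Mapping[tuple[int, str], tuple[StructureModel, StructureModel]],
    modes: Sequence[CombinationMode] = (CombinationMode.POOLED,),
) -> pd.DataFrame:
    """Scan every window combination for every (position, modification) pair.

    ``model_pairs`` maps (modified position N, modification code) to a
    (modified, unmodified) structure pair.  Returns one row per
    (position, modification, combination, mode) in deterministic order, with
    columns ``position, modification, combination, mode, sirmsd_A, K``.
    """
    rows = []
    for (position, modification) in sorted(model_pairs):
        modified, unmodified = model_pairs[(position, modification)]
        for label, offsets in WINDOW_COMBINATIONS:
            window = WindowSpec.from_offsets(position, offsets)
            for mode in modes:
                result = sirmsd_window(modified, unmodified, window, mode)
                rows.append({
                    "position": position,
                    "modification": modification,
                    "combination": label,
                    "mode": CombinationMode(mode).value,
                    "sirmsd_A": result.value,
                    "K": result.K,
                })
    return pd.DataFrame(
        rows, columns=["position", "modification", "combination", "mode",
                       "sirmsd_A", "K"])
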