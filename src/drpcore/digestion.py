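"""Partial-digestion state enumeration and chain-fragment derivation.

Trypsin digestion of a disulphide-knotted 2S albumin rarely goes to
completion: the observed digestion-resistant species correspond to a small
subset of the permitted cleavage sites actually being hydrolysed.  A
:class:`DigestionState` records one such subset; :func:`fragment_state`
derives the contiguous chain fragments it produces.  Enumeration is
exhaustive up to ``max_cuts`` — candidate pruning on mass happens
downstream in :mod:`drpcore.ms_inference`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .errors import StateError
from .sequence_model import (
    CleavageSite,
    IsoformRecord,
    TRYPSIN_MINIMAL,
    find_cleavage_sites,
)


@dataclass(frozen=True)
class DigestionState:
    """A chosen subset of permitted cleavage sites, actually cleaved."""

    isoform_id: str
    cut_positions: tuple
    terminal_variant: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "cut_positions", tuple(sorted(set(self.cut_positions)))
        )

    @property
    def n_cuts(self) -> int:
        return len(self.cut_positions)


@dataclass(frozen=True)
class ChainFragment:
    """A contiguous stretch of the (variant-adjusted) sequence.

    ``start``/``end`` are 1-based inclusive; ``cys_positions`` are absolute
    positions (same frame as ``start``) of cysteines inside the fragment.
    """

    start: int
    end: int
    sequence: str
    cys_positions: tuple = ()

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise StateError(f"bad fragment bounds {self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise StateError(
                f"fragment {self.start}-{self.end} does not match its "
                f"sequence of length {len(self.sequence)}"
            )

    @property
    def n_cys(self) -> int:
        return len(self.cys_positions)

    def __len__(self) -> int:
        return len(self.sequence)


def enumerate_states(
    sites: list[CleavageSite],
    max_cuts: int,
    isoform_id: str = "",
    terminal_variant: int = 0,
) -> list[DigestionState]:
    """All subsets of ``sites`` of size 0..max_cuts, lexicographic order."""
    if max_cuts < 0:
        raise ValueError(f"max_cuts must be >= 0, got {max_cuts}")
    positions = sorted({s.position for s in sites})
    states = []
    for k in range(min(max_cuts, len(positions)) + 1):
        for combo in itertools.combinations(positions, k):
            states.append(
                DigestionState(isoform_id, combo, terminal_variant)
            )
    return states


def fragments_from_cuts(sequence: str, cuts) -> list[ChainFragment]:
    """Partition ``sequence`` at the bonds after each position in ``cuts``."""
    bounds = [0, *sorted(cuts), len(sequence)]
    frags = []
    for a, b in zip(bounds, bounds[1:]):
        sub = sequence[a:b]
        frags.append(
            ChainFragment(
                start=a + 1,
                end=b,
                sequence=sub,
                cys_positions=tuple(
                    a + 1 + k for k, c in enumerate(sub) if c == "C"
                ),
            )
        )
    return frags


def fragment_state(
    record: IsoformRecord,
    state: DigestionState,
    permitted=None,
) -> list[ChainFragment]:
    """Chain fragments produced by a digestion state.

    ``record`` must already be the variant-adjusted isoform the state refers
    to.  ``permitted`` (a set of positions) skips re-deriving the site list;
    when omitted the default trypsin rule is used for validation.
    """
    if permitted is None:
        permitted = {
            s.position for s in find_cleavage_sites(record, TRYPSIN_MINIMAL)
        }
    illegal = set(state.cut_positions) - set(permitted)
    if illegal:
        raise StateError(
            f"cut positions {sorted(illegal)} are not permitted cleavage "
            f"sites of {record.id!r}"
        )
    return fragments_from_cuts(record.sequence, state.cut_positions)
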