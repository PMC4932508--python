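"""Annotated protein isoforms and protease cleavage-site location.

An :class:`IsoformRecord` carries a mature-chain sequence together with the
annotations that matter for digestion-resistant peptide (DRP) analysis of
2S albumins: disulphide topology, hydroxyproline sites, and natural
terminal-processing heterogeneity (e.g. the Y/RY C-terminal trimming seen
in peanut conglutins).  Positions are 1-based throughout; a cleavage site
at position ``i`` cuts the peptide bond between residues ``i`` and ``i+1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, TopologyError

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class IsoformRecord:
    """A validated protein isoform with digestion-relevant annotations.

    Attributes
    ----------
    id : str
        Record identifier (FASTA header word).
    sequence : str
        One-letter amino-acid codes, standard 20-letter alphabet.
    disulphides : frozenset of (int, int)
        Unordered cysteine position pairs, stored as (low, high).
    hydroxyprolines : frozenset of int
        Positions of prolines that may carry a +16 Da hydroxylation.
    terminal_variants : tuple of (int, int)
        ``(n_trim, c_trim)`` alternatives describing natural terminal
        processing; ``(0, 0)`` is the unprocessed chain.
    origin_offset : int
        Number of N-terminal residues removed relative to the original
        record; position ``p`` here maps back to ``p + origin_offset``.
    """

    id: str
    sequence: str
    disulphides: frozenset = frozenset()
    hydroxyprolines: frozenset = frozenset()
    terminal_variants: tuple = ((0, 0),)
    origin_offset: int = 0

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"{self.id!r}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise FormatError(
                f"{self.id!r}: non-standard residues {sorted(bad)}"
            )
        n = len(self.sequence)
        pairs = frozenset(
            (min(i, j), max(i, j)) for i, j in self.disulphides
        )
        object.__setattr__(self, "disulphides", pairs)
        object.__setattr__(
            self, "hydroxyprolines", frozenset(self.hydroxyprolines)
        )
        object.__setattr__(
            self,
            "terminal_variants",
            tuple((int(a), int(b)) for a, b in self.terminal_variants),
        )
        seen_cys = set()
        for i, j in self.disulphides:
            if i == j:
                raise TopologyError(
                    f"{self.id!r}: disulphide partners must differ ({i},{j})"
                )
            for p in (i, j):
                if not 1 <= p <= n:
                    raise TopologyError(
                        f"{self.id!r}: disulphide position {p} outside 1..{n}"
                    )
                if self.sequence[p - 1] != "C":
                    raise TopologyError(
                        f"{self.id!r}: disulphide position {p} is "
                        f"{self.sequence[p - 1]!r}, not Cys"
                    )
                if p in seen_cys:
                    raise TopologyError(
                        f"{self.id!r}: Cys {p} in more than one disulphide"
                    )
                seen_cys.add(p)
        for p in self.hydroxyprolines:
            if not 1 <= p <= n:
                raise TopologyError(
                    f"{self.id!r}: hydroxyproline position {p} outside 1..{n}"
                )
            if self.sequence[p - 1] != "P":
                raise TopologyError(
                    f"{self.id!r}: hydroxyproline position {p} is "
                    f"{self.sequence[p - 1]!r}, not Pro"
                )
        for n_trim, c_trim in self.terminal_variants:
            if n_trim < 0 or c_trim < 0:
                raise TopologyError(f"{self.id!r}: negative terminal trim")
            if n_trim + c_trim >= n:
                raise TopologyError(
                    f"{self.id!r}: trim ({n_trim},{c_trim}) leaves no residues"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageSite:
    """Cleavable peptide bond after residue ``position`` (1-based)."""

    position: int
    residue: str
    context: str


@dataclass(frozen=True)
class CleavageRuleSet:
    """Protease specificity as target residues plus context patterns.

    ``blocked`` and ``overrides`` are (previous, target, next) triples;
    ``'*'`` matches anything (including a missing neighbour at a terminus).
    Overrides win over blocks, encoding exceptions-to-exceptions such as
    trypsin cleaving W-K|P despite the general proline block.
    """

    name: str
    target_residues: frozenset
    blocked: tuple = ()
    overrides: tuple = ()

    def permits(self, prev: str, target: str, nxt: str) -> bool:
        if target not in self.target_residues:
            return False

        def matches(pat):
            return all(
                p == "*" or p == c for p, c in zip(pat, (prev, target, nxt))
            )

        if any(matches(pat) for pat in self.overrides):
            return True
        return not any(matches(pat) for pat in self.blocked)


#: Cleave after Lys/Arg unless the next residue is Pro.
TRYPSIN_MINIMAL = CleavageRuleSet(
    name="trypsin-minimal",
    target_residues=frozenset("KR"),
    blocked=(("*", "K", "P"), ("*", "R", "P")),
)

#: Keil-rule trypsin with the standard context exceptions
#: (blocked CKD/DKD/CKH/CKY/KKR and CRK/RRH/RRR; WKP and MRP still cleave).
TRYPSIN_KEIL = CleavageRuleSet(
    name="trypsin-keil",
    target_residues=frozenset("KR"),
    blocked=(
        ("*", "K", "P"),
        ("*", "R", "P"),
        ("C", "K", "D"),
        ("D", "K", "D"),
        ("C", "K", "H"),
        ("C", "K", "Y"),
        ("K", "K", "R"),
        ("C", "R", "K"),
        ("R", "R", "H"),
        ("R", "R", "R"),
    ),
    overrides=(("W", "K", "P"), ("M", "R", "P")),
)

RULESETS = {"minimal": TRYPSIN_MINIMAL, "keil": TRYPSIN_KEIL}


def find_cleavage_sites(
    record: IsoformRecord, rules: CleavageRuleSet = TRYPSIN_MINIMAL
) -> list[CleavageSite]:
    """Locate cleavable bonds; deterministic, strictly increasing positions.

    The final residue is never a site because there is no bond after it.
    """
    seq = record.sequence
    sites = []
    for i in range(1, len(seq)):  # bond after residue i (1-based)
        target = seq[i - 1]
        prev = seq[i - 2] if i >= 2 else ""
        nxt = seq[i]
        if rules.permits(prev, target, nxt):
            lo = max(0, i - 3)
            hi = min(len(seq), i + 2)
            sites.append(
                CleavageSite(position=i, residue=target, context=seq[lo:hi])
            )
    return sites


def apply_terminal_variant(
    record: IsoformRecord, variant: tuple[int, int]
) -> IsoformRecord:
    """Trim ``(n_trim, c_trim)`` residues and re-index annotations.

    Raises :class:`TopologyError` when the trim would delete a
    disulphide-bonded cysteine while keeping the bond.
    """
    n_trim, c_trim = int(variant[0]), int(variant[1])
    n = len(record.sequence)
    if n_trim < 0 or c_trim < 0:
        raise TopologyError(f"negative trim {variant}")
    if n_trim + c_trim >= n:
        raise TopologyError(f"trim {variant} leaves an empty sequence")
    if n_trim == 0 and c_trim == 0:
        return record
    lo, hi = n_trim + 1, n - c_trim  # retained original positions
    for i, j in record.disulphides:
        if not (lo <= i <= hi and lo <= j <= hi):
            raise TopologyError(
                f"trim {variant} removes disulphide-bonded Cys of ({i},{j})"
            )
    return IsoformRecord(
        id=record.id,
        sequence=record.sequence[n_trim : n - c_trim],
        disulphides=frozenset(
            (i - n_trim, j - n_trim) for i, j in record.disulphides
        ),
        hydroxyprolines=frozenset(
            p - n_trim for p in record.hydroxyprolines if lo <= p <= hi
        ),
        terminal_variants=((0, 0),),
        origin_offset=record.origin_offset + n_trim,
    )


def to_original_coordinates(record: IsoformRecord, position: int) -> int:
    """Map a position in a variant-adjusted record back to the parent."""
    return position + record.origin_offset


# --------------------------------------------------------------------------
# on-disk representation: FASTA sequence + JSON topology sidecar
# --------------------------------------------------------------------------

def load_isoform(
    fasta_path, topology_path, record_id: str | None = None
) -> IsoformRecord:
    """Read a FASTA record plus its JSON topology sidecar.

    The sidecar holds ``{"disulphides": [[i, j], ...],
    "hydroxyprolines": [...], "terminal_variants": [[n, c], ...]}``.
    """
    fasta_path, topology_path = Path(fasta_path), Path(topology_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if record_id is None:
        if len(records) != 1:
            raise FormatError(
                f"{fasta_path}: expected exactly one record, found "
                f"{len(records)}; pass record_id to select one"
            )
        rec = records[0]
    else:
        hits = [r for r in records if r.id == record_id]
        if len(hits) != 1:
            raise FormatError(
                f"{fasta_path}: expected exactly one record {record_id!r}, "
                f"found {len(hits)}"
            )
        rec = hits[0]
    try:
        topo = json.loads(topology_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{topology_path}: invalid JSON ({exc})") from exc
    return IsoformRecord(
        id=rec.id,
        sequence=str(rec.seq).upper(),
        disulphides=frozenset(
            tuple(pair) for pair in topo.get("disulphides", [])
        ),
        hydroxyprolines=frozenset(topo.get("hydroxyprolines", [])),
        terminal_variants=tuple(
            tuple(v) for v in topo.get("terminal_variants", [[0, 0]])
        )
        or ((0, 0),),
    )


def write_isoform(record: IsoformRecord, fasta_path, topology_path) -> None:
    """Write the FASTA + topology sidecar pair read back by `load_isoform`."""
    fasta_path, topology_path = Path(fasta_path), Path(topology_path)
    SeqIO.write(
        [SeqRecord(Seq(record.sequence), id=record.id, description="")],
        str(fasta_path),
        "fasta",
    )
    topo = {
        "disulphides": [list(p) for p in sorted(record.disulphides)],
        "hydroxyprolines": sorted(record.hydroxyprolines),
        "terminal_variants": [list(v) for v in record.terminal_variants],
    }
    topology_path.write_text(json.dumps(topo, indent=1) + "\n")
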