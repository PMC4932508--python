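"""Disulphide-linked DRP species assembly, theoretical masses, and pI.

After partial digestion the chain fragments of a 2S albumin remain
associated wherever a disulphide bond spans two fragments; the connected
components of that fragment/bond graph are the observable species.  A
fragment without any bonded cysteine detaches from the core as a released
peptide.  Masses follow the usual peptide bookkeeping:

* residue masses + one water per chain;
* −2 H per intact disulphide bond;
* +16 Da (nominal) per occupied hydroxyproline;
* +57 Da (nominal) per carbamidomethylated cysteine, applicable only after
  reduction — partial alkylation of a chain with ``n`` cysteines yields the
  characteristic ladder of ``n + 1`` masses spaced 57 Da apart.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
from pyteomics import mass as _pmass
from scipy.optimize import brentq

from .digestion import ChainFragment
from .errors import TopologyError

PROTON_MASS = 1.007276


@dataclass(frozen=True)
class MassOptions:
    """Mass-bookkeeping constants for one convention (mono or average)."""

    mode: str = "monoisotopic"
    proton_mass: float = PROTON_MASS
    water: float = 18.010565
    disulphide_delta: float = -2.015650
    hydroxylation_delta: float = 15.994915
    alkylation_delta: float = 57.021464

    @classmethod
    def monoisotopic(cls) -> "MassOptions":
        return cls()

    @classmethod
    def average(cls) -> "MassOptions":
        return cls(
            mode="average",
            water=18.0153,
            disulphide_delta=-2.0159,
            hydroxylation_delta=15.9994,
            alkylation_delta=57.0513,
        )


MONO = MassOptions.monoisotopic()
AVERAGE = MassOptions.average()


@lru_cache(maxsize=2)
def residue_masses(mode: str = "monoisotopic") -> dict:
    """Per-residue masses from the pyteomics elemental compositions."""
    if mode == "monoisotopic":
        return {
            aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
        }
    if mode == "average":
        return {
            aa: _pmass.calculate_mass(
                composition=_pmass.std_aa_comp[aa], average=True
            )
            for aa in "ACDEFGHIKLMNPQRSTVWY"
        }
    raise ValueError(f"unknown mass mode {mode!r}")


def _sequence_of(fragment) -> str:
    return (
        fragment.sequence
        if isinstance(fragment, ChainFragment)
        else str(fragment)
    )


def chain_mass(
    fragment,
    n_hydroxyprolines: int = 0,
    n_alkylated_cys: int = 0,
    opts: MassOptions = MONO,
) -> float:
    """Neutral mass of one chain with the given modification counts."""
    seq = _sequence_of(fragment)
    if not seq:
        raise ValueError("empty fragment has no mass")
    if not 0 <= n_alkylated_cys <= seq.count("C"):
        raise ValueError(
            f"n_alkylated_cys={n_alkylated_cys} exceeds the "
            f"{seq.count('C')} cysteines of the fragment"
        )
    if not 0 <= n_hydroxyprolines <= seq.count("P"):
        raise ValueError(
            f"n_hydroxyprolines={n_hydroxyprolines} exceeds the "
            f"{seq.count('P')} prolines of the fragment"
        )
    table = residue_masses(opts.mode)
    return (
        sum(table[aa] for aa in seq)
        + opts.water
        + n_hydroxyprolines * opts.hydroxylation_delta
        + n_alkylated_cys * opts.alkylation_delta
    )


@dataclass(frozen=True)
class DrpSpecies:
    """Chains held together by disulphide bonds (or a released peptide)."""

    chains: tuple  # ChainFragments sorted by start
    internal_disulphides: frozenset = frozenset()
    released: bool = False

    @property
    def id(self) -> str:
        return "+".join(f"{c.start}-{c.end}" for c in self.chains)

    @property
    def n_disulphides(self) -> int:
        return len(self.internal_disulphides)


def assemble_species(
    fragments: list[ChainFragment], disulphides
) -> list[DrpSpecies]:
    """Group fragments into species = connected components under bonds.

    Every disulphide position must fall inside exactly one fragment; a
    position outside all fragments raises :class:`TopologyError`.  A
    singleton fragment with no bonded cysteine is flagged ``released``.
    """
    def owner(pos: int) -> int:
        for k, f in enumerate(fragments):
            if f.start <= pos <= f.end:
                return k
        raise TopologyError(
            f"disulphide position {pos} not covered by any fragment"
        )

    graph = nx.Graph()
    graph.add_nodes_from(range(len(fragments)))
    bond_owners = []
    for i, j in disulphides:
        a, b = owner(i), owner(j)
        graph.add_edge(a, b)
        bond_owners.append(((min(i, j), max(i, j)), {a, b}))

    species = []
    for comp in nx.connected_components(graph):
        members = sorted(comp, key=lambda k: fragments[k].start)
        internal = frozenset(
            bond for bond, owners in bond_owners if owners <= comp
        )
        species.append(
            DrpSpecies(
                chains=tuple(fragments[k] for k in members),
                internal_disulphides=internal,
                released=(len(members) == 1 and not internal),
            )
        )
    species.sort(key=lambda s: s.chains[0].start)
    return species


def species_intact_mass(
    species: DrpSpecies,
    opts: MassOptions = MONO,
    n_hydroxyprolines: int = 0,
) -> float:
    """Neutral mass of the non-reduced species (no alkylation possible)."""
    total = sum(chain_mass(c, 0, 0, opts) for c in species.chains)
    return (
        total
        + species.n_disulphides * opts.disulphide_delta
        + n_hydroxyprolines * opts.hydroxylation_delta
    )


def alkylation_ladder(
    fragment,
    opts: MassOptions = MONO,
    n_hydroxyprolines: int = 0,
) -> list[float]:
    """Masses of the partial-alkylation ladder, k = 0..nCys, ascending."""
    seq = _sequence_of(fragment)
    base = chain_mass(fragment, n_hydroxyprolines, 0, opts)
    return [
        base + k * opts.alkylation_delta for k in range(seq.count("C") + 1)
    ]


# --------------------------------------------------------------------------
# theoretical isoelectric point
# --------------------------------------------------------------------------

# EMBOSS pKa set (iep); absolute pI shifts by roughly +/-0.3 between
# published tables, which is why pI is used as a verification direction
# rather than a hard filter.
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


def net_charge(fragment, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a free peptide at ``ph``."""
    seq = _sequence_of(fragment)
    if not seq:
        raise ValueError("empty fragment has no charge")
    charge = 1.0 / (1.0 + 10.0 ** (ph - PKA_NTERM))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_CTERM - ph))
    for aa, pka in PKA_POSITIVE.items():
        charge += seq.count(aa) / (1.0 + 10.0 ** (ph - pka))
    for aa, pka in PKA_NEGATIVE.items():
        charge -= seq.count(aa) / (1.0 + 10.0 ** (pka - ph))
    return charge


def theoretical_pi(fragment) -> float:
    """pH at which the peptide's net charge is zero (bisection on 0..14)."""
    return float(
        brentq(lambda ph: net_charge(fragment, ph), 0.0, 14.0, xtol=1e-6)
    )
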