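"""Species assembly, theoretical masses, alkylation ladders, pI."""

import numpy as np
import pytest

from drpcore import (
    AVERAGE,
    MONO,
    alkylation_ladder,
    assemble_species,
    chain_mass,
    species_intact_mass,
    theoretical_pi,
)
from drpcore.digestion import ChainFragment, fragments_from_cuts
from drpcore.errors import TopologyError
from drpcore.species_mass import net_charge


def frag(start, seq):
    return ChainFragment(
        start=start,
        end=start + len(seq) - 1,
        sequence=seq,
        cys_positions=tuple(
            start + k for k, c in enumerate(seq) if c == "C"
        ),
    )


class TestChainMass:
    def test_glycine_monoisotopic(self):
        assert chain_mass("G") == pytest.approx(75.03203, abs=1e-5)

    def test_alkylated_cysteine(self):
        assert chain_mass("C", 0, 1) == pytest.approx(178.04121, abs=1e-5)

    def test_alkylation_increment_is_57(self, rng):
        for _ in range(20):
            seq = "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWYC"), size=12)
            )
            n_cys = seq.count("C")
            if not n_cys:
                continue
            for k in range(n_cys):
                delta = chain_mass(seq, 0, k + 1) - chain_mass(seq, 0, k)
                assert delta == pytest.approx(57.02146, abs=1e-5)

    def test_hydroxylation_increment(self):
        assert chain_mass("APA", 1, 0) - chain_mass("APA") == pytest.approx(
            15.994915, abs=1e-6
        )

    def test_average_mode_heavier_water(self):
        assert chain_mass("G", opts=AVERAGE) > chain_mass("G", opts=MONO)

    @pytest.mark.parametrize(
        "kwargs", [{"n_alkylated_cys": 1}, {"n_hydroxyprolines": 1}]
    )
    def test_counts_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            chain_mass("AG", **kwargs)

    def test_empty_fragment_rejected(self):
        with pytest.raises(ValueError):
            chain_mass("")

    def test_mass_additivity_over_partitions(self, rng):
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(200):
            seq = "".join(rng.choice(alphabet, size=rng.integers(3, 60)))
            n_cuts = int(rng.integers(0, min(5, len(seq) - 1)))
            cuts = sorted(
                rng.choice(range(1, len(seq)), size=n_cuts, replace=False)
            )
            frags = fragments_from_cuts(seq, cuts)
            total = sum(chain_mass(f) for f in frags)
            expected = chain_mass(seq) + n_cuts * MONO.water
            assert total == pytest.approx(expected, abs=1e-6)


class TestAssembly:
    def test_single_bond_joins_two_fragments(self):
        a, b = frag(1, "ACK"), frag(4, "DCE")
        (sp,) = assemble_species([a, b], {(2, 5)})
        assert sp.chains == (a, b) and not sp.released
        assert sp.internal_disulphides == frozenset({(2, 5)})

    def test_single_internal_cut_keeps_one_species(self, bonded_record):
        # one hydrolysed bond inside a crosslinked protein: two chains, one species
        frags = fragments_from_cuts(bonded_record.sequence, (3,))
        species = assemble_species(frags, bonded_record.disulphides)
        assert len(species) == 1 and len(species[0].chains) == 2

    def test_cys_free_fragment_released(self):
        frags = [frag(1, "ACK"), frag(4, "DE"), frag(6, "GCR")]
        species = assemble_species(frags, {(2, 7)})
        released = [sp for sp in species if sp.released]
        assert len(species) == 2 and len(released) == 1
        assert released[0].chains[0].sequence == "DE"

    def test_uncovered_disulphide_position_rejected(self):
        with pytest.raises(TopologyError):
            assemble_species([frag(1, "ACK")], {(2, 9)})

    def test_conservation_every_fragment_in_one_species(self, rng):
        for _ in range(100):
            frags, species = _random_assembly(rng)
            seen = [c for sp in species for c in sp.chains]
            assert sorted(seen, key=lambda f: f.start) == frags

    def test_components_match_union_find_oracle(self, rng):
        for _ in range(500):
            frags, bonds = _random_fragments_and_bonds(rng)
            species = assemble_species(frags, bonds)
            got = {
                frozenset((c.start, c.end) for c in sp.chains)
                for sp in species
            }
            assert got == _union_find_components(frags, bonds)


def _random_fragments_and_bonds(rng, n_res=60):
    seq = "".join(
        rng.choice(list("ACDEFGHIKLMNCQRSTCWY"), size=n_res)
    )
    n_cuts = int(rng.integers(0, 8))
    cuts = sorted(rng.choice(range(1, n_res), size=n_cuts, replace=False))
    frags = fragments_from_cuts(seq, cuts)
    cys = [i + 1 for i, c in enumerate(seq) if c == "C"]
    rng.shuffle(cys)
    n_bonds = int(rng.integers(0, len(cys) // 2 + 1))
    bonds = {
        (min(cys[2 * k], cys[2 * k + 1]), max(cys[2 * k], cys[2 * k + 1]))
        for k in range(n_bonds)
    }
    return frags, bonds


def _random_assembly(rng):
    frags, bonds = _random_fragments_and_bonds(rng)
    return frags, assemble_species(frags, bonds)


def _union_find_components(frags, bonds):
    parent = list(range(len(frags)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def owner(pos):
        return next(
            k for k, f in enumerate(frags) if f.start <= pos <= f.end
        )

    for i, j in bonds:
        a, b = find(owner(i)), find(owner(j))
        parent[a] = b
    comps = {}
    for k, f in enumerate(frags):
        comps.setdefault(find(k), set()).add((f.start, f.end))
    return {frozenset(v) for v in comps.values()}


class TestSpeciesMass:
    def test_disulphide_arithmetic(self):
        a, b = frag(1, "ACK"), frag(4, "DCE")
        (sp,) = assemble_species([a, b], {(2, 5)})
        expected = chain_mass(a) + chain_mass(b) - 2.015650
        assert species_intact_mass(sp) == pytest.approx(expected, abs=1e-6)

    def test_no_bonds_is_plain_sum(self):
        frags = [frag(1, "AGK"), frag(4, "DE")]
        species = assemble_species(frags, set())
        total = sum(species_intact_mass(sp) for sp in species)
        assert total == pytest.approx(
            sum(chain_mass(f) for f in frags), abs=1e-9
        )

    def test_reduction_alkylation_algebra(self, rng):
        # intact + 2*1.00783*nSS + 57.02146*nCys == sum of fully
        # reduced, fully alkylated chain masses
        for _ in range(50):
            frags, bonds = _random_fragments_and_bonds(rng)
            for sp in assemble_species(frags, bonds):
                intact = species_intact_mass(sp)
                n_ss = sp.n_disulphides
                n_cys = sum(c.n_cys for c in sp.chains)
                reduced = sum(
                    chain_mass(c, 0, c.n_cys) for c in sp.chains
                )
                assert intact + 2 * 1.00783 * n_ss + 57.02146 * n_cys == (
                    pytest.approx(reduced, abs=1e-3)
                )


class TestAlkylationLadder:
    def test_three_cys_ladder(self):
        ladder = alkylation_ladder(frag(1, "CACGC"))
        assert len(ladder) == 4
        spacing = np.diff(ladder)
        assert np.allclose(spacing, MONO.alkylation_delta)
        assert ladder == sorted(ladder)

    def test_no_cys_single_mass(self):
        assert len(alkylation_ladder(frag(1, "AGDE"))) == 1

    def test_two_step_spacing(self):
        ladder = alkylation_ladder(frag(1, "CACGC"))
        assert ladder[2] - ladder[0] == pytest.approx(114.04293, abs=1e-5)


class TestIsoelectricPoint:
    def test_basic_peptide_above_7(self):
        assert theoretical_pi("KKKK") > 7

    def test_acidic_peptide_below_7(self):
        assert theoretical_pi("DDDD") < 7

    def test_charge_at_pi_is_zero_vs_grid_oracle(self, rng):
        for _ in range(50):
            seq = "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=rng.integers(2, 30))
            )
            pi = theoretical_pi(seq)
            assert abs(net_charge(seq, pi)) < 1e-3
            # dense grid scan oracle: sign change brackets the returned pI
            grid = np.linspace(0, 14, 2801)
            charges = np.array([net_charge(seq, ph) for ph in grid])
            crossing = grid[np.argmin(np.abs(charges))]
            assert abs(pi - crossing) < 0.01

    def test_monotonicity_in_composition(self, rng):
        for _ in range(30):
            seq = "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=rng.integers(2, 20))
            )
            assert theoretical_pi(seq + "K") >= theoretical_pi(seq) - 1e-9
            assert theoretical_pi(seq + "D") <= theoretical_pi(seq) + 1e-9
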