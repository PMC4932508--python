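"""ESI charge-state deconvolution and joint intact/reduced mass inference.

Positive-mode electrospray of an intact protein species of neutral mass M
produces an envelope of peaks at m/z = (M + z·m_H+)/z over consecutive
charges z.  :func:`deconvolute` inverts that relation with a deterministic
consecutive-charge consensus: every (peak, z) interpretation is
back-calculated to a neutral-mass candidate, candidates are clustered
within a ppm tolerance, and clusters supported by at least two peaks at
consecutive charges are accepted greedily by decreasing support (which
suppresses the M/k harmonic artefacts of wrong charge assignments).

:func:`infer_digestion` then ranks enumerated digestion states by how many
experimental neutral masses — from both the non-reduced and the
reduced/alkylated sample — their theoretical species explain, requiring
joint consistency: the matched reduced chains of a candidate must
algebraically reconstruct its matched intact species mass through the
disulphide bookkeeping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .digestion import DigestionState, enumerate_states, fragments_from_cuts
from .errors import InputError
from .sequence_model import (
    CleavageRuleSet,
    IsoformRecord,
    TRYPSIN_MINIMAL,
    apply_terminal_variant,
    find_cleavage_sites,
)
from .species_mass import (
    MONO,
    MassOptions,
    assemble_species,
    residue_masses,
)


@dataclass
class PeakList:
    """Centroided positive-mode peaks (m/z, intensity)."""

    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "positive"
    scan_range: tuple = (300.0, 3000.0)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise InputError("mz and intensity lengths differ")
        if np.any(self.intensity < 0):
            raise InputError("negative peak intensity")
        lo, hi = self.scan_range
        if self.mz.size and (self.mz.min() < lo or self.mz.max() > hi):
            raise InputError(
                f"peaks outside scan range {self.scan_range}"
            )

    def __len__(self) -> int:
        return self.mz.size


@dataclass(frozen=True)
class NeutralMass:
    """One deconvoluted neutral mass with its supporting charge states."""

    mass: float
    support: int
    charges: tuple
    flagged: bool = False  # single-charge observation, no envelope consensus


@dataclass
class NeutralMassSet:
    masses: list

    def values(self) -> np.ndarray:
        return np.array([m.mass for m in self.masses], dtype=float)

    def __len__(self) -> int:
        return len(self.masses)

    def __iter__(self):
        return iter(self.masses)


def envelope_mz(mass: float, charges, proton: float = MONO.proton_mass):
    """m/z positions of a neutral mass over the given charge states."""
    z = np.asarray(list(charges), dtype=float)
    return (mass + z * proton) / z


def deconvolute(
    peaklist: PeakList,
    z_min: int = 1,
    z_max: int = 30,
    mass_tol_ppm: float = 10.0,
    proton: float = MONO.proton_mass,
) -> NeutralMassSet:
    """Collapse charge-state envelopes to neutral masses.

    Accepted masses require >=2 peaks at consecutive charges agreeing within
    ``mass_tol_ppm``; the consensus is the mean of the contributing
    back-calculations.  When ``z_min == z_max`` the charge is unambiguous and
    unexplained peaks are reported individually with ``support=1`` and
    ``flagged=True``.
    """
    if len(peaklist) == 0:
        raise InputError("empty peak list")
    if not 1 <= z_min <= z_max:
        raise ValueError(f"invalid charge range {z_min}..{z_max}")

    zs = np.arange(z_min, z_max + 1)
    # candidate neutral masses for every (peak, z) interpretation
    cand_mass = (peaklist.mz[:, None] * zs[None, :] - proton * zs[None, :]).ravel()
    cand_peak = np.repeat(np.arange(len(peaklist)), zs.size)
    cand_z = np.tile(zs, len(peaklist))
    order = np.argsort(cand_mass)
    cand_mass, cand_peak, cand_z = (
        cand_mass[order],
        cand_peak[order],
        cand_z[order],
    )

    # greedy clustering of the sorted candidates within the ppm tolerance
    clusters = []
    start = 0
    run_sum = 0.0
    for k in range(cand_mass.size):
        if k == start:
            run_sum = cand_mass[k]
            continue
        mean = run_sum / (k - start)
        if abs(cand_mass[k] - mean) <= mass_tol_ppm * 1e-6 * mean:
            run_sum += cand_mass[k]
        else:
            clusters.append((start, k))
            start = k
            run_sum = cand_mass[k]
    clusters.append((start, cand_mass.size))

    def consecutive(charges) -> bool:
        cs = sorted(set(charges))
        return any(b - a == 1 for a, b in zip(cs, cs[1:]))

    scored = []
    for a, b in clusters:
        # one interpretation per peak: keep the one nearest the cluster mean
        mean = cand_mass[a:b].mean()
        best = {}
        for k in range(a, b):
            p = cand_peak[k]
            if p not in best or abs(cand_mass[k] - mean) < abs(
                cand_mass[best[p]] - mean
            ):
                best[p] = k
        idx = sorted(best.values())
        if len(idx) >= 2 and consecutive(cand_z[idx]):
            scored.append((len(idx), mean, idx))

    # greedy acceptance by support so harmonic clusters cannot steal peaks
    scored.sort(key=lambda t: (-t[0], t[1]))
    used = np.zeros(len(peaklist), dtype=bool)
    out = []
    for _, _, idx in scored:
        free = [k for k in idx if not used[cand_peak[k]]]
        if len(free) < 2 or not consecutive(cand_z[free]):
            continue
        used[[cand_peak[k] for k in free]] = True
        consensus = float(cand_mass[free].mean())
        out.append(
            NeutralMass(
                mass=consensus,
                support=len(free),
                charges=tuple(int(z) for z in sorted(cand_z[free])),
            )
        )
        # absorb straggler peaks explainable by the accepted envelope at
        # any charge (within 2x tolerance) so they cannot seed M/k harmonics
        for p in np.nonzero(~used)[0]:
            back = peaklist.mz[p] * zs - proton * zs
            if np.any(
                np.abs(back - consensus) <= 2 * mass_tol_ppm * 1e-6 * consensus
            ):
                used[p] = True

    if z_min == z_max:
        for p in np.nonzero(~used)[0]:
            out.append(
                NeutralMass(
                    mass=float(peaklist.mz[p] * z_min - proton * z_min),
                    support=1,
                    charges=(z_min,),
                    flagged=True,
                )
            )
    out.sort(key=lambda m: m.mass)
    return NeutralMassSet(out)


@dataclass(frozen=True)
class MatchResult:
    species_id: str
    experimental_mass: float
    theoretical_mass: float
    ppm_error: float
    assignment: tuple = ()  # e.g. ("intact", n_hp) or ("reduced", n_hp, n_alk)


def match_masses(
    observed,
    theoretical: list,
    tol_ppm: float = 10.0,
) -> list[MatchResult]:
    """All (observed, theoretical) pairs within ``tol_ppm``.

    ``theoretical`` entries are ``(species_id, mass_da, assignment)``.
    Results are sorted by |ppm error| (then by id for determinism).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    obs = (
        observed.values()
        if isinstance(observed, NeutralMassSet)
        else np.asarray(observed, dtype=float)
    )
    results = []
    for sid, theo, assignment in theoretical:
        ppm = (obs - theo) / theo * 1e6
        for k in np.nonzero(np.abs(ppm) <= tol_ppm)[0]:
            results.append(
                MatchResult(
                    species_id=sid,
                    experimental_mass=float(obs[k]),
                    theoretical_mass=float(theo),
                    ppm_error=float(ppm[k]),
                    assignment=tuple(assignment),
                )
            )
    results.sort(
        key=lambda r: (abs(r.ppm_error), r.species_id, r.theoretical_mass)
    )
    return results


@dataclass
class InferenceConfig:
    max_cuts: int = 6
    tol_ppm: float = 10.0
    tol_da: float = 1.0  # used instead of ppm in average-mass mode
    mass_options: MassOptions = field(default_factory=MassOptions.monoisotopic)
    ruleset: CleavageRuleSet = TRYPSIN_MINIMAL
    guard_band: float = 0.005  # relative mass window for candidate pruning
    max_candidates: int = 25


@dataclass
class Candidate:
    """One scored digestion hypothesis."""

    state: DigestionState
    n_explained: int
    joint_consistent: bool
    mean_abs_ppm: float
    intact_matches: list
    reduced_matches: list

    @property
    def rank_key(self):
        # more masses explained > joint consistency > lower ppm > fewer cuts
        return (
            -self.n_explained,
            0 if self.joint_consistent else 1,
            self.mean_abs_ppm,
            self.state.n_cuts,
            self.state.terminal_variant,
            self.state.cut_positions,
        )


@dataclass
class RankedInference:
    candidates: list
    diagnostics: dict


def rank_candidates(candidates: list[Candidate]) -> list[Candidate]:
    return sorted(candidates, key=lambda c: c.rank_key)


def infer_digestion(
    intact_obs: NeutralMassSet,
    reduced_obs: NeutralMassSet,
    record: IsoformRecord,
    config: InferenceConfig | None = None,
) -> RankedInference:
    """Rank digestion states by joint intact + reduced mass coverage.

    For every terminal variant and every cleavage subset up to
    ``config.max_cuts``: the disulphide-linked species are assembled, their
    intact masses (with the hydroxylation sub-ladder) are matched against
    the non-reduced observations, the per-chain hydroxylation x alkylation
    ladders against the reduced/alkylated observations, and the candidate
    scored by the number of distinct experimental masses explained.
    """
    config = config or InferenceConfig()
    opts = config.mass_options
    if len(intact_obs) == 0 and len(reduced_obs) == 0:
        raise InputError("no experimental masses supplied")
    diagnostics = {
        "intact_masses": len(intact_obs),
        "reduced_masses": len(reduced_obs),
        "states_examined": 0,
        "states_pruned": 0,
        "warnings": [],
    }
    if len(reduced_obs) == 0:
        diagnostics["warnings"].append(
            "no reduced/alkylated masses: intact-only mode"
        )

    intact_vals = np.sort(intact_obs.values())
    reduced_vals = np.sort(reduced_obs.values())
    table = residue_masses(opts.mode)

    def tol_of(mass: float) -> float:
        if opts.mode == "monoisotopic":
            return config.tol_ppm * 1e-6 * mass
        return config.tol_da

    def near(sorted_vals, mass, rel) -> bool:
        if sorted_vals.size == 0:
            return False
        i = np.searchsorted(sorted_vals, mass)
        lo = sorted_vals[max(i - 1, 0)]
        hi = sorted_vals[min(i, sorted_vals.size - 1)]
        return min(abs(mass - lo), abs(mass - hi)) <= rel * mass

    candidates = []
    for vi, variant in enumerate(record.terminal_variants):
        rec = apply_terminal_variant(record, variant)
        sites = find_cleavage_sites(rec, config.ruleset)
        permitted = [s.position for s in sites]
        # prefix sums make fragment base masses O(1) inside the state loop
        prefix = np.zeros(len(rec.sequence) + 1)
        for k, aa in enumerate(rec.sequence):
            prefix[k + 1] = prefix[k] + table[aa]
        hyp = np.array(sorted(rec.hydroxyprolines), dtype=int)

        def frag_mass(frag) -> float:
            return float(prefix[frag.end] - prefix[frag.start - 1]) + opts.water

        def frag_hyp(frag) -> int:
            return int(
                np.count_nonzero((hyp >= frag.start) & (hyp <= frag.end))
            )

        states = enumerate_states(
            sites, config.max_cuts, isoform_id=rec.id, terminal_variant=vi
        )
        for state in states:
            diagnostics["states_examined"] += 1
            fragments = fragments_from_cuts(rec.sequence, state.cut_positions)
            species = assemble_species(fragments, rec.disulphides)

            sp_info = []
            any_near = False
            for sp in species:
                base = (
                    sum(frag_mass(c) for c in sp.chains)
                    + sp.n_disulphides * opts.disulphide_delta
                )
                n_hp = sum(frag_hyp(c) for c in sp.chains)
                sp_info.append((sp, base, n_hp))
                top = base + n_hp * opts.hydroxylation_delta
                if near(intact_vals, base, config.guard_band) or near(
                    intact_vals, top, config.guard_band
                ):
                    any_near = True
            for frag in fragments:
                base = frag_mass(frag)
                top = (
                    base
                    + frag_hyp(frag) * opts.hydroxylation_delta
                    + frag.n_cys * opts.alkylation_delta
                )
                if near(reduced_vals, base, config.guard_band) or near(
                    reduced_vals, top, config.guard_band
                ):
                    any_near = True
            if not any_near:
                diagnostics["states_pruned"] += 1
                continue

            theo_intact = []
            for sp, base, n_hp in sp_info:
                for k in range(n_hp + 1):
                    theo_intact.append(
                        (
                            sp.id,
                            base + k * opts.hydroxylation_delta,
                            ("intact", k),
                        )
                    )
            theo_reduced = []
            for frag in fragments:
                base = frag_mass(frag)
                fid = f"{frag.start}-{frag.end}"
                for j in range(frag_hyp(frag) + 1):
                    for k in range(frag.n_cys + 1):
                        theo_reduced.append(
                            (
                                fid,
                                base
                                + j * opts.hydroxylation_delta
                                + k * opts.alkylation_delta,
                                ("reduced", j, k),
                            )
                        )

            tol_ppm_eff = (
                config.tol_ppm
                if opts.mode == "monoisotopic"
                else config.tol_da / max(intact_vals.max(), 1.0) * 1e6
            )
            m_int = match_masses(intact_obs, theo_intact, tol_ppm_eff)
            m_red = match_masses(reduced_obs, theo_reduced, tol_ppm_eff)
            explained = {("i", round(m.experimental_mass, 6)) for m in m_int}
            explained |= {("r", round(m.experimental_mass, 6)) for m in m_red}
            if not explained:
                continue

            joint = _jointly_consistent(sp_info, m_int, m_red)
            all_ppm = [abs(m.ppm_error) for m in m_int + m_red]
            candidates.append(
                Candidate(
                    state=state,
                    n_explained=len(explained),
                    joint_consistent=joint,
                    mean_abs_ppm=float(np.mean(all_ppm)),
                    intact_matches=m_int,
                    reduced_matches=m_red,
                )
            )

    ranked = rank_candidates(candidates)[: config.max_candidates]
    if not ranked:
        diagnostics["warnings"].append(
            "no digestion state explained any experimental mass"
        )
    return RankedInference(candidates=ranked, diagnostics=diagnostics)


def _jointly_consistent(sp_info, intact_matches, reduced_matches) -> bool:
    """True when every matched intact species is reconstructed by matched
    reduced chains whose hydroxylation counts sum to the intact assignment."""
    if not intact_matches:
        return False
    red_by_chain = {}
    for m in reduced_matches:
        red_by_chain.setdefault(m.species_id, set()).add(m.assignment[1])
    by_id = {sp.id: sp for sp, _, _ in sp_info}
    for m in intact_matches:
        sp = by_id[m.species_id]
        k_hp = m.assignment[1]
        chain_hps = []
        for c in sp.chains:
            cid = f"{c.start}-{c.end}"
            if cid not in red_by_chain:
                break
            chain_hps.append(sorted(red_by_chain[cid]))
        else:
            if any(
                sum(combo) == k_hp
                for combo in itertools.product(*chain_hps)
            ):
                continue
        return False
    return True
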