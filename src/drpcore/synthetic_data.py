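"""Ground-truthed synthetic data emulating 2S-albumin digestion studies.

The generator produces everything the pipeline consumes, with the truth
recorded alongside: a conglutin-like isoform built on the conserved
eight-cysteine skeleton C-Xn-C-Xn-CC-Xn-C-X-CC-Xn-C with four valid
disulphide pairings; a planted partial-digestion state biased toward
flexible regions; positive-mode charge-state envelopes for the intact
species and the reduced/alkylated chain ladders, with Gaussian ppm mass
noise; and a smooth per-residue RMSF profile depressed near bonded
cysteines and helical core segments and elevated at the termini.

Truth derivation always runs through the production code paths
(:mod:`drpcore.digestion`, :mod:`drpcore.species_mass`), so the generator
cannot drift away from the pipeline it tests.  Noise injection is the only
generator-specific arithmetic.  A fixed seed yields a byte-identical file
set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .digestion import ChainFragment, DigestionState, fragment_state
from .errors import ConfigError
from .flexibility import (
    DEFAULT_RMSF_CUTOFF,
    FlexProfile,
    RESISTANT,
    SUSCEPTIBLE,
    SiteLabelSet,
)
from .ms_inference import PeakList
from .sequence_model import IsoformRecord, find_cleavage_sites, write_isoform
from .species_mass import (
    MONO,
    alkylation_ladder,
    assemble_species,
    species_intact_mass,
)

_SPACER_AA = "ADEFGHILMNQSTVWY"  # spacer alphabet before K/R/P enrichment


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the conglutin setting: a mature chain of ~140 residues
    with the 8-Cys skeleton and 4 disulphides, three hydroxyproline sites,
    one to three hydrolysed bonds, instrument-level 5 ppm mass noise, and
    the charge ranges seen for non-reduced (+8..+17) and reduced (+4..+12)
    species on a 300-3000 m/z scan.
    """

    seed: int = 0
    n_residues: int = 140
    n_disulphides: int = 4
    n_hydroxyprolines: int = 3
    planted_cuts: int = 2
    mass_noise_ppm: float = 5.0
    charge_range_intact: tuple = (8, 17)
    charge_range_reduced: tuple = (4, 12)
    label_flip_prob: float = 0.0
    profile_smoothness: float = 6.0
    scan_range: tuple = (300.0, 3000.0)


@dataclass
class SyntheticTruth:
    """Everything the generator knows about one dataset."""

    isoform: IsoformRecord
    true_state: DigestionState
    fragments: list
    true_species: list
    profile: FlexProfile
    true_labels: SiteLabelSet
    intact_masses: list = field(default_factory=list)  # (species_id, Da)
    reduced_masses: list = field(default_factory=list)  # (chain_id, n_alk, Da)
    config: SyntheticConfig = field(default_factory=SyntheticConfig)


def _rngs(config: SyntheticConfig, n: int = 5):
    children = np.random.SeedSequence(config.seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def gen_isoform(config: SyntheticConfig) -> IsoformRecord:
    """A 2S-albumin-like isoform with the conserved cysteine skeleton."""
    rng = _rngs(config)[0]
    # spacer slots around the skeleton: nt C s1 C loop CC s3 C x CC s4 ct
    min_len = {"nt": 5, "s1": 4, "loop": 12, "s3": 4, "s4": 4, "ct": 3}
    fixed = 8 + 1  # skeleton cysteines + the single X in CXCC
    spare = config.n_residues - fixed - sum(min_len.values())
    if spare < 0:
        raise ConfigError(
            f"n_residues={config.n_residues} too small for the 8-Cys "
            f"skeleton (needs >= {fixed + sum(min_len.values())})"
        )
    if not 0 <= config.n_disulphides <= 4:
        raise ConfigError("n_disulphides must be within 0..4")
    weights = np.array([2.0, 1.0, 3.0, 1.0, 1.0, 1.5])
    extra = rng.multinomial(spare, weights / weights.sum())
    lengths = {
        key: min_len[key] + int(e) for key, e in zip(min_len, extra)
    }

    aa = list(_SPACER_AA)
    probs = np.full(len(aa), (1.0 - 0.22) / len(aa))
    aa += ["K", "R", "P"]
    probs = np.concatenate([probs, [0.07, 0.07, 0.08]])

    def spacer(n, ensure_kr=False, min_pro=0):
        s = list(rng.choice(aa, size=n, p=probs))
        if ensure_kr and not set(s) & {"K", "R"}:
            s[int(rng.integers(n))] = str(rng.choice(["K", "R"]))
        while s.count("P") < min_pro:
            non_p = [k for k, c in enumerate(s) if c != "P"]
            s[int(rng.choice(non_p))] = "P"
        return "".join(s)

    x_res = str(rng.choice(list(_SPACER_AA)))
    parts = [
        spacer(lengths["nt"], ensure_kr=True),
        "C",
        spacer(lengths["s1"]),
        "C",
        spacer(lengths["loop"], ensure_kr=True,
               min_pro=config.n_hydroxyprolines),
        "CC",
        spacer(lengths["s3"]),
        "C",
        x_res,
        "CC",
        spacer(lengths["s4"]),
        "C",
        spacer(lengths["ct"], ensure_kr=True),
    ]
    sequence = "".join(parts)
    cys = [k + 1 for k, c in enumerate(sequence) if c == "C"]
    assert len(cys) == 8
    # nested 2S-albumin-style pairing keeps the core cross-linked
    pairing = [
        (cys[0], cys[5]),
        (cys[1], cys[4]),
        (cys[2], cys[6]),
        (cys[3], cys[7]),
    ][: config.n_disulphides]

    pro = [k + 1 for k, c in enumerate(sequence) if c == "P"]
    n_hyp = min(config.n_hydroxyprolines, len(pro))
    hyp = sorted(
        int(p) for p in rng.choice(pro, size=n_hyp, replace=False)
    )
    return IsoformRecord(
        id=f"syn2s-{config.seed}",
        sequence=sequence,
        disulphides=frozenset(pairing),
        hydroxyprolines=frozenset(hyp),
        terminal_variants=((0, 0),),
    )


def _helix_segments(record: IsoformRecord, max_gap: int = 14):
    """Short inter-cysteine spans of the bonded core, taken as helical."""
    bonded = sorted({p for pair in record.disulphides for p in pair})
    segments = []
    for a, b in zip(bonded, bonded[1:]):
        if 2 < b - a <= max_gap:
            segments.append((a + 1, b - 1))
    return segments


def gen_flex_profile(
    record: IsoformRecord, config: SyntheticConfig
) -> tuple[FlexProfile, SiteLabelSet]:
    """Smooth RMSF-like profile plus threshold-derived site labels.

    The profile is correlated noise around a mobile baseline, multiplied
    down near disulphide-bonded cysteines and helix segments and raised at
    the termini; labels apply the production cutoff rule and are then
    flipped with ``label_flip_prob``.
    """
    rngs = _rngs(config)
    rng_prof, rng_flip = rngs[1], rngs[4]
    n = len(record.sequence)
    idx = np.arange(1, n + 1)

    noise = rng_prof.standard_normal(n)
    smooth = gaussian_filter1d(noise, sigma=config.profile_smoothness,
                               mode="reflect")
    sd = smooth.std() or 1.0
    base = 0.80 + 0.15 * smooth / sd

    edge = np.minimum(idx - 1, n - idx)
    base = base + 0.35 * np.exp(-edge / 4.0)

    factor = np.ones(n)
    bonded = sorted({p for pair in record.disulphides for p in pair})
    for c in bonded:
        factor *= 1.0 - 0.60 * np.exp(-((idx - c) ** 2) / (2 * 2.5 ** 2))
    for a, b in _helix_segments(record):
        centre, width = (a + b) / 2.0, max((b - a) / 2.0, 1.0)
        factor *= 1.0 - 0.45 * np.exp(-((idx - centre) ** 2) / (2 * width ** 2))

    rmsf = np.clip(base * factor, 0.05, None)
    profile = FlexProfile(residues=idx, rmsf=rmsf, window_frames=None,
                          selection="backbone")

    labels = {}
    for site in find_cleavage_sites(record):
        sus = rmsf[site.position - 1] > DEFAULT_RMSF_CUTOFF
        if rng_flip.random() < config.label_flip_prob:
            sus = not sus
        labels[site.position] = SUSCEPTIBLE if sus else RESISTANT
    return profile, SiteLabelSet(labels)


def simulate_true_digestion(
    record: IsoformRecord, config: SyntheticConfig
) -> SyntheticTruth:
    """Plant a digestion state biased toward high-flexibility sites."""
    rng_cuts = _rngs(config)[2]
    profile, labels = gen_flex_profile(record, config)
    sites = find_cleavage_sites(record)
    if len(sites) < config.planted_cuts:
        raise ConfigError(
            f"only {len(sites)} cleavage sites available for "
            f"{config.planted_cuts} planted cuts"
        )
    positions = np.array([s.position for s in sites])
    weight = np.array([profile.rmsf[p - 1] for p in positions]) ** 6
    weight /= weight.sum()
    chosen = rng_cuts.choice(
        positions, size=config.planted_cuts, replace=False, p=weight
    )
    state = DigestionState(record.id, tuple(int(c) for c in sorted(chosen)))
    fragments = fragment_state(record, state,
                               permitted={s.position for s in sites})
    species = assemble_species(fragments, record.disulphides)

    truth = SyntheticTruth(
        isoform=record,
        true_state=state,
        fragments=fragments,
        true_species=species,
        profile=profile,
        true_labels=labels,
        config=config,
    )
    hyp = sorted(record.hydroxyprolines)

    def frag_hyp(frag: ChainFragment) -> int:
        return sum(1 for p in hyp if frag.start <= p <= frag.end)

    for sp in species:
        n_hp = sum(frag_hyp(c) for c in sp.chains)
        truth.intact_masses.append(
            (sp.id, species_intact_mass(sp, MONO, n_hydroxyprolines=n_hp))
        )
    for frag in fragments:
        ladder = alkylation_ladder(frag, MONO, n_hydroxyprolines=frag_hyp(frag))
        fid = f"{frag.start}-{frag.end}"
        for k, m in enumerate(ladder):
            truth.reduced_masses.append((fid, k, m))
    return truth


def _feasible_charges(mass, preferred, scan_range):
    """Charge states whose m/z falls inside the scan window.

    A species needs at least two consecutive observable charges to form an
    envelope; a mass with fewer is not observable in this window and gets
    an empty list (the emitter then skips it, as the instrument would).
    """
    lo, hi = scan_range
    feasible = [
        z for z in range(1, 31) if lo <= (mass + z * MONO.proton_mass) / z <= hi
    ]
    inside = [z for z in feasible if preferred[0] <= z <= preferred[1]]
    if len(inside) >= 2:
        return inside
    return feasible[:3] if len(feasible) >= 2 else []


def gen_peaklists(
    truth: SyntheticTruth, config: SyntheticConfig | None = None
) -> tuple[PeakList, PeakList, list]:
    """Charge-state envelopes for every true mass, with seeded ppm noise.

    Returns (intact peak list, reduced peak list, manifest); the manifest
    maps every emitted peak to its source neutral mass and charge.
    """
    config = config or truth.config
    rng = _rngs(config)[3]
    manifest = []

    def emit(entries, preferred, sample):
        mzs, intens = [], []
        for label, mass in entries:
            charges = _feasible_charges(mass, preferred, config.scan_range)
            if not charges:
                manifest.append(
                    {
                        "sample": sample,
                        "source": label,
                        "true_mass_da": mass,
                        "charge": None,
                        "mz": None,
                        "observable": False,
                    }
                )
                continue
            centre = (len(charges) - 1) / 2.0
            for z in charges:
                mz = (mass + z * MONO.proton_mass) / z
                mz *= 1.0 + rng.normal(0.0, config.mass_noise_ppm * 1e-6)
                shape = np.exp(-((charges.index(z) - centre) ** 2) / 4.0)
                inten = float(
                    shape * rng.lognormal(mean=10.0, sigma=0.25)
                )
                mzs.append(mz)
                intens.append(inten)
                manifest.append(
                    {
                        "sample": sample,
                        "source": label,
                        "true_mass_da": mass,
                        "charge": z,
                        "mz": mz,
                        "observable": True,
                    }
                )
        order = np.argsort(mzs)
        mzs = np.array(mzs)[order]
        intens = np.array(intens)[order]
        lo = min(config.scan_range[0], float(mzs.min()) - 1.0)
        hi = max(config.scan_range[1], float(mzs.max()) + 1.0)
        return PeakList(mz=mzs, intensity=intens, scan_range=(lo, hi))

    intact = emit(
        [(sid, m) for sid, m in truth.intact_masses],
        config.charge_range_intact,
        "intact",
    )
    reduced = emit(
        [(f"{cid}+{k}alk", m) for cid, k, m in truth.reduced_masses],
        config.charge_range_reduced,
        "reduced",
    )
    return intact, reduced, manifest


def generate_dataset(config: SyntheticConfig):
    """One-call generation: isoform -> truth -> peak lists."""
    record = gen_isoform(config)
    truth = simulate_true_digestion(record, config)
    intact, reduced, manifest = gen_peaklists(truth, config)
    return truth, intact, reduced, manifest


def write_dataset(config: SyntheticConfig, outdir) -> dict:
    """Generate and write the full file set; returns the manifest dict."""
    from . import io as _io  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, intact, reduced, peak_manifest = generate_dataset(config)
    rec = truth.isoform

    files = {
        "fasta": "isoform.fasta",
        "topology": "topology.json",
        "intact": "intact_peaks.tsv",
        "reduced": "reduced_peaks.tsv",
        "profile": "rmsf_profile.tsv",
        "labels": "site_labels.tsv",
        "truth": "truth.json",
    }
    write_isoform(rec, outdir / files["fasta"], outdir / files["topology"])
    _io.write_peaklist(intact, outdir / files["intact"])
    _io.write_peaklist(reduced, outdir / files["reduced"])
    _io.write_profile(truth.profile, outdir / files["profile"])
    _io.write_labels(truth.true_labels, outdir / files["labels"])

    manifest = {
        "config": asdict(config),
        "isoform_id": rec.id,
        "true_cut_positions": list(truth.true_state.cut_positions),
        "true_species": [
            {
                "id": sp.id,
                "chains": [[c.start, c.end] for c in sp.chains],
                "n_disulphides": sp.n_disulphides,
                "released": sp.released,
            }
            for sp in truth.true_species
        ],
        "intact_masses": [
            {"species": sid, "mass_da": m} for sid, m in truth.intact_masses
        ],
        "reduced_masses": [
            {"chain": cid, "n_alkylated": k, "mass_da": m}
            for cid, k, m in truth.reduced_masses
        ],
        "labels": {str(p): truth.true_labels[p]
                   for p in truth.true_labels.positions()},
        "files": files,
        "peaks": peak_manifest,
    }
    (outdir / files["truth"]).write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest
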