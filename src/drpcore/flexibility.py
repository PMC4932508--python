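"""Structural-fluctuation analysis and cleavage-susceptibility classification.

Trypsin attack on a folded 2S albumin is governed less by sequence
specificity than by local backbone mobility: cleavable bonds buried in the
disulphide-knotted helical core stay intact while bonds in vibrant termini
and loops are hydrolysed.  This module computes per-residue RMSF with a
sliding window over a coordinate trajectory, the usual compactness and
deviation measures (Rg, Kabsch-superposed RMSD), classifies cleavage sites
as susceptible when their RMSF exceeds a cutoff (default 0.65 A, strict
inequality), and evaluates predictions against observed digestion outcomes
with per-class positive predictive values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InputError

SUSCEPTIBLE = "susceptible"
RESISTANT = "resistant"
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})
DEFAULT_RMSF_CUTOFF = 0.65  # Angstrom
DEFAULT_WINDOW = 20  # frames


@dataclass
class Trajectory:
    """Multi-frame coordinates with per-atom residue/mass metadata.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; every frame
    shares the same atom order.
    """

    coords: np.ndarray
    residue_index: np.ndarray  # 1-based residue of each atom
    atom_names: tuple
    masses: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError("coords must have shape (frames, atoms, 3)")
        n_atoms = self.coords.shape[1]
        if (
            self.residue_index.size != n_atoms
            or len(self.atom_names) != n_atoms
            or self.masses.size != n_atoms
        ):
            raise InputError("atom metadata length mismatch")
        if self.coords.shape[0] < 1:
            raise InputError("trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def selection_mask(self, selection: str) -> np.ndarray:
        if selection == "all":
            return np.ones(len(self.atom_names), dtype=bool)
        if selection == "backbone":
            mask = np.array(
                [name in BACKBONE_ATOMS for name in self.atom_names]
            )
            # fall back to all atoms for coarse inputs without PDB naming
            return mask if mask.any() else np.ones_like(mask)
        raise InputError(f"unknown selection {selection!r}")


@dataclass
class FlexProfile:
    """Per-residue RMSF values (Angstrom)."""

    residues: np.ndarray  # 1-based residue indices, ascending
    rmsf: np.ndarray
    window_frames: int | None = None
    selection: str = "backbone"

    def __post_init__(self):
        self.residues = np.asarray(self.residues, dtype=int)
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if self.residues.size != self.rmsf.size:
            raise InputError("residue/rmsf length mismatch")
        if np.any(self.rmsf < 0):
            raise InputError("negative RMSF value")

    def value_at(self, position: int) -> float:
        hit = np.nonzero(self.residues == position)[0]
        if hit.size != 1:
            raise InputError(f"residue {position} not in profile")
        return float(self.rmsf[hit[0]])

    def __len__(self) -> int:
        return self.residues.size


def compute_rmsf(
    traj: Trajectory,
    window_frames: int = DEFAULT_WINDOW,
    selection: str = "backbone",
) -> FlexProfile:
    """Sliding-window per-residue RMSF, stride 1, window-mean reference.

    For each window the per-atom fluctuation is the RMS displacement from
    the window-mean position; per-residue values average the selected atoms
    and the profile averages all windows.  ``window_frames`` equal to the
    frame count degenerates to the whole-trajectory RMSF.
    """
    if window_frames < 2:
        raise InputError("window_frames must be >= 2")
    if traj.n_frames < window_frames:
        raise InputError(
            f"trajectory has {traj.n_frames} frames, fewer than the "
            f"window of {window_frames}"
        )
    mask = traj.selection_mask(selection)
    x = traj.coords[:, mask, :]  # (F, A, 3)
    win = sliding_window_view(x, window_frames, axis=0)  # (W, A, 3, w)
    mean = win.mean(axis=-1)
    var = (win ** 2).mean(axis=-1) - mean ** 2  # per coordinate
    fluct = np.sqrt(np.clip(var.sum(axis=2), 0.0, None))  # (W, A)

    res = traj.residue_index[mask]
    residues = np.unique(res)
    prof = np.empty(residues.size)
    per_atom = fluct.mean(axis=0)  # average over windows
    for k, r in enumerate(residues):
        prof[k] = per_atom[res == r].mean()
    return FlexProfile(
        residues=residues,
        rmsf=prof,
        window_frames=window_frames,
        selection=selection,
    )


def compute_rg(frame: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration of one frame (Angstrom)."""
    frame = np.asarray(frame, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 3 or frame.shape[0] < 1:
        raise InputError("frame must have shape (atoms, 3)")
    if np.any(masses <= 0) or masses.sum() <= 0:
        raise ValueError("masses must be positive")
    com = np.average(frame, axis=0, weights=masses)
    sq = ((frame - com) ** 2).sum(axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centred ``p`` onto centred ``q``."""
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    return vt.T @ flip @ u.T


def compute_rmsd(
    frame: np.ndarray, reference: np.ndarray, superpose: bool = True
) -> float:
    """RMSD between two conformations, optionally after Kabsch fit."""
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise InputError(
            f"atom-count mismatch {frame.shape} vs {reference.shape}"
        )
    if superpose:
        pc = frame - frame.mean(axis=0)
        qc = reference - reference.mean(axis=0)
        rot = kabsch_rotation(pc, qc)
        diff = (rot @ pc.T).T - qc
    else:
        diff = frame - reference
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))


# --------------------------------------------------------------------------
# susceptibility classification and evaluation
# --------------------------------------------------------------------------

@dataclass
class SiteLabelSet:
    """Per-cleavage-site outcome, 'susceptible' or 'resistant'."""

    labels: dict

    def __post_init__(self):
        bad = {
            v for v in self.labels.values() if v not in (SUSCEPTIBLE, RESISTANT)
        }
        if bad:
            raise InputError(f"unknown outcome labels {sorted(bad)}")

    def positions(self):
        return sorted(self.labels)

    def __getitem__(self, pos: int) -> str:
        return self.labels[pos]

    def __len__(self) -> int:
        return len(self.labels)


def classify_sites(
    profile: FlexProfile,
    sites,
    cutoff: float = DEFAULT_RMSF_CUTOFF,
) -> SiteLabelSet:
    """Predict susceptible where site RMSF is strictly above ``cutoff``.

    A site exactly at the cutoff is classified resistant.
    """
    labels = {}
    for site in sites:
        pos = getattr(site, "position", site)
        value = profile.value_at(pos)
        labels[pos] = SUSCEPTIBLE if value > cutoff else RESISTANT
    return SiteLabelSet(labels)


@dataclass
class ConfusionSummary:
    """Confusion counts with susceptibility as the positive class.

    ``ppv_resistant`` treats resistance as the positive class of the
    mirrored one-vs-rest evaluation, i.e. TN/(TN+FN).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float | None = None

    @property
    def ppv_susceptible(self) -> float | None:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    @property
    def ppv_resistant(self) -> float | None:
        denom = self.tn + self.fn
        return self.tn / denom if denom else None

    @staticmethod
    def _pct(value):
        return None if value is None else int(round(100 * value))

    @property
    def ppv_susceptible_pct(self):
        return self._pct(self.ppv_susceptible)

    @property
    def ppv_resistant_pct(self):
        return self._pct(self.ppv_resistant)


def evaluate_classifier(
    predicted: SiteLabelSet,
    observed: SiteLabelSet,
    cutoff: float | None = None,
) -> ConfusionSummary:
    """Confusion summary of predicted vs observed site outcomes."""
    if set(predicted.labels) != set(observed.labels):
        raise InputError("predicted and observed site sets differ")
    tp = fp = tn = fn = 0
    for pos, pred in predicted.labels.items():
        obs = observed[pos]
        if pred == SUSCEPTIBLE:
            if obs == SUSCEPTIBLE:
                tp += 1
            else:
                fp += 1
        else:
            if obs == RESISTANT:
                tn += 1
            else:
                fn += 1
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn, cutoff=cutoff)
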