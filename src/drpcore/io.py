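"""Plain-text readers and writers for the pipeline's tabular formats.

Peak lists and neutral-mass lists are TSV; flexibility profiles, site
labels and species tables are TSV; trajectories are multi-frame XYZ or a
long-form CSV.  Binary MD formats (DCD/XTC) and mzML are deliberately not
handled here — this module is the documented adapter seam for them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InputError
from .flexibility import FlexProfile, SiteLabelSet, Trajectory
from .ms_inference import NeutralMass, NeutralMassSet, PeakList

# single-letter element masses for bare XYZ input (Da)
_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "CA": 40.078, "FE": 55.845,
}


# -- peak lists -------------------------------------------------------------

def read_peaklist(path) -> PeakList:
    """TSV with columns ``mz`` and ``intensity``."""
    df = _read_tsv(path, {"mz", "intensity"})
    mz = df["mz"].to_numpy(dtype=float)
    lo = min(300.0, float(mz.min()) - 1.0) if mz.size else 300.0
    hi = max(3000.0, float(mz.max()) + 1.0) if mz.size else 3000.0
    return PeakList(
        mz=mz,
        intensity=df["intensity"].to_numpy(dtype=float),
        scan_range=(lo, hi),
    )


def write_peaklist(peaklist: PeakList, path) -> None:
    pd.DataFrame(
        {"mz": peaklist.mz, "intensity": peaklist.intensity}
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_neutral_masses(path) -> NeutralMassSet:
    """TSV with a ``mass_da`` column; bypasses deconvolution."""
    df = _read_tsv(path, {"mass_da"})
    return NeutralMassSet(
        [
            NeutralMass(mass=float(m), support=1, charges=(), flagged=True)
            for m in df["mass_da"]
        ]
    )


def write_neutral_masses(masses: NeutralMassSet, path) -> None:
    pd.DataFrame(
        {
            "mass_da": [m.mass for m in masses],
            "support": [m.support for m in masses],
            "charges": [",".join(map(str, m.charges)) for m in masses],
            "flagged": [m.flagged for m in masses],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


# -- flexibility ------------------------------------------------------------

def read_profile(path) -> FlexProfile:
    df = _read_tsv(path, {"residue_index", "rmsf_A"})
    return FlexProfile(
        residues=df["residue_index"].to_numpy(dtype=int),
        rmsf=df["rmsf_A"].to_numpy(dtype=float),
    )


def write_profile(profile: FlexProfile, path) -> None:
    pd.DataFrame(
        {"residue_index": profile.residues, "rmsf_A": profile.rmsf}
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_labels(path) -> SiteLabelSet:
    df = _read_tsv(path, {"position", "outcome"})
    return SiteLabelSet(
        {int(p): str(o) for p, o in zip(df["position"], df["outcome"])}
    )


def write_labels(labels: SiteLabelSet, path) -> None:
    pos = labels.positions()
    pd.DataFrame(
        {"position": pos, "outcome": [labels[p] for p in pos]}
    ).to_csv(path, sep="\t", index=False)


def read_sites(path) -> list[int]:
    df = _read_tsv(path, {"position"})
    return [int(p) for p in df["position"]]


# -- trajectories -----------------------------------------------------------

def read_trajectory(path) -> Trajectory:
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        return read_xyz(path)
    if path.suffix.lower() == ".csv":
        return read_trajectory_csv(path)
    raise InputError(f"{path}: unsupported trajectory format (.xyz or .csv)")


def read_xyz(path) -> Trajectory:
    """Multi-frame XYZ.  Each atom is treated as its own residue and the
    element symbol sets the mass; use the CSV form for residue grouping."""
    lines = Path(path).read_text().splitlines()
    frames, names = [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(f"{path}: bad XYZ atom count line {i+1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError(f"{path}: truncated XYZ frame at line {i+1}")
        frame_names, coords = [], []
        for row in block:
            parts = row.split()
            frame_names.append(parts[0].upper())
            coords.append([float(v) for v in parts[1:4]])
        if names is None:
            names = frame_names
        elif names != frame_names:
            raise FormatError(f"{path}: inconsistent atom order across frames")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: no frames found")
    masses = np.array([_ELEMENT_MASS.get(nm, 12.011) for nm in names])
    return Trajectory(
        coords=np.array(frames),
        residue_index=np.arange(1, len(names) + 1),
        atom_names=tuple(names),
        masses=masses,
    )


def read_trajectory_csv(path) -> Trajectory:
    """Long-form CSV: frame, atom, residue, x, y, z, mass."""
    df = pd.read_csv(path)
    required = {"frame", "atom", "residue", "x", "y", "z", "mass"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: trajectory CSV needs columns {sorted(required)}"
        )
    df = df.sort_values(["frame", "residue", "atom"], kind="stable")
    frames = sorted(df["frame"].unique())
    first = df[df["frame"] == frames[0]]
    key = list(zip(first["residue"], first["atom"]))
    coords = []
    for f in frames:
        sub = df[df["frame"] == f]
        if list(zip(sub["residue"], sub["atom"])) != key:
            raise FormatError(f"{path}: frame {f} has a different atom set")
        coords.append(sub[["x", "y", "z"]].to_numpy(dtype=float))
    return Trajectory(
        coords=np.array(coords),
        residue_index=first["residue"].to_numpy(dtype=int),
        atom_names=tuple(str(a).upper() for a in first["atom"]),
        masses=first["mass"].to_numpy(dtype=float),
    )


def write_trajectory_csv(traj: Trajectory, path) -> None:
    rows = []
    for f in range(traj.n_frames):
        for a in range(traj.coords.shape[1]):
            rows.append(
                {
                    "frame": f,
                    "atom": traj.atom_names[a],
                    "residue": int(traj.residue_index[a]),
                    "x": traj.coords[f, a, 0],
                    "y": traj.coords[f, a, 1],
                    "z": traj.coords[f, a, 2],
                    "mass": traj.masses[a],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# -- helpers ----------------------------------------------------------------

def _read_tsv(path, required: set) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else None
    try:
        df = pd.read_csv(path, sep=sep, engine="python")
    except Exception as exc:  # pandas raises many parse error types
        raise FormatError(f"{path}: unreadable table ({exc})") from exc
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    return df
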