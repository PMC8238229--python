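"""Backbone parsing, pseudo-rotamer candidate clouds and B-factor widths.

A pseudo-rotamer is a single centroid pseudo-atom standing in for the
nitroxide ring of an MTSSL spin label. Candidate positions for a labeled
residue are laid out deterministically in a 4-9 A shell around CB on the
hemisphere pointing away from CA (typical nitroxide-midpoint offsets),
then clash-filtered against the protein backbone. Crystallographic
B-factors of the CA atoms provide per-residue RMSF values used later to
broaden simulated distance distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .trace_io import ResidueId, format_residue_id, parse_residue_id

__all__ = [
    "BackboneResidue",
    "PseudoRotamerCloud",
    "parse_backbone",
    "generate_cloud",
    "clash_filter",
    "rmsf_from_bfactor",
    "pair_rmsf",
    "reconstruct_cb",
    "read_rotamer_library",
    "write_ensemble",
]

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0
_SHELL_MIN, _SHELL_MAX = 4.0, 9.0


@dataclass
class BackboneResidue:
    """Backbone heavy atoms and CA B-factor of one residue."""

    chain: str
    seqnum: int
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray | None = None
    cb: np.ndarray | None = None
    b_ca: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n", "ca", "c", "o", "cb"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (3,) or not np.all(np.isfinite(v)):
                    raise ValueError(f"{self.rid_str}: bad {name.upper()} coordinates")
                setattr(self, name, v)
        if self.b_ca < 0:
            raise ValueError(f"{self.rid_str}: negative B-factor")

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain, self.seqnum)

    @property
    def rid_str(self) -> str:
        return format_residue_id((self.chain, self.seqnum))

    def cb_or_ideal(self) -> np.ndarray:
        """CB coordinates, reconstructed from N/CA/C for glycine."""
        if self.cb is not None:
            return self.cb
        return reconstruct_cb(self.n, self.ca, self.c)

    def heavy_atoms(self) -> np.ndarray:
        atoms = [self.n, self.ca, self.c]
        if self.o is not None:
            atoms.append(self.o)
        if self.cb is not None:
            atoms.append(self.cb)
        return np.asarray(atoms)


@dataclass
class PseudoRotamerCloud:
    """Fixed candidate positions with mutable non-negative weights.

    Weights may be all zero before optimization; ``probabilities`` is
    only defined once at least one weight is positive.
    """

    residue: BackboneResidue
    positions: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 3 or self.positions.shape[0] < 1:
            raise ValueError(f"{self.residue.rid_str}: positions must be N x 3, N >= 1")
        if self.weights is None:
            self.weights = np.zeros(self.positions.shape[0])
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.positions.shape[0],):
            raise ValueError(f"{self.residue.rid_str}: weights/positions length mismatch")
        if np.any(self.weights < 0):
            raise ValueError(f"{self.residue.rid_str}: negative rotamer weight")

    @property
    def n_positions(self) -> int:
        return int(self.positions.shape[0])

    @property
    def probabilities(self) -> np.ndarray:
        total = float(self.weights.sum())
        if total <= 0:
            raise ValueError(f"{self.residue.rid_str}: all rotamer weights are zero")
        return self.weights / total

    def centroid(self) -> np.ndarray:
        """Weight-averaged position of the active rotamers."""
        return self.probabilities @ self.positions

    def with_weights(self, weights: np.ndarray) -> "PseudoRotamerCloud":
        return replace(self, weights=np.asarray(weights, dtype=float).copy())


def reconstruct_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal CB placement: 1.53 A bond, tetrahedral angles, L-configuration."""
    n, ca, c = (np.asarray(x, dtype=float) for x in (n, ca, c))
    e1 = n - ca
    e1 /= np.linalg.norm(e1)
    vc = c - ca
    vc = vc / np.linalg.norm(vc)
    cos_tau = float(np.dot(e1, vc))
    e2 = vc - cos_tau * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    cos_t = -1.0 / 3.0  # tetrahedral 109.47 deg to both N and C
    sin_tau = math.sqrt(max(1.0 - cos_tau * cos_tau, 1e-12))
    a = cos_t
    b = (cos_t - a * cos_tau) / sin_tau
    csq = 1.0 - a * a - b * b
    if csq <= 0:
        raise ValueError("degenerate backbone geometry for CB reconstruction")
    direction = a * e1 + b * e2 + math.sqrt(csq) * e3
    return ca + 1.53 * direction


def parse_backbone(path: str | Path) -> list[BackboneResidue]:
    """Read backbone atoms and CA B-factors from a PDB file (first model)."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models/ATOM records")
    model = st[0]
    out: list[BackboneResidue] = []
    for chain in model:
        for res in chain:
            if res.het_flag == "H" and res.name == "HOH":
                continue
            atoms: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                if atom.name in ("N", "CA", "C", "O", "CB") and atom.name not in atoms:
                    atoms[atom.name] = atom
            if not atoms:
                continue
            if "CA" not in atoms:
                raise ValueError(f"{chain.name}:{res.seqid.num} ({res.name}): missing CA")
            if "N" not in atoms or "C" not in atoms:
                raise ValueError(f"{chain.name}:{res.seqid.num} ({res.name}): incomplete backbone")

            def pos(name: str) -> np.ndarray | None:
                if name not in atoms:
                    return None
                p = atoms[name].pos
                return np.array([p.x, p.y, p.z])

            out.append(
                BackboneResidue(
                    chain=chain.name,
                    seqnum=res.seqid.num,
                    n=pos("N"),
                    ca=pos("CA"),
                    c=pos("C"),
                    o=pos("O"),
                    cb=pos("CB"),
                    b_ca=float(atoms["CA"].b_iso),
                )
            )
    if not out:
        raise ValueError(f"{path}: no usable ATOM records")
    return out


def generate_cloud(
    residue: BackboneResidue,
    n_candidates: int = 50,
    library: str | Path | None = None,
) -> PseudoRotamerCloud:
    """Candidate nitroxide-midpoint positions for one labeled residue.

    Without a library file, exactly ``n_candidates`` positions are placed
    deterministically (low-discrepancy spiral) in the 4-9 A shell around
    CB, on the hemisphere pointing away from CA; candidate 0 sits on the
    CA->CB axis at the shell midpoint. All weights start at zero. With a
    library file, positions and weights for this residue are read
    verbatim.
    """
    if library is not None:
        lib = read_rotamer_library(library)
        rid = residue.residue_id
        if rid not in lib:
            raise ValueError(f"library {library}: no entries for residue {residue.rid_str}")
        positions, weights = lib[rid]
        return PseudoRotamerCloud(residue=residue, positions=positions, weights=weights)
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    cb = residue.cb_or_ideal()
    axis = cb - residue.ca
    nrm = np.linalg.norm(axis)
    if nrm < 1e-9:
        raise ValueError(f"{residue.rid_str}: CA and CB coincide")
    axis /= nrm
    # deterministic orthonormal frame around the CA->CB axis
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(axis)))] = 1.0
    e2 = np.cross(axis, ref)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(axis, e2)
    idx = np.arange(n_candidates, dtype=float)
    z = 1.0 - idx / n_candidates            # cos(polar angle) in (0, 1]
    rho = np.sqrt(1.0 - z * z)
    phi = 2.0 * math.pi * _GOLDEN * idx     # golden-angle azimuth
    radius = _SHELL_MIN + (_SHELL_MAX - _SHELL_MIN) * np.mod(0.5 + _GOLDEN * idx, 1.0)
    dirs = (
        z[:, None] * axis[None, :]
        + (rho * np.cos(phi))[:, None] * e2[None, :]
        + (rho * np.sin(phi))[:, None] * e3[None, :]
    )
    positions = cb[None, :] + radius[:, None] * dirs
    return PseudoRotamerCloud(residue=residue, positions=positions)


def clash_filter(
    cloud: PseudoRotamerCloud,
    backbone: list[BackboneResidue],
    cutoff: float = 2.5,
) -> PseudoRotamerCloud:
    """Remove candidates within ``cutoff`` of any other residue's backbone.

    Heavy backbone atoms (N, CA, C, O, CB) of every residue except the
    labeled one participate; survivor order is preserved.
    """
    rid = cloud.residue.residue_id
    others = [r.heavy_atoms() for r in backbone if r.residue_id != rid]
    if not others:
        return replace(cloud)
    atoms = np.vstack(others)
    tree = cKDTree(atoms)
    dmin, _ = tree.query(cloud.positions, k=1)
    keep = dmin >= cutoff
    if not np.any(keep):
        raise ValueError(f"{cloud.residue.rid_str}: all pseudo-rotamers clash (site unlabelable)")
    return PseudoRotamerCloud(
        residue=cloud.residue,
        positions=cloud.positions[keep],
        weights=cloud.weights[keep],
    )


def rmsf_from_bfactor(b_ca: float) -> float:
    """Isotropic B-factor (A^2) -> RMSF (A): sqrt(3 B / (8 pi^2))."""
    if b_ca < 0:
        raise ValueError("B-factor must be >= 0")
    return math.sqrt(3.0 * b_ca / (8.0 * math.pi**2))


def pair_rmsf(rmsf_u: float, rmsf_v: float) -> float:
    """Quadrature combination of two per-residue RMSF values."""
    if rmsf_u < 0 or rmsf_v < 0:
        raise ValueError("RMSF values must be >= 0")
    return math.hypot(rmsf_u, rmsf_v)


def read_rotamer_library(path: str | Path) -> dict[ResidueId, tuple[np.ndarray, np.ndarray]]:
    """Read ensemble coordinate text records: ``residue_id x y z weight``."""
    groups: dict[ResidueId, list[list[float]]] = {}
    order: dict[ResidueId, None] = {}
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s[0] in "#%":
            continue
        fields = s.split()
        if len(fields) < 5:
            raise ValueError(f"{path}: bad record {s!r} (need residue_id x y z weight)")
        rid = parse_residue_id(fields[0])
        groups.setdefault(rid, []).append([float(x) for x in fields[1:5]])
        order.setdefault(rid)
    out = {}
    for rid in order:
        arr = np.asarray(groups[rid])
        out[rid] = (arr[:, :3].copy(), arr[:, 3].copy())
    return out


def write_ensemble(clouds: dict[ResidueId, PseudoRotamerCloud], path: str | Path) -> None:
    """Write clouds in the ensemble coordinate text format (library dialect)."""
    lines = ["# residue_id x y z weight"]
    for rid, cloud in clouds.items():
        for pos, w in zip(cloud.positions, cloud.weights):
            lines.append(
                f"{format_residue_id(rid)} {pos[0]:.4f} {pos[1]:.4f} {pos[2]:.4f} {w:.8g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
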