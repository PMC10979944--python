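"""Geometry on protein coordinate files.

Covers the structural-context half of the screen: rigid superposition
(Kabsch), ligand-contact listing (e.g. His NE2 atoms coordinating a heme
iron), an implicit-membrane slab, transmembrane-segment detection, bis-His
heme-site detection, and the distance from a flavinylation-motif Ser/Thr to
a flavin-binding pocket.

A membrane is modeled as a slab: a center point, a unit normal, and a
half-thickness (default 15 Angstrom, a typical hydrophobic half-width).
"Centrally located" histidines — the bis-His signature of transmembrane
b-type cytochromes — are pairs whose NE2 midpoint lies within a central
fraction of the slab.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "Structure",
    "MembraneSlab",
    "TMSegment",
    "HemeSiteCandidate",
    "Contact",
    "read_structure",
    "write_structure",
    "kabsch_superpose",
    "ligand_contacts",
    "estimate_slab",
    "find_tm_segments",
    "detect_bishis_sites",
    "motif_pocket_distance",
]


@dataclass(frozen=True)
class Atom:
    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    x: float
    y: float
    z: float

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.atom_name)


@dataclass(frozen=True)
class Structure:
    """A flat atom list with alt-locations already resolved."""

    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinate for atom {a.key}")
            if a.key in seen:
                raise ValueError(f"duplicate atom {a.key} after alt-location filtering")
            seen.add(a.key)

    @property
    def chains(self) -> tuple[str, ...]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return tuple(out)

    def coords(self, atoms: Iterable[Atom] | None = None) -> np.ndarray:
        sel = self.atoms if atoms is None else tuple(atoms)
        return np.array([[a.x, a.y, a.z] for a in sel]).reshape(-1, 3)

    def select(
        self,
        chain_id: str | None = None,
        residue_name: str | None = None,
        atom_name: str | None = None,
    ) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if (chain_id is None or a.chain_id == chain_id)
            and (residue_name is None or a.residue_name == residue_name)
            and (atom_name is None or a.atom_name == atom_name)
        ]

    def get_atom(self, chain_id: str, residue_seq: int, atom_name: str) -> Atom:
        for a in self.atoms:
            if a.key == (chain_id, residue_seq, atom_name):
                return a
        raise KeyError(f"no atom {(chain_id, residue_seq, atom_name)}")

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int, str]]:
        """Ordered (chain, residue_seq, residue_name) triples."""
        out: list[tuple[str, int, str]] = []
        seen = set()
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            key = (a.chain_id, a.residue_seq)
            if key not in seen:
                seen.add(key)
                out.append((a.chain_id, a.residue_seq, a.residue_name))
        return out

    def ca_atoms(self, chain_id: str | None = None) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.atom_name == "CA"
            and a.element != "CA"  # exclude calcium ions
            and (chain_id is None or a.chain_id == chain_id)
        ]


@dataclass(frozen=True)
class MembraneSlab:
    normal: tuple[float, float, float]
    center: tuple[float, float, float]
    half_thickness: float = 15.0

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-6:
            raise ValueError("slab normal must be a unit vector")
        if self.half_thickness <= 0:
            raise ValueError("half_thickness must be > 0")

    def depth(self, point: np.ndarray) -> float:
        """Signed distance from the slab center plane along the normal."""
        return float(np.dot(np.asarray(point) - np.asarray(self.center), self.normal))


@dataclass(frozen=True)
class TMSegment:
    chain_id: str
    start_res: int
    end_res: int

    def __contains__(self, item: tuple[str, int]) -> bool:
        chain, res = item
        return chain == self.chain_id and self.start_res <= res <= self.end_res


@dataclass(frozen=True)
class HemeSiteCandidate:
    """A pair of His residues whose NE2 atoms face each other across a
    putative heme-iron position (axial bis-His coordination geometry)."""

    his_a: tuple[str, int]
    his_b: tuple[str, int]
    ne2_distance: float
    midpoint_depth: float
    cross_segment: bool


@dataclass(frozen=True)
class Contact:
    ligand_atom: tuple[str, int, str]
    protein_atom: tuple[str, int, str]
    protein_residue_name: str
    distance: float


def read_structure(path: str | Path) -> Structure:
    """Read a PDB file (first model), resolving alternate locations.

    For each (chain, residue, atom name) the conformer with the highest
    occupancy is kept; ties prefer altloc 'A'/blank.  HETATM records
    (hemes, flavins, ions) are retained.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: cannot parse PDB file: {exc}") from None
    if not st:
        raise ValueError(f"{path}: no models found")
    model = st[0]
    best: dict[tuple[str, int, str], tuple[float, str, Atom]] = {}
    order: list[tuple[str, int, str]] = []
    for chain in model:
        for res in chain:
            for at in res:
                key = (chain.name, res.seqid.num, at.name)
                altloc = at.altloc or ""
                occ = at.occ if at.occ > 0 else 1.0
                atom = Atom(
                    atom_name=at.name,
                    element=at.element.name.upper(),
                    residue_name=res.name,
                    residue_seq=res.seqid.num,
                    chain_id=chain.name,
                    x=at.pos.x,
                    y=at.pos.y,
                    z=at.pos.z,
                )
                prev = best.get(key)
                if prev is None:
                    best[key] = (occ, altloc, atom)
                    order.append(key)
                elif altloc == "" and prev[1] == "":
                    # true duplicate, not an alt-location pair: surface it
                    raise ValueError(f"{path}: duplicate atom {key}")
                elif (occ, _altloc_rank(altloc)) > (prev[0], _altloc_rank(prev[1])):
                    best[key] = (occ, altloc, atom)
    return Structure(tuple(best[k][2] for k in order))


def _altloc_rank(altloc: str) -> int:
    if altloc == "":
        return 2
    return 1 if altloc == "A" else 0


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = "flavscreen"
    model = gemmi.Model("1")
    # group atoms by chain and residue, preserving order (gemmi's add_*
    # methods copy their argument, so build bottom-up)
    by_chain: dict[str, dict[tuple[int, str], list[Atom]]] = {}
    for a in structure.atoms:
        by_chain.setdefault(a.chain_id, {}).setdefault((a.residue_seq, a.residue_name), []).append(a)
    for chain_id, residues in by_chain.items():
        chain = gemmi.Chain(chain_id)
        for (resseq, resname), res_atoms in residues.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resseq, " ")
            for a in res_atoms:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(a.x, a.y, a.z)
                at.occ = 1.0
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps mobile points onto the reference
    frame with minimal RMSD over all proper rigid motions.  The rotation is
    reflection-corrected (determinant +1).  Correspondence is positional
    and supplied by the caller; both arrays must be N x 3 with N >= 3.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be N x 3")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / P.shape[0]))
    return R, t, rmsd


def ligand_contacts(
    structure: Structure,
    ligand_selector: str,
    contact_atoms: Iterable[str],
    cutoff: float,
) -> list[Contact]:
    """List protein atoms of given names within ``cutoff`` of a ligand.

    ``ligand_selector`` is a residue name (e.g. ``HEM``); each contact
    carries the ligand atom achieving the minimal distance.  Sorted by
    distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    names = set(contact_atoms)
    lig = [a for a in structure.atoms if a.residue_name == ligand_selector]
    prot = [
        a
        for a in structure.atoms
        if a.residue_name != ligand_selector and a.atom_name in names
    ]
    if not lig or not prot:
        return []
    dmat = cdist(structure.coords(prot), structure.coords(lig))
    out: list[Contact] = []
    for i, a in enumerate(prot):
        j = int(np.argmin(dmat[i]))
        if dmat[i, j] <= cutoff:
            out.append(
                Contact(lig[j].key, a.key, a.residue_name, float(dmat[i, j]))
            )
    out.sort(key=lambda c: (c.distance, c.protein_atom))
    return out


def estimate_slab(
    structure: Structure,
    segments: Sequence[TMSegment] | None = None,
    half_thickness: float = 15.0,
    normal: Sequence[float] | None = None,
) -> MembraneSlab:
    """Estimate the membrane slab of a transmembrane protein.

    With ``segments`` supplied, the normal is the sign-aligned average of
    per-segment Calpha displacement vectors (end minus start) and the center
    is the mean Calpha of segment residues.  Without segments, the normal is
    the dominant principal axis of the Calpha cloud — adequate for helix
    bundles whose long axis crosses the membrane — and the center is the
    Calpha centroid.  An explicit ``normal`` overrides both estimates.
    """
    cas = structure.ca_atoms()
    if not cas:
        raise ValueError("structure has no Calpha atoms")
    if segments:
        seg_cas = [
            [a for a in structure.ca_atoms(s.chain_id) if s.start_res <= a.residue_seq <= s.end_res]
            for s in segments
        ]
        seg_cas = [s for s in seg_cas if len(s) >= 2]
        if not seg_cas:
            raise ValueError("supplied segments contain no Calpha atoms")
        disp = np.array([s[-1].pos - s[0].pos for s in seg_cas])
        ref = disp[0] / np.linalg.norm(disp[0])
        signs = np.where(disp @ ref < 0, -1.0, 1.0)
        n = (disp * signs[:, None]).mean(axis=0)
        center = np.concatenate([structure.coords(s) for s in seg_cas]).mean(axis=0)
    else:
        X = structure.coords(cas)
        center = X.mean(axis=0)
        # principal axis of the Calpha trace, after smoothing each chain
        # with an 18-residue moving average: 18 residues x 100 deg/residue
        # is exactly five helical turns, so the off-axis circular component
        # of an ideal helix cancels and the axis direction is exact
        smoothed = []
        for chain in structure.chains:
            C = structure.coords(structure.ca_atoms(chain))
            if len(C) >= 18:
                kernel = np.ones(18) / 18.0
                C = np.column_stack(
                    [np.convolve(C[:, i], kernel, mode="valid") for i in range(3)]
                )
            smoothed.append(C)
        S = np.concatenate(smoothed)
        _, _, Vt = np.linalg.svd(S - S.mean(axis=0))
        n = Vt[0]
    if normal is not None:
        n = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise ValueError("degenerate membrane normal")
    n = n / nn
    # deterministic sign: make the largest-magnitude component positive
    imax = int(np.argmax(np.abs(n)))
    if n[imax] < 0:
        n = -n
    return MembraneSlab(tuple(n), tuple(float(v) for v in center), half_thickness)


def find_tm_segments(
    structure: Structure,
    slab: MembraneSlab,
    min_length: int = 15,
    max_length: int = 45,
    margin: float = 5.0,
) -> list[TMSegment]:
    """Detect membrane-spanning segments from Calpha depths.

    A segment is a run of consecutive residues whose Calpha depth traverses
    from <= -(half_thickness - margin) to >= +(half_thickness - margin) (or
    the reverse).  The traversing core is extended on both sides over
    contiguous residues still inside the slab (|depth| <= half_thickness),
    then length-filtered to [min_length, max_length] (longer runs are
    trimmed symmetrically).  Reported in residue order per chain.
    """
    t = slab.half_thickness - margin
    if t <= 0:
        raise ValueError("margin leaves no traversal band")
    segments: list[TMSegment] = []
    for chain in structure.chains:
        cas = structure.ca_atoms(chain)
        if not cas:
            continue
        depths = [slab.depth(a.pos) for a in cas]
        i_side = None  # (index, side) of latest extreme-band residue
        for i, d in enumerate(depths):
            side = -1 if d <= -t else (1 if d >= t else 0)
            if side == 0:
                continue
            if i_side is None or i_side[1] == side:
                i_side = (i, side)
                continue
            # completed traversal from i_side[0] to i
            lo, hi = i_side[0], i
            while lo > 0 and abs(depths[lo - 1]) <= slab.half_thickness:
                lo -= 1
            while hi < len(depths) - 1 and abs(depths[hi + 1]) <= slab.half_thickness:
                hi += 1
            length = hi - lo + 1
            if length >= min_length:
                while length > max_length:
                    if length % 2:
                        lo += 1
                    else:
                        hi -= 1
                    length -= 1
                segments.append(TMSegment(chain, cas[lo].residue_seq, cas[hi].residue_seq))
            i_side = (i, side)
    return segments


def detect_bishis_sites(
    structure: Structure,
    slab: MembraneSlab,
    segments: Sequence[TMSegment] | None = None,
    max_ne2_distance: float = 8.0,
    central_fraction: float = 0.5,
    accept_nd1: bool = False,
) -> list[HemeSiteCandidate]:
    """Find candidate bis-His heme sites: close, membrane-central His pairs.

    All His pairs whose NE2-NE2 distance is at most ``max_ne2_distance``
    (default 8 A: twice the ~4.4 A holo Fe-bis-His NE2 spacing, allowing
    for relaxed apo/predicted models) and whose NE2 midpoint lies within
    +/-(central_fraction * half_thickness) of the slab center are reported,
    sorted by distance.  A His may appear in several pairs.  With
    ``accept_nd1`` the closer of NE2/ND1 per residue is used, since
    tautomer placement in predicted models is unreliable.
    """
    if max_ne2_distance <= 0:
        raise ValueError("max_ne2_distance must be > 0")
    if not (0 < central_fraction <= 1):
        raise ValueError("central_fraction must be in (0, 1]")
    atom_names = ("NE2", "ND1") if accept_nd1 else ("NE2",)
    his_atoms: dict[tuple[str, int], list[Atom]] = {}
    for a in structure.atoms:
        if a.residue_name == "HIS" and a.atom_name in atom_names:
            his_atoms.setdefault((a.chain_id, a.residue_seq), []).append(a)
    keys = sorted(his_atoms)
    window = central_fraction * slab.half_thickness

    def segment_of(key: tuple[str, int]) -> int | None:
        if not segments:
            return None
        for i, s in enumerate(segments):
            if key in s:
                return i
        return None

    sites: list[HemeSiteCandidate] = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            pairs = [
                (a, b, float(np.linalg.norm(a.pos - b.pos)))
                for a in his_atoms[keys[i]]
                for b in his_atoms[keys[j]]
            ]
            a, b, dist = min(pairs, key=lambda p: p[2])
            if dist > max_ne2_distance:
                continue
            depth = slab.depth((a.pos + b.pos) / 2.0)
            if abs(depth) > window:
                continue
            sa, sb = segment_of(keys[i]), segment_of(keys[j])
            cross = sa is not None and sb is not None and sa != sb
            sites.append(HemeSiteCandidate(keys[i], keys[j], dist, depth, cross))
    sites.sort(key=lambda s: (s.ne2_distance, s.his_a, s.his_b))
    return sites


def motif_pocket_distance(
    structure: Structure,
    motif_residue: tuple[str, int],
    pocket_atoms: Sequence[tuple[str, int, str]] | np.ndarray,
) -> float:
    """Distance from a motif Ser/Thr side-chain oxygen to a pocket centroid.

    Measures whether a flavinylated residue is positioned to engage a
    flavin-binding site.  ``pocket_atoms`` is either a list of
    (chain, residue_seq, atom_name) selectors or an M x 3 coordinate array.
    """
    chain, resseq = motif_residue
    res_atoms = [
        a for a in structure.atoms if a.chain_id == chain and a.residue_seq == resseq
    ]
    if not res_atoms:
        raise KeyError(f"no residue {motif_residue}")
    resname = res_atoms[0].residue_name
    if resname not in {"SER", "THR"}:
        raise ValueError(f"motif residue {motif_residue} is {resname}, not SER/THR")
    og = [a for a in res_atoms if a.atom_name in {"OG", "OG1"}]
    if not og:
        raise ValueError(f"motif residue {motif_residue} lacks a side-chain oxygen")
    if isinstance(pocket_atoms, np.ndarray):
        pocket = np.asarray(pocket_atoms, dtype=float).reshape(-1, 3)
    else:
        pocket = np.array([structure.get_atom(*sel).pos for sel in pocket_atoms])
    if pocket.size == 0:
        raise ValueError("empty pocket selection")
    centroid = pocket.mean(axis=0)
    return float(np.linalg.norm(og[0].pos - centroid))
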