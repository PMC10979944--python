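"""Seeded synthetic-data generators with planted ground truth.

These stand in for database-scale inputs: thousands of small genomes with
planted apbE/substrate/decoy neighborhoods, proteins with controlled
flavinylation-motif placement, idealized transmembrane helix bundles with
planted bis-His pairs, and alignments with controlled column conservation.
Every generator is a pure function of its parameters and a seed
(byte-identical reruns), and every planted feature is constructed to be
discoverable by the corresponding detector at default thresholds.

A single global seed fans out to per-component substreams via
``numpy.random.SeedSequence`` spawn keys, so adding a generator does not
perturb the output of the others.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation import DEFAULT_MOTIF, DomainHit, scan_motifs
from .conservation import Alignment
from .genome_io import AMINO_ACIDS, Gene, GeneTable, Protein, TaxonomyRecord
from .structure_context import Atom, Structure

__all__ = [
    "SyntheticTruth",
    "PlantedCluster",
    "PlantedDecoy",
    "DECOY_KINDS",
    "gen_genome",
    "gen_protein_with_motifs",
    "gen_helix_bundle",
    "gen_alignment",
    "gen_taxonomy",
    "write_truth",
    "read_truth",
]

DECOY_KINDS = ("motif_no_apbE", "apbE_no_motif", "wrong_domain")

# accessions used for planting; background hits draw from a disjoint pool
APBE_ACC = "PF02424"
SUBSTRATE_ANCHOR_ACCS = ("PF03358", "PF12682")
CYTOCHROME_ACC = "PF14358"
_BACKGROUND_ACCS = tuple(f"PF9{i:04d}" for i in range(60))

_RISE = 1.5  # Angstrom per residue along an ideal alpha-helix axis
_TURN = math.radians(100.0)  # rotation per residue
_CA_RADIUS = 2.3  # Calpha distance from the helix axis


@dataclass(frozen=True)
class PlantedCluster:
    genome_id: str
    contig_id: str
    anchor_gene_id: str
    motif_positions: tuple[int, ...] = ()


@dataclass(frozen=True)
class PlantedDecoy:
    genome_id: str
    contig_id: str
    anchor_gene_id: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in DECOY_KINDS:
            raise ValueError(f"unknown decoy kind {self.kind!r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth manifest of everything a generator planted."""

    seed: int
    planted_substrate_clusters: tuple[PlantedCluster, ...] = ()
    planted_decoys: tuple[PlantedDecoy, ...] = ()
    planted_cytochrome_clusters: tuple[PlantedCluster, ...] = ()
    planted_his_pairs: tuple[tuple[tuple[str, int], tuple[str, int]], ...] = ()


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# proteins


def _plant_motif_variant(rng: np.random.Generator) -> str:
    return rng.choice(["S", "T"]) + "GA" + rng.choice(["S", "T"])


def gen_protein_with_motifs(
    length: int,
    motif_positions: Sequence[int],
    seed: int = 0,
    protein_id: str = "synthetic",
    rng: np.random.Generator | None = None,
) -> Protein:
    """Generate a protein containing [S/T]GA[S/T] exactly at the given starts.

    Background residues are uniform over the 20 amino acids, with any
    accidental motif occurrence removed by re-randomizing one background
    residue inside the offending window (repeat until the scan count equals
    the request).  ``motif_positions`` are 1-based starts and must be
    non-overlapping (at least 4 apart) and fit within the sequence.
    """
    if rng is None:
        rng = _rng(seed, 1)
    positions = sorted(int(p) for p in motif_positions)
    for p in positions:
        if not 1 <= p <= length - 3:
            raise ValueError(f"motif start {p} does not fit in length {length}")
    for a, b in zip(positions, positions[1:]):
        if b - a < 4:
            raise ValueError(f"motif starts {a} and {b} overlap")
    seq = list(rng.choice(list(AMINO_ACIDS), size=length))
    planted_spans: set[int] = set()
    for p in positions:
        for off, ch in enumerate(_plant_motif_variant(rng)):
            seq[p - 1 + off] = ch
            planted_spans.add(p + off)
    for _ in range(10 * length + 100):
        protein = Protein(protein_id, "".join(seq))
        sites = scan_motifs(protein, DEFAULT_MOTIF)
        extra = [s for s in sites if s.start not in positions]
        if not extra and len(sites) == len(positions):
            return protein
        if not extra:  # pragma: no cover - planting is exact by construction
            raise RuntimeError("planted motif destroyed during repair")
        window = range(extra[0].start, extra[0].end + 1)
        editable = [i for i in window if i not in planted_spans]
        if not editable:  # pragma: no cover - disjoint plant spans guarantee this
            raise RuntimeError("cannot repair spurious motif inside planted span")
        i = int(rng.choice(editable))
        seq[i - 1] = str(rng.choice(list(AMINO_ACIDS)))
    raise RuntimeError("motif repair did not converge")  # pragma: no cover


# ---------------------------------------------------------------------------
# genomes


def _substrate_motif_positions(rng: np.random.Generator, length: int) -> tuple[int, ...]:
    # 1-2 motif-like sites in the C-terminal half, mirroring the candidates'
    # extended C-terminal regions / internal insertions
    if rng.random() < 0.5:
        return (int(rng.integers(length // 2, length - 3)),)
    first = int(rng.integers(length // 2, length - 60))
    second = int(rng.integers(first + 10, length - 3))
    return (first, second)


def gen_genome(
    n_contigs: int,
    genes_per_contig: int,
    n_substrate_clusters: int,
    n_decoys: int,
    n_cytochrome_clusters: int,
    seed: int = 0,
    k: int = 5,
) -> tuple[GeneTable, dict[str, Protein], list[DomainHit], SyntheticTruth]:
    """Generate genomes with planted substrate/decoy/cytochrome neighborhoods.

    Each contig is its own single-contig genome (the many-small-genomes
    shape of a database-scale screen).  Contigs are partitioned into
    disjoint blocks of width 2k+1; each planted cluster occupies one block
    with its anchor at the block center, so windows of distinct clusters
    never overlap.  Planted domain hits get E-values <= 1e-5 and background
    hits >= 1e-2, so the default 1e-3 cutoff separates them with margin.
    Decoy kinds cycle through ``motif_no_apbE`` (anchor + motif, no apbE),
    ``apbE_no_motif`` (anchor without motif, apbE present) and
    ``wrong_domain`` (motif + apbE, but a non-anchor domain).

    Returns ``(gene table, proteins, domain hits, truth manifest)``.
    """
    rng = _rng(seed, 2)
    width = 2 * k + 1
    blocks_per_contig = genes_per_contig // width
    slots = [(c, b) for c in range(n_contigs) for b in range(blocks_per_contig)]
    total = n_substrate_clusters + n_decoys + n_cytochrome_clusters
    if total > len(slots):
        raise ValueError(
            f"cannot pack {total} clusters into {len(slots)} non-overlapping "
            f"windows ({n_contigs} contigs x {blocks_per_contig} blocks)"
        )
    chosen = [slots[i] for i in rng.permutation(len(slots))[:total]]
    plan: dict[tuple[int, int], tuple[str, str]] = {}
    anchor_cycle = itertools.cycle(SUBSTRATE_ANCHOR_ACCS)
    decoy_cycle = itertools.cycle(DECOY_KINDS)
    for slot in chosen[:n_substrate_clusters]:
        plan[slot] = ("substrate", next(anchor_cycle))
    for slot in chosen[n_substrate_clusters : n_substrate_clusters + n_decoys]:
        plan[slot] = ("decoy", next(decoy_cycle))
    for slot in chosen[n_substrate_clusters + n_decoys :]:
        plan[slot] = ("cytochrome", CYTOCHROME_ACC)

    table: GeneTable = {}
    proteins: dict[str, Protein] = {}
    hits: list[DomainHit] = []
    substrates: list[PlantedCluster] = []
    decoys: list[PlantedDecoy] = []
    cytochromes: list[PlantedCluster] = []

    def add_hit(pid: str, acc: str, length: int, planted: bool) -> None:
        if planted:
            ev = 10.0 ** rng.uniform(-12, -5)
            bits = float(rng.uniform(100, 300))
        else:
            ev = 10.0 ** rng.uniform(-2, 1)
            bits = float(rng.uniform(5, 30))
        start = int(rng.integers(1, max(2, length // 4)))
        end = min(length, start + int(rng.integers(50, 150)))
        hits.append(DomainHit(pid, acc, acc, ev, bits, start, end))

    for c in range(n_contigs):
        genome_id = f"G{c:04d}"
        contig_id = f"{genome_id}_c1"
        # (accession, planted, motif_positions or None) per gene index
        roles: dict[int, tuple[str, bool, tuple[int, ...]]] = {}
        for b in range(blocks_per_contig):
            kind = plan.get((c, b))
            if kind is None:
                continue
            anchor_idx = b * width + k
            others = [i for i in range(b * width, b * width + width) if i != anchor_idx]
            apbe_idx = int(others[rng.integers(len(others))])
            anchor_len = 250
            what, detail = kind
            anchor_gene_id = f"{genome_id}_{anchor_idx:04d}"
            if what == "substrate":
                pos = _substrate_motif_positions(rng, anchor_len)
                roles[anchor_idx] = (detail, True, pos)
                roles[apbe_idx] = (APBE_ACC, True, ())
                substrates.append(PlantedCluster(genome_id, contig_id, anchor_gene_id, pos))
            elif what == "cytochrome":
                roles[anchor_idx] = (CYTOCHROME_ACC, True, ())
                roles[apbe_idx] = (APBE_ACC, True, ())
                cytochromes.append(PlantedCluster(genome_id, contig_id, anchor_gene_id))
            else:
                anchor_acc = SUBSTRATE_ANCHOR_ACCS[int(rng.integers(2))]
                pos = _substrate_motif_positions(rng, anchor_len)
                if detail == "motif_no_apbE":
                    roles[anchor_idx] = (anchor_acc, True, pos)
                elif detail == "apbE_no_motif":
                    roles[anchor_idx] = (anchor_acc, True, ())
                    roles[apbe_idx] = (APBE_ACC, True, ())
                else:  # wrong_domain: confident hit to a non-anchor family
                    wrong = _BACKGROUND_ACCS[int(rng.integers(len(_BACKGROUND_ACCS)))]
                    roles[anchor_idx] = (wrong, True, pos)
                    roles[apbe_idx] = (APBE_ACC, True, ())
                decoys.append(PlantedDecoy(genome_id, contig_id, anchor_gene_id, detail))
        genes = []
        for i in range(genes_per_contig):
            gene_id = f"{genome_id}_{i:04d}"
            start = 1 + i * 1000
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(gene_id, genome_id, contig_id, start, start + 899, strand))
            if i in roles:
                acc, planted, motif_pos = roles[i]
                length = 250 if motif_pos or acc != APBE_ACC else 350
                proteins[gene_id] = gen_protein_with_motifs(
                    length, motif_pos, protein_id=gene_id, rng=rng
                )
                add_hit(gene_id, acc, length, planted)
            else:
                length = int(rng.integers(150, 400))
                proteins[gene_id] = gen_protein_with_motifs(
                    length, (), protein_id=gene_id, rng=rng
                )
                acc = _BACKGROUND_ACCS[int(rng.integers(len(_BACKGROUND_ACCS)))]
                add_hit(gene_id, acc, length, planted=False)
        # genes were constructed in start order; assign ranks directly
        table[(genome_id, contig_id)] = [replace(g, index=i) for i, g in enumerate(genes)]
    truth = SyntheticTruth(
        seed=seed,
        planted_substrate_clusters=tuple(substrates),
        planted_decoys=tuple(decoys),
        planted_cytochrome_clusters=tuple(cytochromes),
    )
    return table, proteins, hits, truth


_PHYLA = ("Firmicutes", "Proteobacteria", "Actinobacteriota", "Bacteroidota")


def gen_taxonomy(genome_ids: Sequence[str], seed: int = 0) -> dict[str, TaxonomyRecord]:
    """Assign each genome a GTDB-style 7-rank string over a few phyla."""
    rng = _rng(seed, 3)
    out: dict[str, TaxonomyRecord] = {}
    for gid in genome_ids:
        p = _PHYLA[int(rng.integers(len(_PHYLA)))]
        tax = (
            f"d__Bacteria;p__{p};c__{p}_c;o__{p}_o;f__{p}_f;g__{p}_g;s__{p}_g sp{int(rng.integers(1, 999)):03d}"
        )
        out[gid] = TaxonomyRecord(gid, tax)
    return out


# ---------------------------------------------------------------------------
# helix bundles


def _helix_frame(n_helices: int, radius: float, helix: int) -> tuple[np.ndarray, int]:
    theta = 2 * math.pi * helix / n_helices
    axis = np.array([radius * math.cos(theta), radius * math.sin(theta), 0.0])
    direction = 1 if helix % 2 == 0 else -1
    return axis, direction


def _ca_position(
    axis: np.ndarray, direction: int, half_span: float, j: int, phase: float
) -> np.ndarray:
    ang = phase + _TURN * j
    z = direction * (-half_span + _RISE * j)
    return axis + np.array([_CA_RADIUS * math.cos(ang), _CA_RADIUS * math.sin(ang), z])


def gen_helix_bundle(
    n_helices: int = 6,
    residues_per_helix: int = 30,
    radius: float = 8.0,
    his_pair_depths: Sequence[float] = (),
    n_decoy_his: int = 0,
    seed: int = 0,
    ne2_separation: float = 4.4,
) -> tuple[Structure, SyntheticTruth]:
    """Build an idealized transmembrane helix bundle with planted His pairs.

    Helices use textbook ideal alpha-helix parameters (1.5 A rise and 100
    degree turn per residue, Calpha 2.3 A off-axis), alternate up/down on a
    circle of the given radius about the z axis, and are centered on z = 0
    so the estimated membrane slab is centered at the origin.  All residues
    are Ala (full backbone + CB) except planted His.

    Each requested pair depth plants two His on roughly opposite helices
    with their NE2 atoms facing each other across the bundle interior at
    ``ne2_separation`` (default 4.4 A, the spacing of an axial bis-His iron
    site: two ~2.2 A Fe-NE2 bonds).  Decoy His are single residues placed
    off-center (|z| >= 9 A) with outward-pointing NE2, re-drawn until no
    decoy can form a close, membrane-central pair with any other His.
    """
    if n_helices < 1:
        raise ValueError("need at least one helix")
    if len(his_pair_depths) > 0 and n_helices < 2:
        raise ValueError("His pairs need at least two helices")
    rng = _rng(seed, 4)
    half_span = _RISE * (residues_per_helix - 1) / 2.0
    n_res = residues_per_helix
    ca: dict[int, np.ndarray] = {}  # residue number -> CA
    res_helix: dict[int, int] = {}
    phases = [float(rng.uniform(0, 2 * math.pi)) for _ in range(n_helices)]
    for h in range(n_helices):
        axis, direction = _helix_frame(n_helices, radius, h)
        for j in range(n_res):
            resnum = h * n_res + j + 1
            ca[resnum] = _ca_position(axis, direction, half_span, j, phases[h])
            res_helix[resnum] = h

    def residue_at_depth(h: int, depth: float) -> int:
        axis, direction = _helix_frame(n_helices, radius, h)
        j = round((direction * depth + half_span) / _RISE)
        j = min(max(j, 0), n_res - 1)
        return h * n_res + j + 1

    max_pairs = n_helices // 2
    if len(his_pair_depths) > max_pairs:
        raise ValueError(
            f"{len(his_pair_depths)} pairs need {2 * len(his_pair_depths)} helices"
        )
    his_atoms: dict[int, np.ndarray] = {}  # residue -> NE2 position
    pairs: list[tuple[int, int]] = []
    for p, depth in enumerate(his_pair_depths):
        # adjacent up/down helix duos keep distinct pairs' NE2 groups far
        # apart (>= ~9.8 A for a 6-helix, 8 A-radius bundle)
        h1, h2 = 2 * p, 2 * p + 1
        r1, r2 = residue_at_depth(h1, depth), residue_at_depth(h2, depth)
        if r1 in his_atoms or r2 in his_atoms:
            raise ValueError("His pair placements collide; use fewer pairs or longer helices")
        # anchor NE2 geometry on the helix axes (not the phase-shifted CAs)
        # so the spacing between distinct pairs' NE2 groups is deterministic
        a1, _ = _helix_frame(n_helices, radius, h1)
        a2, _ = _helix_frame(n_helices, radius, h2)
        mid = (a1 + a2) / 2.0
        mid[2] = depth
        for r, axis in ((r1, a1), (r2, a2)):
            u = np.array([axis[0] - mid[0], axis[1] - mid[1], 0.0])
            u = u / np.linalg.norm(u)
            his_atoms[r] = mid + u * (ne2_separation / 2.0)
        pairs.append((r1, r2))

    def central_pair_possible(pos: np.ndarray) -> bool:
        for other in his_atoms.values():
            d = float(np.linalg.norm(pos - other))
            midz = (pos[2] + other[2]) / 2.0
            if d <= 8.5 and abs(midz) <= 8.0:  # slack beyond default thresholds
                return True
        return False

    for _ in range(n_decoy_his):
        for _attempt in range(200):
            h = int(rng.integers(n_helices))
            depth = float(rng.uniform(9.0, min(13.0, half_span))) * (
                1 if rng.random() < 0.5 else -1
            )
            r = residue_at_depth(h, depth)
            if r in his_atoms:
                continue
            axis, _ = _helix_frame(n_helices, radius, h)
            out_dir = axis / np.linalg.norm(axis) if radius > 0 else np.array([1.0, 0, 0])
            pos = ca[r] + out_dir * 4.0
            if not central_pair_possible(pos):
                his_atoms[r] = pos
                break
        else:
            raise RuntimeError("could not place a decoy His without creating a site")

    # threshold-aware guarantee: no non-planted pair may look like a site
    planted = {frozenset(p) for p in pairs}
    his_keys = sorted(his_atoms)
    for i, a in enumerate(his_keys):
        for b in his_keys[i + 1 :]:
            if frozenset((a, b)) in planted:
                continue
            d = float(np.linalg.norm(his_atoms[a] - his_atoms[b]))
            midz = (his_atoms[a][2] + his_atoms[b][2]) / 2.0
            if d <= 8.5 and abs(midz) <= 8.0:
                raise RuntimeError(
                    f"spurious His pair {(a, b)} (d={d:.2f}, depth={midz:.2f}); "
                    "adjust pair depths or bundle geometry"
                )

    atoms: list[Atom] = []
    resnums = sorted(ca)
    for r in resnums:
        pos = ca[r]
        resname = "HIS" if r in his_atoms else "ALA"
        prev_ca = ca.get(r - 1) if res_helix.get(r - 1) == res_helix[r] else None
        next_ca = ca.get(r + 1) if res_helix.get(r + 1) == res_helix[r] else None
        n_dir = (prev_ca - pos) if prev_ca is not None else np.array([0.0, 0.0, -1.0])
        c_dir = (next_ca - pos) if next_ca is not None else np.array([0.0, 0.0, 1.0])
        n_dir = n_dir / np.linalg.norm(n_dir)
        c_dir = c_dir / np.linalg.norm(c_dir)
        radial = pos - np.array([0.0, 0.0, pos[2]])
        rn = np.linalg.norm(radial)
        radial = radial / rn if rn > 0 else np.array([1.0, 0.0, 0.0])

        def add(name: str, element: str, p: np.ndarray) -> None:
            atoms.append(Atom(name, element, resname, r, "A", float(p[0]), float(p[1]), float(p[2])))

        add("N", "N", pos + n_dir * 1.45)
        add("CA", "C", pos)
        add("C", "C", pos + c_dir * 1.52)
        add("O", "O", pos + c_dir * 1.52 + radial * 1.23)
        add("CB", "C", pos + radial * 1.53)
        if r in his_atoms:
            ne2 = his_atoms[r]
            v = ne2 - pos
            add("CG", "C", pos + v * 0.4)
            add("ND1", "N", pos + v * 0.7 + radial * 0.5)
            add("NE2", "N", ne2)
    truth = SyntheticTruth(
        seed=seed,
        planted_his_pairs=tuple((("A", a), ("A", b)) for a, b in pairs),
    )
    return Structure(tuple(atoms)), truth


# ---------------------------------------------------------------------------
# alignments


def gen_alignment(
    n_sequences: int,
    n_columns: int,
    conserved_spec: Mapping[int, tuple[str, float]] | None = None,
    seed: int = 0,
) -> Alignment:
    """Generate an alignment with specified per-column conservation.

    ``conserved_spec`` maps a 1-based column index to (residue, frequency);
    in that column exactly round(frequency * n_sequences) rows carry the
    residue and the rest are uniform over the other 19 amino acids.
    Unspecified columns are uniform over all 20.  No gaps are produced.
    """
    spec = dict(conserved_spec or {})
    for col, (res, freq) in spec.items():
        if not 1 <= col <= n_columns:
            raise ValueError(f"conserved column {col} outside [1, {n_columns}]")
        if res not in AMINO_ACIDS:
            raise ValueError(f"invalid residue {res!r}")
        if not 0 < freq <= 1:
            raise ValueError(f"frequency must be in (0, 1], got {freq}")
    rng = _rng(seed, 5)
    aa = np.array(list(AMINO_ACIDS))
    matrix = rng.choice(aa, size=(n_sequences, n_columns))
    for col, (res, freq) in sorted(spec.items()):
        n_cons = int(round(freq * n_sequences))
        rows = rng.permutation(n_sequences)
        others = [c for c in AMINO_ACIDS if c != res]
        for r in rows[:n_cons]:
            matrix[r, col - 1] = res
        for r in rows[n_cons:]:
            matrix[r, col - 1] = rng.choice(others)
    seqs = tuple(
        (f"seq{i:04d}", "".join(matrix[i])) for i in range(n_sequences)
    )
    return Alignment(seqs)


# ---------------------------------------------------------------------------
# truth manifest I/O (plain key-value TSV)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write a truth manifest as a documented tab-separated key-value file.

    Record kinds: ``seed``, ``substrate`` (genome, contig, anchor gene,
    comma-joined motif starts), ``decoy`` (..., kind), ``cytochrome``,
    ``his_pair`` (chain:res, chain:res).
    """
    with open(path, "w") as fh:
        fh.write(f"seed\t{truth.seed}\n")
        for c in truth.planted_substrate_clusters:
            pos = ",".join(map(str, c.motif_positions))
            fh.write(f"substrate\t{c.genome_id}\t{c.contig_id}\t{c.anchor_gene_id}\t{pos}\n")
        for d in truth.planted_decoys:
            fh.write(f"decoy\t{d.genome_id}\t{d.contig_id}\t{d.anchor_gene_id}\t{d.kind}\n")
        for c in truth.planted_cytochrome_clusters:
            fh.write(f"cytochrome\t{c.genome_id}\t{c.contig_id}\t{c.anchor_gene_id}\n")
        for (ca_, cb) in truth.planted_his_pairs:
            fh.write(f"his_pair\t{ca_[0]}:{ca_[1]}\t{cb[0]}:{cb[1]}\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    seed = 0
    subs, decs, cyts, pairs = [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "seed":
                seed = int(fields[1])
            elif kind == "substrate":
                pos = tuple(int(p) for p in fields[4].split(",") if p)
                subs.append(PlantedCluster(fields[1], fields[2], fields[3], pos))
            elif kind == "decoy":
                decs.append(PlantedDecoy(fields[1], fields[2], fields[3], fields[4]))
            elif kind == "cytochrome":
                cyts.append(PlantedCluster(fields[1], fields[2], fields[3]))
            elif kind == "his_pair":
                a_chain, a_res = fields[1].split(":")
                b_chain, b_res = fields[2].split(":")
                pairs.append(((a_chain, int(a_res)), (b_chain, int(b_res))))
            else:
                raise ValueError(f"{path}:{lineno}: unknown record kind {kind!r}")
    return SyntheticTruth(
        seed=seed,
        planted_substrate_clusters=tuple(subs),
        planted_decoys=tuple(decs),
        planted_cytochrome_clusters=tuple(cyts),
        planted_his_pairs=tuple(pairs),
    )
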