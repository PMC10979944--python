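"""Gene-neighborhood colocalization screen — the discovery engine.

A candidate flavinylation substrate is a protein that (i) carries an
anchor-family domain (FMN_red, Flavodoxin_4 or DUF4405 by default),
(ii) contains at least one [S/T]GA[S/T]-like flavinylation motif, and
(iii) lies in a gene neighborhood (anchor +/- k genes, k = 5 by default)
that also encodes the ApbE FMN transferase.  Candidate transmembrane
cytochromes are DUF4405-family members of apbE neighborhoods that lack a
recognizable electron-transfer system.

Strand is ignored for colocalization: the window is defined purely on gene
rank along the contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .annotation import (
    DEFAULT_EVALUE_CUTOFF,
    DEFAULT_MOTIF,
    DomainAssignment,
    DomainHit,
    MotifSite,
    assign_domains,
    scan_motifs,
)
from .genome_io import Gene, GeneTable, Protein, TaxonomyRecord

__all__ = [
    "GeneCluster",
    "ClusterClassification",
    "ScreenConfig",
    "collect_neighborhood",
    "classify_cluster",
    "run_screen",
    "taxonomy_summary",
    "report_to_frame",
    "write_report",
]

# Editable defaults; the original screen's accession sets are not enumerated
# anywhere, so these ship explicit and overridable (see ScreenConfig docs).
DEFAULT_APBE_ACCESSIONS = frozenset({"PF02424"})
DEFAULT_ANCHOR_ACCESSIONS = frozenset({"PF03358", "PF12682", "PF14358"})
DEFAULT_CYTOCHROME_ACCESSIONS = frozenset({"PF14358"})
DEFAULT_KNOWN_ET_ACCESSIONS = frozenset({"PF03116", "PF04205", "PF03413", "PF01794"})
DEFAULT_TRANSPORTER_ACCESSIONS: frozenset[str] = frozenset()

REPORT_COLUMNS = [
    "genome_id",
    "contig_id",
    "anchor_gene",
    "anchor_accession",
    "k",
    "has_apbE",
    "has_known_ET",
    "has_transporter",
    "n_substrate_candidates",
    "candidate_ids",
    "n_cytochrome_candidates",
    "cytochrome_ids",
]


@dataclass(frozen=True)
class GeneCluster:
    """An anchor gene plus its +/- k genomic neighbors (anchor included)."""

    anchor: Gene
    members: tuple[Gene, ...]
    k: int

    def __post_init__(self) -> None:
        if len(self.members) > 2 * self.k + 1:
            raise ValueError("cluster has more members than the window allows")
        if self.anchor not in self.members:
            raise ValueError("anchor must be a cluster member")


@dataclass(frozen=True)
class ClusterClassification:
    """The screen's verdict on one neighborhood."""

    cluster: GeneCluster
    has_apbE: bool
    has_known_ET_system: bool
    has_flavin_transporter: bool
    substrate_candidates: tuple[tuple[str, tuple[MotifSite, ...]], ...]
    cytochrome_candidates: tuple[str, ...]


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable parameters of the colocalization screen.

    ``k`` is the flank size in genes on each side of the anchor.  Accession
    sets are versionless Pfam accessions; all ship with editable defaults
    because the original accession sets are not published in full:
    apbE = PF02424; anchors = PF03358 (FMN_red), PF12682 (Flavodoxin_4),
    PF14358 (DUF4405); known electron-transfer systems = NqrB/RnfD-like,
    FMN_bind, PepSY-like, MsrQ-like entries; the transporter set is empty
    until supplied.
    """

    k: int = 5
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    apbE_accessions: frozenset[str] = DEFAULT_APBE_ACCESSIONS
    anchor_accessions: frozenset[str] = DEFAULT_ANCHOR_ACCESSIONS
    cytochrome_accessions: frozenset[str] = DEFAULT_CYTOCHROME_ACCESSIONS
    known_ET_accessions: frozenset[str] = DEFAULT_KNOWN_ET_ACCESSIONS
    transporter_accessions: frozenset[str] = DEFAULT_TRANSPORTER_ACCESSIONS
    motif_pattern: str = DEFAULT_MOTIF
    mode: str = "anchor-first"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.mode not in {"anchor-first", "apbe-first"}:
            raise ValueError(f"unknown screen mode {self.mode!r}")
        overlap = self.apbE_accessions & self.anchor_accessions
        if overlap:
            raise ValueError(f"apbE and anchor accession sets overlap: {sorted(overlap)}")


def collect_neighborhood(genome: Iterable[Gene], anchor: Gene, k: int = 5) -> GeneCluster:
    """Collect the genes with rank in [anchor.index - k, anchor.index + k].

    ``genome`` is the gene list of one contig (as produced by
    :func:`flavscreen.genome_io.read_gene_table`); the window truncates at
    contig boundaries.
    """
    contig = sorted(
        (g for g in genome if g.contig_id == anchor.contig_id and g.genome_id == anchor.genome_id),
        key=lambda g: g.index,
    )
    if anchor not in contig:
        raise ValueError(f"anchor {anchor.gene_id} not found on its contig")
    members = tuple(g for g in contig if abs(g.index - anchor.index) <= k)
    return GeneCluster(anchor=anchor, members=members, k=k)


def _best(assignments: Mapping[str, DomainAssignment], gene: Gene) -> str | None:
    a = assignments.get(gene.gene_id)
    return a.best_accession if a is not None else None


def classify_cluster(
    cluster: GeneCluster,
    assignments: Mapping[str, DomainAssignment],
    proteins: Mapping[str, Protein],
    config: ScreenConfig = ScreenConfig(),
) -> ClusterClassification:
    """Classify one neighborhood by its members' domain content and motifs.

    Flags depend only on genes inside the window.  Substrate candidates
    require apbE colocalization; members carrying an anchor-family domain
    are motif-scanned regardless, so a missing protein sequence for such a
    member is an error even when the cluster lacks apbE.
    """
    bests = {g.gene_id: _best(assignments, g) for g in cluster.members}
    has_apbE = any(b in config.apbE_accessions for b in bests.values() if b)
    has_et = any(b in config.known_ET_accessions for b in bests.values() if b)
    has_transporter = any(b in config.transporter_accessions for b in bests.values() if b)

    substrate: list[tuple[str, tuple[MotifSite, ...]]] = []
    cytochrome: list[str] = []
    for g in cluster.members:
        b = bests[g.gene_id]
        if b in config.anchor_accessions:
            protein = proteins.get(g.gene_id)
            if protein is None:
                raise KeyError(
                    f"no protein sequence for {g.gene_id} (needed for motif scanning)"
                )
            sites = scan_motifs(protein, config.motif_pattern)
            if sites and has_apbE:
                substrate.append((g.gene_id, tuple(sites)))
        if b in config.cytochrome_accessions and has_apbE and not has_et:
            cytochrome.append(g.gene_id)
    return ClusterClassification(
        cluster=cluster,
        has_apbE=has_apbE,
        has_known_ET_system=has_et,
        has_flavin_transporter=has_transporter,
        substrate_candidates=tuple(substrate),
        cytochrome_candidates=tuple(cytochrome),
    )


def run_screen(
    genomes: GeneTable,
    proteins: Mapping[str, Protein],
    hits: Iterable[DomainHit] | Mapping[str, DomainAssignment],
    config: ScreenConfig = ScreenConfig(),
) -> list[ClusterClassification]:
    """Run the whole screen: pick anchors, window them, classify every window.

    In ``anchor-first`` mode (default) anchors are genes whose best domain is
    in ``config.anchor_accessions`` — the candidate-family-centric reading.
    In ``apbe-first`` mode anchors are apbE genes themselves, the framing
    used when mining apbE neighborhoods for unknown cytochromes.  Output is
    deterministically ordered by (genome_id, contig_id, anchor index).
    """
    if isinstance(hits, Mapping):
        assignments = hits
    else:
        assignments = assign_domains(hits, config.evalue_cutoff)
    anchor_set = (
        config.anchor_accessions if config.mode == "anchor-first" else config.apbE_accessions
    )
    report: list[ClusterClassification] = []
    for key in sorted(genomes):
        contig_genes = genomes[key]
        for gene in contig_genes:  # already index-ordered
            if _best(assignments, gene) in anchor_set:
                cluster = collect_neighborhood(contig_genes, gene, config.k)
                report.append(classify_cluster(cluster, assignments, proteins, config))
    return report


def taxonomy_summary(
    report: Iterable[ClusterClassification],
    taxonomy: Mapping[str, TaxonomyRecord],
) -> pd.DataFrame:
    """Tally clusters and distinct genomes per phylum.

    Genomes absent from the taxonomy mapping are counted under
    ``unclassified``.  Returns a DataFrame with columns
    (phylum, genome_count, cluster_count), sorted by descending
    cluster_count then phylum.
    """
    rows = []
    for cls in report:
        gid = cls.cluster.anchor.genome_id
        rec = taxonomy.get(gid)
        rows.append({"phylum": rec.phylum if rec else "unclassified", "genome_id": gid})
    if not rows:
        return pd.DataFrame(columns=["phylum", "genome_count", "cluster_count"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("phylum")
        .agg(genome_count=("genome_id", "nunique"), cluster_count=("genome_id", "size"))
        .reset_index()
        .sort_values(["cluster_count", "phylum"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return out


def report_to_frame(report: Iterable[ClusterClassification]) -> pd.DataFrame:
    """Flatten classifications into the stable-column report table."""
    rows = []
    for cls in report:
        a = cls.cluster.anchor
        rows.append(
            {
                "genome_id": a.genome_id,
                "contig_id": a.contig_id,
                "anchor_gene": a.gene_id,
                "anchor_accession": "",  # filled by caller when assignments known
                "k": cls.cluster.k,
                "has_apbE": cls.has_apbE,
                "has_known_ET": cls.has_known_ET_system,
                "has_transporter": cls.has_flavin_transporter,
                "n_substrate_candidates": len(cls.substrate_candidates),
                "candidate_ids": ",".join(pid for pid, _ in cls.substrate_candidates),
                "n_cytochrome_candidates": len(cls.cytochrome_candidates),
                "cytochrome_ids": ",".join(cls.cytochrome_candidates),
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(
    report: Iterable[ClusterClassification],
    path: str | Path,
    assignments: Mapping[str, DomainAssignment] | None = None,
) -> pd.DataFrame:
    """Write the cluster report as TSV with the documented column order."""
    df = report_to_frame(report)
    if assignments is not None and not df.empty:
        df["anchor_accession"] = [
            (assignments[g].best_accession or "") if g in assignments else ""
            for g in df["anchor_gene"]
        ]
    df.to_csv(path, sep="\t", index=False)
    return df
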