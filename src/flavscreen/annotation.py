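"""Domain assignment from hmmsearch tables and flavinylation-motif scanning.

The ApbE FMN transferase flavinylates a Ser/Thr inside a conserved
[S/T]GA[S/T]-like motif; the final bracket position is the residue that
receives the flavin.  The scanner here is a native degenerate-pattern
matcher (profile-HMM scoring stays in hmmsearch, whose per-domain tabular
output this module consumes).

The best-hit E-value filter uses the per-domain *independent* E-value
column of the domtblout layout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .genome_io import AMINO_ACIDS, Protein

__all__ = [
    "DomainHit",
    "DomainAssignment",
    "MotifSite",
    "DEFAULT_MOTIF",
    "DEFAULT_EVALUE_CUTOFF",
    "read_domtbl",
    "write_domtbl",
    "assign_domains",
    "parse_pattern",
    "scan_motifs",
    "count_domain_copies",
]

DEFAULT_MOTIF = "[ST]GA[ST]"
DEFAULT_EVALUE_CUTOFF = 1e-3


def normalize_accession(accession: str) -> str:
    """Strip a Pfam version suffix: PF03358.18 -> PF03358."""
    return accession.split(".")[0]


@dataclass(frozen=True)
class DomainHit:
    """One per-domain hit row: a profile matched against a protein region."""

    protein_id: str
    domain_accession: str
    domain_name: str
    evalue: float
    bitscore: float
    ali_start: int
    ali_end: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.protein_id}/{self.domain_accession}: negative E-value")
        if self.ali_start < 1 or self.ali_end < self.ali_start:
            raise ValueError(
                f"{self.protein_id}/{self.domain_accession}: bad alignment interval "
                f"{self.ali_start}..{self.ali_end}"
            )


@dataclass(frozen=True)
class DomainAssignment:
    """Best-match call for one protein plus all hits passing the cutoff."""

    protein_id: str
    best_accession: str | None
    best_evalue: float | None
    all_passing_hits: tuple[DomainHit, ...]


@dataclass(frozen=True)
class MotifSite:
    """A matched flavinylation-motif occurrence.

    ``flavinylated_pos`` is the 1-based position of the modified Ser/Thr —
    the residue matching the final class of the pattern.
    """

    protein_id: str
    start: int
    end: int
    matched: str
    flavinylated_pos: int


# domtblout column indices (whitespace-delimited, comment lines start with #):
# 0 target, 1 target acc, 2 tlen, 3 query name, 4 query acc, 5 qlen,
# 6 full E-value, 7 full score, 8 full bias, 9 dom #, 10 dom total,
# 11 c-Evalue, 12 i-Evalue, 13 dom score, 14 dom bias,
# 15-16 hmm coords, 17-18 ali coords, 19-20 env coords, 21 acc, 22+ description
_DOMTBL_MIN_COLS = 22


def read_domtbl(path: str | Path) -> list[DomainHit]:
    """Read an hmmsearch per-domain tabular file ("domtblout").

    One :class:`DomainHit` per data row, taking the independent E-value
    (column 13) and the alignment coordinates.  The query accession is
    normalized to a versionless Pfam accession.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_COLS:
                raise ValueError(
                    f"{path}:{lineno}: truncated row ({len(fields)} of "
                    f"{_DOMTBL_MIN_COLS} columns)"
                )
            try:
                evalue = float(fields[12])
                bitscore = float(fields[13])
                ali_start = int(fields[17])
                ali_end = int(fields[18])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field: {exc}") from None
            hits.append(
                DomainHit(
                    protein_id=fields[0],
                    domain_accession=normalize_accession(fields[4]),
                    domain_name=fields[3],
                    evalue=evalue,
                    bitscore=bitscore,
                    ali_start=ali_start,
                    ali_end=ali_end,
                )
            )
    return hits


def write_domtbl(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the domtblout column layout (inverse of :func:`read_domtbl`).

    Columns the model does not carry (bias, envelope coordinates, ...) are
    filled with placeholders; readers of this layout are whitespace-driven.
    """
    with open(path, "w") as fh:
        fh.write("# flavscreen domain-hit table (hmmsearch domtblout layout)\n")
        for h in hits:
            fh.write(
                f"{h.protein_id} - 0 {h.domain_name} {h.domain_accession} 0 "
                f"{h.evalue:.3g} {h.bitscore:.1f} 0.0 1 1 "
                f"{h.evalue:.3g} {h.evalue:.3g} {h.bitscore:.1f} 0.0 "
                f"1 {h.ali_end - h.ali_start + 1} {h.ali_start} {h.ali_end} "
                f"{h.ali_start} {h.ali_end} 0.99 -\n"
            )


def _hit_order(h: DomainHit) -> tuple:
    # ascending E-value, then descending bitscore, then accession, then position
    return (h.evalue, -h.bitscore, h.domain_accession, h.ali_start, h.ali_end)


def assign_domains(
    hits: Iterable[DomainHit], evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> dict[str, DomainAssignment]:
    """Call the best domain per protein at an E-value cutoff.

    Hits with E-value above the cutoff are discarded.  The best hit is the
    one with minimal E-value; ties break by maximal bitscore, then
    lexicographic accession.  Proteins with no passing hit get
    ``best_accession = None`` (they do not appear in the output mapping
    unless they had at least one raw hit).
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    out: dict[str, DomainAssignment] = {}
    for pid in sorted(by_protein):
        passing = sorted(
            (h for h in by_protein[pid] if h.evalue <= evalue_cutoff), key=_hit_order
        )
        if passing:
            out[pid] = DomainAssignment(pid, passing[0].domain_accession,
                                        passing[0].evalue, tuple(passing))
        else:
            out[pid] = DomainAssignment(pid, None, None, ())
    return out


def parse_pattern(pattern: str) -> list[frozenset[str]]:
    """Parse a bracket-notation degenerate pattern into per-position classes.

    ``"[ST]GA[ST]"`` -> [{S,T}, {G}, {A}, {S,T}].  Only the 20 standard
    one-letter amino-acid codes are accepted inside classes.
    """
    if not pattern:
        raise ValueError("empty motif pattern")
    classes: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.find("]", i)
            if j == -1:
                raise ValueError(f"unclosed bracket in pattern {pattern!r}")
            members = pattern[i + 1 : j].upper()
            if not members:
                raise ValueError(f"empty class in pattern {pattern!r}")
            i = j + 1
        else:
            members = ch.upper()
            i += 1
        bad = set(members) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"invalid residue(s) {sorted(bad)} in pattern {pattern!r}")
        classes.append(frozenset(members))
    return classes


def _pattern_regex(classes: Sequence[frozenset[str]]) -> re.Pattern[str]:
    body = "".join(
        f"[{''.join(sorted(c))}]" if len(c) > 1 else next(iter(c)) for c in classes
    )
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({body}))")


def scan_motifs(
    protein: Protein,
    pattern: str = DEFAULT_MOTIF,
    region: tuple[int, int] | None = None,
) -> list[MotifSite]:
    """Find all occurrences of a degenerate motif, overlaps included.

    Parameters
    ----------
    protein:
        Protein to scan.
    pattern:
        Bracket-notation pattern; the default is the ApbE flavinylation
        motif [ST]GA[ST], whose final position is the flavinylated residue.
    region:
        Optional 1-based inclusive residue interval restricting the scan
        (matches must start and end inside it); e.g. a caller-supplied
        extracytosolic region mask.

    Returns
    -------
    list of :class:`MotifSite` in ascending start order.
    """
    classes = parse_pattern(pattern)
    seq = protein.sequence
    if region is not None:
        lo, hi = region
        if lo < 1 or hi > len(seq) or hi < lo:
            raise ValueError(
                f"region {region} outside sequence [1, {len(seq)}] of {protein.protein_id}"
            )
    else:
        lo, hi = 1, len(seq)
    rx = _pattern_regex(classes)
    plen = len(classes)
    sites: list[MotifSite] = []
    for m in rx.finditer(seq, lo - 1, hi):
        start = m.start() + 1
        end = start + plen - 1
        if end > hi:
            continue
        sites.append(MotifSite(protein.protein_id, start, end, m.group(1), end))
    return sites


def count_domain_copies(
    hits: Iterable[DomainHit],
    protein_id: str,
    accession: str,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> tuple[int, bool]:
    """Count non-overlapping copies of one domain within one protein.

    Multi-copy flavinylated domains (e.g. FMN-bind_2) tend to occur in even
    numbers, pairing into pseudo-symmetric two-site units; the returned
    ``is_even`` flag supports that tally.  Overlapping passing hits are
    resolved greedily by ascending E-value (ties by bitscore, accession,
    position), discarding any hit whose alignment interval overlaps an
    already-kept one.
    """
    accession = normalize_accession(accession)
    candidates = sorted(
        (
            h
            for h in hits
            if h.protein_id == protein_id
            and normalize_accession(h.domain_accession) == accession
            and h.evalue <= evalue_cutoff
        ),
        key=_hit_order,
    )
    kept: list[DomainHit] = []
    for h in candidates:
        if all(h.ali_start > k.ali_end or h.ali_end < k.ali_start for k in kept):
            kept.append(h)
    n = len(kept)
    return n, n % 2 == 0
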