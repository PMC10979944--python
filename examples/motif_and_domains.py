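"""Scan a protein for flavinylation motifs and call its domains.

The ApbE FMN transferase attaches FMN to the final Ser/Thr of a
[S/T]GA[S/T]-like motif.  Domain calls take the best hmmsearch hit at
E <= 1e-3; multi-copy domains are counted after greedy overlap resolution.
"""

from flavscreen import DomainHit, Protein, assign_domains, count_domain_copies, scan_motifs

protein = Protein("demo", "MKTLLAQEWSGASGATLLNNDKEWFQSGATYW")
for site in scan_motifs(protein):
    print(
        f"motif {site.matched} at {site.start}..{site.end}; "
        f"flavinylated residue {protein.sequence[site.flavinylated_pos - 1]}{site.flavinylated_pos}"
    )

hits = [
    DomainHit("demo", "PF04205", "FMN_bind", 1e-12, 120.0, 10, 150),
    DomainHit("demo", "PF04205", "FMN_bind", 1e-9, 95.0, 160, 300),
    DomainHit("demo", "PF03358", "FMN_red", 1e-4, 20.0, 5, 90),
]
assignment = assign_domains(hits)["demo"]
print(f"best domain: {assignment.best_accession} at E = {assignment.best_evalue:g}")

copies, is_even = count_domain_copies(hits, "demo", "PF04205")
print(f"FMN_bind copies: {copies} (even: {is_even})")
# An even copy number is the signature of paired two-site flavinylated units.
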