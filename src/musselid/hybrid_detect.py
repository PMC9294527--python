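"""Diagnostic-site discovery and IUPAC-heterozygote hybrid calling.

Two species that hybridize can be told apart at *diagnostic sites*:
alignment columns fixed for one base in every reference of species A and a
different base in every reference of species B.  A diploid F1 hybrid is
heterozygous at each of these columns, which Sanger sequencing reports as a
double peak and the base caller encodes as the IUPAC code covering both
parental alleles (e.g. C/T -> Y).  A record is called a putative hybrid when
its IUPAC base set contains *both* parental alleles at at least
``min_het_sites`` diagnostic columns.
"""

from __future__ import annotations

from dataclasses import dataclass

from musselid.seqio import IUPAC_BASES, AlignedSet

STATUS_PURE_A = "pure_A"
STATUS_PURE_B = "pure_B"
STATUS_HYBRID = "putative_hybrid"
STATUS_UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class DiagnosticSite:
    column: int       # 1-based alignment column
    allele_A: str
    allele_B: str


@dataclass
class DiagnosticPanel:
    """Fixed diagnostic differences between two reference species sets."""

    sites: list[DiagnosticSite]
    species_A: str
    species_B: str

    def __post_init__(self) -> None:
        for s in self.sites:
            if s.allele_A == s.allele_B:
                raise ValueError(f"column {s.column}: alleles must differ")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def columns(self) -> list[int]:
        return [s.column for s in self.sites]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("column\tallele_A\tallele_B\n")
            for s in self.sites:
                fh.write(f"{s.column}\t{s.allele_A}\t{s.allele_B}\n")


@dataclass
class HybridCall:
    """Per-record hybrid-detection outcome over a diagnostic panel."""

    id: str
    status: str           # pure_A | pure_B | putative_hybrid | undetermined
    het_sites: int        # panel columns whose base set contains both alleles
    genotype: str         # observed characters at the panel columns, in order


def find_diagnostic_sites(
    aln: AlignedSet,
    refs_A,
    refs_B,
    species_A: str = "species_A",
    species_B: str = "species_B",
) -> DiagnosticPanel:
    """Scan alignment columns for fixed differences between two reference sets.

    A column qualifies when every A-reference carries the same unambiguous,
    ungapped base, every B-reference likewise, and the two bases differ.
    """
    refs_A, refs_B = list(refs_A), list(refs_B)
    if not refs_A or not refs_B:
        raise ValueError("both reference sets must be non-empty")
    recs_A = [aln[i] for i in refs_A]
    recs_B = [aln[i] for i in refs_B]
    sites = []
    for col in range(1, aln.length + 1):
        chars_A = {r.seq[col - 1] for r in recs_A}
        chars_B = {r.seq[col - 1] for r in recs_B}
        if len(chars_A) != 1 or len(chars_B) != 1:
            continue
        a, b = next(iter(chars_A)), next(iter(chars_B))
        if a == b or len(IUPAC_BASES[a]) != 1 or len(IUPAC_BASES[b]) != 1:
            continue
        sites.append(DiagnosticSite(column=col, allele_A=a, allele_B=b))
    return DiagnosticPanel(sites=sites, species_A=species_A, species_B=species_B)


def call_hybrids(
    aln: AlignedSet,
    panel: DiagnosticPanel,
    min_het_sites: int = 1,
) -> dict[str, HybridCall]:
    """Call every record against a diagnostic panel.

    A panel column counts as heterozygous when the record's IUPAC base set
    contains both parental alleles; a gap there counts toward neither parent
    nor the heterozygote tally.  Records with ``het_sites >= min_het_sites``
    are putative hybrids; records matching one parent exactly at every column
    are pure; anything else is undetermined.

    The default ``min_het_sites=1`` is deliberately permissive: field data
    show individuals heterozygous at a single diagnostic site that still
    represent hybrid ancestry, and the threshold is exposed for stricter use.
    """
    if not panel.sites:
        raise ValueError("diagnostic panel is empty")
    if min_het_sites < 1:
        raise ValueError("min_het_sites must be >= 1")
    calls: dict[str, HybridCall] = {}
    for rec in aln:
        het = 0
        all_a = True
        all_b = True
        genotype = []
        for site in panel.sites:
            ch = rec.seq[site.column - 1]
            genotype.append(ch)
            bases = IUPAC_BASES[ch]
            if site.allele_A in bases and site.allele_B in bases:
                het += 1
            if ch != site.allele_A:
                all_a = False
            if ch != site.allele_B:
                all_b = False
        if het >= min_het_sites:
            status = STATUS_HYBRID
        elif all_a:
            status = STATUS_PURE_A
        elif all_b:
            status = STATUS_PURE_B
        else:
            status = STATUS_UNDETERMINED
        calls[rec.id] = HybridCall(
            id=rec.id, status=status, het_sites=het, genotype="".join(genotype)
        )
    return calls


def hybrid_ids(calls: dict[str, HybridCall]) -> list[str]:
    """Ids called putative hybrids, in input order."""
    return [c.id for c in calls.values() if c.status == STATUS_HYBRID]


def write_hybrid_report(calls: dict[str, HybridCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tstatus\thet_sites\tgenotype\n")
        for c in calls.values():
            fh.write(f"{c.id}\t{c.status}\t{c.het_sites}\t{c.genotype}\n")
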