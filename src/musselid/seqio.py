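"""Domain types, IUPAC alphabet semantics, and file I/O for aligned barcodes.

Sequences are aligned DNA barcode reads over the IUPAC nucleotide alphabet
plus the gap character.  Ambiguity codes matter here: a diploid individual
sequenced by Sanger shows a "double peak" at a heterozygous position, which
base callers encode as the IUPAC code covering both alleles (Y = C/T,
R = A/G, M = A/C, ...).  Hybrid detection and the intersect-is-match
similarity policy are built on top of this base-set semantics.

All alignment coordinates exposed by this package are 1-based columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC+gap alphabet."""


class AlignmentError(ValueError):
    """Records violate the aligned-set contract (length or id uniqueness)."""


#: IUPAC nucleotide codes mapped to the set of unambiguous bases they denote.
#: The gap character maps to the empty set: it denotes no base at all.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset(),
}

_CODE_OF_BASES: dict[frozenset[str], str] = {v: k for k, v in IUPAC_BASES.items()}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

UNLABELLED = "unlabelled"


def iupac_bases(code: str) -> frozenset[str]:
    """Return the set of unambiguous bases an IUPAC code denotes."""
    try:
        return IUPAC_BASES[code.upper()]
    except KeyError:
        raise AlphabetError(f"not an IUPAC nucleotide code: {code!r}") from None


def iupac_code(bases: frozenset[str] | set[str]) -> str:
    """Return the IUPAC code denoting exactly this base set (inverse of iupac_bases)."""
    try:
        return _CODE_OF_BASES[frozenset(bases)]
    except KeyError:
        raise AlphabetError(f"no IUPAC code for base set {sorted(bases)!r}") from None


def is_transition(x: str, y: str) -> bool:
    """True when x→y is a transition (purine↔purine or pyrimidine↔pyrimidine)."""
    return (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES)


def _normalize_seq(record_id: str, seq: str) -> str:
    out = seq.upper().replace("U", "T")
    for col, ch in enumerate(out, start=1):
        if ch not in IUPAC_BASES:
            raise AlphabetError(
                f"record {record_id!r}: illegal character {ch!r} at column {col}"
            )
    return out


@dataclass
class BarcodeRecord:
    """One aligned barcode sequence with an id and optional species labels.

    ``label`` carries the nominal species; ``aux_labels`` maps the name of an
    independent labelling scheme (e.g. an HRM assay or a SNP panel) to that
    scheme's species call for this individual.
    """

    id: str
    seq: str
    label: str | None = None
    aux_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seq:
            raise AlphabetError(f"record {self.id!r}: empty sequence")
        self.seq = _normalize_seq(self.id, self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def base_set(self, column: int) -> frozenset[str]:
        """Base set at a 1-based alignment column."""
        return IUPAC_BASES[self.seq[column - 1]]

    def is_ambiguous(self) -> bool:
        """True when any position carries a multi-base IUPAC code."""
        return any(len(IUPAC_BASES[c]) > 1 for c in self.seq)


@dataclass
class AlignedSet:
    """An ordered collection of equal-length BarcodeRecords with unique ids."""

    records: list[BarcodeRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("aligned set must contain at least one record")
        length = len(self.records[0])
        for rec in self.records:
            if len(rec) != length:
                raise AlignmentError(
                    f"record {rec.id!r} has length {len(rec)}, expected {length}"
                )
        ids = [rec.id for rec in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate record ids: {dupes}")
        self._index = {rec.id: rec for rec in self.records}

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, record_id: str) -> BarcodeRecord:
        return self._index[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._index

    def subset(self, ids) -> "AlignedSet":
        """New AlignedSet restricted to the given ids, in this set's order."""
        wanted = set(ids)
        return AlignedSet([r for r in self.records if r.id in wanted])

    def without(self, ids) -> "AlignedSet":
        """New AlignedSet excluding the given ids."""
        drop = set(ids)
        return AlignedSet([r for r in self.records if r.id not in drop])

    def column(self, column: int) -> list[str]:
        """Characters at a 1-based alignment column, in record order."""
        return [rec.seq[column - 1] for rec in self.records]


def read_fasta(path) -> AlignedSet:
    """Read an aligned FASTA file into an AlignedSet.

    A header of the form ``>id|species`` sets the record's nominal species
    label; a bare ``>id`` leaves the label unset.  Sequences are upper-cased
    and U is normalized to T.  Unequal lengths raise AlignmentError and
    illegal characters raise AlphabetError naming the record and column.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id  # keep species names with spaces
        if "|" in header:
            rec_id, label = header.split("|", 1)
        else:
            rec_id, label = header, None
        records.append(BarcodeRecord(id=rec_id, seq=str(rec.seq), label=label))
    return AlignedSet(records)


def write_fasta(aln: AlignedSet, path) -> None:
    """Write an AlignedSet as FASTA, encoding labels as ``id|species`` headers."""
    out = []
    for rec in aln:
        header = f"{rec.id}|{rec.label}" if rec.label else rec.id
        out.append(SeqRecord(Seq(rec.seq), id=header, description=""))
    SeqIO.write(out, str(path), "fasta")


def read_labels(path) -> dict[str, dict[str, str]]:
    """Read a tab-separated label table: id → {scheme: species call}.

    The first column must be ``id``; every other column is a labelling
    scheme (``nominal_species``, an HRM assay, a SNP panel, ...).  Missing
    cells map to the explicit value ``"unlabelled"``.  Duplicate ids are an
    error.  An empty file yields an empty mapping.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    if df.empty and len(df.columns) == 0:
        return {}
    id_col = df.columns[0]
    ids = df[id_col].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ids in label table: {dupes}")
    schemes = [c for c in df.columns if c != id_col]
    table: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        calls = {}
        for scheme in schemes:
            val = row[scheme]
            calls[scheme] = UNLABELLED if pd.isna(val) or val == "" else str(val)
        table[str(row[id_col])] = calls
    return table


def write_labels(table: dict[str, dict[str, str]], path) -> None:
    """Write a label table (inverse of read_labels)."""
    schemes = sorted({s for calls in table.values() for s in calls})
    rows = [{"id": i, **{s: calls.get(s, UNLABELLED) for s in schemes}}
            for i, calls in table.items()]
    pd.DataFrame(rows, columns=["id", *schemes]).to_csv(path, sep="\t", index=False)


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to newick with branch lengths and support-as-node-labels.

    Every leaf must carry a taxon label; bootstrap supports, when present as
    internal ``node.label`` strings, are emitted as internal node labels.
    """
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree has an unlabelled tip; cannot write newick")
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return text.strip() + ("\n" if not text.endswith("\n") else "")


def read_newick(text: str) -> dendropy.Tree:
    """Parse newick text (support-as-node-label dialect) into a dendropy Tree."""
    return dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
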