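"""Readers/writers for the standard formats the pipeline touches.

Coordinates are 0-based half-open everywhere inside the package and are
converted to 1-based inclusive only at the GFF3 boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino-acid"

# IUPAC nucleotide codes (including ambiguity codes) and amino acids;
# '-'/'.' admit aligned sequences.
NT_ALPHABET = set("ACGTMRWSYKVHDBN-.")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-.")

IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "M": "AC", "R": "AG", "W": "AT", "S": "CG", "Y": "CT", "K": "GT",
    "V": "ACG", "H": "ACT", "D": "AGT", "B": "CGT", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTMRWSYKVHDBN", "TGCAKYWSRMBDHVN")

FEATURE_TYPES = {
    "LTR_retrotransposon",
    "long_terminal_repeat",
    "target_site_duplication",
    "ORF",
    "protein_domain",
    "primer_binding_site",
    "RR_tract",
    "PCR_product",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named sequence over a declared alphabet."""

    id: str
    residues: str
    alphabet: str = NUCLEOTIDE
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = NT_ALPHABET if self.alphabet == NUCLEOTIDE else AA_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} outside "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Feature:
    """A located annotation on a sequence (0-based half-open)."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    type: str = "ORF"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _normalize_residues(residues: str, alphabet: str) -> str:
    residues = residues.upper()
    if alphabet == NUCLEOTIDE:
        residues = residues.replace("U", "T")
    return residues


def read_fasta(path, alphabet: str = NUCLEOTIDE) -> list[SequenceRecord]:
    """Read a multi-record FASTA file, preserving record order.

    Headers are split at the first whitespace into id/description.
    Residues are uppercased; U is mapped to T for nucleotide input.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=_normalize_residues(str(rec.seq), alphabet),
                alphabet=alphabet,
                description=desc,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_genbank(path) -> SequenceRecord:
    """Read a single-record GenBank flat file (reader only)."""
    rec = SeqIO.read(str(path), "genbank")
    return SequenceRecord(
        id=rec.id,
        residues=_normalize_residues(str(rec.seq), NUCLEOTIDE),
        alphabet=NUCLEOTIDE,
        description=rec.description,
    )


def _gff3_escape(value: str) -> str:
    return (
        str(value)
        .replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
    )


def _gff3_unescape(value: str) -> str:
    return (
        value
        .replace("%2C", ",")
        .replace("%3D", "=")
        .replace("%3B", ";")
        .replace("%25", "%")
    )


def write_gff3(features: Iterable[Feature], path) -> None:
    """Write features as GFF3 (1-based inclusive), deterministically ordered."""
    feats = sorted(features, key=lambda f: (f.seq_id, f.start, f.end, f.type))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            if f.attributes:
                attrs = ";".join(
                    f"{_gff3_escape(k)}={_gff3_escape(v)}"
                    for k, v in sorted(f.attributes.items())
                )
            else:
                attrs = "."
            fh.write(
                "\t".join(
                    [
                        f.seq_id,
                        "chromomine",
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[Feature]:
    features: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs: dict = {}
            if cols[8] != ".":
                for item in cols[8].split(";"):
                    if not item:
                        continue
                    key, _, val = item.partition("=")
                    attrs[_gff3_unescape(key)] = _gff3_unescape(val)
            features.append(
                Feature(
                    seq_id=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    type=cols[2],
                    attributes=attrs,
                )
            )
    return features


def write_newick(tree, path) -> None:
    """Serialize a phylogeny (branch lengths, bootstrap labels) to Newick."""
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path):
    from .phylo import Tree

    return Tree.from_newick(Path(path).read_text())


def write_json(obj: Mapping, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
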