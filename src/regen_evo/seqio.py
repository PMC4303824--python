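"""Sequence, alignment, clade-map and tree I/O plus back-translation.

Alignments are plain dict-backed containers (id -> row string) so the
rest of the pipeline can index rows and columns without carrying
Biopython objects around; parsing of FASTA / Clustal / Newick itself is
delegated to Biopython and DendroPy.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
from Bio import AlignIO, SeqIO
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "CladeMap",
    "ProteinAlignment",
    "CodonAlignment",
    "PAIR_CODES",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_clade_map",
    "translate",
    "back_translate",
    "read_newick",
    "write_newick",
]

GAP = "-"
GAP_CODON = "---"

#: Clade-pair comparison codes, as indices into ``CladeMap.clade_order``.
#: With the default order (plant, fungi, metazoa) these are the classic
#: fp = fungi x plant, mf = metazoa x fungi, mp = metazoa x plant codes.
PAIR_CODES: dict[str, tuple[int, int]] = {"fp": (1, 0), "mf": (2, 1), "mp": (2, 0)}

_CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(_CODON_TABLE))  # 61 codons


class SeqIOError(ValueError):
    """Raised on malformed sequence input."""


@dataclass(frozen=True)
class CladeMap:
    """Assignment of sequence ids to one of three clade labels.

    ``clade_order`` fixes the meaning of the pair codes: with order
    (P, F, M) the comparisons are fp = (F, P), mf = (M, F), mp = (M, P).
    """

    entries: dict[str, str]
    clade_order: tuple[str, str, str] = ("plant", "fungi", "metazoa")

    def __post_init__(self) -> None:
        if len(set(self.clade_order)) != 3:
            raise SeqIOError("clade_order must contain three distinct labels")

    def clade_of(self, seq_id: str) -> str:
        return self.entries[seq_id]

    def members(self, clade: str) -> list[str]:
        return [i for i, c in self.entries.items() if c == clade]

    def pair_clades(self, code: str) -> tuple[str, str]:
        a, b = PAIR_CODES[code]
        return self.clade_order[a], self.clade_order[b]

    def require_three_clades(self, ids: Iterable[str] | None = None) -> None:
        ids = list(self.entries) if ids is None else list(ids)
        present = {self.entries[i] for i in ids}
        missing = [c for c in self.clade_order if c not in present]
        if missing:
            raise SeqIOError(f"clade(s) with no sequences: {missing}")


@dataclass
class ProteinAlignment:
    """Aligned amino-acid rows (equal length, '-' gaps, 'X' allowed)."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise SeqIOError(f"unequal alignment row lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def column(self, i: int) -> dict[str, str]:
        return {k: v[i] for k, v in self.rows.items()}


@dataclass
class CodonAlignment:
    """Aligned codon rows over {A,C,G,T,-}; gap codon is '---'."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise SeqIOError(f"unequal codon row lengths: {sorted(lengths)}")
        if lengths and next(iter(lengths)) % 3:
            raise SeqIOError("codon alignment length not divisible by 3")
        for sid, row in self.rows.items():
            for j in range(0, len(row), 3):
                codon = row[j : j + 3]
                if 0 < codon.count(GAP) < 3:
                    raise SeqIOError(f"partially gapped codon {codon!r} in {sid!r}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def codon(self, seq_id: str, i: int) -> str:
        return self.rows[seq_id][3 * i : 3 * i + 3]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence map.

    Ids are the first whitespace-delimited token of each header.
    Duplicate ids and empty files are errors.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise SeqIOError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise SeqIOError(f"no sequences found in {path}")
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path: str | Path, fmt: str | None = None) -> ProteinAlignment:
    """Read a protein alignment from aligned FASTA or Clustal format.

    The format is sniffed from the first line unless ``fmt`` is given
    ("fasta" or "clustal").
    """
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "fasta" if first.startswith(">") else "clustal"
    if fmt == "fasta":
        return ProteinAlignment(read_fasta(path))
    aln = AlignIO.read(str(path), fmt)
    rows: dict[str, str] = {}
    for rec in aln:
        if rec.id in rows:
            raise SeqIOError(f"duplicate sequence id {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq).upper()
    return ProteinAlignment(rows)


def read_clade_map(
    path: str | Path,
    clade_order: tuple[str, str, str] = ("plant", "fungi", "metazoa"),
    strict: bool = True,
) -> CladeMap:
    """Read a two-column (id TAB clade) table into a :class:`CladeMap`.

    With ``strict`` the file must contain exactly the three labels of
    ``clade_order`` (in any order); otherwise labels are free strings.
    """
    entries: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SeqIOError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sid, clade = parts[0].strip(), parts[1].strip()
            if sid in entries:
                raise SeqIOError(f"{path}:{lineno}: duplicate id {sid!r}")
            entries[sid] = clade
    labels = set(entries.values())
    if strict and labels != set(clade_order):
        raise SeqIOError(
            f"clade map labels {sorted(labels)} do not match expected "
            f"{sorted(clade_order)} (strict mode)"
        )
    return CladeMap(entries=entries, clade_order=clade_order)


def translate(cds: str) -> str:
    """Translate a (possibly gapped) nucleotide string codon by codon.

    '---' maps to '-'; codons with ambiguity characters map to 'X';
    stop codons map to '*'. Length must be divisible by 3.
    """
    if len(cds) % 3:
        raise SeqIOError(f"CDS length {len(cds)} not divisible by 3")
    cds = cds.upper()
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon == GAP_CODON:
            out.append(GAP)
        elif codon in _CODON_TABLE:
            out.append(_CODON_TABLE[codon])
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append("X")
    return "".join(out)


def back_translate(
    protein_aln: ProteinAlignment, cds: Mapping[str, str]
) -> CodonAlignment:
    """Replace each aligned residue by its source codon; gaps become '---'.

    Each sequence's ungapped protein row must equal the translation of
    its CDS (a terminal stop codon is tolerated and dropped; internal
    stops are an error). 'X' residues keep their source codon verbatim.
    """
    rows: dict[str, str] = {}
    for sid, prot_row in protein_aln.rows.items():
        if sid not in cds:
            raise SeqIOError(f"no CDS provided for aligned sequence {sid!r}")
        nt = cds[sid].upper().replace("-", "")
        if len(nt) % 3:
            raise SeqIOError(f"CDS for {sid!r} has length not divisible by 3")
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        residues = [c for c in prot_row if c != GAP]
        if len(codons) != len(residues):
            raise SeqIOError(
                f"{sid!r}: CDS encodes {len(codons)} residues but aligned row "
                f"has {len(residues)}"
            )
        for pos, (codon, res) in enumerate(zip(codons, residues), 1):
            if codon in STOP_CODONS:
                raise SeqIOError(f"{sid!r}: internal stop codon at residue {pos}")
            aa = _CODON_TABLE.get(codon, "X")
            if res != "X" and aa != res:
                raise SeqIOError(
                    f"{sid!r}: CDS/protein mismatch at residue {pos}: "
                    f"codon {codon} -> {aa}, alignment has {res}"
                )
        it = iter(codons)
        rows[sid] = "".join(GAP_CODON if c == GAP else next(it) for c in prot_row)
    return CodonAlignment(rows)


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree (path or literal string) with branch lengths."""
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise SeqIOError(f"invalid Newick: {exc}") from exc
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise SeqIOError("Newick tree contains an unlabeled leaf")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialize a tree to Newick (branch lengths to 6 decimals)."""
    buf = io.StringIO()
    tree.write(
        file=buf,
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
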