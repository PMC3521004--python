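"""File formats the annotation pipeline touches.

Internal coordinates are 0-based half-open everywhere; GFF3 files use the
standard 1-based inclusive convention and are converted on read/write.
Sequences are stored upper-case over the 20 amino-acid letters plus ``X``;
anything else (including gap characters in plain FASTA) is mapped to ``X``
with a logged warning, because metagenome-derived protein predictions are
routinely dirty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
GAP_CHARS = "-."


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ProteinRecord:
    """A protein sequence with an accession-like identifier.

    ``genus``/``phylum`` are optional taxon labels used by the tree and
    census stages; they are carried through FASTA descriptions of the form
    ``genus=<G> phylum=<P>`` when present.
    """

    id: str
    sequence: str
    description: str = ""
    genus: str | None = None
    phylum: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        self.sequence = _sanitize_sequence(self.sequence, self.id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """A stranded gene interval on a contig (0-based half-open)."""

    contig: str
    start: int
    end: int
    strand: str
    locus_id: str
    label: str | None = None  # csgA..csgH, csgA/B, or None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.locus_id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"feature {self.locus_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length gapped rows with ids."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.records:
            n = len(self.records[0][1])
            for rid, row in self.records:
                if len(row) != n:
                    raise FormatError(
                        f"ragged alignment: row {rid!r} has length {len(row)}, expected {n}"
                    )

    @property
    def length(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def ungapped(self, index: int) -> str:
        rid, row = self.records[index]
        return "".join(c for c in row if c not in GAP_CHARS)

    def column(self, j: int) -> str:
        return "".join(row[j] for _, row in self.records)


def _sanitize_sequence(seq: str, rid: str) -> str:
    seq = seq.upper()
    bad = sorted({c for c in seq if c not in AA_INDEX and c != "X"})
    if bad:
        logger.warning(
            "sequence %s: letters %s outside the amino-acid alphabet mapped to X",
            rid,
            "".join(bad),
        )
        seq = "".join(c if c in AA_INDEX or c == "X" else "X" for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Duplicate ids and empty sequences are errors; sequence letters are
    upper-cased and non-alphabet letters become ``X``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        genus, phylum = _parse_taxon_tags(desc)
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq),
                description=desc,
                genus=genus,
                phylum=phylum,
            )
        )
    return records


def _parse_taxon_tags(description: str) -> tuple[str | None, str | None]:
    genus = phylum = None
    for token in description.split():
        if token.startswith("genus="):
            genus = token[len("genus="):]
        elif token.startswith("phylum="):
            phylum = token[len("phylum="):]
    return genus, phylum


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            tags = []
            if rec.description:
                tags.append(rec.description)
            if rec.genus and f"genus={rec.genus}" not in rec.description:
                tags.append(f"genus={rec.genus}")
            if rec.phylum and f"phylum={rec.phylum}" not in rec.description:
                tags.append(f"phylum={rec.phylum}")
            header = " ".join([rec.id] + tags)
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


_GFF_TYPES = {"gene", "CDS"}


def read_gff(path: str | Path, feature_types: set[str] | None = None) -> list[GeneFeature]:
    """Read gene/CDS rows of a GFF3 file (1-based inclusive -> 0-based half-open).

    ``locus_id`` comes from the ``ID`` or ``locus_tag`` attribute; a csg gene
    name is taken from a ``label`` or ``gene`` attribute when it looks like
    one (csgA..csgH or csgA/B).
    """
    feature_types = feature_types or _GFF_TYPES
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns, got {len(cols)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
            if ftype not in feature_types:
                continue
            start1, end1 = int(start_s), int(end_s)
            if start1 > end1:
                raise FormatError(f"{path}:{lineno}: start {start1} > end {end1}")
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}:{lineno}: unstranded or unknown strand symbol {strand!r}"
                )
            attr = _parse_gff_attributes(attrs)
            locus = attr.get("ID") or attr.get("locus_tag")
            if not locus:
                raise FormatError(f"{path}:{lineno}: feature lacks ID/locus_tag attribute")
            label = attr.get("label") or attr.get("gene")
            if label is not None and not _is_csg_label(label):
                label = None
            features.append(
                GeneFeature(
                    contig=contig,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    locus_id=locus,
                    label=label,
                )
            )
    return features


def _parse_gff_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _is_csg_label(label: str) -> bool:
    return label == "csgA/B" or (
        len(label) == 4 and label.startswith("csg") and label[3] in "ABCDEFGH"
    )


def write_gff(features: Sequence[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.locus_id}"
            if f.label:
                attrs += f";label={f.label}"
            fh.write(
                "\t".join(
                    [f.contig, "curliscan", "gene", str(f.start + 1), str(f.end),
                     ".", f.strand, ".", attrs]
                )
                + "\n"
            )


def read_feature_table(path: str | Path) -> list[GeneFeature]:
    """Read the minimal TSV alternative to GFF3.

    Columns: contig, start, end, strand, locus_id, label (0-based half-open,
    label may be empty). A header line starting with 'contig' is skipped.
    """
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "contig":
                continue
            if len(cols) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 TSV columns")
            label = cols[5] if len(cols) > 5 and cols[5] else None
            features.append(
                GeneFeature(
                    contig=cols[0], start=int(cols[1]), end=int(cols[2]),
                    strand=cols[3], locus_id=cols[4], label=label,
                )
            )
    return features


def read_msa(path: str | Path, dialect: str = "fasta") -> Msa:
    """Read an alignment in aligned-FASTA or Stockholm dialect.

    ``#=GC``/``#=GR`` annotation lines in Stockholm files are ignored; rows
    must be of equal length, otherwise the offending id is reported.
    """
    if dialect not in ("fasta", "stockholm"):
        raise ValueError(f"unknown MSA dialect {dialect!r}")
    if dialect == "fasta":
        rows: list[tuple[str, str]] = []
        seen: set[str] = set()
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate MSA id {rec.id!r} in {path}")
            seen.add(rec.id)
            rows.append((rec.id, str(rec.seq).upper()))
        if not rows:
            raise FormatError(f"no alignment rows in {path}")
        n = len(rows[0][1])
        for rid, row in rows:
            if len(row) != n:
                raise FormatError(
                    f"{path}: ragged alignment, row {rid!r} has length {len(row)}, expected {n}"
                )
        return Msa(rows)
    aln = AlignIO.read(str(path), "stockholm")
    return Msa([(rec.id, str(rec.seq).upper()) for rec in aln])


def write_msa(msa: Msa, path: str | Path, dialect: str = "fasta") -> None:
    if dialect == "fasta":
        with open(path, "w") as fh:
            for rid, row in msa.records:
                fh.write(f">{rid}\n{row}\n")
    elif dialect == "stockholm":
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            for rid, row in msa.records:
                fh.write(f"{rid} {row}\n")
            fh.write("//\n")
    else:
        raise ValueError(f"unknown MSA dialect {dialect!r}")


# ---------------------------------------------------------------------------
# plain-text profile-HMM dialect
#
# A small key/value + per-state-table format:
#   CURLISCAN-HMM 1
#   name <str> / n_match <int> / score_cutoff <float|none>
#   background: 20 floats; match <j>: 20 floats; insert: 20 floats
#   transitions <j>: 7 floats (MM MI MD IM II DM DD), j = 0..n_match
# Floats are printed with repr precision so the round-trip is exact.
# ---------------------------------------------------------------------------

def write_hmm(hmm, path: str | Path) -> None:
    """Serialize a :class:`curliscan.phmm.ProfileHMM` to the plain-text dialect."""
    with open(path, "w") as fh:
        fh.write("CURLISCAN-HMM 1\n")
        fh.write(f"name {hmm.name}\n")
        fh.write(f"n_match {hmm.n_match}\n")
        cut = "none" if hmm.score_cutoff is None else _fmt(hmm.score_cutoff)
        fh.write(f"score_cutoff {cut}\n")
        fh.write("background " + " ".join(_fmt(x) for x in hmm.background) + "\n")
        for j in range(hmm.n_match):
            fh.write(f"match {j} " + " ".join(_fmt(x) for x in hmm.match_emissions[j]) + "\n")
        fh.write("insert " + " ".join(_fmt(x) for x in hmm.insert_emissions) + "\n")
        for j in range(hmm.n_match + 1):
            fh.write(
                f"transitions {j} " + " ".join(_fmt(x) for x in hmm.transitions[j]) + "\n"
            )
        fh.write("end\n")


def _fmt(x: float) -> str:
    return repr(float(x))


def read_hmm(path: str | Path):
    """Parse the plain-text HMM dialect; errors carry the offending line number."""
    from .phmm import ProfileHMM  # deferred to avoid an import cycle

    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("CURLISCAN-HMM"):
        raise FormatError(f"{path}:1: not a curliscan HMM file")
    kv: dict[str, str] = {}
    match_rows: dict[int, np.ndarray] = {}
    trans_rows: dict[int, np.ndarray] = {}
    insert_row = background = None
    saw_end = False
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split()
        try:
            key = parts[0]
            if key == "end":
                saw_end = True
                break
            elif key in ("name", "n_match", "score_cutoff"):
                kv[key] = parts[1]
            elif key == "background":
                background = np.array([float(x) for x in parts[1:]])
            elif key == "insert":
                insert_row = np.array([float(x) for x in parts[1:]])
            elif key == "match":
                match_rows[int(parts[1])] = np.array([float(x) for x in parts[2:]])
            elif key == "transitions":
                trans_rows[int(parts[1])] = np.array([float(x) for x in parts[2:]])
            else:
                raise FormatError(f"{path}:{lineno}: unknown record {key!r}")
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed HMM record: {exc}") from exc
    if not saw_end:
        raise FormatError(f"{path}: truncated HMM file (missing 'end')")
    try:
        n_match = int(kv["n_match"])
        name = kv["name"]
        cutoff = None if kv["score_cutoff"] == "none" else float(kv["score_cutoff"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing header field {exc}") from exc
    if background is None or insert_row is None:
        raise FormatError(f"{path}: missing background/insert emission rows")
    if sorted(match_rows) != list(range(n_match)):
        raise FormatError(f"{path}: expected match rows 0..{n_match - 1}")
    if sorted(trans_rows) != list(range(n_match + 1)):
        raise FormatError(f"{path}: expected transition rows 0..{n_match}")
    me = np.vstack([match_rows[j] for j in range(n_match)])
    tr = np.vstack([trans_rows[j] for j in range(n_match + 1)])
    return ProfileHMM(
        name=name,
        match_emissions=me,
        insert_emissions=insert_row,
        transitions=tr,
        background=background,
        score_cutoff=cutoff,
    )


def write_newick(tree, path: str | Path) -> None:
    """Write a :class:`curliscan.trees.Tree` as a Newick file."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
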