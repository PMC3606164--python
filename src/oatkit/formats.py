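"""Domain types and file formats.

Everything the toolkit reads or writes lives here: variety-tagged FASTA
reads, consed-dialect ACE assemblies, genotype/intensity/linkage-map CSV
tables, BLAST outfmt-6 match tables and the candidate-SNP TSV.  All
user-facing coordinates are 1-based inclusive (ACE convention); padded
positions count ``*`` columns, unpadded positions do not.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOTYPE_ALPHABET = frozenset("ABHU")
_MISSING_SYNONYMS = {"-", "NA", "", "N/A", "nan"}

BLAST_OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Read:
    """A sequence read tagged with its source variety (the MID-tag role)."""

    id: str
    variety: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Placement:
    """One read placed on a padded consensus.

    ``start`` is the 1-based padded offset of the first base; the padded
    sequence is stored in aligned orientation (reverse-complemented reads
    are stored as they align, with ``reverse`` set).
    """

    read_id: str
    start: int
    padded_sequence: str
    reverse: bool = False
    variety: str | None = None

    @property
    def end(self) -> int:
        """1-based padded offset of the last base (inclusive)."""
        return self.start + len(self.padded_sequence) - 1


@dataclass
class Assembly:
    """A consensus template plus placed reads (one ACE contig)."""

    contig_id: str
    padded_consensus: str
    placements: list[Placement] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.padded_consensus)
        for p in self.placements:
            if p.start < 1 or p.end > n:
                raise FormatError(
                    f"contig {self.contig_id}: placement {p.read_id} "
                    f"[{p.start},{p.end}] outside consensus bounds [1,{n}]"
                )

    @property
    def unpadded_map(self) -> list[int | None]:
        """Per padded column (0-based index): 1-based unpadded position.

        ``*`` columns map to None.  The mapping is monotone over non-pad
        columns by construction.
        """
        out: list[int | None] = []
        u = 0
        for ch in self.padded_consensus:
            if ch == "*":
                out.append(None)
            else:
                u += 1
                out.append(u)
        return out

    @property
    def unpadded_consensus(self) -> str:
        return self.padded_consensus.replace("*", "")

    def depth(self, unpadded_pos: int) -> int:
        """Number of placed reads spanning the given 1-based unpadded column."""
        padded = self._padded_of(unpadded_pos)
        return sum(1 for p in self.placements if p.start <= padded <= p.end)

    def _padded_of(self, unpadded_pos: int) -> int:
        u = 0
        for i, ch in enumerate(self.padded_consensus):
            if ch != "*":
                u += 1
                if u == unpadded_pos:
                    return i + 1
        raise IndexError(f"unpadded position {unpadded_pos} out of range")


@dataclass
class GenotypeMatrix:
    """Samples x loci calls in the parent-referenced {A, B, H, U} alphabet.

    A = maternal-background allele, B = paternal allele, H = heterozygous,
    U = missing.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.calls.to_numpy().ravel()) - GENOTYPE_ALPHABET
        if bad:
            raise FormatError(f"genotype calls outside alphabet ABHU: {sorted(bad)}")
        if self.calls.index.has_duplicates or self.calls.columns.has_duplicates:
            raise FormatError("duplicate sample or locus labels")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class LinkageMap:
    """Markers with linkage-group labels and cM positions."""

    entries: pd.DataFrame  # columns: marker, group, position_cm

    def __post_init__(self) -> None:
        df = self.entries
        required = {"marker", "group", "position_cm"}
        if not required.issubset(df.columns):
            raise FormatError(f"linkage map needs columns {sorted(required)}")
        if df["marker"].duplicated().any():
            dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
            raise FormatError(f"duplicate marker {dup!r} in linkage map")
        if (df["position_cm"] < 0).any():
            raise FormatError("negative cM position in linkage map")

    @property
    def groups(self) -> list[str]:
        return sorted(self.entries["group"].astype(str).unique())

    def markers_of(self, group: str) -> pd.DataFrame:
        sub = self.entries[self.entries["group"].astype(str) == str(group)]
        return sub.sort_values(["position_cm", "marker"], kind="stable")

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.entries["marker"], self.entries["group"].astype(str)))


@dataclass
class SyntenyMatch:
    """One query-SNP-to-model-genome hit, coordinates normalized start<=end."""

    query_id: str
    genome: str
    chromosome: str
    subject_start: int
    subject_end: int
    bit_score: float
    evalue: float
    reverse: bool = False

    def __post_init__(self) -> None:
        if self.subject_start > self.subject_end:
            raise ValueError("subject coordinates not normalized")
        if self.evalue < 0:
            raise ValueError("negative E-value")

    @property
    def midpoint(self) -> float:
        return (self.subject_start + self.subject_end) / 2


# ---------------------------------------------------------------------------
# FASTA


def _variety_from_manifest(read_id: str, path: Path, manifest) -> str | None:
    if manifest is None:
        return None
    if read_id in manifest:
        return manifest[read_id]
    hits = [p for p in manifest if read_id.startswith(p)]
    if hits:
        return manifest[max(hits, key=len)]
    return manifest.get(path.name)


def read_fasta(path, variety_manifest=None) -> list[Read]:
    """Read variety-tagged reads from FASTA, in file order.

    Variety identity comes from the manifest (id, id-prefix, or file-name
    keys) or from a ``variety=`` token on the header; a record resolvable
    by neither is an error, never a silent default.
    """
    path = Path(path)
    reads: list[Read] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        variety = _variety_from_manifest(rec.id, path, variety_manifest)
        if variety is None:
            for token in rec.description.split():
                if token.startswith("variety="):
                    variety = token[len("variety="):]
                    break
        if variety is None:
            raise FormatError(
                f"{path.name}: no variety label for read {rec.id!r} "
                "(provide a manifest or a variety= header token)"
            )
        if rec.id in seen:
            raise FormatError(f"{path.name}: duplicate read id {rec.id!r}")
        seen.add(rec.id)
        reads.append(Read(rec.id, variety, str(rec.seq).upper()))
    return reads


def write_fasta(reads, path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"variety={r.variety}")
        for r in reads
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# ACE (consed dialect)


def _wrap(seq: str, width: int = 50) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_ace(assemblies, path) -> None:
    """Write assemblies in consed ACE dialect (AS/CO/AF/RD + DS variety tag)."""
    assemblies = list(assemblies)
    n_reads = sum(len(a.placements) for a in assemblies)
    with open(path, "w") as fh:
        fh.write(f"AS {len(assemblies)} {n_reads}\n\n")
        for a in assemblies:
            fh.write(
                f"CO {a.contig_id} {len(a.padded_consensus)} "
                f"{len(a.placements)} 0 U\n"
            )
            fh.write(_wrap(a.padded_consensus) + "\n\n")
            for p in a.placements:
                strand = "C" if p.reverse else "U"
                fh.write(f"AF {p.read_id} {strand} {p.start}\n")
            fh.write("\n")
            for p in a.placements:
                fh.write(f"RD {p.read_id} {len(p.padded_sequence)} 0 0\n")
                fh.write(_wrap(p.padded_sequence) + "\n")
                n = len(p.padded_sequence)
                fh.write(f"QA 1 {n} 1 {n}\n")
                variety = "" if p.variety is None else f" VARIETY: {p.variety}"
                fh.write(f"DS CHROMAT_FILE: {p.read_id}{variety}\n\n")


def read_ace(path) -> list[Assembly]:
    """Parse a consed-dialect ACE file.

    AS/CO/AF/RD are required; BQ, QA and DS blocks are tolerated (DS
    ``VARIETY:`` tokens are honoured).  AS counts must agree with the
    parsed structure and placements must lie within consensus bounds.
    """
    lines = Path(path).read_text().splitlines()
    i = 0

    def _next_tag():
        nonlocal i
        while i < len(lines) and not lines[i].strip():
            i += 1
        return lines[i].split() if i < len(lines) else None

    header = _next_tag()
    if not header or header[0] != "AS" or len(header) < 3:
        raise FormatError(f"{path}: missing AS header")
    i += 1
    declared_contigs, declared_reads = int(header[1]), int(header[2])

    _tags = ("AS ", "CO ", "AF ", "RD ", "BQ", "QA ", "DS", "CT{", "WA{", "RT{")

    def _read_sequence() -> str:
        nonlocal i
        chunks = []
        while i < len(lines):
            line = lines[i].strip()
            if not line or any(line.startswith(t) for t in _tags):
                break
            chunks.append(line)
            i += 1
        return "".join(chunks)

    assemblies: list[Assembly] = []
    current_af: dict[str, tuple[bool, int]] = {}
    placements: list[Placement] = []
    contig: tuple[str, str] | None = None
    read_order: list[str] = []
    varieties: dict[str, str] = {}
    last_rd: str | None = None

    def _flush():
        nonlocal placements, current_af, contig, read_order
        if contig is None:
            return
        cid, consensus = contig
        ordered = sorted(placements, key=lambda p: read_order.index(p.read_id))
        for p in ordered:
            if p.read_id in varieties:
                p.variety = varieties[p.read_id]
        assemblies.append(Assembly(cid, consensus, ordered))
        placements, current_af, read_order = [], {}, []

    while i < len(lines):
        fields = lines[i].split()
        if not fields:
            i += 1
            continue
        tag = fields[0]
        if tag == "CO":
            _flush()
            i += 1
            contig = (fields[1], _read_sequence().upper())
        elif tag == "AF":
            current_af[fields[1]] = (fields[2] == "C", int(fields[3]))
            i += 1
        elif tag == "RD":
            rid = fields[1]
            i += 1
            seq = _read_sequence().upper()
            if rid not in current_af:
                raise FormatError(f"{path}: RD {rid} without AF line")
            rev, start = current_af[rid]
            placements.append(Placement(rid, start, seq, reverse=rev))
            read_order.append(rid)
            last_rd = rid
        elif tag == "DS":
            if last_rd is not None and "VARIETY:" in fields:
                varieties[last_rd] = fields[fields.index("VARIETY:") + 1]
            i += 1
        elif tag == "BQ":
            i += 1
            _read_sequence()
        else:  # QA and anything else: tolerated
            i += 1
    _flush()

    n_reads = sum(len(a.placements) for a in assemblies)
    if len(assemblies) != declared_contigs or n_reads != declared_reads:
        raise FormatError(
            f"{path}: AS declares {declared_contigs} contigs/{declared_reads} "
            f"reads but file contains {len(assemblies)}/{n_reads}"
        )
    return assemblies


# ---------------------------------------------------------------------------
# candidate-SNP table

SNP_TABLE_COLUMNS = [
    "template", "position", "ref", "alt", "depth", "n_var_ref", "n_var_alt",
    "n_var_impure", "maf_pred", "flank_left", "flank_right", "design_score",
    "status", "context",
]


def write_snp_table(candidates, path=None) -> str:
    """Render candidate SNPs as TSV (context in left[ref/alt]right form)."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(SNP_TABLE_COLUMNS)
    for c in candidates:
        writer.writerow([
            c.template_id, c.position, c.ref, c.alt, c.depth, c.n_var_ref,
            c.n_var_alt, c.n_var_impure, f"{c.maf_pred:.6g}", c.flank_left,
            c.flank_right,
            "" if c.design_score is None else f"{c.design_score:.6g}",
            ",".join(c.status), c.context,
        ])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_snp_table(path):
    """Read a candidate-SNP TSV back into CandidateSnp records."""
    from .snp_discovery import CandidateSnp  # local import to avoid a cycle

    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(CandidateSnp(
                    template_id=row["template"],
                    position=int(row["position"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    depth=int(row["depth"]),
                    variety_alleles={},
                    n_var_ref=int(row["n_var_ref"]),
                    n_var_alt=int(row["n_var_alt"]),
                    n_var_impure=int(row["n_var_impure"]),
                    maf_pred=float(row["maf_pred"]),
                    flank_left=int(row["flank_left"]),
                    flank_right=int(row["flank_right"]),
                    design_score=(float(row["design_score"])
                                  if row["design_score"] else None),
                    flags=frozenset(row["status"].split(",")) - {"PASS"},
                    context=row["context"],
                ))
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# CSV tables


def read_genotype_csv(path) -> GenotypeMatrix:
    """Samples-by-loci CSV; '-', 'NA' and blank map to U."""
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    df = df.apply(lambda col: col.str.strip())
    df = df.replace(sorted(_MISSING_SYNONYMS), "U")
    bad = set(df.to_numpy().ravel()) - GENOTYPE_ALPHABET
    if bad:
        raise FormatError(f"{path}: genotype symbols outside ABHU: {sorted(bad)}")
    df.index = df.index.astype(str)
    return GenotypeMatrix(df)


def write_genotype_csv(genotypes: GenotypeMatrix, path) -> None:
    genotypes.calls.to_csv(path, index_label="sample")


def read_intensity_csv(path) -> pd.DataFrame:
    """Samples-by-representations numeric intensity matrix."""
    df = pd.read_csv(path, index_col=0)
    try:
        return df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric intensity value: {exc}") from exc


def write_intensity_csv(intensities: pd.DataFrame, path) -> None:
    intensities.to_csv(path, index_label="sample")


def read_map_csv(path) -> LinkageMap:
    df = pd.read_csv(path, dtype={"marker": str, "group": str})
    if "position_cm" in df.columns:
        try:
            df["position_cm"] = df["position_cm"].astype(float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cM position: {exc}") from exc
    return LinkageMap(df[["marker", "group", "position_cm"]])


def write_map_csv(lmap: LinkageMap, path) -> None:
    lmap.entries.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# BLAST outfmt-6


def read_blast_tab(path, genome: str) -> list[SyntenyMatch]:
    """Parse 12-column BLAST outfmt-6; subject coordinates are normalized
    to start<=end with an orientation flag."""
    out: list[SyntenyMatch] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(BLAST_OUTFMT6_COLUMNS):
                raise FormatError(
                    f"{path}: row {lineno}: expected "
                    f"{len(BLAST_OUTFMT6_COLUMNS)} columns, got {len(fields)}"
                )
            try:
                sstart, send = int(fields[8]), int(fields[9])
                evalue, bitscore = float(fields[10]), float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}: row {lineno}: {exc}") from exc
            reverse = sstart > send
            if reverse:
                sstart, send = send, sstart
            out.append(SyntenyMatch(
                query_id=fields[0], genome=genome, chromosome=fields[1],
                subject_start=sstart, subject_end=send,
                bit_score=bitscore, evalue=evalue, reverse=reverse,
            ))
    return out
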