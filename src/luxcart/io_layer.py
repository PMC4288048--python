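"""Readers, writers and the internal record types shared by the pipeline.

All coordinates are kept in GFF3's 1-based inclusive convention end to end;
nothing downstream converts to half-open intervals. Strands are ``"+"``
(forward) and ``"-"`` (reverse).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
from Bio import SearchIO, SeqIO

__all__ = [
    "GeneRecord",
    "ProteinRecord",
    "DomainHit",
    "LuxcartInputError",
    "read_gff",
    "read_fasta",
    "read_domain_hits",
    "write_report",
    "read_verdict_table",
]

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: accession grammars accepted for domain signatures
_PF_RE = re.compile(r"^PF\d{5}$")
_IPR_RE = re.compile(r"^IPR\d{6}$")


class LuxcartInputError(ValueError):
    """Raised for malformed or inconsistent user-supplied input files."""


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One annotated protein-coding gene on a contig (1-based inclusive)."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    gene_id: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.start < self.end):
            raise LuxcartInputError(
                f"gene {self.gene_id}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise LuxcartInputError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """Amino-acid sequence keyed by its gene identifier."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise LuxcartInputError(f"protein {self.gene_id}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise LuxcartInputError(
                f"protein {self.gene_id}: invalid residue(s) {sorted(bad)}"
            )


@dataclass(frozen=True)
class DomainHit:
    """One domain-signature hit on a protein.

    ``evalue`` is the per-domain independent e-value for HMMER hits and absent
    (None) for InterPro membership rows, which carry no e-value.
    """

    gene_id: str
    signature_id: str
    evalue: Optional[float] = None
    ali_start: Optional[int] = None
    ali_end: Optional[int] = None

    def __post_init__(self) -> None:
        if not (_PF_RE.match(self.signature_id) or _IPR_RE.match(self.signature_id)):
            raise LuxcartInputError(
                f"signature {self.signature_id!r} matches neither the Pfam "
                "(PFxxxxx) nor the InterPro (IPRxxxxxx) accession grammar"
            )
        if self.evalue is not None and self.evalue < 0:
            raise LuxcartInputError(
                f"hit {self.gene_id}/{self.signature_id}: negative e-value"
            )


def _strip_version(accession: str) -> str:
    return accession.split(".", 1)[0]


def read_gff(path: str | Path, genome_id: str = "genome") -> list[GeneRecord]:
    """Read CDS features from a GFF3 file into GeneRecords.

    Coordinates stay 1-based inclusive. Records are returned sorted by
    (contig, start). A CDS without a usable strand, a malformed line, or a
    duplicate identifier is a hard error.
    """
    path = Path(path)
    _validate_gff_lines(path)
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", merge_strategy="error", keep_order=True
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    except ValueError as exc:
        raise LuxcartInputError(f"{path.name}: {exc}") from exc
    records = []
    seen: set[str] = set()
    for feat in db.features_of_type("CDS"):
        if feat.strand not in ("+", "-"):
            raise LuxcartInputError(
                f"{path.name}: CDS {feat.id} has no usable strand ({feat.strand!r})"
            )
        gene_id = feat.id
        if gene_id in seen:
            raise LuxcartInputError(f"{path.name}: duplicate gene_id {gene_id}")
        seen.add(gene_id)
        product = feat.attributes.get("product", [""])[0]
        records.append(
            GeneRecord(
                genome_id=genome_id,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                gene_id=gene_id,
                product=product,
            )
        )
    records.sort(key=lambda g: (g.contig_id, g.start, g.gene_id))
    return records


def _validate_gff_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise LuxcartInputError(
                    f"{path.name} line {lineno}: expected 9 tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError:
                raise LuxcartInputError(
                    f"{path.name} line {lineno}: non-integer coordinates"
                ) from None


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA; sequences are upper-cased and a trailing '*' stripped."""
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise LuxcartInputError(f"{path.name}: duplicate FASTA id {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        records.append(ProteinRecord(gene_id=rec.id, sequence=seq))
    return records


def read_domain_hits(
    path: str | Path, dialect: Optional[str] = None
) -> list[DomainHit]:
    """Read a domain-hit table in hmmscan domtblout or InterProScan 5 TSV form.

    With ``dialect=None`` the format is sniffed: a tab-separated body is taken
    as InterProScan TSV, otherwise as domtblout. Rows whose accession matches
    neither the Pfam nor the InterPro grammar (other member databases, GO
    terms and the like) are skipped.
    """
    path = Path(path)
    if dialect is None:
        dialect = _sniff_dialect(path)
    if dialect == "domtblout":
        return _read_domtblout(path)
    if dialect == "interproscan_tsv":
        return _read_interproscan(path)
    raise LuxcartInputError(f"unknown domain-hit dialect {dialect!r}")


def _sniff_dialect(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            return "interproscan_tsv" if "\t" in line else "domtblout"
    return "domtblout"  # empty file; either reader yields []


def _read_domtblout(path: Path) -> list[DomainHit]:
    # cheap per-line validation first, so errors can name the offending row
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 23:
                raise LuxcartInputError(
                    f"{path.name} line {lineno}: domtblout rows need >=23 "
                    f"columns, found {len(fields)}"
                )
            for col in (6, 11, 12):  # E-value, c-Evalue, i-Evalue
                try:
                    float(fields[col])
                except ValueError:
                    raise LuxcartInputError(
                        f"{path.name} line {lineno}: non-numeric e-value "
                        f"field {fields[col]!r}"
                    ) from None
    hits: list[DomainHit] = []
    with open(path) as fh:
        for qresult in SearchIO.parse(fh, "hmmscan3-domtab"):
            for hit in qresult:
                accession = _strip_version(hit.accession or "")
                if not _PF_RE.match(accession):
                    accession = _strip_version(hit.id)
                if not (_PF_RE.match(accession) or _IPR_RE.match(accession)):
                    continue
                for hsp in hit:
                    hits.append(
                        DomainHit(
                            gene_id=qresult.id,
                            signature_id=accession,
                            evalue=float(hsp.evalue),
                            ali_start=hsp.query_start + 1,
                            ali_end=hsp.query_end,
                        )
                    )
    return hits


def _read_interproscan(path: Path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise LuxcartInputError(
                    f"{path.name} line {lineno}: InterProScan TSV rows need "
                    f">=12 columns, found {len(fields)}"
                )
            gene_id = fields[0]
            member_acc = _strip_version(fields[4])
            score = fields[8].strip()
            evalue: Optional[float] = None
            if score not in ("", "-"):
                try:
                    evalue = float(score)
                except ValueError:
                    raise LuxcartInputError(
                        f"{path.name} line {lineno}: non-numeric score field "
                        f"{score!r}"
                    ) from None
            ali_start = _maybe_int(fields[6])
            ali_end = _maybe_int(fields[7])
            if _PF_RE.match(member_acc):
                hits.append(
                    DomainHit(gene_id, member_acc, evalue, ali_start, ali_end)
                )
            ipr_acc = _strip_version(fields[11])
            if _IPR_RE.match(ipr_acc):
                # InterPro membership row: no e-value by construction
                hits.append(DomainHit(gene_id, ipr_acc, None, ali_start, ali_end))
    return hits


def _maybe_int(text: str) -> Optional[int]:
    try:
        return int(text)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# report writing

VERDICT_COLUMNS = ["gene_id", "verdict", "present", "missing", "truncation_flag"]
ARRANGEMENT_COLUMNS = [
    "genome",
    "contig",
    "category",
    "members",
    "strands",
    "topology",
    "upstream_bp",
    "truncated_neighbor",
]
SUMMARY_COLUMNS = [
    "genome_id",
    "genus",
    "n_canonical",
    "n_double",
    "double_topologies",
    "n_luxI_solo",
    "n_luxR_solo",
    "has_any_luxR",
    "has_any_luxI",
]


def write_report(
    out_dir: str | Path,
    *,
    verdicts: Sequence = (),
    calls: Sequence = (),
    summaries: Sequence = (),
    proteins: Mapping[str, str] | None = None,
) -> dict[str, Path]:
    """Write the four pipeline output files into ``out_dir``.

    Emits the per-gene verdict table, the per-arrangement table with topology
    labels, the per-genome summary table, and a FASTA of authenticated
    LuxR/LuxI candidates for external phylogenetics. Output is byte-stable:
    rows are sorted on explicit keys and floats use fixed formatting.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise LuxcartInputError(f"cannot create output directory: {exc}") from exc

    paths = {
        "verdicts": out_dir / "verdicts.tsv",
        "arrangements": out_dir / "arrangements.tsv",
        "summaries": out_dir / "summaries.tsv",
        "candidates": out_dir / "candidates.faa",
    }

    vrows = sorted(
        (
            v.gene_id,
            v.verdict,
            ",".join(sorted(v.present_signatures)),
            ",".join(sorted(v.missing_signatures)),
            str(v.n_terminal_truncation_suspected),
        )
        for v in verdicts
    )
    _write_tsv(paths["verdicts"], VERDICT_COLUMNS, vrows)

    arows = sorted(
        (
            c.genome_id,
            c.contig_id,
            c.category,
            ",".join(c.members),
            ",".join(c.strands),
            c.topology_label,
            "" if c.upstream_intergenic_bp is None else str(c.upstream_intergenic_bp),
            str(c.adjacent_truncated_luxR),
        )
        for c in calls
    )
    _write_tsv(paths["arrangements"], ARRANGEMENT_COLUMNS, arows)

    srows = sorted(
        (
            s.genome_id,
            s.genus,
            str(s.n_canonical),
            str(s.n_double),
            ";".join(s.double_topologies),
            str(s.n_luxI_solo),
            str(s.n_luxR_solo),
            str(s.has_any_luxR),
            str(s.has_any_luxI),
        )
        for s in summaries
    )
    _write_tsv(paths["summaries"], SUMMARY_COLUMNS, srows)

    proteins = proteins or {}
    candidate_ids = sorted(
        {v.gene_id for v in verdicts if v.verdict.startswith("AUTHENTIC")}
    )
    with open(paths["candidates"], "w") as fh:
        for gid in candidate_ids:
            if gid in proteins:
                fh.write(f">{gid}\n")
                seq = proteins[gid]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
    return paths


def _write_tsv(path: Path, header: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_verdict_table(path: str | Path) -> list[tuple]:
    """Re-read a verdict TSV written by :func:`write_report` (round-trip aid)."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != VERDICT_COLUMNS:
            raise LuxcartInputError(f"{path}: unexpected verdict table header")
        for line in fh:
            gene_id, verdict, present, missing, flag = line.rstrip("\n").split("\t")
            rows.append(
                (
                    gene_id,
                    verdict,
                    frozenset(present.split(",")) - {""},
                    frozenset(missing.split(",")) - {""},
                    flag == "True",
                )
            )
    return rows
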