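"""Conserved-residue profiling against TraR/TraI reference numbering.

Candidate proteins are globally aligned to a packaged reference sequence
(Needleman-Wunsch, BLOSUM62, affine gaps) and the residues falling in the
columns of the reference's invariant sites are read off. LuxR-family sites
follow TraR numbering: W57, Y61, D70 and W85 in the autoinducer-binding
domain and E178, L182, G188 in the helix-turn-helix DNA-binding domain. A
tyrosine-to-tryptophan change at position 61 (Y61W) is the hallmark of the
plant-associated-bacteria (PAB) LuxR solo subfamily and raises a dedicated
flag.

The packaged reference backbones are synthetic stand-ins carrying the
canonical residues at the canonical positions (see the fixture files); any
user-supplied site map with a real reference sequence works identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml
from Bio import Align
from Bio.Align import substitution_matrices

from .io_layer import PROTEIN_ALPHABET, LuxcartInputError, ProteinRecord

__all__ = [
    "ReferenceSiteMap",
    "Site",
    "SiteObservation",
    "SubstitutionReport",
    "make_aligner",
    "align_to_reference",
    "check_conserved_sites",
    "load_sitemap",
]

GAP_OPEN = -10.0   # score of the first gap residue
GAP_EXTEND = -1.0  # score of each further gap residue


@dataclass(frozen=True)
class Site:
    position: int        # 1-based position on the reference
    expected: str        # expected residue at that position
    role: str            # autoinducer_binding | DNA_binding | synthase_active


@dataclass(frozen=True)
class ReferenceSiteMap:
    reference_id: str
    reference_sequence: str
    sites: tuple[Site, ...]

    def __post_init__(self) -> None:
        for site in self.sites:
            if not (1 <= site.position <= len(self.reference_sequence)):
                raise LuxcartInputError(
                    f"{self.reference_id}: site position {site.position} outside "
                    f"reference length {len(self.reference_sequence)}"
                )
            actual = self.reference_sequence[site.position - 1]
            if actual != site.expected:
                raise LuxcartInputError(
                    f"{self.reference_id}: reference has {actual} at position "
                    f"{site.position}, site map expects {site.expected}"
                )


@dataclass(frozen=True)
class SiteObservation:
    position: int
    expected: str
    observed: str        # residue, or "-" when the site falls in a query gap
    role: str

    @property
    def conserved(self) -> bool:
        return self.observed == self.expected

    @property
    def label(self) -> str:
        """Substitution label in standard notation, e.g. ``W57V``."""
        return f"{self.expected}{self.position}{self.observed}"


@dataclass(frozen=True)
class SubstitutionReport:
    gene_id: str
    reference_id: str
    observations: tuple[SiteObservation, ...]

    @property
    def substitutions(self) -> tuple[SiteObservation, ...]:
        return tuple(o for o in self.observations if not o.conserved and o.observed != "-")

    @property
    def pab_like_flag(self) -> bool:
        """True iff the PAB-solo hallmark Y61W is observed."""
        return any(o.label == "Y61W" for o in self.observations)


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _check_alphabet(gene_id: str, seq: str) -> None:
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise LuxcartInputError(f"{gene_id}: invalid residue(s) {sorted(bad)}")


def align_to_reference(
    query: ProteinRecord, reference: ReferenceSiteMap
) -> Align.Alignment:
    """Global alignment of the query against the reference sequence.

    Reference is the alignment target, query the... query. Among co-optimal
    alignments the engine's first enumeration is taken, which is
    deterministic for fixed inputs.
    """
    _check_alphabet(query.gene_id, query.sequence)
    aligner = make_aligner()
    return aligner.align(reference.reference_sequence, query.sequence)[0]


def check_conserved_sites(
    query: ProteinRecord, reference: ReferenceSiteMap
) -> SubstitutionReport:
    """Read the query residues aligned to each reference site."""
    alignment = align_to_reference(query, reference)
    # indices: for each reference (target) column, the aligned query residue
    ref_aln, qry_aln = alignment[0], alignment[1]
    ref_pos = 0
    site_by_pos = {s.position: s for s in reference.sites}
    observed: dict[int, str] = {}
    for ref_char, qry_char in zip(ref_aln, qry_aln):
        if ref_char == "-":
            continue
        ref_pos += 1
        if ref_pos in site_by_pos:
            observed[ref_pos] = qry_char  # "-" when query gapped here
    observations = tuple(
        SiteObservation(s.position, s.expected, observed[s.position], s.role)
        for s in reference.sites
    )
    return SubstitutionReport(query.gene_id, reference.reference_id, observations)


def check_conserved_sites_msa(
    aligned_query: str,
    aligned_reference: str,
    reference: ReferenceSiteMap,
    gene_id: str = "query",
) -> SubstitutionReport:
    """Site report from a user-supplied alignment (two rows of one MSA).

    Column reading replaces the built-in pairwise alignment; the ungapped
    reference row must equal the site map's reference sequence.
    """
    if len(aligned_query) != len(aligned_reference):
        raise LuxcartInputError("aligned rows differ in length")
    if aligned_reference.replace("-", "") != reference.reference_sequence:
        raise LuxcartInputError(
            "ungapped reference row does not match the site map's reference"
        )
    ref_pos = 0
    site_by_pos = {s.position: s for s in reference.sites}
    observed: dict[int, str] = {}
    for ref_char, qry_char in zip(aligned_reference, aligned_query):
        if ref_char == "-":
            continue
        ref_pos += 1
        if ref_pos in site_by_pos:
            observed[ref_pos] = qry_char
    observations = tuple(
        SiteObservation(s.position, s.expected, observed[s.position], s.role)
        for s in reference.sites
    )
    return SubstitutionReport(gene_id, reference.reference_id, observations)


_PACKAGED = {"TraR": "sitemap_traR.synthetic.yaml", "TraI": "sitemap_traI.synthetic.yaml"}


def load_sitemap(source: str | Path = "TraR") -> ReferenceSiteMap:
    """Load a packaged site map ("TraR" or "TraI") or a user YAML file."""
    if str(source) in _PACKAGED:
        text = resources.files("luxcart.data").joinpath(_PACKAGED[str(source)]).read_text()
        raw = yaml.safe_load(text)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    sequence = "".join(str(raw["sequence"]).split())
    sites = tuple(
        Site(int(s["position"]), str(s["expected"]), str(s["role"]))
        for s in (raw.get("sites") or [])
    )
    return ReferenceSiteMap(str(raw["reference_id"]), sequence, sites)
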