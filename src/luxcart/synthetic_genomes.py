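"""Synthetic annotated genomes with planted quorum-sensing arrangements.

The generator emits multi-contig genome bundles — gene coordinates, protein
sequences, domain-hit tables and machine-readable truth labels — containing
planted lux arrangements: canonical luxI/R pairs (convergently oriented),
luxR and luxI solos, convergent double luxR-luxR-luxI loci with an optional
named downstream neighborhood, and N-terminally truncated LuxR-like genes.
Background genes are anonymous ORFs; a configurable fraction become decoys
that carry deliberately incomplete lux-like signature evidence (a one- or
two-signature subset, or a prefilter-domain hit with an e-value above the
authentication threshold) and must never authenticate.

Planted proteins derive from packaged synthetic seed sequences; with
``mutation_rate`` 0 they equal the seeds byte for byte. Identical
(config, seed) inputs produce byte-identical bundles.

What this emulates — and what it does not: gene density, strand geometry and
signature evidence of real annotated draft genomes, but not nucleotide-level
evolution, indels, pseudogenes, or annotation noise beyond the planted
decoys.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .homolog_detection import LUXI_REQUIRED, LUXR_REQUIRED
from .io_layer import DomainHit, GeneRecord, LuxcartInputError, ProteinRecord

__all__ = [
    "PlantedArrangement",
    "SyntheticConfig",
    "TruthRecord",
    "Bundle",
    "generate_bundle",
    "write_bundle",
    "mutate_sequence",
    "score_against_truth",
    "load_seed_proteins",
    "CIRCUIT_CATEGORIES",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

CANONICAL_PAIR = "canonical_pair"
LUXR_SOLO = "luxR_solo"
LUXI_SOLO = "luxI_solo"
DOUBLE = "double_luxR_luxI"
TRUNCATED_LUXR = "truncated_luxR"
CATEGORIES = (CANONICAL_PAIR, LUXR_SOLO, LUXI_SOLO, DOUBLE, TRUNCATED_LUXR)
#: categories that correspond to a circuit call (truncated genes do not)
CIRCUIT_CATEGORIES = (CANONICAL_PAIR, LUXR_SOLO, LUXI_SOLO, DOUBLE)

# intergenic gaps and background gene lengths (bp), uniform draws
GAP_RANGE = (50, 400)
GENE_LENGTH_RANGE = (750, 900)
#: spacer placed before every planted arrangement so that lux genes of
#: different arrangements always exceed the default proximity policy's bp
#: limit and cannot be merged into one call
ARRANGEMENT_SPACER_RANGE = (5500, 9000)
# log10 e-value windows straddling the 1e-5 authentication cut
TRUE_EVALUE_LOG10 = (-50.0, -6.0)
DECOY_EVALUE_LOG10 = (-4.0, 0.0)
#: residues removed from the LuxR seed to make a truncated LuxR-like protein
TRUNCATION_LENGTH = 115

_TOKEN_PRODUCTS = {
    "phyH": "phytanoyl dioxygenase",
    "virB1": "virB1",
    "virB2": "virB2",
    "virB3": "virB3",
    "lcmT": "isoprenylcysteine carboxyl methyltransferase",
    "metB": "cystathionine gamma-synthase",
    "X": "hypothetical protein",
}


@dataclass(frozen=True)
class PlantedArrangement:
    category: str
    topology_label: Optional[str] = None
    contig: Optional[int] = None  # 0-based contig index, or random when None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise LuxcartInputError(f"unknown planted category {self.category!r}")
        if self.topology_label is not None and self.category != DOUBLE:
            raise LuxcartInputError("topology labels only apply to doubles")


@dataclass(frozen=True)
class SyntheticConfig:
    n_contigs: int = 2
    n_background_genes: int = 20
    planted_arrangements: tuple[PlantedArrangement, ...] = ()
    mutation_rate: float = 0.0
    decoy_rate: float = 0.1
    seed: int = 0
    genome_id: str = "synthetic"
    contig_length_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise LuxcartInputError("need at least one contig")
        if not (0 <= self.mutation_rate < 1):
            raise LuxcartInputError("mutation_rate must lie in [0, 1)")
        if not (0 <= self.decoy_rate <= 1):
            raise LuxcartInputError("decoy_rate must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        planted = tuple(
            PlantedArrangement(
                p["category"], p.get("topology_label"), p.get("contig")
            )
            for p in raw.pop("planted_arrangements", [])
        )
        return cls(planted_arrangements=planted, **raw)


@dataclass(frozen=True)
class TruthRecord:
    gene_ids: tuple[str, ...]
    category: str
    topology_label: str
    contig_id: str


@dataclass(frozen=True)
class Bundle:
    genes: tuple[GeneRecord, ...]
    proteins: tuple[ProteinRecord, ...]
    hits: tuple[DomainHit, ...]
    truth: tuple[TruthRecord, ...]


def load_seed_proteins() -> dict[str, str]:
    """Packaged synthetic seed sequences, keyed by seed name."""
    text = resources.files("luxcart.data").joinpath("seed_proteins.synthetic.faa").read_text()
    seeds: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seeds[name] = ""
        elif name:
            seeds[name] += line.strip()
    return seeds


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independently substitute each residue with probability ``rate``.

    A substituted residue is drawn uniformly from the 19 other amino acids;
    length is always preserved.
    """
    if not (0 <= rate < 1):
        raise LuxcartInputError("rate must lie in [0, 1)")
    if rate == 0 or not seq:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    if mask.any():
        idx = np.where(mask)[0]
        for i in idx:
            choices = AMINO_ACIDS[AMINO_ACIDS != arr[i]]
            arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# gene template assembly

_LUXR_PRODUCT = "LuxR family transcriptional regulator"
_LUXI_PRODUCT = "acyl-homoserine lactone synthase"


def _rand_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=n))


def _luxr_hits(gene_id: str, rng: np.random.Generator) -> list[DomainHit]:
    ev = 10.0 ** rng.uniform(*TRUE_EVALUE_LOG10)
    hits = [DomainHit(gene_id, "PF03472", ev, 30, 160)]
    hits += [DomainHit(gene_id, acc, None, 1, 200) for acc in sorted(LUXR_REQUIRED)]
    return hits


def _luxi_hits(gene_id: str, rng: np.random.Generator) -> list[DomainHit]:
    ev = 10.0 ** rng.uniform(*TRUE_EVALUE_LOG10)
    hits = [DomainHit(gene_id, "PF00765", ev, 10, 170)]
    hits += [DomainHit(gene_id, acc, None, 1, 180) for acc in sorted(LUXI_REQUIRED)]
    return hits


def _truncated_hits(gene_id: str) -> list[DomainHit]:
    # C-terminal signatures only: the N-terminal autoinducer-binding
    # signature IPR005143 is lost with the truncation
    kept = sorted(LUXR_REQUIRED - {"IPR005143"})
    return [DomainHit(gene_id, acc, None, 1, 110) for acc in kept]


def _decoy_hits(gene_id: str, rng: np.random.Generator) -> list[DomainHit]:
    if rng.random() < 0.5:
        # signature-starved decoy: one or two LuxR-required signatures
        k = int(rng.integers(1, 3))
        accs = sorted(rng.choice(sorted(LUXR_REQUIRED), size=k, replace=False))
        return [DomainHit(gene_id, acc, None, 1, 100) for acc in accs]
    # sub-threshold decoy: prefilter domain with an e-value above the cut
    domain = "PF03472" if rng.random() < 0.5 else "PF00765"
    ev = 10.0 ** rng.uniform(*DECOY_EVALUE_LOG10)
    return [DomainHit(gene_id, domain, ev, 20, 120)]


@dataclass
class _GeneTemplate:
    role: str            # luxR | luxI | truncated_luxR | background | neighborhood
    strand: str
    product: str
    sequence: str
    hits: tuple = ()


def _arrangement_templates(
    arr: PlantedArrangement,
    seeds: dict[str, str],
    rate: float,
    rng: np.random.Generator,
) -> list[_GeneTemplate]:
    mut = lambda s: mutate_sequence(s, rate, rng)
    if arr.category == CANONICAL_PAIR:
        # convergent pair: luxI(+) immediately followed by luxR(-)
        return [
            _GeneTemplate("luxI", "+", _LUXI_PRODUCT, mut(seeds["luxI_seed_A"])),
            _GeneTemplate("luxR", "-", _LUXR_PRODUCT, mut(seeds["luxR_seed_A"])),
        ]
    if arr.category == LUXR_SOLO:
        return [_GeneTemplate("luxR", "+", _LUXR_PRODUCT, mut(seeds["luxR_seed_A"]))]
    if arr.category == LUXI_SOLO:
        return [_GeneTemplate("luxI", "+", _LUXI_PRODUCT, mut(seeds["luxI_seed_A"]))]
    if arr.category == TRUNCATED_LUXR:
        truncated = seeds["luxR_seed_A"][TRUNCATION_LENGTH:]
        return [
            _GeneTemplate(
                "truncated_luxR", "+", "LuxR-like protein, N-terminally truncated",
                mut(truncated),
            )
        ]
    # double: tandem luxR(+) luxR(+) with convergent luxI(-), optionally
    # followed by the requested downstream neighborhood
    templates = [
        _GeneTemplate("luxR", "+", _LUXR_PRODUCT, mut(seeds["luxR_seed_A"])),
        _GeneTemplate("luxR", "+", _LUXR_PRODUCT, mut(seeds["luxR_seed_B"])),
        _GeneTemplate("luxI", "-", _LUXI_PRODUCT, mut(seeds["luxI_seed_A"])),
    ]
    for token in _topology_tokens(arr.topology_label):
        product = _TOKEN_PRODUCTS.get(token, token)
        templates.append(
            _GeneTemplate("neighborhood", "-", product, _rand_protein(rng, 150))
        )
    return templates


def _topology_tokens(label: Optional[str]) -> tuple[str, ...]:
    if label is None:
        return ()
    from .circuit_classification import load_topology_catalog

    for pattern in load_topology_catalog():
        if pattern.label == label:
            return pattern.downstream
    raise LuxcartInputError(
        f"topology label {label!r} not present in the packaged catalog"
    )


# ---------------------------------------------------------------------------
# bundle generation


def generate_bundle(config: SyntheticConfig) -> Bundle:
    rng = np.random.default_rng(config.seed)
    seeds = load_seed_proteins()

    # contig assignment for planted arrangements and background genes
    contig_items: list[list] = [[] for _ in range(config.n_contigs)]
    for arr in config.planted_arrangements:
        idx = arr.contig if arr.contig is not None else int(rng.integers(config.n_contigs))
        if not (0 <= idx < config.n_contigs):
            raise LuxcartInputError(f"arrangement contig index {idx} out of range")
        contig_items[idx].append(arr)
    for _ in range(config.n_background_genes):
        contig_items[int(rng.integers(config.n_contigs))].append("background")

    # choose decoy background genes up front so their count is exact
    n_decoys = int(round(config.decoy_rate * config.n_background_genes))
    decoy_flags = np.zeros(config.n_background_genes, dtype=bool)
    if n_decoys:
        decoy_flags[rng.choice(config.n_background_genes, size=n_decoys, replace=False)] = True

    genes: list[GeneRecord] = []
    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    truth: list[TruthRecord] = []
    serial = 0
    background_serial = 0

    for c_idx in range(config.n_contigs):
        contig_id = f"ctg{c_idx + 1}"
        items = contig_items[c_idx]
        order = rng.permutation(len(items)) if items else []
        pos = 1
        for item_idx in order:
            item = items[int(item_idx)]
            if item == "background":
                pos += int(rng.integers(GAP_RANGE[0], GAP_RANGE[1] + 1))
            else:
                pos += int(
                    rng.integers(ARRANGEMENT_SPACER_RANGE[0], ARRANGEMENT_SPACER_RANGE[1] + 1)
                )
            if item == "background":
                length = int(rng.integers(GENE_LENGTH_RANGE[0], GENE_LENGTH_RANGE[1] + 1))
                serial += 1
                gene_id = f"g{serial:04d}"
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    GeneRecord(
                        config.genome_id, contig_id, pos, pos + length - 1,
                        strand, gene_id, "hypothetical protein",
                    )
                )
                proteins.append(ProteinRecord(gene_id, _rand_protein(rng, length // 3)))
                if decoy_flags[background_serial]:
                    hits.extend(_decoy_hits(gene_id, rng))
                background_serial += 1
                pos += length
                continue

            templates = _arrangement_templates(item, seeds, config.mutation_rate, rng)
            lux_ids: list[str] = []
            for t_idx, tpl in enumerate(templates):
                if t_idx:
                    pos += int(rng.integers(GAP_RANGE[0], GAP_RANGE[1] + 1))
                length = 3 * len(tpl.sequence) + 3
                serial += 1
                gene_id = f"g{serial:04d}"
                genes.append(
                    GeneRecord(
                        config.genome_id, contig_id, pos, pos + length - 1,
                        tpl.strand, gene_id, tpl.product,
                    )
                )
                proteins.append(ProteinRecord(gene_id, tpl.sequence))
                if tpl.role == "luxR":
                    hits.extend(_luxr_hits(gene_id, rng))
                elif tpl.role == "luxI":
                    hits.extend(_luxi_hits(gene_id, rng))
                elif tpl.role == "truncated_luxR":
                    hits.extend(_truncated_hits(gene_id))
                if tpl.role in ("luxR", "luxI", "truncated_luxR"):
                    lux_ids.append(gene_id)
                pos += length
            truth.append(
                TruthRecord(
                    tuple(lux_ids),
                    item.category,
                    item.topology_label or "",
                    contig_id,
                )
            )
        if config.contig_length_bp is not None and pos - 1 > config.contig_length_bp:
            raise LuxcartInputError(
                f"{contig_id}: planted content needs {pos - 1} bp but the contig "
                f"is capped at {config.contig_length_bp} bp"
            )

    genes.sort(key=lambda g: (g.contig_id, g.start, g.gene_id))
    proteins.sort(key=lambda p: p.gene_id)
    hits.sort(key=lambda h: (h.gene_id, h.signature_id))
    truth.sort(key=lambda t: (t.contig_id, t.gene_ids))
    return Bundle(tuple(genes), tuple(proteins), tuple(hits), tuple(truth))


# ---------------------------------------------------------------------------
# serialization in the exact formats the io layer reads

_DOMAIN_NAMES = {"PF03472": "Autoind_bind", "PF00765": "Autoind_synth"}


def write_bundle(bundle: Bundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as GFF3 + FASTA + domtblout + InterProScan TSV + truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff": out_dir / "genome.gff3",
        "fasta": out_dir / "proteins.faa",
        "domtblout": out_dir / "hits.domtblout",
        "interproscan": out_dir / "hits.interproscan.tsv",
        "truth": out_dir / "truth.tsv",
    }
    lengths = {p.gene_id: len(p.sequence) for p in bundle.proteins}

    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in bundle.genes:
            attrs = f"ID={g.gene_id};product={g.product}" if g.product else f"ID={g.gene_id}"
            fh.write(
                f"{g.contig_id}\tluxcart_synth\tCDS\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\t{attrs}\n"
            )

    with open(paths["fasta"], "w") as fh:
        for p in bundle.proteins:
            fh.write(f">{p.gene_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")

    with open(paths["domtblout"], "w") as fh:
        fh.write("# planted domain hits (hmmscan domtblout dialect)\n")
        for h in bundle.hits:
            if h.evalue is None:
                continue
            name = _DOMAIN_NAMES.get(h.signature_id, "domain")
            qlen = lengths.get(h.gene_id, 200)
            a0 = h.ali_start or 1
            a1 = h.ali_end or qlen
            ev = f"{h.evalue:.3g}"
            fh.write(
                f"{name} {h.signature_id}.18 140 {h.gene_id} - {qlen} "
                f"{ev} 70.0 0.1 1 1 {ev} {ev} 69.0 0.1 2 139 "
                f"{a0} {a1} {a0} {a1} 0.95 planted domain hit\n"
            )

    with open(paths["interproscan"], "w") as fh:
        for h in bundle.hits:
            if h.evalue is not None:
                continue
            qlen = lengths.get(h.gene_id, 200)
            a0 = h.ali_start or 1
            a1 = h.ali_end or qlen
            fh.write(
                f"{h.gene_id}\t-\t{qlen}\tInterProScan\t-\t-\t{a0}\t{a1}\t-\tT\t-\t"
                f"{h.signature_id}\t-\n"
            )

    with open(paths["truth"], "w") as fh:
        fh.write("gene_ids\tcategory\ttopology_label\tcontig_id\n")
        for t in bundle.truth:
            fh.write(
                f"{','.join(t.gene_ids)}\t{t.category}\t{t.topology_label}\t{t.contig_id}\n"
            )
    return paths


def read_truth(path: str | Path) -> list[TruthRecord]:
    records = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            gene_ids, category, topology, contig = line.rstrip("\n").split("\t")
            records.append(
                TruthRecord(tuple(gene_ids.split(",")), category, topology, contig)
            )
    return records


# ---------------------------------------------------------------------------
# truth scoring


def score_against_truth(
    truth: Iterable[TruthRecord], calls: Iterable
) -> dict[str, float]:
    """Exact-match precision/recall of circuit calls against planted truth.

    A call matches a truth record iff the category and the member gene set
    both agree. Truncated-LuxR truth records are not circuit calls and are
    excluded from recall.
    """
    truth_set = {
        (t.category, frozenset(t.gene_ids))
        for t in truth
        if t.category in CIRCUIT_CATEGORIES
    }
    call_set = {(c.category, frozenset(c.members)) for c in calls}
    tp = len(truth_set & call_set)
    precision = tp / len(call_set) if call_set else 1.0
    recall = tp / len(truth_set) if truth_set else 1.0
    return {
        "precision": precision,
        "recall": recall,
        "n_truth": float(len(truth_set)),
        "n_calls": float(len(call_set)),
    }
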