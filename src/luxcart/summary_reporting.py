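"""Per-genome census rows, genus roll-ups and the end-to-end pipeline.

A GenomeSummary is the per-genome census row: counts of canonical luxI/R
pairs, convergent double luxR-luxR-luxI loci (with their topology labels),
luxI solos and luxR solos. GenusRollup aggregates rows per genus against the
total number of sequenced genomes in that genus, reproducing the structure
of a published census table; a packaged fixture transcribing that table is
available via :func:`load_census_fixture`.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .circuit_classification import (
    CANONICAL_PAIR,
    DOUBLE,
    LUXI_SOLO,
    LUXR_SOLO,
    CircuitCall,
    ProximityPolicy,
    annotate_topologies,
    call_arrangements,
)
from .homolog_detection import SignatureRuleSet, classify_proteins
from .io_layer import (
    DomainHit,
    GeneRecord,
    LuxcartInputError,
    ProteinRecord,
    read_domain_hits,
    read_fasta,
    read_gff,
    write_report,
)

__all__ = [
    "GenomeSummary",
    "GenusRollup",
    "summarize_genome",
    "rollup",
    "load_census_fixture",
    "run_genome",
    "run_manifest",
]


@dataclass(frozen=True)
class GenomeSummary:
    genome_id: str
    genus: str
    n_canonical: int
    n_double: int
    double_topologies: tuple[str, ...]
    n_luxI_solo: int
    n_luxR_solo: int

    @property
    def has_any_luxR(self) -> bool:
        return 2 * self.n_double + self.n_canonical + self.n_luxR_solo >= 1

    @property
    def has_any_luxI(self) -> bool:
        return self.n_double + self.n_canonical + self.n_luxI_solo >= 1

    @property
    def has_any_lux(self) -> bool:
        return self.has_any_luxR or self.has_any_luxI


@dataclass(frozen=True)
class GenusRollup:
    genus: str
    n_genomes_with_lux: int
    n_genomes_total: int
    n_genomes_canonical: int
    n_genomes_double: int
    n_genomes_luxI_solo: int
    n_genomes_luxR_solo: int

    def __post_init__(self) -> None:
        for count in (
            self.n_genomes_with_lux,
            self.n_genomes_canonical,
            self.n_genomes_double,
            self.n_genomes_luxI_solo,
            self.n_genomes_luxR_solo,
        ):
            if count > self.n_genomes_total:
                raise LuxcartInputError(
                    f"{self.genus}: category count {count} exceeds genus total "
                    f"{self.n_genomes_total}"
                )


def summarize_genome(
    calls: Iterable[CircuitCall], genome_id: str, genus: str = ""
) -> GenomeSummary:
    """Fold a genome's circuit calls into one census row."""
    calls = list(calls)
    foreign = sorted({c.genome_id for c in calls} - {genome_id})
    if foreign:
        raise LuxcartInputError(
            f"calls from genome(s) {', '.join(foreign)} passed to summary of {genome_id}"
        )
    topo = tuple(
        sorted(c.topology_label for c in calls if c.category == DOUBLE)
    )
    return GenomeSummary(
        genome_id=genome_id,
        genus=genus,
        n_canonical=sum(c.category == CANONICAL_PAIR for c in calls),
        n_double=sum(c.category == DOUBLE for c in calls),
        double_topologies=topo,
        n_luxI_solo=sum(c.category == LUXI_SOLO for c in calls),
        n_luxR_solo=sum(c.category == LUXR_SOLO for c in calls),
    )


def rollup(
    summaries: Iterable[GenomeSummary],
    totals_per_genus: Mapping[str, int],
) -> tuple[list[GenusRollup], dict[str, int]]:
    """Per-genus and global tallies over per-genome census rows.

    ``totals_per_genus`` supplies the number of sequenced genomes per genus
    (rows only exist for genomes with lux genes, so totals cannot be derived
    from the rows). Raises when a genus present in the rows has no total.
    """
    summaries = list(summaries)
    by_genus: dict[str, list[GenomeSummary]] = defaultdict(list)
    for s in summaries:
        by_genus[s.genus].append(s)
    missing = sorted(set(by_genus) - set(totals_per_genus))
    if missing:
        raise LuxcartInputError(f"totals missing for genus: {', '.join(missing)}")

    rollups = []
    for genus in sorted(totals_per_genus):
        rows = by_genus.get(genus, [])
        rollups.append(
            GenusRollup(
                genus=genus,
                n_genomes_with_lux=sum(r.has_any_lux for r in rows),
                n_genomes_total=int(totals_per_genus[genus]),
                n_genomes_canonical=sum(r.n_canonical >= 1 for r in rows),
                n_genomes_double=sum(r.n_double >= 1 for r in rows),
                n_genomes_luxI_solo=sum(r.n_luxI_solo >= 1 for r in rows),
                n_genomes_luxR_solo=sum(r.n_luxR_solo >= 1 for r in rows),
            )
        )
    global_counts = {
        "n_genomes_total": int(sum(totals_per_genus.values())),
        "n_genomes_with_lux": sum(s.has_any_lux for s in summaries),
        "n_genomes_with_luxR": sum(s.has_any_luxR for s in summaries),
        "n_genomes_with_luxI": sum(s.has_any_luxI for s in summaries),
        "n_genomes_canonical": sum(s.n_canonical >= 1 for s in summaries),
        "n_genomes_double": sum(s.n_double >= 1 for s in summaries),
        "n_genomes_luxI_solo": sum(s.n_luxI_solo >= 1 for s in summaries),
        "n_genomes_luxR_solo": sum(s.n_luxR_solo >= 1 for s in summaries),
    }
    return rollups, global_counts


def load_census_fixture() -> tuple[list[GenomeSummary], dict[str, int]]:
    """The packaged 40-row census table and its per-genus genome totals.

    The fixture transcribes a published per-genome census of lux circuit
    arrangements across 62 Sphingomonadaceae genomes; see the packaged
    census_notes.md for provenance caveats.
    """
    table = resources.files("luxcart.data").joinpath("census_table.tsv")
    with resources.as_file(table) as path:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
    summaries = [
        GenomeSummary(
            genome_id=row.organism,
            genus=row.genus,
            n_canonical=int(row.n_canonical),
            n_double=int(row.n_double),
            double_topologies=tuple(
                t for t in str(row.double_topologies).split(";") if t
            ),
            n_luxI_solo=int(row.n_luxI_solo),
            n_luxR_solo=int(row.n_luxR_solo),
        )
        for row in df.itertuples()
    ]
    totals_file = resources.files("luxcart.data").joinpath("census_totals.tsv")
    with resources.as_file(totals_file) as path:
        tdf = pd.read_csv(path, sep="\t")
    totals = dict(zip(tdf.genus, tdf.n_genomes_total.astype(int)))
    return summaries, totals


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_genome(
    genes: Sequence[GeneRecord],
    hits: Sequence[DomainHit],
    genome_id: str,
    genus: str = "",
    rules: SignatureRuleSet | None = None,
    policy: ProximityPolicy | None = None,
    catalog=None,
    synonyms=None,
):
    """Classify, call and summarize one genome; returns (verdicts, calls, summary)."""
    verdicts = classify_proteins(
        hits, rules, all_gene_ids=[g.gene_id for g in genes]
    )
    calls = call_arrangements(genes, verdicts, policy)
    calls = annotate_topologies(calls, genes, catalog, synonyms)
    summary = summarize_genome(calls, genome_id, genus)
    return verdicts, calls, summary


MANIFEST_COLUMNS = ["genome_id", "genus", "fasta", "gff", "hits", "dialect"]


def run_manifest(
    manifest_path: str | Path,
    out_dir: str | Path,
    rules: SignatureRuleSet | None = None,
    policy: ProximityPolicy | None = None,
    catalog=None,
    synonyms=None,
) -> tuple[list[GenomeSummary], dict[str, Path]]:
    """Run the pipeline over a manifest of genome bundles and write reports.

    Manifest is a TSV with columns genome_id, genus, fasta, gff, hits,
    dialect; the ``hits`` column may list several files separated by commas
    (e.g. a domtblout plus an InterProScan TSV), and ``dialect`` may be empty
    for sniffing. Relative paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    try:
        df = pd.read_csv(manifest_path, sep="\t", keep_default_na=False)
    except Exception as exc:
        raise LuxcartInputError(f"cannot read manifest: {exc}") from exc
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise LuxcartInputError(
            f"manifest lacks column(s): {', '.join(missing_cols)}"
        )

    all_verdicts, all_calls, summaries = [], [], []
    proteins: dict[str, str] = {}
    for row in df.itertuples():
        genes = read_gff(base / row.gff, genome_id=row.genome_id)
        prots = read_fasta(base / row.fasta)
        hits: list[DomainHit] = []
        for hit_file in str(row.hits).split(","):
            hit_file = hit_file.strip()
            if hit_file:
                hits.extend(
                    read_domain_hits(base / hit_file, dialect=row.dialect or None)
                )
        verdicts, calls, summary = run_genome(
            genes, hits, row.genome_id, row.genus, rules, policy, catalog, synonyms
        )
        for vlist in verdicts.values():
            all_verdicts.extend(vlist)
        all_calls.extend(calls)
        summaries.append(summary)
        proteins.update({p.gene_id: p.sequence for p in prots})

    paths = write_report(
        out_dir,
        verdicts=all_verdicts,
        calls=all_calls,
        summaries=summaries,
        proteins=proteins,
    )
    return summaries, paths
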