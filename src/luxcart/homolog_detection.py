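"""Two-tier authentication of LuxR and LuxI homologs from domain signatures.

Tier one is a Pfam-domain prefilter: a protein is shortlisted when it carries
the autoinducer-binding domain PF03472 (LuxR side) or the autoinducer-synthase
domain PF00765 (LuxI side) with a per-domain e-value strictly below 1e-5.
Tier two is a signature-completeness test on InterPro accessions: an authentic
LuxR homolog must carry all four of IPR005143 (autoinducer binding), IPR016032
(response-regulator C-terminal effector), IPR011991 (winged helix-turn-helix)
and IPR000792 (LuxR-type C-terminal); an authentic LuxI homolog must carry
both IPR001690 (autoinducer synthesis protein) and IPR018311 (autoinducer
synthesis conserved site).

A protein carrying a non-empty proper subset of the LuxR set is reported as
LUXR_LIKE_INCOMPLETE; when the missing part includes the N-terminal
autoinducer-binding signature IPR005143 while the C-terminal IPR000792 is
present, the protein is flagged as a suspected N-terminally truncated LuxR.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

from .io_layer import DomainHit

__all__ = [
    "SignatureRuleSet",
    "HomologVerdict",
    "prefilter",
    "classify_protein",
    "classify_proteins",
    "group_hits_by_gene",
]

LUXR_PREFILTER = frozenset({"PF03472"})
LUXI_PREFILTER = frozenset({"PF00765"})
LUXR_REQUIRED = frozenset({"IPR005143", "IPR016032", "IPR011991", "IPR000792"})
LUXI_REQUIRED = frozenset({"IPR001690", "IPR018311"})

AUTHENTIC_LUXR = "AUTHENTIC_LUXR"
AUTHENTIC_LUXI = "AUTHENTIC_LUXI"
LUXR_LIKE_INCOMPLETE = "LUXR_LIKE_INCOMPLETE"
NONE = "NONE"

#: verdict strength used by the monotonicity property: adding evidence may
#: only move a protein rightward.
VERDICT_RANK = {NONE: 0, LUXR_LIKE_INCOMPLETE: 1, AUTHENTIC_LUXR: 2, AUTHENTIC_LUXI: 2}


@dataclass(frozen=True)
class SignatureRuleSet:
    luxR_prefilter: frozenset[str] = LUXR_PREFILTER
    luxI_prefilter: frozenset[str] = LUXI_PREFILTER
    evalue_max: float = 1e-5
    luxR_required: frozenset[str] = LUXR_REQUIRED
    luxI_required: frozenset[str] = LUXI_REQUIRED

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if not self.luxR_required or not self.luxI_required:
            raise ValueError("required signature sets must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SignatureRuleSet":
        """Load an override rule set; absent keys keep their defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("luxR_prefilter", "luxI_prefilter", "luxR_required", "luxI_required"):
            if key in raw:
                kwargs[key] = frozenset(raw[key])
        if "evalue_max" in raw:
            kwargs["evalue_max"] = float(raw["evalue_max"])
        return cls(**kwargs)


@dataclass(frozen=True)
class HomologVerdict:
    gene_id: str
    verdict: str
    present_signatures: frozenset[str] = frozenset()
    missing_signatures: frozenset[str] = frozenset()
    n_terminal_truncation_suspected: bool = False
    dual_authentic: bool = False


def group_hits_by_gene(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    grouped: dict[str, list[DomainHit]] = defaultdict(list)
    for hit in hits:
        grouped[hit.gene_id].append(hit)
    return dict(grouped)


def prefilter(hits: Iterable[DomainHit], rules: SignatureRuleSet | None = None) -> set[str]:
    """Genes with >=1 prefilter-domain hit below the e-value ceiling.

    Hits without an e-value (InterProScan membership rows) pass the filter:
    with InterProScan-only input the HMM prefilter has no evidence to act on
    and the completeness test alone decides.
    """
    rules = rules or SignatureRuleSet()
    wanted = rules.luxR_prefilter | rules.luxI_prefilter
    kept: set[str] = set()
    for hit in hits:
        if hit.signature_id not in wanted:
            continue
        if hit.evalue is None or hit.evalue < rules.evalue_max:
            kept.add(hit.gene_id)
    return kept


def classify_protein(
    gene_id: str,
    hits: Iterable[DomainHit],
    rules: SignatureRuleSet | None = None,
) -> list[HomologVerdict]:
    """Signature-completeness verdict(s) for one protein.

    The rule is set-membership: a signature hit repeated on several protein
    regions counts once. A protein that satisfies both the LuxR and the LuxI
    completeness rules (never observed in real data) is reported with both
    verdicts, each flagged ``dual_authentic``.
    """
    rules = rules or SignatureRuleSet()
    present = frozenset(h.signature_id for h in hits if h.gene_id == gene_id)
    luxR_missing = rules.luxR_required - present
    luxI_missing = rules.luxI_required - present

    verdicts: list[HomologVerdict] = []
    if not luxR_missing:
        verdicts.append(
            HomologVerdict(gene_id, AUTHENTIC_LUXR, present, frozenset())
        )
    if not luxI_missing:
        verdicts.append(
            HomologVerdict(gene_id, AUTHENTIC_LUXI, present, frozenset())
        )
    if len(verdicts) == 2:
        return [
            HomologVerdict(v.gene_id, v.verdict, v.present_signatures,
                           v.missing_signatures, dual_authentic=True)
            for v in verdicts
        ]
    if verdicts:
        return verdicts

    luxR_present = rules.luxR_required & present
    if luxR_present:  # non-empty proper subset of the LuxR requirement
        truncated = "IPR005143" in luxR_missing and "IPR000792" in present
        return [
            HomologVerdict(
                gene_id,
                LUXR_LIKE_INCOMPLETE,
                present,
                luxR_missing,
                n_terminal_truncation_suspected=truncated,
            )
        ]
    return [
        HomologVerdict(
            gene_id, NONE, present, (rules.luxR_required | rules.luxI_required) - present
        )
    ]


def classify_proteins(
    hits: Iterable[DomainHit],
    rules: SignatureRuleSet | None = None,
    all_gene_ids: Iterable[str] | None = None,
    apply_prefilter: bool = True,
) -> dict[str, list[HomologVerdict]]:
    """Classify every protein with hits (and, optionally, every listed gene).

    With ``apply_prefilter`` (the default, matching the two-tier protocol) a
    gene carrying e-valued evidence for a prefilter domain can only reach an
    AUTHENTIC verdict if at least one such hit clears the e-value ceiling.
    Two-dialect behavior: a gene with no e-valued prefilter-domain hit at all
    (InterProScan-only input) goes straight to the completeness test. The
    incomplete/truncated tier is read from InterProScan evidence alone and is
    never blocked by the prefilter.
    """
    rules = rules or SignatureRuleSet()
    hits = list(hits)
    grouped = group_hits_by_gene(hits)
    shortlisted = prefilter(hits, rules) if apply_prefilter else None

    gene_ids = set(grouped)
    if all_gene_ids is not None:
        gene_ids |= set(all_gene_ids)

    prefilter_domains = rules.luxR_prefilter | rules.luxI_prefilter
    out: dict[str, list[HomologVerdict]] = {}
    for gene_id in sorted(gene_ids):
        gene_hits = grouped.get(gene_id, [])
        verdicts = classify_protein(gene_id, gene_hits, rules)
        has_hmm_evidence = any(
            h.signature_id in prefilter_domains and h.evalue is not None
            for h in gene_hits
        )
        if (
            shortlisted is not None
            and gene_id not in shortlisted
            and has_hmm_evidence
        ):
            verdicts = [
                v
                if not v.verdict.startswith("AUTHENTIC")
                else HomologVerdict(
                    v.gene_id, NONE, v.present_signatures, frozenset()
                )
                for v in verdicts
            ]
            # collapse a dual verdict demoted on both sides
            uniq = {(v.gene_id, v.verdict): v for v in verdicts}
            verdicts = sorted(uniq.values(), key=lambda v: v.verdict)
        out[gene_id] = verdicts
    return out
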