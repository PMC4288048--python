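"""Arrangement calling: canonical luxI/R pairs, solos and convergent doubles.

Authenticated lux genes on a contig are grouped into circuit arrangements by
genomic proximity. Doubles (two tandem luxR genes plus a proximal luxI) take
precedence over canonical pairs, otherwise the middle luxR of a
luxR-luxR-luxI trio would be stolen as a pair partner. Within that
precedence the assignment maximizes the number of doubles, then the number of
canonical pairs, then minimizes the summed intergenic distance, with ties
broken toward smaller start coordinates. Leftover authenticated genes become
luxR or luxI solos.

"Close proximity" is quantified as at most ``max_intervening_genes`` genes
and at most ``max_gap_bp`` base pairs between partners, always on the same
contig. Tandem means the two luxR genes share a strand; the strand relation
between the luxR pair and the luxI (convergent/divergent/tandem) is reported
rather than enforced.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy.optimize import linear_sum_assignment

from .homolog_detection import (
    AUTHENTIC_LUXI,
    AUTHENTIC_LUXR,
    LUXR_LIKE_INCOMPLETE,
    HomologVerdict,
)
from .io_layer import GeneRecord, LuxcartInputError

__all__ = [
    "ProximityPolicy",
    "CircuitCall",
    "TopologyPattern",
    "call_arrangements",
    "type_topology",
    "load_topology_catalog",
    "load_synonym_map",
    "annotate_topologies",
]

CANONICAL_PAIR = "canonical_pair"
LUXR_SOLO = "luxR_solo"
LUXI_SOLO = "luxI_solo"
DOUBLE = "double_luxR_luxI"

#: above this many candidate tandem-luxR pairs on one contig the exact
#: lexicographic search falls back to a left-to-right greedy sweep
_EXACT_SEARCH_LIMIT = 16
_BIG = 10.0**15


@dataclass(frozen=True)
class ProximityPolicy:
    max_intervening_genes: int = 3
    max_gap_bp: int = 5000
    same_contig_required: bool = True

    def __post_init__(self) -> None:
        if self.max_intervening_genes < 0 or self.max_gap_bp < 0:
            raise ValueError("proximity limits must be non-negative")
        if not self.same_contig_required:
            raise ValueError("cross-contig pairing is not supported")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProximityPolicy":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**{k: raw[k] for k in ("max_intervening_genes", "max_gap_bp") if k in raw})


@dataclass(frozen=True)
class CircuitCall:
    genome_id: str
    contig_id: str
    category: str
    members: tuple[str, ...]          # gene ids in genomic order
    roles: tuple[str, ...]            # "luxR" / "luxI", parallel to members
    strands: tuple[str, ...]
    relations: tuple[str, ...]        # strand relation between consecutive members
    topology_label: str = "N/A"
    upstream_intergenic_bp: Optional[int] = None
    adjacent_truncated_luxR: bool = False


@dataclass(frozen=True)
class TopologyPattern:
    """Ordered downstream product tokens; "X" matches one hypothetical gene."""

    label: str
    downstream: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.downstream:
            raise ValueError(f"topology {self.label}: empty pattern")


# ---------------------------------------------------------------------------
# verdict normalization


def _primary_verdicts(
    verdicts: Mapping[str, object],
) -> dict[str, str]:
    """Normalize the verdict mapping to gene_id -> verdict string.

    Accepts plain strings, HomologVerdict objects, or lists of verdicts (the
    classify_proteins output). A dual-authentic gene is treated as a LuxR for
    arrangement purposes; the homolog layer keeps the flag.
    """
    out: dict[str, str] = {}
    for gene_id, value in verdicts.items():
        if isinstance(value, str):
            out[gene_id] = value
        elif isinstance(value, HomologVerdict):
            out[gene_id] = value.verdict
        else:
            names = [v.verdict for v in value]  # type: ignore[union-attr]
            if AUTHENTIC_LUXR in names:
                out[gene_id] = AUTHENTIC_LUXR
            elif AUTHENTIC_LUXI in names:
                out[gene_id] = AUTHENTIC_LUXI
            elif names:
                out[gene_id] = names[0]
            else:
                out[gene_id] = "NONE"
    return out


# ---------------------------------------------------------------------------
# geometry helpers


def _gap_bp(a: GeneRecord, b: GeneRecord) -> int:
    first, second = (a, b) if a.start <= b.start else (b, a)
    return max(0, second.start - first.end - 1)


def _relation(a: GeneRecord, b: GeneRecord) -> str:
    """Strand relation of two genes in genomic order (a before b)."""
    if a.strand == b.strand:
        return "tandem"
    return "convergent" if a.strand == "+" else "divergent"


class _Contig:
    def __init__(self, genes: Sequence[GeneRecord]):
        self.genes = sorted(genes, key=lambda g: (g.start, g.gene_id))
        self.index = {g.gene_id: i for i, g in enumerate(self.genes)}

    def intervening(self, a: GeneRecord, b: GeneRecord) -> int:
        return abs(self.index[a.gene_id] - self.index[b.gene_id]) - 1

    def within(self, a: GeneRecord, b: GeneRecord, policy: ProximityPolicy) -> bool:
        return (
            self.intervening(a, b) <= policy.max_intervening_genes
            and _gap_bp(a, b) <= policy.max_gap_bp
        )

    def distance(self, a: GeneRecord, b: GeneRecord) -> int:
        return _gap_bp(a, b)


# ---------------------------------------------------------------------------
# assignment search


def _match_pairs(
    rs: list[GeneRecord],
    is_: list[GeneRecord],
    contig: _Contig,
    policy: ProximityPolicy,
) -> list[tuple[GeneRecord, GeneRecord]]:
    """Maximum-cardinality luxR-luxI matching, nearest-first among optima.

    Cost of a feasible pairing is its bp distance; infeasible pairings get a
    prohibitive cost, so the assignment maximizes the number of realized
    pairs before minimizing distance. A tiny start-coordinate term breaks
    exact distance ties toward smaller start coordinates.
    """
    if not rs or not is_:
        return []
    cost = np.full((len(rs), len(is_)), _BIG)
    for i, r in enumerate(rs):
        for j, lx in enumerate(is_):
            if contig.within(r, lx, policy):
                cost[i, j] = contig.distance(r, lx) + r.start * 1e-9
    rows, cols = linear_sum_assignment(cost)
    return [
        (rs[i], is_[j]) for i, j in zip(rows, cols) if cost[i, j] < _BIG / 2
    ]


def _candidate_tandem_pairs(
    rs: list[GeneRecord], contig: _Contig, policy: ProximityPolicy
) -> list[tuple[GeneRecord, GeneRecord]]:
    pairs = []
    for a, b in itertools.combinations(rs, 2):
        if a.start > b.start:
            a, b = b, a
        if a.strand == b.strand and contig.within(a, b, policy):
            pairs.append((a, b))
    pairs.sort(key=lambda p: (p[0].start, p[1].start))
    return pairs


def _pair_luxI_feasible(
    pair: tuple[GeneRecord, GeneRecord],
    lux_i: GeneRecord,
    contig: _Contig,
    policy: ProximityPolicy,
) -> bool:
    return contig.within(pair[0], lux_i, policy) or contig.within(pair[1], lux_i, policy)


def _iter_double_assignments(
    chosen: list[tuple[GeneRecord, GeneRecord]],
    is_: list[GeneRecord],
    contig: _Contig,
    policy: ProximityPolicy,
):
    """All injective assignments of a proximal luxI to every chosen pair.

    The search must consider every feasible luxI choice, not just the
    nearest one: which luxI the double consumes can decide whether a
    canonical pair remains formable from the leftovers.
    """
    feasible = [
        [x for x in is_ if _pair_luxI_feasible(pair, x, contig, policy)]
        for pair in chosen
    ]

    def rec(i: int, used: set[str], acc: list[GeneRecord]):
        if i == len(chosen):
            yield [
                (a, b, x) for (a, b), x in zip(chosen, acc)
            ]
            return
        for x in feasible[i]:
            if x.gene_id in used:
                continue
            yield from rec(i + 1, used | {x.gene_id}, acc + [x])

    yield from rec(0, set(), [])


def _solve_contig(
    rs: list[GeneRecord],
    is_: list[GeneRecord],
    contig: _Contig,
    policy: ProximityPolicy,
) -> tuple[
    list[tuple[GeneRecord, GeneRecord, GeneRecord]],
    list[tuple[GeneRecord, GeneRecord]],
]:
    """Lexicographically maximal (doubles, pairs) assignment for one contig."""
    candidates = _candidate_tandem_pairs(rs, contig, policy)
    if len(candidates) > _EXACT_SEARCH_LIMIT:
        return _solve_contig_greedy(rs, is_, contig, policy, candidates)

    best: Optional[tuple] = None
    # enumerate vertex-disjoint subsets of candidate tandem pairs, largest
    # first so the doubles-precedence rule is explicit
    for size in range(min(len(candidates), len(is_)), -1, -1):
        if best is not None and best[0] > size:
            break
        for subset in itertools.combinations(candidates, size):
            used: set[str] = set()
            ok = True
            for a, b in subset:
                if a.gene_id in used or b.gene_id in used:
                    ok = False
                    break
                used.update((a.gene_id, b.gene_id))
            if not ok:
                continue
            for doubles in _iter_double_assignments(list(subset), is_, contig, policy):
                consumed = {g.gene_id for trio in doubles for g in trio}
                rest_r = [r for r in rs if r.gene_id not in consumed]
                rest_i = [x for x in is_ if x.gene_id not in consumed]
                pairs = _match_pairs(rest_r, rest_i, contig, policy)
                span = sum(
                    min(contig.distance(a, c), contig.distance(b, c))
                    for a, b, c in doubles
                ) + sum(contig.distance(r, x) for r, x in pairs)
                key = (len(doubles), len(pairs), -span)
                if best is None or key > best[:3]:
                    best = (*key, doubles, pairs)
        if best is not None and best[0] == size:
            break
    assert best is not None
    return best[3], best[4]


def _solve_contig_greedy(rs, is_, contig, policy, candidates):
    """Left-to-right greedy fallback for pathologically lux-dense contigs."""
    used: set[str] = set()
    doubles = []
    for a, b in candidates:
        if a.gene_id in used or b.gene_id in used:
            continue
        feas = [
            x
            for x in is_
            if x.gene_id not in used and _pair_luxI_feasible((a, b), x, contig, policy)
        ]
        if not feas:
            continue
        lx = min(
            feas,
            key=lambda x: (min(contig.distance(a, x), contig.distance(b, x)), x.start),
        )
        doubles.append((a, b, lx))
        used.update((a.gene_id, b.gene_id, lx.gene_id))
    rest_r = [r for r in rs if r.gene_id not in used]
    rest_i = [x for x in is_ if x.gene_id not in used]
    pairs = _match_pairs(rest_r, rest_i, contig, policy)
    return doubles, pairs


# ---------------------------------------------------------------------------
# public entry point


def call_arrangements(
    genes: Iterable[GeneRecord],
    verdicts: Mapping[str, object],
    policy: ProximityPolicy | None = None,
) -> list[CircuitCall]:
    """Group authenticated lux genes into circuit arrangement calls.

    Deterministic and independent of input order. Raises if a verdict refers
    to a gene absent from ``genes``. The lux-gene conservation law —
    #luxR = 2*doubles + pairs + luxR solos and #luxI = doubles + pairs +
    luxI solos — is checked on every invocation.
    """
    policy = policy or ProximityPolicy()
    genes = list(genes)
    by_id = {g.gene_id: g for g in genes}
    vmap = _primary_verdicts(verdicts)
    missing = sorted(set(vmap) - set(by_id))
    if missing:
        raise LuxcartInputError(
            f"verdicts refer to unknown gene(s): {', '.join(missing)}"
        )

    calls: list[CircuitCall] = []
    contig_ids = sorted({g.contig_id for g in genes})
    n_r = n_i = 0
    for contig_id in contig_ids:
        contig = _Contig([g for g in genes if g.contig_id == contig_id])
        rs = [g for g in contig.genes if vmap.get(g.gene_id) == AUTHENTIC_LUXR]
        is_ = [g for g in contig.genes if vmap.get(g.gene_id) == AUTHENTIC_LUXI]
        n_r += len(rs)
        n_i += len(is_)
        doubles, pairs = _solve_contig(rs, is_, contig, policy)
        consumed: set[str] = set()
        for trio in doubles:
            consumed.update(g.gene_id for g in trio)
            calls.append(_build_call(trio, ("luxR", "luxR", "luxI"), contig, vmap))
        for duo in pairs:
            consumed.update(g.gene_id for g in duo)
            calls.append(_build_call(duo, ("luxR", "luxI"), contig, vmap))
        for r in rs:
            if r.gene_id not in consumed:
                calls.append(_build_call((r,), ("luxR",), contig, vmap))
        for x in is_:
            if x.gene_id not in consumed:
                calls.append(_build_call((x,), ("luxI",), contig, vmap))

    _check_conservation(calls, n_r, n_i)
    calls.sort(key=lambda c: (c.contig_id, by_id[c.members[0]].start))
    return calls


def _build_call(
    members_in: tuple[GeneRecord, ...],
    roles_in: tuple[str, ...],
    contig: _Contig,
    vmap: Mapping[str, str],
) -> CircuitCall:
    order = np.argsort([g.start for g in members_in], kind="stable")
    members = tuple(members_in[i] for i in order)
    roles = tuple(roles_in[i] for i in order)
    strands = tuple(g.strand for g in members)
    relations = tuple(
        _relation(members[i], members[i + 1]) for i in range(len(members) - 1)
    )
    if len(members) == 3:
        category = DOUBLE
    elif len(members) == 2:
        category = CANONICAL_PAIR
    else:
        category = LUXR_SOLO if roles[0] == "luxR" else LUXI_SOLO

    truncated = False
    for g in members:
        i = contig.index[g.gene_id]
        for j in (i - 1, i + 1):
            if 0 <= j < len(contig.genes):
                if vmap.get(contig.genes[j].gene_id) == LUXR_LIKE_INCOMPLETE:
                    truncated = True

    upstream_bp: Optional[int] = None
    if category == LUXI_SOLO:
        g = members[0]
        i = contig.index[g.gene_id]
        if g.strand == "+" and i > 0:
            upstream_bp = max(0, g.start - contig.genes[i - 1].end - 1)
        elif g.strand == "-" and i + 1 < len(contig.genes):
            upstream_bp = max(0, contig.genes[i + 1].start - g.end - 1)

    return CircuitCall(
        genome_id=members[0].genome_id,
        contig_id=members[0].contig_id,
        category=category,
        members=tuple(g.gene_id for g in members),
        roles=roles,
        strands=strands,
        relations=relations,
        topology_label="N/A",
        upstream_intergenic_bp=upstream_bp,
        adjacent_truncated_luxR=truncated,
    )


def _check_conservation(calls: Sequence[CircuitCall], n_r: int, n_i: int) -> None:
    n_double = sum(c.category == DOUBLE for c in calls)
    n_pair = sum(c.category == CANONICAL_PAIR for c in calls)
    n_rs = sum(c.category == LUXR_SOLO for c in calls)
    n_is = sum(c.category == LUXI_SOLO for c in calls)
    if n_r != 2 * n_double + n_pair + n_rs or n_i != n_double + n_pair + n_is:
        raise AssertionError(
            "lux-gene conservation law violated: "
            f"R={n_r}, I={n_i}, doubles={n_double}, pairs={n_pair}, "
            f"solos=({n_rs},{n_is})"
        )


# ---------------------------------------------------------------------------
# topology typing


def load_topology_catalog(path: str | Path | None = None) -> list[TopologyPattern]:
    if path is None:
        source = resources.files("luxcart.data").joinpath("topologies.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    patterns = [
        TopologyPattern(str(p["label"]), tuple(p["downstream"]))
        for p in (raw or {}).get("patterns", [])
    ]
    labels = [p.label for p in patterns]
    if len(labels) != len(set(labels)):
        raise LuxcartInputError("topology catalog has duplicate labels")
    return patterns


def load_synonym_map(path: str | Path | None = None) -> dict[str, set[str]]:
    if path is None:
        source = resources.files("luxcart.data").joinpath("synonyms.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    out: dict[str, set[str]] = {}
    for token, syns in (raw or {}).items():
        out[str(token)] = {_norm(token)} | {_norm(s) for s in (syns or [])}
    return out


def _norm(label: str) -> str:
    return " ".join(str(label).strip().lower().split())


def _token_matches(token: str, product: str, synonyms: Mapping[str, set[str]]) -> bool:
    norm = _norm(product)
    if token == "X":
        if "hypothetical" in norm:
            return True
    return norm in synonyms.get(token, {_norm(token)})


def type_topology(
    call: CircuitCall,
    genes: Iterable[GeneRecord],
    catalog: Sequence[TopologyPattern] | None = None,
    synonyms: Mapping[str, set[str]] | None = None,
    max_downstream: int = 8,
) -> str:
    """Label the downstream neighborhood of a double luxR-luxR-luxI call.

    Reads the product labels of up to ``max_downstream`` genes downstream of
    the luxI member (away from the luxR pair) and matches them against the
    catalog, longest pattern first. Non-double calls return "N/A"; no match
    returns "UNTYPED".
    """
    if call.category != DOUBLE:
        return "N/A"
    catalog = load_topology_catalog() if catalog is None else list(catalog)
    synonyms = load_synonym_map() if synonyms is None else synonyms

    contig_genes = sorted(
        (g for g in genes if g.contig_id == call.contig_id),
        key=lambda g: (g.start, g.gene_id),
    )
    by_id = {g.gene_id: g for g in contig_genes}
    lux_i = by_id[call.members[call.roles.index("luxI")]]
    lux_r_starts = [by_id[m].start for m, r in zip(call.members, call.roles) if r == "luxR"]
    away_right = lux_i.start >= max(lux_r_starts)
    if away_right:
        downstream = [g for g in contig_genes if g.start > lux_i.start]
    else:
        downstream = [g for g in contig_genes if g.start < lux_i.start][::-1]
    downstream = [g for g in downstream if g.gene_id not in call.members][:max_downstream]
    labels = [g.product for g in downstream]

    for pattern in sorted(catalog, key=lambda p: -len(p.downstream)):
        if len(labels) < len(pattern.downstream):
            continue
        if all(
            _token_matches(tok, lab, synonyms)
            for tok, lab in zip(pattern.downstream, labels)
        ):
            return pattern.label
    return "UNTYPED"


def annotate_topologies(
    calls: Sequence[CircuitCall],
    genes: Iterable[GeneRecord],
    catalog: Sequence[TopologyPattern] | None = None,
    synonyms: Mapping[str, set[str]] | None = None,
) -> list[CircuitCall]:
    """Return calls with topology labels filled in (doubles only)."""
    genes = list(genes)
    catalog = load_topology_catalog() if catalog is None else list(catalog)
    synonyms = load_synonym_map() if synonyms is None else synonyms
    out = []
    for call in calls:
        label = type_topology(call, genes, catalog, synonyms)
        if call.category == DOUBLE and label == "N/A":
            label = "UNTYPED"
        out.append(replace(call, topology_label=label))
    return out
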