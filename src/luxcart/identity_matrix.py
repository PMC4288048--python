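"""SDT-style pairwise percent-identity matrices over protein sets.

Each pair is globally aligned with the same engine and parameters as the
residue-numbering module; identity is the percentage of identical aligned
residue pairs. Two gap-handling modes are exposed because published
matrix tools differ: the default divides by the number of columns where both
sequences have a residue; the gap-inclusive mode divides by the full
alignment length, so it can only be lower.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_layer import LuxcartInputError, ProteinRecord
from .residue_analysis import make_aligner

__all__ = ["IdentityMatrix", "pairwise_identity", "identity_matrix", "group_summary"]

MODES = ("ungapped_columns", "full_length")


def pairwise_identity(
    a: ProteinRecord, b: ProteinRecord, mode: str = "ungapped_columns"
) -> float:
    """Percent identity of the global alignment of two proteins, in [0, 100]."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if not a.sequence or not b.sequence:
        raise LuxcartInputError("cannot align an empty sequence")
    if a.sequence == b.sequence:
        return 100.0
    # canonical argument order: among co-optimal alignments the engine's
    # choice depends on which sequence is target, so order by sequence to
    # make the measure symmetric by construction
    if b.sequence < a.sequence:
        a, b = b, a
    aligner = make_aligner()
    alignment = aligner.align(a.sequence, b.sequence)[0]
    row_a, row_b = alignment[0], alignment[1]
    identical = sum(x == y and x != "-" for x, y in zip(row_a, row_b))
    if mode == "ungapped_columns":
        denom = sum(x != "-" and y != "-" for x, y in zip(row_a, row_b))
    else:
        denom = len(row_a)
    return 100.0 * identical / denom if denom else 0.0


def identity_matrix(
    proteins: Sequence[ProteinRecord], mode: str = "ungapped_columns"
) -> "IdentityMatrix":
    labels = [p.gene_id for p in proteins]
    if len(set(labels)) != len(labels):
        raise LuxcartInputError("duplicate gene ids in identity matrix input")
    n = len(proteins)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(proteins[i], proteins[j], mode=mode)
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(tuple(labels), values)


@dataclass(frozen=True)
class IdentityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # square, symmetric, diagonal 100

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise LuxcartInputError("identity matrix shape does not match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 100.0):
            raise LuxcartInputError("identity matrix must be symmetric with 100 diagonal")
        if v.min() < 0 or v.max() > 100:
            raise LuxcartInputError("identities must lie in [0, 100]")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.2f")

    def to_long_csv(self, path) -> None:
        frame = self.to_frame().stack().rename("identity").rename_axis(["a", "b"])
        frame.reset_index().to_csv(path, index=False, float_format="%.2f")


def group_summary(
    matrix: IdentityMatrix,
    partner_groups: Mapping[str, tuple[str, str]],
) -> dict[str, Optional[float]]:
    """Within-locus vs cross-locus identity statistics for double-LuxR sets.

    ``partner_groups`` maps each gene id to ``(locus_id, slot)`` with slot
    "A" or "B": the two partner LuxRs of one double locus share a locus_id
    and occupy different slots. "Within" compares the A and B partners of one
    locus; "between" compares the same slot across different loci.
    """
    unknown = sorted(set(partner_groups) - set(matrix.labels))
    if unknown:
        raise LuxcartInputError(f"group refers to unknown label(s): {', '.join(unknown)}")

    loci: dict[str, dict[str, str]] = {}
    for gene_id, (locus, slot) in partner_groups.items():
        if slot not in ("A", "B"):
            raise LuxcartInputError(f"{gene_id}: slot must be 'A' or 'B', got {slot!r}")
        loci.setdefault(locus, {})[slot] = gene_id

    within = [
        matrix.value(slots["A"], slots["B"])
        for slots in loci.values()
        if "A" in slots and "B" in slots
    ]
    between = []
    for slot in ("A", "B"):
        members = sorted(
            slots[slot] for slots in loci.values() if slot in slots
        )
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                between.append(matrix.value(members[i], members[j]))

    return {
        "within_locus_min": min(within) if within else None,
        "within_locus_max": max(within) if within else None,
        "within_locus_mean": float(np.mean(within)) if within else None,
        "between_locus_max": max(between) if between else None,
        "n_loci": float(len(loci)),
    }
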