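"""Polymorphic-block analysis of variant alignments: block detection, block
alleles, four-gamete recombination testing, cross-group sharing, and
uncorrected P distances (exportable as PHYLIP/NEXUS for network tools)."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import AlignmentError

GAP = "-"


@dataclass
class VariantAlignment:
    """Equal-length sequences with variant names and optional group labels."""

    names: list[str]
    sequences: list[str]
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise AlignmentError("names and sequences differ in count")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("variant names are not unique")
        if len({len(s) for s in self.sequences}) > 1:
            raise AlignmentError("ragged alignment: sequences differ in length")
        if self.groups is not None and len(self.groups) != len(self.names):
            raise AlignmentError("groups and names differ in count")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def column(self, j: int) -> list[str]:
        return [s[j] for s in self.sequences]


@dataclass
class BlockSet:
    """Disjoint column-interval blocks covering all polymorphic columns, with
    one allele label per variant per block."""

    blocks: list[tuple[int, int]]                  # 0-based inclusive column intervals
    allele_labels: list[list[str]]                 # [variant][block]
    allele_sequences: list[dict[str, str]] = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def polymorphic_columns(
    alignment: VariantAlignment, gap_as_state: bool = False
) -> list[int]:
    """0-based indices of columns with at least two distinct residues."""
    if len(alignment.sequences) < 2:
        raise AlignmentError("polymorphic_columns requires >= 2 rows")
    out = []
    for j in range(alignment.n_columns):
        states = set(alignment.column(j))
        if not gap_as_state:
            states.discard(GAP)
        if len(states) >= 2:
            out.append(j)
    return out


def detect_blocks(columns: list[int], max_gap: int = 3) -> list[tuple[int, int]]:
    """Group sorted polymorphic columns into intervals, merging neighbours
    separated by at most ``max_gap`` monomorphic columns."""
    if sorted(columns) != list(columns):
        raise AlignmentError("columns must be sorted ascending")
    if not columns:
        return []
    blocks = []
    start = prev = columns[0]
    for c in columns[1:]:
        if c - prev - 1 <= max_gap:
            prev = c
        else:
            blocks.append((start, prev))
            start = prev = c
    blocks.append((start, prev))
    return blocks


def assign_block_alleles(
    alignment: VariantAlignment,
    blocks: list[tuple[int, int]],
    polymorphic: list[int] | None = None,
) -> BlockSet:
    """Label each variant's residue combination over each block's polymorphic
    columns; distinct combinations get labels A, B, C ... in order of first
    appearance."""
    if polymorphic is None:
        polymorphic = polymorphic_columns(alignment)
    poly = set(polymorphic)
    labels: list[list[str]] = [[] for _ in alignment.sequences]
    allele_seqs: list[dict[str, str]] = []
    for (start, end) in blocks:
        cols = [j for j in range(start, end + 1) if j in poly]
        seen: dict[str, str] = {}
        block_map: dict[str, str] = {}
        for i, seq in enumerate(alignment.sequences):
            key = "".join(seq[j] for j in cols)
            if key not in seen:
                seen[key] = chr(ord("A") + len(seen))
                block_map[seen[key]] = key
            labels[i].append(seen[key])
        allele_seqs.append(block_map)
    return BlockSet(list(blocks), labels, allele_seqs)


def four_gamete(blockset: BlockSet, block_i: int, block_j: int) -> str:
    """Four-gamete test between two blocks: for every binarized allele pair,
    recombination is detected iff all four haplotype combinations occur.
    Returns ``"recombination_detected"`` or ``"compatible"``."""
    col_i = [row[block_i] for row in blockset.allele_labels]
    col_j = [row[block_j] for row in blockset.allele_labels]
    alleles_i = sorted(set(col_i))
    alleles_j = sorted(set(col_j))
    if len(alleles_i) < 2 or len(alleles_j) < 2:
        return "compatible"
    for a1, a2 in combinations(alleles_i, 2):
        for b1, b2 in combinations(alleles_j, 2):
            combos = {
                (ai, bj)
                for ai, bj in zip(col_i, col_j)
                if ai in (a1, a2) and bj in (b1, b2)
            }
            if len(combos) == 4:
                return "recombination_detected"
    return "compatible"


def four_gamete_report(blockset: BlockSet) -> list[tuple[int, int, str]]:
    """Four-gamete outcome for every block pair."""
    return [
        (i, j, four_gamete(blockset, i, j))
        for i, j in combinations(range(blockset.n_blocks), 2)
    ]


@dataclass
class SharingReport:
    block_allele_groups: dict[tuple[int, str], set[str]]
    shared_block_alleles: list[tuple[int, str, set[str]]]
    shared_full_variants: list[tuple[str, str]]

    @property
    def any_full_variant_shared(self) -> bool:
        return bool(self.shared_full_variants)


def cross_group_sharing(
    blockset: BlockSet, alignment: VariantAlignment
) -> SharingReport:
    """Which groups carry each block allele, and whether any complete variant
    sequence is shared between groups."""
    if alignment.groups is None or len(set(alignment.groups)) < 2:
        raise AlignmentError("cross_group_sharing requires >= 2 group labels")
    carriers: dict[tuple[int, str], set[str]] = {}
    for i, row in enumerate(blockset.allele_labels):
        for b, allele in enumerate(row):
            carriers.setdefault((b, allele), set()).add(alignment.groups[i])
    shared = [
        (b, allele, groups)
        for (b, allele), groups in sorted(carriers.items())
        if len(groups) > 1
    ]
    shared_full = []
    for i, j in combinations(range(len(alignment.sequences)), 2):
        if (
            alignment.groups[i] != alignment.groups[j]
            and alignment.sequences[i] == alignment.sequences[j]
        ):
            shared_full.append((alignment.names[i], alignment.names[j]))
    return SharingReport(carriers, shared, shared_full)


def p_distance_matrix(alignment: VariantAlignment) -> np.ndarray:
    """Uncorrected P distances with pairwise deletion of gapped positions."""
    if len(alignment.sequences) < 2:
        raise AlignmentError("p_distance_matrix requires >= 2 rows")
    n = len(alignment.sequences)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        si, sj = alignment.sequences[i], alignment.sequences[j]
        compared = mismatches = 0
        for x, y in zip(si, sj):
            if x == GAP or y == GAP:
                continue
            compared += 1
            if x != y:
                mismatches += 1
        if compared == 0:
            raise AlignmentError(
                f"no comparable sites between {alignment.names[i]!r} and "
                f"{alignment.names[j]!r}"
            )
        mat[i, j] = mat[j, i] = mismatches / compared
    return mat


def to_phylip(alignment: VariantAlignment, matrix: np.ndarray) -> str:
    """Square PHYLIP distance-matrix format."""
    lines = [f"    {len(alignment.names)}"]
    for name, row in zip(alignment.names, matrix):
        safe = name[:10].ljust(10)
        lines.append(safe + "  " + "  ".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"


def to_nexus(alignment: VariantAlignment, matrix: np.ndarray) -> str:
    """NEXUS distances block consumable by split-network tools."""
    n = len(alignment.names)
    lines = [
        "#NEXUS",
        "BEGIN Taxa;",
        f"DIMENSIONS ntax={n};",
        "TAXLABELS",
    ]
    lines += [f"  [{i + 1}] '{name}'" for i, name in enumerate(alignment.names)]
    lines += [
        ";",
        "END;",
        "BEGIN Distances;",
        f"DIMENSIONS ntax={n};",
        "FORMAT labels=left diagonal triangle=both;",
        "MATRIX",
    ]
    for name, row in zip(alignment.names, matrix):
        lines.append(f"  '{name}' " + " ".join(f"{v:.6f}" for v in row))
    lines += [";", "END;"]
    return "\n".join(lines) + "\n"
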