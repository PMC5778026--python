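"""Typing of cloned amplicon sequences into named variants and per-line
repertoires, via the two fixed polymorphic regions of each gene."""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .errors import (
    LengthMismatchError,
    RegionError,
    TableError,
    UnknownLabelError,
)
from .util import hamming, translate_cds

REGION_IDS = ("upstream", "downstream")

_NAME_RX = re.compile(r"^(?P<gene>\w+)_(?P<group>[IV]+)\((?P<up>[^/)]+)/(?P<down>[^/)]+)\)$")


@dataclass(frozen=True, order=True)
class VariantName:
    """A variant identified by its (upstream, downstream) allele labels,
    rendered as ``gene_GROUP(up/down)``, e.g. ``cidA_IV(δ/1)``."""

    gene_id: str
    group: str
    upstream: str
    downstream: str

    def render(self) -> str:
        return f"{self.gene_id}_{self.group}({self.upstream}/{self.downstream})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "VariantName":
        m = _NAME_RX.match(text.strip())
        if not m:
            raise UnknownLabelError(f"unparseable variant name {text!r}")
        return cls(m["gene"], m["group"], m["up"], m["down"])


@dataclass
class Repertoire:
    """Named variants detected in one line, with clone support counts."""

    line_id: str
    variants: dict[str, dict[VariantName, int]] = field(default_factory=dict)
    discarded: dict[str, int] = field(default_factory=dict)
    clones_typed: dict[str, int] = field(default_factory=dict)

    def gene_variants(self, gene_id: str) -> set[VariantName]:
        return set(self.variants.get(gene_id, ()))

    def merge(self, other: "Repertoire") -> "Repertoire":
        merged = Repertoire(
            self.line_id,
            {**self.variants, **other.variants},
            {**self.discarded, **other.discarded},
            {**self.clones_typed, **other.clones_typed},
        )
        return merged


@dataclass(frozen=True)
class SignatureFlags:
    """Presence flags for the two incompatibility-signature variants."""

    has_cidA_delta: bool
    has_cidB_a2: bool

    @property
    def category(self) -> str:
        if self.has_cidA_delta and self.has_cidB_a2:
            return "both"
        if self.has_cidA_delta:
            return "cidA_only"
        if self.has_cidB_a2:
            return "cidB_only"
        return "neither"


def extract_region(sequence, gene_config, region_id: str, level: str = "nt") -> str:
    """Slice one polymorphic region out of a full CDS; ``level='aa'``
    translates it (regions are in CDS frame by construction)."""
    start, end = gene_config.region_coords[region_id]  # 1-based inclusive
    if end > len(sequence):
        raise RegionError(
            f"{gene_config.gene_id}/{region_id}: interval [{start},{end}] outside "
            f"sequence of length {len(sequence)}"
        )
    nt = sequence[start - 1 : end]
    if level == "nt":
        return nt
    if level == "aa":
        return translate_cds(nt)
    raise RegionError(f"unknown level {level!r}")


def assign_allele(
    region_sequence: str,
    registry: dict[str, str],
    open_registry: bool = False,
    new_label_prefix: str = "n",
) -> str:
    """Map a region sequence to its allele label by exact match.

    In open-registry mode an unseen sequence gets the next unused label in a
    fixed series (``n1``, ``n2``, ...) and is registered, so the same novel
    sequence always receives the same label. In closed mode a miss raises,
    reporting the nearest registered allele by Hamming distance."""
    if not registry and not open_registry:
        raise UnknownLabelError("empty registry in closed mode")
    for label, allele in registry.items():
        if allele == region_sequence:
            return label
    if open_registry:
        i = 1
        while f"{new_label_prefix}{i}" in registry:
            i += 1
        label = f"{new_label_prefix}{i}"
        registry[label] = region_sequence
        return label
    best_label, best_dist = None, None
    for label, allele in registry.items():
        if len(allele) != len(region_sequence):
            continue
        d = hamming(allele, region_sequence)
        if best_dist is None or d < best_dist:
            best_label, best_dist = label, d
    if best_label is None:
        raise LengthMismatchError(
            f"query length {len(region_sequence)} matches no registered allele length"
        )
    raise UnknownLabelError(
        f"no exact allele match; nearest is {best_label!r} at Hamming {best_dist}"
    )


def type_variant(sequence, gene_config, registries, open_registry: bool = False) -> VariantName:
    """Name a clone from its two region alleles."""
    labels = {}
    for region_id in REGION_IDS:
        region = extract_region(sequence, gene_config, region_id)
        labels[region_id] = assign_allele(
            region, registries[region_id], open_registry=open_registry
        )
    return VariantName(
        gene_config.gene_id, gene_config.group, labels["upstream"], labels["downstream"]
    )


def build_repertoire(
    clones,
    gene_config,
    registries,
    min_support: int = 2,
    line_id: str = "line",
    open_registry: bool = False,
) -> Repertoire:
    """Type clones individually and keep variants with sufficient support.

    Variants under ``min_support`` clones are treated as putative chimeras or
    PCR/sequencing artifacts: excluded from the repertoire but counted in
    ``discarded``.
    """
    if not clones:
        raise TableError("build_repertoire requires at least one clone")
    counts: Counter[VariantName] = Counter()
    for clone in clones:
        counts[type_variant(clone, gene_config, registries, open_registry)] += 1
    kept = {v: n for v, n in counts.items() if n >= min_support}
    discarded = sum(n for v, n in counts.items() if n < min_support)
    if not kept:
        raise TableError(
            f"all {len(clones)} clones discarded at min_support={min_support}"
        )
    gene = gene_config.gene_id
    return Repertoire(
        line_id,
        variants={gene: dict(sorted(kept.items()))},
        discarded={gene: discarded},
        clones_typed={gene: len(clones)},
    )


def signature_flags(repertoire: Repertoire) -> SignatureFlags:
    """Flag the two variants whose joint presence marks incompatible lines:
    any cidA variant with upstream δ (δ/1 or δ/2), and cidB (a/2) exactly."""
    for gene in ("cidA", "cidB"):
        if gene not in repertoire.variants:
            raise TableError(f"repertoire for {repertoire.line_id} lacks {gene}")
    has_delta = any(v.upstream == "δ" for v in repertoire.gene_variants("cidA"))
    has_a2 = any(
        v.upstream == "a" and v.downstream == "2"
        for v in repertoire.gene_variants("cidB")
    )
    return SignatureFlags(has_delta, has_a2)


@dataclass
class TraceReport:
    predicted: set[int]
    observed: set[int]

    @property
    def missing_from_predicted(self) -> set[int]:
        """Observed mixed positions the repertoire cannot explain — a flag for
        a possible missing variant."""
        return self.observed - self.predicted

    @property
    def missing_from_observed(self) -> set[int]:
        return self.predicted - self.observed

    @property
    def consistent(self) -> bool:
        return self.predicted == self.observed


def predicted_mixed_positions(variant_sequences: list[str]) -> set[int]:
    """0-based columns at which the line's variant sequences disagree — the
    positions a direct sequencing trace would show as mixed signal."""
    if not variant_sequences:
        raise TableError("no variant sequences supplied")
    if len({len(s) for s in variant_sequences}) != 1:
        raise LengthMismatchError("variant sequences differ in length")
    ref = variant_sequences[0]
    mixed = set()
    for other in variant_sequences[1:]:
        mixed.update(i for i, (x, y) in enumerate(zip(ref, other)) if x != y)
    # columns where non-reference variants disagree among themselves
    for i in range(len(ref)):
        if len({s[i] for s in variant_sequences}) > 1:
            mixed.add(i)
    return mixed


def check_trace_consistency(
    variant_sequences: list[str], observed_mixed_positions: set[int]
) -> TraceReport:
    """Compare trace-observed mixed positions with those predicted from the
    cloned repertoire; a symmetric difference signals missing variants or
    trace artifacts."""
    return TraceReport(
        predicted_mixed_positions(variant_sequences),
        set(observed_mixed_positions),
    )
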