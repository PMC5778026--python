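"""Amplification detection from normalized read depth, and qPCR copy ratios.

The copy-number estimate is the mean normalized depth over the operon
(polymorphic regions and the duplicated cidB tail excluded) divided by the
aggregated normalized means of the single-copy marker genes. Three
adjustments are applied: (i) depth is normalized by the genome-wide mean,
(ii) polymorphic regions are excluded, (iii) the identically-duplicated cidB
tail is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoverageError, RegionError, TableError


@dataclass
class CoverageProfile:
    """Per-base depth over the reference, with normalization metadata."""

    depth: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.depth < 0).any():
            raise CoverageError("negative depth values")

    @property
    def genome_mean(self) -> float:
        return float(self.depth.mean())

    def __len__(self) -> int:
        return len(self.depth)


@dataclass
class RegionSet:
    """Named reference intervals, all 0-based half-open internally."""

    operon: dict[str, tuple[int, int]]
    markers: dict[str, tuple[int, int]]
    exclusions: dict[str, tuple[int, int]] = field(default_factory=dict)
    extra: dict[str, tuple[int, int]] = field(default_factory=dict)

    @classmethod
    def from_annotations(
        cls,
        annotations: dict[str, tuple[int, int]],
        exclusions: dict[str, tuple[int, int]],
    ) -> "RegionSet":
        operon = {k: v for k, v in annotations.items() if k in ("cidA", "cidB")}
        markers = {k: v for k, v in annotations.items() if k.startswith("marker_")}
        extra = {
            k: v
            for k, v in annotations.items()
            if k not in operon and k not in markers
        }
        return cls(operon, markers, dict(exclusions), extra)

    @classmethod
    def from_bed_records(cls, records: list[tuple[str, int, int, str]]) -> "RegionSet":
        """Build from BED rows (chrom, start, end, name). Names ``cidA``/
        ``cidB`` form the operon, ``marker_*`` the single-copy set and
        ``exclude_*`` the exclusions; everything else is kept as extra."""
        operon, markers, exclusions, extra = {}, {}, {}, {}
        for _, start, end, name in records:
            if name in ("cidA", "cidB"):
                operon[name] = (start, end)
            elif name.startswith("marker_"):
                markers[name] = (start, end)
            elif name.startswith("exclude_"):
                exclusions[name] = (start, end)
            else:
                extra[name] = (start, end)
        if not operon:
            raise RegionError("BED contains no operon genes (cidA/cidB)")
        return cls(operon, markers, exclusions, extra)

    def validate(self, reference_length: int) -> None:
        for name, (start, end) in {
            **self.operon, **self.markers, **self.exclusions, **self.extra
        }.items():
            if not (0 <= start < end <= reference_length):
                raise RegionError(
                    f"region {name!r} [{start},{end}) outside reference bounds"
                )


@dataclass
class CopyNumberEstimate:
    estimate: float
    method: str                      # coverage | qpcr
    operon_mean: float | None = None
    marker_means: dict[str, float] = field(default_factory=dict)
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.estimate <= 0:
            raise CoverageError("copy-number estimate must be positive")


@dataclass
class PlacementTable:
    """Placed-read records: start, length, strand, and the index of the
    originating read in the input list (unplaced reads are only counted)."""

    starts: np.ndarray
    lengths: np.ndarray
    strands: np.ndarray              # 0 forward, 1 reverse
    n_unplaced: int = 0
    read_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.read_indices is None:
            self.read_indices = np.arange(len(self.starts))

    def __len__(self) -> int:
        return len(self.starts)


def _build_index(reference: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(reference) - k + 1):
        index.setdefault(reference[i : i + k], []).append(i)
    return index


def map_reads_exact(
    reads: list[tuple[str, str]] | list[str],
    reference: str,
    seed_length: int = 20,
    max_mismatch_frac: float = 0.10,
) -> PlacementTable:
    """Place each read at its best exact/near-exact reference locus.

    Seed-and-extend against a k-mer index of the forward reference; both the
    read and its reverse complement are tried. Ties on mismatch count go to
    the leftmost locus, so reads from all copies of an amplified region pile
    onto the single reference copy. Reads worse than ``max_mismatch_frac``
    everywhere are counted unplaced.
    """
    from .util import revcomp

    if not reference:
        raise CoverageError("empty reference")
    seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    ref_arr = np.frombuffer(reference.encode(), dtype=np.uint8)
    index = _build_index(reference, seed_length)
    starts, lengths, strands, read_indices = [], [], [], []
    n_unplaced = 0
    for read_idx, seq in enumerate(seqs):
        best = None  # (mismatches, start, strand)
        max_mm = int(max_mismatch_frac * len(seq))
        for strand, oriented in enumerate((seq, revcomp(seq))):
            read_arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
            candidates: set[int] = set()
            for off in range(0, len(oriented) - seed_length + 1, seed_length):
                for pos in index.get(oriented[off : off + seed_length], ()):
                    cand = pos - off
                    if 0 <= cand <= len(reference) - len(oriented):
                        candidates.add(cand)
            for cand in sorted(candidates):
                mm = int(
                    (ref_arr[cand : cand + len(oriented)] != read_arr).sum()
                )
                if mm <= max_mm and (
                    best is None or (mm, cand, strand) < best
                ):
                    best = (mm, cand, strand)
        if best is None:
            n_unplaced += 1
            continue
        _, start, strand = best
        starts.append(start)
        lengths.append(len(seq))
        strands.append(strand)
        read_indices.append(read_idx)
    return PlacementTable(
        np.asarray(starts, dtype=int),
        np.asarray(lengths, dtype=int),
        np.asarray(strands, dtype=int),
        n_unplaced,
        np.asarray(read_indices, dtype=int),
    )


def compute_coverage(placements: PlacementTable, reference_length: int) -> CoverageProfile:
    """Per-base depth: number of placed reads overlapping each base."""
    diff = np.zeros(reference_length + 1, dtype=float)
    for start, length in zip(placements.starts, placements.lengths):
        if start < 0 or start + length > reference_length:
            raise CoverageError(f"placement [{start},{start + length}) out of bounds")
        diff[start] += 1
        diff[start + length] -= 1
    return CoverageProfile(np.cumsum(diff[:-1]))


def normalize(profile: CoverageProfile) -> CoverageProfile:
    """Divide by the genome-wide mean so the normalized mean is one."""
    mean = profile.genome_mean
    if mean <= 0:
        raise CoverageError("cannot normalize an all-zero coverage profile")
    return CoverageProfile(profile.depth / mean, normalized=True)


def region_mean(
    profile: CoverageProfile,
    region: tuple[int, int],
    exclusions: list[tuple[int, int]] = (),
) -> float:
    """Mean depth over region bases not covered by any exclusion interval."""
    start, end = region
    if not (0 <= start < end <= len(profile)):
        raise RegionError(f"region [{start},{end}) outside profile bounds")
    mask = np.zeros(end - start, dtype=bool)
    for (xs, xe) in exclusions:
        lo, hi = max(xs, start), min(xe, end)
        if lo < hi:
            mask[lo - start : hi - start] = True
    if mask.all():
        raise RegionError(f"region [{start},{end}) fully excluded")
    return float(profile.depth[start:end][~mask].mean())


def estimate_copy_number(
    profile: CoverageProfile,
    regions: RegionSet,
    marker_aggregation: str = "mean",
) -> CopyNumberEstimate:
    """Operon copy number as normalized operon depth over the aggregated
    normalized means of the single-copy marker genes."""
    if not regions.markers:
        raise CoverageError("at least one single-copy marker gene is required")
    prof = profile if profile.normalized else normalize(profile)
    exclusions = list(regions.exclusions.values())
    marker_means = {
        name: region_mean(prof, interval, exclusions)
        for name, interval in sorted(regions.markers.items())
    }
    zero = [name for name, m in marker_means.items() if m == 0]
    if zero:
        raise CoverageError(f"marker genes with zero coverage: {zero}")
    # operon mean over the union of gene bases, exclusions removed
    total, n_bases = 0.0, 0
    for name, (start, end) in sorted(regions.operon.items()):
        mask = np.zeros(end - start, dtype=bool)
        for (xs, xe) in exclusions:
            lo, hi = max(xs, start), min(xe, end)
            if lo < hi:
                mask[lo - start : hi - start] = True
        vals = prof.depth[start:end][~mask]
        total += float(vals.sum())
        n_bases += len(vals)
    if n_bases == 0:
        raise RegionError("operon fully excluded")
    operon_mean = total / n_bases
    values = list(marker_means.values())
    if marker_aggregation == "mean":
        marker_agg = float(np.mean(values))
    elif marker_aggregation == "median":
        marker_agg = float(np.median(values))
    else:
        raise CoverageError(f"unknown marker aggregation {marker_aggregation!r}")
    return CopyNumberEstimate(
        estimate=operon_mean / marker_agg,
        method="coverage",
        operon_mean=operon_mean,
        marker_means=marker_means,
        details={"marker_aggregation": marker_aggregation,
                 "marker_aggregate": marker_agg},
    )


def qpcr_copy_ratio(
    table,
    target_locus: str,
    reference_locus: str = "wsp",
    efficiency: float = 2.0,
) -> CopyNumberEstimate:
    """Relative copies of target vs reference locus from replicate-mean Cq:
    ``ratio = efficiency ** (meanCq(reference) - meanCq(target))``."""
    means = {}
    for locus in (target_locus, reference_locus):
        sub = table[table["locus"] == locus]
        if len(sub) == 0:
            raise TableError(f"locus {locus!r} missing from Cq table")
        means[locus] = float(sub["cq"].mean())
    ratio = efficiency ** (means[reference_locus] - means[target_locus])
    return CopyNumberEstimate(
        estimate=ratio,
        method="qpcr",
        details={
            "target": target_locus,
            "reference": reference_locus,
            "efficiency": efficiency,
            "mean_cq": means,
            "delta_cq": means[reference_locus] - means[target_locus],
        },
    )
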