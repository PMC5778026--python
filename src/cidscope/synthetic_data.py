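"""Seeded generators for every input the pipeline consumes.

The simulator emulates the study design the downstream stages assume: a
reference genome carrying exactly one operon copy (plus 14 single-copy marker
genes, a single-copy ``wsp`` locus, and an identically-duplicated copy of the
cidB 3' tail), sample genomes carrying ``k`` operon copies whose variants are
block-recombinants of small allele pools, uniform read sampling, clone
sampling, qPCR Cq tables, and line panels where crossing type follows a
variant-signature rule with a configurable discordance rate.

All randomness flows from explicit seeds; every generator is pure given
(config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import (
    CidscopeError,
    LengthMismatchError,
    RegionError,
    UnknownLabelError,
)
from .repertoire import Repertoire, SignatureFlags, VariantName, signature_flags
from .rflp import Enzyme, digest, find_sites, load_enzymes, scrub_sites
from .util import STOP_CODONS, aa_to_nt_interval, revcomp

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AllelePool:
    """The alternative sequences observed for one polymorphic region."""

    gene_id: str
    region_id: str
    alleles: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.alleles.values()}
        if len(lengths) != 1:
            raise LengthMismatchError(
                f"{self.gene_id}/{self.region_id}: allele lengths differ: {lengths}"
            )
        labels = list(self.alleles)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                if self.alleles[a] == self.alleles[b]:
                    raise CidscopeError(
                        f"{self.gene_id}/{self.region_id}: alleles {a!r} and {b!r} identical"
                    )

    @property
    def length(self) -> int:
        return len(next(iter(self.alleles.values())))


@dataclass
class GeneConfig:
    """Coordinates of a gene's polymorphic regions on its constant backbone."""

    gene_id: str
    scaffold: str                              # CDS backbone
    region_coords: dict[str, tuple[int, int]]  # 1-based inclusive nt
    protein_region_coords: dict[str, tuple[int, int]]
    excluded_tail_start: int | None = None     # 1-based nt, cidB only
    group: str = "IV"

    def __post_init__(self) -> None:
        prev_end = 0
        for region_id, (start, end) in sorted(
            self.region_coords.items(), key=lambda kv: kv[1]
        ):
            if start <= prev_end:
                raise RegionError(f"{self.gene_id}: region intervals overlap or are unordered")
            if start % 3 != 1:
                raise RegionError(f"{self.gene_id}/{region_id}: region start not in CDS frame")
            if (end - start + 1) % 3 != 0:
                raise RegionError(f"{self.gene_id}/{region_id}: region length not a codon multiple")
            if end > len(self.scaffold):
                raise RegionError(f"{self.gene_id}/{region_id}: region beyond scaffold end")
            prev_end = end

    def region_slice(self, region_id: str) -> slice:
        start, end = self.region_coords[region_id]
        return slice(start - 1, end)


@dataclass
class GeneModel:
    """A gene's backbone, allele pools and diagnostic-test geometry."""

    config: GeneConfig
    pools: dict[str, AllelePool]
    flank5: str
    flank3: str
    amplicon_cds_span: tuple[int, int]   # 0-based, relative to CDS start (may be negative)
    primers: tuple[str, str]             # forward, reverse (reverse given 5'->3')
    test_enzymes: tuple[str, ...]

    @property
    def gene_id(self) -> str:
        return self.config.gene_id

    def locus_sequence(self, cds: str | None = None) -> str:
        """Gene CDS embedded in its flanks (the PCR template)."""
        return self.flank5 + (cds if cds is not None else self.config.scaffold) + self.flank3

    def amplicon(self, cds: str | None = None) -> str:
        a, b = self.amplicon_cds_span
        locus = self.locus_sequence(cds)
        return locus[len(self.flank5) + a : len(self.flank5) + b]


@dataclass
class OperonModel:
    """Full simulator configuration plus the assembled reference genome."""

    seed: int
    genes: dict[str, GeneModel]
    intergenic: str
    marker_genes: list[str]
    wsp: str
    reference: str
    annotations: dict[str, tuple[int, int]]     # 0-based half-open on reference
    exclusions: dict[str, tuple[int, int]]
    enzymes: dict[str, Enzyme]

    def make_variant_pair(
        self, cidA_labels: tuple[str, str], cidB_labels: tuple[str, str]
    ) -> tuple[tuple[str, VariantName], tuple[str, VariantName]]:
        a = make_variant(self.genes["cidA"].config, *cidA_labels, self.genes["cidA"].pools)
        b = make_variant(self.genes["cidB"].config, *cidB_labels, self.genes["cidB"].pools)
        return a, b


@dataclass
class SimulatedStrain:
    strain_id: str
    reference_genome: str
    sample_genome: str
    annotations: dict[str, tuple[int, int]]
    exclusions: dict[str, tuple[int, int]]
    repertoire_truth: list[tuple[VariantName, VariantName]]
    k_operon: int
    gene_copy_seqs: dict[str, list[str]]
    model: OperonModel


@dataclass
class LineRecord:
    line_id: str
    population_id: str
    wpip_group: str
    repertoire_truth: Repertoire
    crossing_type: str            # compatible | incompatible | undetermined
    flipped: bool = False

    def flags(self) -> SignatureFlags:
        return signature_flags(self.repertoire_truth)


# ---------------------------------------------------------------------------
# sequence construction helpers

_REGION_IDS = ("upstream", "downstream")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _frame_stops(seq: str) -> list[int]:
    return [i for i in range(0, len(seq) - 2, 3) if seq[i : i + 3] in STOP_CODONS]


def _clean_coding(
    rng: np.random.Generator,
    n: int,
    enzymes: list[Enzyme],
    protected: tuple[tuple[int, str], ...] = (),
    max_tries: int = 200,
) -> str:
    """Random in-frame stop-free sequence with no enzyme sites outside the
    ``protected`` (offset, concrete-site) plantings, which are written last."""
    for _ in range(max_tries):
        seq = scrub_sites(_rand_seq(rng, n), enzymes, rng)
        chars = list(seq)
        for off, site in protected:
            chars[off : off + len(site)] = site
        seq = "".join(chars)
        prot_idx = {
            i for off, site in protected for i in range(off, off + len(site))
        }
        ok = True
        for _ in range(50):
            stops = _frame_stops(seq)
            if not stops:
                break
            chars = list(seq)
            fixed_any = False
            for s in stops:
                for i in (s, s + 1, s + 2):
                    if i not in prot_idx:
                        chars[i] = "C"
                        fixed_any = True
                        break
            if not fixed_any:
                ok = False
                break
            seq = "".join(chars)
        else:
            ok = False
        if not ok or _frame_stops(seq):
            continue
        planted_cuts = sorted(
            {c for e in enzymes for c in find_sites(seq, e)}
        )
        expected = sorted(
            {off + e.cut_offset for off, site in protected for e in enzymes
             if _site_matches(e, site)}
        )
        if planted_cuts == expected:
            return seq
    raise CidscopeError("could not build a clean coding sequence")


def _site_matches(enzyme: Enzyme, concrete: str) -> bool:
    if len(concrete) != len(enzyme.recognition):
        return False
    from .util import IUPAC

    return all(b in IUPAC[c] for b, c in zip(concrete, enzyme.recognition.upper()))


def _diverge(
    rng: np.random.Generator,
    base: str,
    n_mut: int,
    enzymes: list[Enzyme],
    protected: tuple[tuple[int, str], ...] = (),
    avoid: list[str] = (),
    min_div: int = 1,
    max_tries: int = 500,
) -> str:
    """Mutate ``base`` at ~n_mut positions, keep it site-clean (except
    plantings), stop-free, and at Hamming >= min_div from every ``avoid``."""
    prot_idx = {i for off, site in protected for i in range(off, off + len(site))}
    free = [i for i in range(len(base)) if i not in prot_idx]
    for _ in range(max_tries):
        chars = list(base)
        for i in rng.choice(free, size=min(n_mut, len(free)), replace=False):
            chars[i] = "ACGT"[(("ACGT".index(chars[i])) + int(rng.integers(1, 4))) % 4]
        for off, site in protected:
            chars[off : off + len(site)] = site
        seq = "".join(chars)
        if _frame_stops(seq):
            continue
        cuts = sorted({c for e in enzymes for c in find_sites(seq, e)})
        expected = sorted(
            {off + e.cut_offset for off, site in protected for e in enzymes
             if _site_matches(e, site)}
        )
        if cuts != expected:
            continue
        if all(
            sum(x != y for x, y in zip(seq, other)) >= min_div for other in avoid
        ):
            return seq
    raise CidscopeError("allele divergence search did not converge")


# ---------------------------------------------------------------------------
# default model

_GENE_DATA = json.loads(
    resources.files("cidscope.data").joinpath("gene_regions.json").read_text()
)["genes"]

#: planted allele-specific restriction sites, as (allele offset, concrete site)
_CIDA_SHARED_SITES = (
    (471, "TCAGA"),    # Hpy188I -> cut at CDS 474
    (595, "AAATTT"),   # ApoI    -> cut at CDS 596
    (650, "TCAGA"),    # Hpy188I -> cut at CDS 653
    (701, "TCAGA"),    # Hpy188I -> cut at CDS 704
)
_CIDA_UP_SITES = {"α": ((69, "AAATTT"),), "β": ((37, "TCAGA"),), "γ": ((37, "TCAGA"),), "δ": ()}
_CIDB_SHARED_SITES = ((538, "TCGA"),)      # TaqI -> cut at CDS 539
_CIDB_DOWN_SITES = {"1": ((83, "GGTACC"),), "2": (), "3": ((52, "GGTACC"),)}

_FLANK5 = 200
_FLANK3 = 200
_CIDA_AMPLICON = (-50, 728)    # 778 bp, CDS-relative
_CIDB_AMPLICON = (300, 1567)   # 1267 bp
_PRIMER_LEN = 24
_INTERGENIC_LEN = 100
_N_MARKERS = 14
_MARKER_LEN = 600
_WSP_LEN = 600


def _build_pool(
    rng: np.random.Generator,
    gene_id: str,
    region_id: str,
    length: int,
    labels: list[str],
    plantings: dict[str, tuple[tuple[int, str], ...]],
    enzymes: list[Enzyme],
) -> AllelePool:
    min_div = max(1, math.ceil(0.05 * length))
    n_mut = max(min_div + 2, math.ceil(0.08 * length))
    # all alleles diverge from one neutral backbone, so they are variants of
    # a common sequence rather than unrelated random strings
    neutral = _clean_coding(rng, length, enzymes, ())
    alleles: dict[str, str] = {}
    for label in labels:
        alleles[label] = _diverge(
            rng,
            neutral,
            n_mut,
            enzymes,
            plantings.get(label, ()),
            avoid=list(alleles.values()),
            min_div=min_div,
        )
    return AllelePool(gene_id, region_id, alleles)


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    enzymes: dict[str, Enzyme],
    test_enzyme_names: tuple[str, ...],
    shared_sites: tuple[tuple[int, str], ...],
    region_plantings: dict[str, dict[str, tuple[tuple[int, str], ...]]],
    amplicon_span: tuple[int, int],
) -> GeneModel:
    data = _GENE_DATA[gene_id]
    cds_len = data["cds_length_nt"]
    enz_list = list(enzymes.values())

    region_coords = {}
    protein_coords = {}
    for region_id, spec in data["regions"].items():
        s_aa, e_aa = spec["aa"]
        protein_coords[region_id] = (s_aa, e_aa)
        region_coords[region_id] = aa_to_nt_interval(s_aa, e_aa)

    pools = {}
    for region_id in _REGION_IDS:
        start, end = region_coords[region_id]
        labels = data[f"{region_id}_labels"]
        pools[region_id] = _build_pool(
            rng, gene_id, region_id, end - start + 1, labels,
            region_plantings.get(region_id, {}), enz_list,
        )

    # scaffold: constant backbone, sites scrubbed, shared cuts planted; the
    # region slots carry the first allele of each pool
    shared = tuple(shared_sites)
    backbone = _clean_coding(rng, cds_len, enz_list, shared)
    chars = list(backbone)
    for region_id in _REGION_IDS:
        start, end = region_coords[region_id]
        first_label = data[f"{region_id}_labels"][0]
        chars[start - 1 : end] = pools[region_id].alleles[first_label]
    scaffold = "".join(chars)

    flank5 = scrub_sites(_rand_seq(rng, _FLANK5), enz_list, rng)
    flank3 = scrub_sites(_rand_seq(rng, _FLANK3), enz_list, rng)

    config = GeneConfig(
        gene_id=gene_id,
        scaffold=scaffold,
        region_coords=region_coords,
        protein_region_coords=protein_coords,
        excluded_tail_start=data.get("excluded_tail_start_nt"),
        group=data["group"],
    )

    locus = flank5 + scaffold + flank3
    a, b = amplicon_span
    fwd = locus[_FLANK5 + a : _FLANK5 + a + _PRIMER_LEN]
    rev = revcomp(locus[_FLANK5 + b - _PRIMER_LEN : _FLANK5 + b])
    return GeneModel(
        config=config,
        pools=pools,
        flank5=flank5,
        flank3=flank3,
        amplicon_cds_span=amplicon_span,
        primers=(fwd, rev),
        test_enzymes=test_enzyme_names,
    )


def _expected_cut_count(gene: GeneModel, up: str, down: str) -> int:
    plant = {"cidA": (_CIDA_SHARED_SITES, _CIDA_UP_SITES, {}),
             "cidB": (_CIDB_SHARED_SITES, {}, _CIDB_DOWN_SITES)}[gene.gene_id]
    shared, up_sites, down_sites = plant
    a, b = gene.amplicon_cds_span
    n = sum(1 for off, _ in shared if a <= off < b)
    n += len(up_sites.get(up, ())) if gene.gene_id == "cidA" else 0
    n += len(down_sites.get(down, ())) if gene.gene_id == "cidB" else 0
    return n


def default_model(seed: int = 0) -> OperonModel:
    """Build the default deterministic simulator configuration.

    The constructed genes are verified: for every allele combination, the
    diagnostic amplicon must digest to exactly the planted cut count. A
    handful of candidate sub-seeds is tried so the returned model is always
    clean, deterministically, for any input seed.
    """
    enzymes = load_enzymes()
    for attempt in range(20):
        rng = np.random.default_rng((seed, attempt))
        try:
            cidA = _build_gene(
                rng, "cidA", enzymes, ("ApoI", "Hpy188I"),
                _CIDA_SHARED_SITES, {"upstream": _CIDA_UP_SITES}, _CIDA_AMPLICON,
            )
            cidB = _build_gene(
                rng, "cidB", enzymes, ("BanI", "TaqI"),
                _CIDB_SHARED_SITES, {"downstream": _CIDB_DOWN_SITES}, _CIDB_AMPLICON,
            )
            genes = {"cidA": cidA, "cidB": cidB}
            for gene in genes.values():
                test_enz = [enzymes[n] for n in gene.test_enzymes]
                for up in gene.pools["upstream"].alleles:
                    for down in gene.pools["downstream"].alleles:
                        cds, _ = make_variant(gene.config, up, down, gene.pools)
                        res = digest(gene.amplicon(cds), test_enz)
                        if len(res.cut_positions) != _expected_cut_count(gene, up, down):
                            raise CidscopeError("spurious or missing amplicon cuts")
        except CidscopeError:
            continue
        enz_list = list(enzymes.values())
        intergenic = scrub_sites(_rand_seq(rng, _INTERGENIC_LEN), enz_list, rng)
        markers = [_rand_seq(rng, _MARKER_LEN) for _ in range(_N_MARKERS)]
        wsp = _rand_seq(rng, _WSP_LEN)
        reference, annotations, exclusions = _assemble_reference(
            rng, genes, intergenic, markers, wsp
        )
        return OperonModel(
            seed=seed,
            genes=genes,
            intergenic=intergenic,
            marker_genes=markers,
            wsp=wsp,
            reference=reference,
            annotations=annotations,
            exclusions=exclusions,
            enzymes=enzymes,
        )
    raise CidscopeError(f"default_model failed to converge for seed {seed}")


def _assemble_reference(rng, genes, intergenic, markers, wsp):
    parts: list[str] = []
    annotations: dict[str, tuple[int, int]] = {}
    pos = 0

    def add(seq: str, name: str | None = None):
        nonlocal pos
        if name:
            annotations[name] = (pos, pos + len(seq))
        parts.append(seq)
        pos += len(seq)

    cidA, cidB = genes["cidA"], genes["cidB"]
    add(_rand_seq(rng, 300))
    add(cidA.flank5)
    operon_start = pos
    add(cidA.config.scaffold, "cidA")
    add(intergenic)
    add(cidB.config.scaffold, "cidB")
    annotations["operon"] = (operon_start, pos)
    add(cidB.flank3)
    add(_rand_seq(rng, 200))
    for i, marker in enumerate(markers, start=1):
        add(marker, f"marker_{i:02d}")
        add(_rand_seq(rng, 120))
    add(wsp, "wsp")
    add(_rand_seq(rng, 120))
    tail_start_1b = cidB.config.excluded_tail_start
    tail = cidB.config.scaffold[tail_start_1b - 1 :]
    add(tail, "cidB_tail_dup")
    add(_rand_seq(rng, 200))

    exclusions: dict[str, tuple[int, int]] = {}
    for gene_id in ("cidA", "cidB"):
        gstart, _ = annotations[gene_id]
        cfg = genes[gene_id].config
        for region_id, (s, e) in cfg.region_coords.items():
            exclusions[f"exclude_{gene_id}_{region_id}"] = (gstart + s - 1, gstart + e)
    bstart, bend = annotations["cidB"]
    exclusions["exclude_cidB_tail"] = (bstart + tail_start_1b - 1, bend)
    return "".join(parts), annotations, exclusions


# ---------------------------------------------------------------------------
# operations


def make_variant(
    gene_config: GeneConfig,
    upstream_label: str,
    downstream_label: str,
    pools: dict[str, AllelePool],
) -> tuple[str, VariantName]:
    """Splice chosen region alleles into the gene backbone and name the
    result ``gene_GROUP(up/down)``."""
    labels = {"upstream": upstream_label, "downstream": downstream_label}
    chars = list(gene_config.scaffold)
    for region_id, label in labels.items():
        pool = pools[region_id]
        if label not in pool.alleles:
            raise UnknownLabelError(
                f"{gene_config.gene_id}/{region_id}: unknown allele label {label!r}"
            )
        allele = pool.alleles[label]
        start, end = gene_config.region_coords[region_id]
        if len(allele) != end - start + 1:
            raise LengthMismatchError(
                f"{gene_config.gene_id}/{region_id}: allele length {len(allele)} != "
                f"interval length {end - start + 1}"
            )
        chars[start - 1 : end] = allele
    name = VariantName(
        gene_config.gene_id, gene_config.group, upstream_label, downstream_label
    )
    return "".join(chars), name


_DEFAULT_CHOICES = [
    (("α", "1"), ("a", "1")),
    (("δ", "1"), ("a", "2")),
    (("β", "1"), ("b", "3")),
    (("γ", "2"), ("b", "2")),
    (("δ", "2"), ("a", "2")),
    (("α", "2"), ("b", "1")),
]


def simulate_strain(
    model: OperonModel,
    k_operon: int,
    variant_choices: list[tuple[tuple[str, str], tuple[str, str]]] | None = None,
    seed: int = 0,
    strain_id: str = "sim",
) -> SimulatedStrain:
    """Plant ``k_operon`` operon copies (chosen variants, unique spacers
    between copies) into the model's sample genome; the reference keeps one."""
    if k_operon < 1:
        raise CidscopeError(f"k_operon must be >= 1, got {k_operon}")
    if variant_choices is None:
        variant_choices = [
            _DEFAULT_CHOICES[i % len(_DEFAULT_CHOICES)] for i in range(k_operon)
        ]
    if len(variant_choices) != k_operon:
        raise CidscopeError("variant_choices length must equal k_operon")
    rng = np.random.default_rng(seed)
    copies = []
    truth = []
    gene_copy_seqs: dict[str, list[str]] = {"cidA": [], "cidB": []}
    for cidA_labels, cidB_labels in variant_choices:
        (seq_a, name_a), (seq_b, name_b) = model.make_variant_pair(cidA_labels, cidB_labels)
        copies.append(seq_a + model.intergenic + seq_b)
        truth.append((name_a, name_b))
        gene_copy_seqs["cidA"].append(seq_a)
        gene_copy_seqs["cidB"].append(seq_b)
    spacers = [_rand_seq(rng, 300) for _ in range(k_operon - 1)]
    core = copies[0]
    for spacer, copy in zip(spacers, copies[1:]):
        core += spacer + copy
    start, end = model.annotations["operon"]
    sample = model.reference[:start] + core + model.reference[end:]
    return SimulatedStrain(
        strain_id=strain_id,
        reference_genome=model.reference,
        sample_genome=sample,
        annotations=dict(model.annotations),
        exclusions=dict(model.exclusions),
        repertoire_truth=truth,
        k_operon=k_operon,
        gene_copy_seqs=gene_copy_seqs,
        model=model,
    )


def simulate_reads(
    strain: SimulatedStrain | str,
    mean_depth: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Uniform single-end read sampling at Poisson-distributed count
    ``depth * G / L``; per-base substitution errors at ``error_rate``."""
    genome = strain.sample_genome if isinstance(strain, SimulatedStrain) else strain
    if mean_depth <= 0:
        raise CidscopeError("mean_depth must be positive")
    if read_length > len(genome):
        raise CidscopeError("read_length exceeds genome length")
    if not 0.0 <= error_rate <= 0.5:
        raise CidscopeError(f"error_rate {error_rate} outside [0, 0.5]")
    rng = np.random.default_rng(seed)
    g = len(genome)
    n_reads = int(rng.poisson(mean_depth * g / read_length))
    starts = rng.integers(0, g - read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        s = int(starts[i])
        seq = genome[s : s + read_length]
        if strands[i]:
            seq = revcomp(seq)
        if error_rate > 0:
            mask = rng.random(read_length) < error_rate
            if mask.any():
                chars = list(seq)
                for j in np.nonzero(mask)[0]:
                    chars[j] = "ACGT"[("ACGT".index(chars[j]) + int(rng.integers(1, 4))) % 4]
                seq = "".join(chars)
        reads.append((f"read_{i:06d}", seq))
    return reads


def simulate_clones(
    strain: SimulatedStrain,
    gene_id: str,
    n_clones: int,
    error_rate: float = 0.0,
    seed: int = 0,
    weights: list[float] | None = None,
) -> list[str]:
    """Draw clones from the strain's variant copies of one gene (uniform or
    per supplied weights) with per-base substitution error."""
    if gene_id not in strain.gene_copy_seqs:
        raise UnknownLabelError(f"gene {gene_id!r} absent from strain {strain.strain_id}")
    if n_clones < 1:
        raise CidscopeError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    seqs = strain.gene_copy_seqs[gene_id]
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(seqs) or w.sum() <= 0 or (w < 0).any():
            raise CidscopeError("weights must be non-negative, one per copy, sum > 0")
        p = w / w.sum()
    picks = rng.choice(len(seqs), size=n_clones, p=p)
    clones = []
    for idx in picks:
        seq = seqs[int(idx)]
        if error_rate > 0:
            mask = rng.random(len(seq)) < error_rate
            if mask.any():
                chars = list(seq)
                for j in np.nonzero(mask)[0]:
                    chars[j] = "ACGT"[("ACGT".index(chars[j]) + int(rng.integers(1, 4))) % 4]
                seq = "".join(chars)
        clones.append(seq)
    return clones


def simulate_qpcr(
    strain: SimulatedStrain,
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_cq: float = 25.0,
    replicates: int = 3,
):
    """Cq table for the three assayed loci: ``Cq = baseline - log_eff(copies)
    + noise``; wsp has one copy, cidA and cidB have ``k_operon``."""
    import pandas as pd

    if not 1.0 < efficiency <= 2.0:
        raise CidscopeError(f"efficiency {efficiency} outside (1, 2]")
    if noise_sd < 0:
        raise CidscopeError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    copies = {"wsp": 1, "cidA": strain.k_operon, "cidB": strain.k_operon}
    rows = []
    for locus, n in copies.items():
        for rep in range(1, replicates + 1):
            cq = baseline_cq - math.log(n, efficiency) + (
                rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            )
            rows.append({"sample_id": strain.strain_id, "locus": locus,
                         "replicate": rep, "cq": cq})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# line panels

_CATEGORY_REPERTOIRES = {
    "both": ({("α", "1"), ("δ", "1")}, {("a", "1"), ("a", "2")}),
    "cidA_only": ({("α", "1"), ("δ", "1")}, {("a", "1")}),
    "cidB_only": ({("α", "1")}, {("a", "1"), ("a", "2")}),
    "neither": ({("α", "1")}, {("a", "1")}),
}


def _repertoire_from_labels(line_id, cidA_pairs, cidB_pairs, group="IV") -> Repertoire:
    variants = {
        "cidA": {VariantName("cidA", group, u, d): 1 for u, d in sorted(cidA_pairs)},
        "cidB": {VariantName("cidB", group, u, d): 1 for u, d in sorted(cidB_pairs)},
    }
    return Repertoire(
        line_id,
        variants=variants,
        discarded={"cidA": 0, "cidB": 0},
        clones_typed={g: len(v) for g, v in variants.items()},
    )


def default_signature_rule(repertoire: Repertoire) -> bool:
    """Incompatibility signature: both cidA δ (either downstream) and
    cidB (a/2) present."""
    return signature_flags(repertoire).category == "both"


def simulate_panel(
    n_lines: int,
    signature_rule=None,
    discordance_rate: float = 0.0,
    seed: int = 0,
    planted: list[tuple[int, str, str]] | None = None,
    group: str = "IV",
    n_populations: int = 15,
) -> list[LineRecord]:
    """Generate a panel of lines whose crossing type follows the signature
    rule, then flips with probability ``discordance_rate``.

    ``planted`` overrides random generation with exact counts of
    (n, signature category, crossing type) — flips are not applied there.
    """
    if not 0.0 <= discordance_rate < 1.0:
        raise CidscopeError(f"discordance_rate {discordance_rate} outside [0, 1)")
    if signature_rule is None:
        signature_rule = default_signature_rule
    rng = np.random.default_rng(seed)
    records: list[LineRecord] = []

    if planted is not None:
        i = 0
        for count, category, crossing in planted:
            cidA_pairs, cidB_pairs = _CATEGORY_REPERTOIRES[category]
            for _ in range(count):
                i += 1
                rep = _repertoire_from_labels(f"line_{i:04d}", cidA_pairs, cidB_pairs, group)
                records.append(LineRecord(
                    f"line_{i:04d}", f"pop_{(i - 1) % n_populations + 1:02d}",
                    group, rep, crossing,
                ))
        return records

    for i in range(1, n_lines + 1):
        cidA_pairs = {("α", "1")}
        if rng.random() < 0.20:
            cidA_pairs.add(("δ", "1"))
        if rng.random() < 0.05:
            cidA_pairs.add(("δ", "2"))
        if rng.random() < 0.30:
            cidA_pairs.add(("β", "1"))
        if rng.random() < 0.25:
            cidA_pairs.add(("γ", "2"))
        cidB_pairs = {("a", "1")}
        if rng.random() < 0.18:
            cidB_pairs.add(("a", "2"))
        if rng.random() < 0.25:
            cidB_pairs.add(("b", "3"))
        if rng.random() < 0.15:
            cidB_pairs.add(("b", "2"))
        rep = _repertoire_from_labels(f"line_{i:04d}", cidA_pairs, cidB_pairs, group)
        crossing = "incompatible" if signature_rule(rep) else "compatible"
        flipped = bool(rng.random() < discordance_rate)
        if flipped:
            crossing = "compatible" if crossing == "incompatible" else "incompatible"
        records.append(LineRecord(
            f"line_{i:04d}", f"pop_{(i - 1) % n_populations + 1:02d}",
            group, rep, crossing, flipped,
        ))
    return records
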