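"""End-to-end orchestration: simulate -> coverage -> type -> rflp -> blocks
-> associate, with a checksummed run manifest."""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import association as assoc
from . import blocks as blocks_mod
from . import coverage_cn as cov
from . import io_utils as io
from . import repertoire as rep
from . import rflp as rflp_mod
from . import synthetic_data as synth

log = logging.getLogger("cidscope")

ALL_STAGES = ("simulate", "coverage", "type", "rflp", "blocks", "associate")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "cidscope_run"
    stages: tuple[str, ...] = ALL_STAGES
    # simulator
    k_operon: int = 3
    depth: float = 30.0
    read_length: int = 100
    error_rate: float = 0.0
    n_clones: int = 48
    n_lines: int = 180
    discordance_rate: float = 0.0
    panel_mode: str = "planted_demo"   # planted_demo | random
    qpcr_noise_sd: float = 0.1
    # typing / rflp
    min_support: int = 2
    tolerance_bp: int = 5
    positive_rule: str = "any_variant"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _setup_logging() -> None:
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[cidscope:%(stage)s] %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)


def _info(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


def demo_panel_planting() -> list[tuple[int, str, str]]:
    """The 180-line composition used by the demo/association stage: 17
    signature-positive incompatible lines; among 163 compatible lines 8 carry
    both signature variants, 8 carry only the cidA one, 147 carry neither."""
    return [
        (17, "both", "incompatible"),
        (8, "both", "compatible"),
        (8, "cidA_only", "compatible"),
        (147, "neither", "compatible"),
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages on synthetic data; returns the manifest."""
    _setup_logging()
    out = io.ensure_dir(config.out_dir)
    manifest: dict = {"config": asdict(config), "seed": config.seed, "outputs": {}}

    def record(name: str, path: Path):
        manifest["outputs"][name] = {
            "path": str(path),
            "sha256": _sha256(Path(path)),
        }

    model = synth.default_model(config.seed)
    strain = synth.simulate_strain(
        model, config.k_operon, seed=config.seed, strain_id=f"strain_s{config.seed}"
    )

    if "simulate" in config.stages:
        _info("simulate", f"k_operon={config.k_operon} depth={config.depth}")
        io.write_fasta(out / "reference.fa", [("ref", strain.reference_genome)])
        io.write_fasta(out / "sample.fa", [("sample", strain.sample_genome)])
        io.write_bed(out / "regions.bed", {**strain.annotations, **strain.exclusions})
        reads = synth.simulate_reads(
            strain, config.depth, config.read_length, config.error_rate, config.seed
        )
        io.write_fasta(out / "reads.fa", reads)
        for gene_id in ("cidA", "cidB"):
            clones = synth.simulate_clones(
                strain, gene_id, config.n_clones, config.error_rate, config.seed
            )
            io.write_fasta(
                out / f"clones_{gene_id}.fa",
                [(f"{gene_id}_clone_{i:03d}", s) for i, s in enumerate(clones)],
            )
        qpcr = synth.simulate_qpcr(
            strain, noise_sd=config.qpcr_noise_sd, seed=config.seed
        )
        io.write_tsv(out / "qpcr.tsv", qpcr)
        panel = _make_panel(config)
        io.write_tsv(out / "panel.tsv", _panel_frame(panel))
        io.write_json(out / "truth.json", {
            "seed": config.seed,
            "k_operon": strain.k_operon,
            "repertoire_truth": [
                [a.render(), b.render()] for a, b in strain.repertoire_truth
            ],
        })
        for name in ("reference.fa", "sample.fa", "regions.bed", "reads.fa",
                     "clones_cidA.fa", "clones_cidB.fa", "qpcr.tsv",
                     "panel.tsv", "truth.json"):
            record(name, out / name)

    if "coverage" in config.stages:
        _info("coverage", "mapping reads and estimating copy number")
        reads = [(n, s) for n, s in io.read_fasta(out / "reads.fa")]
        placements = cov.map_reads_exact(reads, strain.reference_genome)
        profile = cov.normalize(
            cov.compute_coverage(placements, len(strain.reference_genome))
        )
        regions = cov.RegionSet.from_annotations(strain.annotations, strain.exclusions)
        estimate = cov.estimate_copy_number(profile, regions)
        qpcr = io.read_tsv(out / "qpcr.tsv", ["sample_id", "locus", "replicate", "cq"])
        q_a = cov.qpcr_copy_ratio(qpcr, "cidA")
        q_ab = cov.qpcr_copy_ratio(qpcr, "cidA", "cidB")
        io.write_json(out / "coverage.json", {
            "coverage_estimate": estimate.estimate,
            "operon_mean": estimate.operon_mean,
            "marker_means": estimate.marker_means,
            "n_unplaced": placements.n_unplaced,
            "qpcr_cidA_vs_wsp": q_a.estimate,
            "qpcr_cidA_vs_cidB": q_ab.estimate,
        })
        per_region = pd.DataFrame(
            [
                {"region": name, "start": s, "end": e,
                 "mean_normalized_depth": cov.region_mean(
                     profile, (s, e), list(strain.exclusions.values()))}
                for name, (s, e) in sorted(strain.annotations.items())
            ]
        )
        io.write_tsv(out / "coverage_regions.tsv", per_region)
        record("coverage.json", out / "coverage.json")
        record("coverage_regions.tsv", out / "coverage_regions.tsv")

    repertoires: dict[str, rep.Repertoire] = {}
    if "type" in config.stages:
        _info("type", f"typing {config.n_clones} clones per gene")
        merged: rep.Repertoire | None = None
        rows = []
        for gene_id in ("cidA", "cidB"):
            gene = model.genes[gene_id]
            clones = [s for _, s in io.read_fasta(out / f"clones_{gene_id}.fa")]
            registries = {
                r: dict(gene.pools[r].alleles) for r in ("upstream", "downstream")
            }
            one = rep.build_repertoire(
                clones, gene.config, registries,
                min_support=config.min_support, line_id=strain.strain_id,
            )
            merged = one if merged is None else merged.merge(one)
            for variant, support in one.variants[gene_id].items():
                rows.append({"line_id": strain.strain_id, "gene": gene_id,
                             "variant": variant.render(), "support": support})
        repertoires[strain.strain_id] = merged
        io.write_tsv(out / "repertoire.tsv", pd.DataFrame(rows))
        flags = rep.signature_flags(merged)
        io.write_json(out / "flags.json", {
            "line_id": strain.strain_id,
            "has_cidA_delta": flags.has_cidA_delta,
            "has_cidB_a2": flags.has_cidB_a2,
            "category": flags.category,
        })
        record("repertoire.tsv", out / "repertoire.tsv")
        record("flags.json", out / "flags.json")

    if "rflp" in config.stages:
        _info("rflp", "in-silico PCR-RFLP on the strain's variant copies")
        rows = []
        for gene_id in ("cidA", "cidB"):
            gene = model.genes[gene_id]
            enz = [model.enzymes[n] for n in gene.test_enzymes]
            for cds, (name_a, name_b) in zip(
                strain.gene_copy_seqs[gene_id], strain.repertoire_truth
            ):
                variant = name_a if gene_id == "cidA" else name_b
                template = gene.locus_sequence(cds)
                amplicon = rflp_mod.insilico_pcr(template, *gene.primers)
                result = rflp_mod.digest(amplicon, enz)
                rows.append({
                    "sample": strain.strain_id,
                    "test": f"{gene_id}_diagnostic",
                    "variant_truth": variant.render(),
                    "amplicon_bp": len(amplicon),
                    "fragments": ";".join(map(str, result.fragments)),
                })
        io.write_tsv(out / "rflp_calls.tsv", pd.DataFrame(rows))
        record("rflp_calls.tsv", out / "rflp_calls.tsv")

    if "blocks" in config.stages:
        _info("blocks", "block/four-gamete analysis of all cidA variants")
        gene = model.genes["cidA"]
        names, seqs = [], []
        for up in gene.pools["upstream"].alleles:
            for down in gene.pools["downstream"].alleles:
                cds, vname = synth.make_variant(gene.config, up, down, gene.pools)
                names.append(vname.render())
                seqs.append(cds)
        aln = blocks_mod.VariantAlignment(names, seqs)
        poly = blocks_mod.polymorphic_columns(aln)
        intervals = blocks_mod.detect_blocks(poly, max_gap=3)
        blockset = blocks_mod.assign_block_alleles(aln, intervals, poly)
        fg = blocks_mod.four_gamete_report(blockset)
        io.write_tsv(out / "blocks.tsv", pd.DataFrame(
            [{"block": i, "start": s, "end": e}
             for i, (s, e) in enumerate(blockset.blocks)]
        ))
        io.write_tsv(out / "four_gamete.tsv", pd.DataFrame(
            [{"block_i": i, "block_j": j, "result": r} for i, j, r in fg]
        ))
        mat = blocks_mod.p_distance_matrix(aln)
        (out / "distances.phy").write_text(blocks_mod.to_phylip(aln, mat))
        (out / "distances.nex").write_text(blocks_mod.to_nexus(aln, mat))
        for name in ("blocks.tsv", "four_gamete.tsv", "distances.phy", "distances.nex"):
            record(name, out / name)

    if "associate" in config.stages:
        _info("associate", "signature x crossing-type association")
        frame = io.read_tsv(out / "panel.tsv",
                            ["line_id", "crossing_type", "has_cidA_delta", "has_cidB_a2"])
        panel = [
            (row.crossing_type,
             rep.SignatureFlags(bool(row.has_cidA_delta), bool(row.has_cidB_a2)))
            for row in frame.itertuples()
        ]
        table = assoc.build_contingency(panel, config.positive_rule)
        result = assoc.prop_test_yates(table)
        report = assoc.discordance_report(panel)
        io.write_json(out / "association.json", {
            "chi2": result.chi2,
            "df": result.df,
            "p": result.p,
            "corrected": result.corrected,
            "positive_rule": config.positive_rule,
            "table": table.counts,
            "n_undetermined": table.n_undetermined,
        })
        io.write_tsv(out / "discordance.tsv", pd.DataFrame(
            [{"crossing_type": ct, "category": cat, "count": n}
             for (ct, cat), n in sorted(report.counts.items())]
        ))
        record("association.json", out / "association.json")
        record("discordance.tsv", out / "discordance.tsv")

    io.write_json(out / "run_manifest.json", manifest)
    return manifest


def _make_panel(config: RunConfig) -> list[synth.LineRecord]:
    if config.panel_mode == "planted_demo":
        return synth.simulate_panel(
            180, planted=demo_panel_planting(), seed=config.seed
        )
    return synth.simulate_panel(
        config.n_lines, discordance_rate=config.discordance_rate, seed=config.seed
    )


def _panel_frame(panel: list[synth.LineRecord]) -> pd.DataFrame:
    rows = []
    for line in panel:
        flags = line.flags()
        rows.append({
            "line_id": line.line_id,
            "population": line.population_id,
            "group": line.wpip_group,
            "cidA_variants": ",".join(
                v.render() for v in sorted(line.repertoire_truth.gene_variants("cidA"))
            ),
            "cidB_variants": ",".join(
                v.render() for v in sorted(line.repertoire_truth.gene_variants("cidB"))
            ),
            "crossing_type": line.crossing_type,
            "has_cidA_delta": flags.has_cidA_delta,
            "has_cidB_a2": flags.has_cidB_a2,
        })
    return pd.DataFrame(rows)
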