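from collections import Counter

import numpy as np
import pytest

from cidscope.errors import AmpliconError, EnzymeError
from cidscope.rflp import (
    DigestResult,
    Enzyme,
    ReferencePattern,
    amplicon_map_from_config,
    build_amplicon_from_map,
    call_pattern,
    digest,
    find_sites,
    insilico_pcr,
    load_enzymes,
    load_patterns,
    patterns_for_test,
)
from cidscope.synthetic_data import make_variant
from cidscope.util import IUPAC, revcomp

ENZYMES = load_enzymes()
PATTERNS = load_patterns()


def brute_force_sites(seq: str, enzyme: Enzyme, scan_reverse: bool) -> list[int]:
    """Independent IUPAC scan oracle (checks both strands if requested)."""
    rec = enzyme.recognition.upper()
    cuts = set()
    for i in range(len(seq) - len(rec) + 1):
        if all(b in IUPAC[c] for b, c in zip(seq[i : i + len(rec)], rec)):
            cuts.add(i + enzyme.cut_offset)
    if scan_reverse:
        rc = revcomp(seq)
        for i in range(len(rc) - len(rec) + 1):
            if all(b in IUPAC[c] for b, c in zip(rc[i : i + len(rec)], rec)):
                cuts.add(len(seq) - (i + len(rec) - enzyme.cut_offset))
    return sorted(c for c in cuts if 0 < c < len(seq))


class TestEnzyme:
    @pytest.mark.parametrize("name", ["ApoI", "Hpy188I", "BanI", "TaqI"])
    def test_shipped_enzymes_palindromic(self, name):
        assert ENZYMES[name].is_palindromic

    def test_invalid_iupac_rejected(self):
        with pytest.raises(EnzymeError):
            Enzyme("bad", "ACGX", 1)

    def test_cut_offset_bounds(self):
        with pytest.raises(EnzymeError):
            Enzyme("bad", "ACGT", 5)


class TestFindSites:
    def test_no_site(self):
        assert find_sites("AAAA", ENZYMES["TaqI"]) == []

    def test_taqi_example(self):
        # TCGA at 0-based 3, cut T^CGA -> between-base index 4
        assert find_sites("AAATCGAAA", ENZYMES["TaqI"]) == [4]

    def test_apoi_example(self):
        # GAATTC matches R^AATTY at 0-based 1, cut after position 2 (1-based)
        assert find_sites("GGAATTCC", ENZYMES["ApoI"]) == [2]

    @pytest.mark.parametrize("name", ["ApoI", "Hpy188I", "BanI", "TaqI"])
    def test_matches_regex_scan_oracle(self, name):
        rng = np.random.default_rng(17)
        enzyme = ENZYMES[name]
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            assert find_sites(seq, enzyme) == brute_force_sites(seq, enzyme, True)

    @pytest.mark.parametrize("name", ["ApoI", "Hpy188I", "BanI", "TaqI"])
    def test_palindromy_forward_scan_suffices(self, name):
        # forward-only scanning equals forward+reverse scanning
        rng = np.random.default_rng(23)
        enzyme = ENZYMES[name]
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            assert (
                brute_force_sites(seq, enzyme, False)
                == brute_force_sites(seq, enzyme, True)
            )

    def test_nonpalindromic_reverse_strand_scanned(self):
        # contrived asymmetric recognition: ACCTGC (cut at +1)
        enz = Enzyme("AsymI", "ACCTGC", 1)
        assert not enz.is_palindromic
        seq = "TTTT" + revcomp("ACCTGC") + "TTTT"
        assert find_sites(seq, enz) == [4 + 6 - 1]


class TestDigest:
    def test_no_sites_single_fragment(self):
        res = digest("A" * 120, [ENZYMES["TaqI"]])
        assert res.fragments == [120] and res.cut_positions == []

    def test_alpha_map_amplicon_reproduces_printed_multiset(self):
        length, cuts = amplicon_map_from_config(PATTERNS, "cidA_upstream", "α")
        amplicon = build_amplicon_from_map(length, cuts, ENZYMES, seed=1)
        res = digest(amplicon, [ENZYMES["ApoI"], ENZYMES["Hpy188I"]])
        assert res.fragments == [471, 122, 57, 53, 51, 24]

    def test_conservation_over_random_sequences(self):
        rng = np.random.default_rng(3)
        enz = [ENZYMES["TaqI"], ENZYMES["ApoI"]]
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 400))))
            res = digest(seq, enz)
            assert sum(res.fragments) == len(seq)
            assert len(res.fragments) == len(res.cut_positions) + 1
            # concatenating positional fragments reconstructs the sequence
            bounds = [0, *res.cut_positions, len(seq)]
            assert "".join(seq[a:b] for a, b in zip(bounds, bounds[1:])) == seq

    def test_requires_enzyme(self):
        with pytest.raises(EnzymeError):
            digest("ACGT", [])


class TestInsilicoPcr:
    def test_primers_spanning_template(self):
        rng = np.random.default_rng(5)
        template = "".join(rng.choice(list("ACGT"), size=200))
        amplicon = insilico_pcr(template, template[:20], revcomp(template[-20:]))
        assert amplicon == template

    def test_model_cidA_amplicon_is_778(self, model):
        gene = model.genes["cidA"]
        amplicon = insilico_pcr(gene.locus_sequence(), *gene.primers)
        assert len(amplicon) == 778

    def test_model_cidB_amplicon_is_1267(self, model):
        gene = model.genes["cidB"]
        amplicon = insilico_pcr(gene.locus_sequence(), *gene.primers)
        assert len(amplicon) == 1267

    def test_mismatch_threshold(self):
        rng = np.random.default_rng(6)
        template = "".join(rng.choice(list("ACGT"), size=150))
        fwd = list(template[:20])
        fwd[10] = "A" if fwd[10] != "A" else "C"
        fwd = "".join(fwd)
        rev = revcomp(template[-20:])
        with pytest.raises(AmpliconError):
            insilico_pcr(template, fwd, rev, max_mismatch=0)
        assert insilico_pcr(template, fwd, rev, max_mismatch=1) == template

    def test_short_primer_rejected(self):
        with pytest.raises(AmpliconError):
            insilico_pcr("ACGT" * 30, "ACGTACG", "ACGTACGTACGT")

    def test_ambiguous_non_nested_amplicons(self):
        rng = np.random.default_rng(7)
        unit = "".join(rng.choice(list("ACGT"), size=60))
        spacer = "".join(rng.choice(list("ACGT"), size=40))
        template = unit + spacer + unit
        with pytest.raises(AmpliconError, match="non-nested"):
            insilico_pcr(template, unit[:15], revcomp(unit[-15:]))


class TestCallPattern:
    def setup_method(self):
        self.patterns, self.tolerance = patterns_for_test(PATTERNS, "cidB_downstream")

    def _result(self, fragments):
        return DigestResult(sorted(fragments, reverse=True), [], [], sum(fragments))

    def test_cidB_2(self):
        call = call_pattern(self._result([1028, 239]), self.patterns, self.tolerance)
        assert call.call == "2"

    def test_cidB_1(self):
        call = call_pattern(self._result([892, 239, 145]), self.patterns, self.tolerance)
        assert call.call == "1"

    def test_no_call(self):
        call = call_pattern(self._result([999]), self.patterns, self.tolerance)
        assert call.call == "no_call"

    def test_mixed_template_union(self):
        frags = [1028, 239, 892, 145]
        call = call_pattern(self._result(frags), self.patterns, self.tolerance,
                            mixed=True)
        assert call.call == "1+2"

    def test_cidA_patterns_distinguishable(self):
        patterns, tolerance = patterns_for_test(PATTERNS, "cidA_upstream")
        for pat in patterns:
            call = call_pattern(self._result(pat.fragments), patterns, tolerance)
            assert call.call == pat.name


class TestShippedPatternConfig:
    @pytest.mark.parametrize("test,name,expected", [
        ("cidA_upstream", "α", [471, 122, 57, 53, 51, 24]),
        ("cidA_upstream", "β/γ", [441, 122, 83, 57, 51, 24]),
        ("cidA_upstream", "δ", [524, 122, 57, 51, 24]),
        ("cidB_downstream", "1", [892, 239, 145]),
        ("cidB_downstream", "2", [1028, 239]),
        ("cidB_downstream", "3", [861, 239, 167]),
    ])
    def test_construct_and_digest_each_pattern(self, test, name, expected):
        length, cuts = amplicon_map_from_config(PATTERNS, test, name)
        amplicon = build_amplicon_from_map(length, cuts, ENZYMES, seed=11)
        enz = [ENZYMES[n] for n in PATTERNS["tests"][test]["enzymes"]]
        res = digest(amplicon, enz)
        assert res.fragments == sorted(expected, reverse=True)
        assert sum(res.fragments) == length

    def test_amplicon_sizes_match_published(self):
        assert PATTERNS["tests"]["cidA_upstream"]["amplicon_length"] == 778
        sizes = {
            p["amplicon_length"]
            for p in PATTERNS["tests"]["cidB_downstream"]["patterns"]
        }
        assert sizes == {1267, 1276}


def derived_patterns(model, gene_id):
    """Patterns derived by digesting each pure-variant amplicon of the
    synthetic gene model, collapsing identical fragment multisets."""
    gene = model.genes[gene_id]
    enz = [model.enzymes[n] for n in gene.test_enzymes]
    by_label: dict[str, Counter] = {}
    discr_region = "upstream" if gene_id == "cidA" else "downstream"
    for up in gene.pools["upstream"].alleles:
        for down in gene.pools["downstream"].alleles:
            cds, _ = make_variant(gene.config, up, down, gene.pools)
            frags = Counter(digest(gene.amplicon(cds), enz).fragments)
            label = up if discr_region == "upstream" else down
            if label in by_label:
                assert by_label[label] == frags, "non-discriminating region leaked"
            by_label[label] = frags
    merged: dict[str, list[int]] = {}
    for label, frags in by_label.items():
        partner = next(
            (k for k, v in merged.items() if Counter(v) == frags), None
        )
        if partner is not None:
            merged[f"{partner}/{label}"] = merged.pop(partner)
        else:
            merged[label] = sorted(frags.elements(), reverse=True)
    return [ReferencePattern(name, frags) for name, frags in merged.items()]


class TestSequenceRflpConcordance:
    def test_beta_gamma_collapse_to_one_class(self, model):
        patterns = derived_patterns(model, "cidA")
        names = {p.name for p in patterns}
        assert "β/γ" in names
        assert len(patterns) == 3  # α, β/γ, δ

    @pytest.mark.parametrize("gene_id", ["cidA", "cidB"])
    def test_rflp_call_concordant_with_sequence_typing(self, model, gene_id):
        gene = model.genes[gene_id]
        enz = [model.enzymes[n] for n in gene.test_enzymes]
        patterns = derived_patterns(model, gene_id)
        for up in gene.pools["upstream"].alleles:
            for down in gene.pools["downstream"].alleles:
                cds, name = make_variant(gene.config, up, down, gene.pools)
                amplicon = insilico_pcr(gene.locus_sequence(cds), *gene.primers)
                res = digest(amplicon, enz)
                call = call_pattern(res, patterns, tolerance=5)
                truth = up if gene_id == "cidA" else down
                assert truth in call.call.split("/")
                # delta-presence concordance with sequence-based typing
                if gene_id == "cidA":
                    assert (call.call == "δ") == (name.upstream == "δ")
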