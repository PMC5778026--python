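"""In-silico PCR and restriction digestion with fragment-pattern calling.

The shipped enzyme set and reference fragment patterns live in
``cidscope/data/enzymes.json`` and ``cidscope/data/patterns.json``; both are
plain editable config files, loadable through :func:`load_enzymes` and
:func:`load_patterns`.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import AmpliconError, EnzymeError
from .util import IUPAC, hamming, iupac_regex, revcomp


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme as a degenerate recognition and a cut offset.

    ``cut_offset`` counts bases after the recognition start on the scanned
    strand; a site starting at sequence position ``p`` cuts between bases
    ``p + cut_offset - 1`` and ``p + cut_offset`` (0-based between-base index
    ``p + cut_offset``).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        for code in self.recognition.upper():
            if code not in IUPAC:
                raise EnzymeError(
                    f"{self.name}: invalid IUPAC code {code!r} in recognition"
                )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise EnzymeError(f"{self.name}: cut_offset outside recognition site")

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.recognition.upper()) == self.recognition.upper()

    def concrete_site(self, rng: np.random.Generator | None = None) -> str:
        """One concrete realisation of the degenerate recognition."""
        out = []
        for code in self.recognition.upper():
            bases = IUPAC[code]
            if len(bases) == 1:
                out.append(bases)
            elif rng is None:
                out.append(bases[0])
            else:
                out.append(bases[int(rng.integers(len(bases)))])
        return "".join(out)


@dataclass
class DigestResult:
    """Outcome of digesting a linear amplicon."""

    fragments: list[int]          # descending bp
    cut_positions: list[int]      # 0-based between-base indices, sorted
    enzymes: list[str]
    length: int

    @property
    def fragments_positional(self) -> list[int]:
        """Fragment lengths in positional (left-to-right) order."""
        bounds = [0, *self.cut_positions, self.length]
        return [b - a for a, b in zip(bounds, bounds[1:])]


@dataclass
class ReferencePattern:
    name: str
    fragments: list[int]
    non_discriminating: frozenset[int] = field(default_factory=frozenset)

    @property
    def discriminating(self) -> list[int]:
        return [f for f in self.fragments if f not in self.non_discriminating]


@dataclass
class PatternCall:
    call: str                 # pattern name, "name1+name2", "ambiguous", "no_call"
    matches: list[str]
    fragments: list[int]


def load_enzymes(path: str | None = None) -> dict[str, Enzyme]:
    """Load the enzyme config (shipped default when ``path`` is None)."""
    if path is None:
        text = resources.files("cidscope.data").joinpath("enzymes.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    return {
        e["name"]: Enzyme(e["name"], e["recognition"], e["cut_offset"])
        for e in raw["enzymes"]
    }


def load_patterns(path: str | None = None) -> dict:
    """Load the raw pattern config (shipped default when ``path`` is None)."""
    if path is None:
        text = resources.files("cidscope.data").joinpath("patterns.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return json.loads(text)


def patterns_for_test(config: dict, test: str) -> tuple[list[ReferencePattern], int]:
    """Extract :class:`ReferencePattern` objects and tolerance for one test."""
    spec = config["tests"][test]
    pats = [
        ReferencePattern(
            p["name"], list(p["fragments"]), frozenset(p.get("non_discriminating", ()))
        )
        for p in spec["patterns"]
    ]
    return pats, int(spec.get("tolerance_bp", 5))


def find_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """All cut positions (0-based between-base indices) on a linear sequence.

    The forward strand is scanned; non-palindromic recognitions are also
    scanned on the reverse complement and their cuts mapped back. Positions
    at or beyond the sequence ends are dropped; duplicates are merged.
    """
    seq = sequence.upper()
    rx = iupac_regex(enzyme.recognition)
    cuts = {m.start() + enzyme.cut_offset for m in rx.finditer(seq)}
    if not enzyme.is_palindromic:
        n = len(seq)
        for m in iupac_regex(enzyme.recognition).finditer(revcomp(seq)):
            # a cut at rc-coordinate m.start()+offset sits at forward
            # between-base coordinate n - (m.start() + offset)
            cuts.add(n - (m.start() + enzyme.cut_offset))
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(sequence: str, enzymes: list[Enzyme]) -> DigestResult:
    """Double (or multi-) digestion of a linear amplicon."""
    if not enzymes:
        raise EnzymeError("digest requires at least one enzyme")
    cuts: set[int] = set()
    for enz in enzymes:
        cuts.update(find_sites(sequence, enz))
    ordered = sorted(cuts)
    bounds = [0, *ordered, len(sequence)]
    fragments = sorted((b - a for a, b in zip(bounds, bounds[1:])), reverse=True)
    return DigestResult(fragments, ordered, [e.name for e in enzymes], len(sequence))


def _scan_primer(template: str, primer: str, max_mismatch: int) -> list[int]:
    hits = []
    lp = len(primer)
    for i in range(len(template) - lp + 1):
        if hamming(template[i : i + lp], primer) <= max_mismatch:
            hits.append(i)
    return hits


def insilico_pcr(
    template: str,
    forward_primer: str,
    reverse_primer: str,
    max_mismatch: int = 0,
) -> str:
    """Amplify the span from the forward primer's 5' start to the reverse
    primer's 5' start (matched as its reverse complement), inclusive of both
    primer footprints. The leftmost valid pair wins; multiple non-nested
    candidate amplicons are an error."""
    if min(len(forward_primer), len(reverse_primer)) < 12:
        raise AmpliconError("primers must be at least 12 nt")
    template = template.upper()
    fwd_hits = _scan_primer(template, forward_primer.upper(), max_mismatch)
    rev_hits = _scan_primer(template, revcomp(reverse_primer.upper()), max_mismatch)
    if not fwd_hits or not rev_hits:
        raise AmpliconError("no primer pair found on template")
    lr = len(reverse_primer)
    spans = []
    for f in fwd_hits:
        ends = [r + lr for r in rev_hits if r >= f + len(forward_primer)]
        if ends:
            spans.append((f, min(ends)))
    if not spans:
        raise AmpliconError("no primer pair found on template")
    spans = sorted(set(spans))
    for (a1, b1) in spans:
        for (a2, b2) in spans:
            nested = (a1 <= a2 and b2 <= b1) or (a2 <= a1 and b1 <= b2)
            if not nested:
                raise AmpliconError(f"multiple non-nested candidate amplicons: {spans}")
    start, end = spans[0]
    return template[start:end]


def _bands(lengths: list[int], tolerance: int) -> list[int]:
    """Collapse a fragment list to distinct band sizes (co-migration merge)."""
    out: list[int] = []
    for f in sorted(lengths):
        if not out or f - out[-1] > tolerance:
            out.append(f)
    return out


def _match_pattern(
    observed: list[int], pattern: ReferencePattern, tolerance: int
) -> bool:
    """One-to-one match: every discriminating expected fragment must pair with
    a distinct observed fragment within tolerance; leftover observed fragments
    must each lie within tolerance of some non-discriminating expected one."""
    remaining = sorted(observed)
    for exp in sorted(pattern.discriminating, reverse=True):
        hit = None
        for i, obs in enumerate(remaining):
            if abs(obs - exp) <= tolerance:
                hit = i
        if hit is None:
            return False
        remaining.pop(hit)
    nondisc = sorted(pattern.non_discriminating)
    for obs in remaining:
        if not any(abs(obs - nd) <= tolerance for nd in nondisc):
            return False
    return True


def _match_mixed(
    observed: list[int],
    pat_a: ReferencePattern,
    pat_b: ReferencePattern,
    tolerance: int,
) -> bool:
    """Band-set match against the union of two patterns (mixed template)."""
    obs_bands = _bands(observed, tolerance)
    exp_all = _bands(list(pat_a.fragments) + list(pat_b.fragments), tolerance)
    exp_disc = _bands(pat_a.discriminating + pat_b.discriminating, tolerance)
    for exp in exp_disc:
        if not any(abs(obs - exp) <= tolerance for obs in obs_bands):
            return False
    for obs in obs_bands:
        if not any(abs(obs - exp) <= tolerance for exp in exp_all):
            return False
    return True


def call_pattern(
    result: DigestResult,
    patterns: list[ReferencePattern],
    tolerance: int = 5,
    mixed: bool = False,
) -> PatternCall:
    """Call the unique reference pattern matching a digest, or a unique pair
    of patterns when ``mixed`` is enabled (templates carrying two variants)."""
    if not patterns:
        raise EnzymeError("call_pattern requires at least one reference pattern")
    observed = list(result.fragments)
    single = [p.name for p in patterns if _match_pattern(observed, p, tolerance)]
    if len(single) == 1:
        return PatternCall(single[0], single, observed)
    if len(single) > 1:
        return PatternCall("ambiguous", single, observed)
    if mixed:
        pairs = []
        for i, pa in enumerate(patterns):
            for pb in patterns[i + 1 :]:
                if _match_mixed(observed, pa, pb, tolerance):
                    pairs.append(f"{pa.name}+{pb.name}")
        if len(pairs) == 1:
            return PatternCall(pairs[0], pairs, observed)
        if len(pairs) > 1:
            return PatternCall("ambiguous", pairs, observed)
    return PatternCall("no_call", [], observed)


def build_amplicon_from_map(
    length: int,
    cut_map: list[tuple[int, str]],
    enzymes: dict[str, Enzyme],
    seed: int = 0,
) -> str:
    """Construct a synthetic amplicon whose digestion yields exactly the cuts
    in ``cut_map`` (absolute between-base positions with the cutting enzyme).

    The backbone is random sequence scrubbed of all configured enzymes'
    sites; a concrete recognition instance is then written at each requested
    cut. Raises if planting produced spurious or missing cuts.
    """
    rng = np.random.default_rng(seed)
    enz_list = list(enzymes.values())
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        seq = scrub_sites(seq, enz_list, rng)
        chars = list(seq)
        ok = True
        for pos, name in cut_map:
            enz = enzymes[name]
            start = pos - enz.cut_offset
            if start < 0 or start + len(enz.recognition) > length:
                raise EnzymeError(f"cut at {pos} ({name}) does not fit in amplicon")
            site = enz.concrete_site()
            chars[start : start + len(site)] = site
        planted = "".join(chars)
        expected = sorted(pos for pos, _ in cut_map)
        got: set[int] = set()
        for enz in enz_list:
            got.update(find_sites(planted, enz))
        if sorted(got) == expected:
            return planted
        ok = False
    raise EnzymeError("could not construct a clean amplicon for the cut map")


def scrub_sites(
    sequence: str, enzymes: list[Enzyme], rng: np.random.Generator
) -> str:
    """Mutate random in-site bases until no enzyme recognises any site."""
    chars = list(sequence.upper())
    for _ in range(200):
        dirty = False
        seq = "".join(chars)
        for enz in enzymes:
            rx = iupac_regex(enz.recognition)
            rec = enz.recognition.upper()
            # mutate the most constrained site position to a base outside its
            # IUPAC class, which is guaranteed to destroy the match
            off = min(range(len(rec)), key=lambda i: len(IUPAC[rec[i]]))
            for m in rx.finditer(seq):
                dirty = True
                i = m.start() + off
                choices = [b for b in "ACGT" if b not in IUPAC[rec[off]]]
                chars[i] = choices[int(rng.integers(len(choices)))]
        if not dirty:
            return "".join(chars)
    raise EnzymeError("site scrubbing did not converge")


def amplicon_map_from_config(
    config: dict, test: str, pattern_name: str
) -> tuple[int, list[tuple[int, str]]]:
    """Turn a shipped pattern's positional fragment order into an absolute cut
    map usable by :func:`build_amplicon_from_map`."""
    spec = config["tests"][test]
    for p in spec["patterns"]:
        if p["name"] == pattern_name:
            length = int(p.get("amplicon_length", spec.get("amplicon_length")))
            cuts = []
            pos = 0
            for frag, enz in zip(p["order"][:-1], p["cut_enzymes"]):
                pos += frag
                cuts.append((pos, enz))
            if pos + p["order"][-1] != length:
                raise EnzymeError(
                    f"pattern {pattern_name}: fragments sum to {pos + p['order'][-1]},"
                    f" amplicon is {length}"
                )
            if Counter(p["order"]) != Counter(p["fragments"]):
                raise EnzymeError(f"pattern {pattern_name}: order != fragments multiset")
            return length, cuts
    raise EnzymeError(f"pattern {pattern_name!r} not found in test {test!r}")
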