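"""In-silico PCR: primer binding, amplification, band patterns, nested PCR.

Binding sites are found on both strands with a bounded number of mismatches
and an exact match required over the 3'-terminal window (polymerase
extension is intolerant of 3' mismatches).  Amplicons form between a
forward-oriented and a reverse-oriented site of a primer pair when the
product does not exceed the assay's maximum amplifiable length — the length
cutoff is what makes gap-PCR allele-specific: on the normal allele the
primers flanking a deletion are too far apart to amplify.

Observed band patterns apply comigration merging: products whose sizes
differ by less than the merge tolerance (default 2%, mimicking agarose-gel
resolution) are reported as a single band carrying all contributing labels.
This is what makes the HKαα/αα vs -α3.7/αα degeneracy emergent rather than
hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hkalpha.cluster import (
    HkaaCompositionConfig,
    ReferenceCluster,
    StructuralAllele,
    build_allele_library,
    build_synthetic_reference,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not 15 <= len(self.sequence) <= 35:
            raise ValueError(f"primer {self.name}: length must be 15-35 nt")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"primer {self.name}: alphabet must be A/C/G/T")


@dataclass(frozen=True)
class MismatchPolicy:
    max_mismatches: int = 1
    three_prime_exact: int = 3  # 3'-terminal window requiring exact match


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    label: str  # expected-product label, e.g. "a3.7-junction"


@dataclass(frozen=True)
class Assay:
    name: str
    primer_pairs: tuple[PrimerPair, ...]
    max_product_bp: int = 6000
    policy: MismatchPolicy = MismatchPolicy()
    cycling_metadata: str = ""  # recorded verbatim; computationally inert

    def __post_init__(self) -> None:
        if self.max_product_bp <= 0:
            raise ValueError("max_product_bp must be positive")


@dataclass(frozen=True)
class BindingSite:
    template: str
    strand: str  # "+" or "-"
    start: int  # 1-based position of the site's leftmost base on the template
    mismatches: int

    def five_prime(self, primer_len: int) -> int:
        """1-based template position of the primer's 5' end."""
        return self.start if self.strand == "+" else self.start + primer_len - 1


@dataclass(frozen=True)
class Amplicon:
    assay: str
    template: str
    label: str
    length: int
    sequence: str


@dataclass
class BandPattern:
    assay: str
    # sorted (size, frozenset of labels) after comigration merging
    bands: list[tuple[int, frozenset[str]]]
    merge_tolerance: float = 0.02

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(size for size, _ in self.bands)


def _window_match_counts(template: bytes, probe: bytes) -> np.ndarray:
    """Match counts of ``probe`` against every window of ``template``."""
    t = np.frombuffer(template, dtype=np.uint8)
    p = np.frombuffer(probe, dtype=np.uint8)
    n, m = len(t), len(p)
    if n < m:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    return (windows == p).sum(axis=1)


def find_binding_sites(
    template: str,
    primer: Primer,
    policy: MismatchPolicy = MismatchPolicy(),
    template_name: str = "template",
) -> list[BindingSite]:
    """All binding sites of the primer on both strands of the template.

    A site requires at most ``policy.max_mismatches`` mismatches overall and
    an exact match over the primer's 3'-terminal ``three_prime_exact`` bases.
    N positions on the template never match.  Sites are sorted by position.
    """
    if not template:
        raise ValueError("template must be non-empty")
    m = len(primer.sequence)
    w = min(policy.three_prime_exact, m)
    sites: list[BindingSite] = []
    tb = template.encode("ascii")

    # + strand: primer matches template as-is; 3' end is the rightmost base.
    probe = primer.sequence.encode("ascii")
    counts = _window_match_counts(tb, probe)
    tail = _window_match_counts(tb, probe[m - w :]) if w else None
    for i in np.flatnonzero(counts >= m - policy.max_mismatches):
        if w and tail[i + m - w] != w:
            continue
        sites.append(BindingSite(template_name, "+", int(i) + 1, int(m - counts[i])))

    # - strand: the primer binds the reverse complement; on the given strand
    # the site reads as revcomp(primer), with the primer 3' end leftmost.
    probe_rc = revcomp(primer.sequence).encode("ascii")
    counts = _window_match_counts(tb, probe_rc)
    head = _window_match_counts(tb, probe_rc[:w]) if w else None
    for i in np.flatnonzero(counts >= m - policy.max_mismatches):
        if w and head[i] != w:
            continue
        sites.append(BindingSite(template_name, "-", int(i) + 1, int(m - counts[i])))

    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def amplify(templates: dict[str, str], assay: Assay) -> list[Amplicon]:
    """Predict all amplicons of the assay's primer pairs on the templates.

    One amplicon per (template, primer pair, convergent site pair): a
    forward-oriented site upstream of a reverse-oriented site, product length
    (distance between the two primer 5' ends + 1) at most max_product_bp.
    Either primer of the pair may provide either orientation.
    """
    out: list[Amplicon] = []
    for tname, seq in templates.items():
        for pair in assay.primer_pairs:
            sites_f = find_binding_sites(seq, pair.forward, assay.policy, tname)
            sites_r = find_binding_sites(seq, pair.reverse, assay.policy, tname)
            for a, b in ((x, y) for x in sites_f for y in sites_r):
                if a.strand == "+" and b.strand == "-":
                    plus, minus = a, b
                    plus_len, minus_len = len(pair.forward.sequence), len(pair.reverse.sequence)
                elif a.strand == "-" and b.strand == "+":
                    plus, minus = b, a
                    plus_len, minus_len = len(pair.reverse.sequence), len(pair.forward.sequence)
                else:
                    continue
                p5 = plus.five_prime(plus_len)
                m5 = minus.five_prime(minus_len)
                length = m5 - p5 + 1
                if length < plus_len + minus_len:  # overlapping/divergent
                    continue
                if length > assay.max_product_bp:
                    continue
                out.append(
                    Amplicon(assay.name, tname, pair.label, length, seq[p5 - 1 : m5])
                )
    out.sort(key=lambda a: (a.template, a.label, a.length))
    return out


def merge_bands(
    amplicons: list[Amplicon], assay_name: str, merge_tolerance: float = 0.02
) -> BandPattern:
    """Comigration merging of amplicon sizes into observed gel bands."""
    if not amplicons:
        return BandPattern(assay_name, [], merge_tolerance)
    items = sorted((a.length, a.label) for a in amplicons)
    bands: list[tuple[int, frozenset[str]]] = []
    cur_sizes = [items[0][0]]
    cur_labels = {items[0][1]}
    for size, label in items[1:]:
        if (size - cur_sizes[0]) < merge_tolerance * size:
            cur_sizes.append(size)
            cur_labels.add(label)
        else:
            bands.append((int(round(np.mean(cur_sizes))), frozenset(cur_labels)))
            cur_sizes, cur_labels = [size], {label}
    bands.append((int(round(np.mean(cur_sizes))), frozenset(cur_labels)))
    return BandPattern(assay_name, bands, merge_tolerance)


def patterns_equal(a: BandPattern, b: BandPattern, tolerance: float = 0.02) -> bool:
    """Two gel patterns are indistinguishable when bands pair within tolerance."""
    if len(a.bands) != len(b.bands):
        return False
    return all(
        abs(sa - sb) < tolerance * max(sa, sb) or sa == sb
        for (sa, _), (sb, _) in zip(a.bands, b.bands)
    )


# --------------------------------------------------------------------------
# Default assay panel on the synthetic reference.
#
# The panel's primer sequences are extracted from the synthetic reference at
# fixed coordinates: junction-flanking pairs for each deletion (gap-PCR), a
# normal-alpha2 control pair, the anti4.2-junction pair, and an outer
# round-1 pair for the two-round nested assay whose product on the HKαα
# allele is exactly 4,500 bp.  For real references, user primer files may be
# supplied instead.  The round-1 primers printed for the unrelated-carriers
# assay (ZW-F/ZW-R) are packaged verbatim for use with real sequence.
# --------------------------------------------------------------------------

ZW_F = Primer("ZW-F", "CTCGGTAGCCGTTCCTCCTGC")
ZW_R = Primer("ZW-R", "AAGTCTGGGAATAAAACTCGGGA")

# (name, plus-strand 1-based ref interval, orientation)
_FIXTURE_PRIMER_COORDS = {
    "a37-F": ((169_000, 169_020), "+"),
    "a37-R": ((181_151, 181_171), "-"),
    "a42-F": ((166_701, 166_721), "+"),
    "a42-R": ((175_701, 175_721), "-"),
    "sea-F": ((166_751, 166_771), "+"),
    "sea-R": ((184_480, 184_500), "-"),
    "thai-F": ((159_211, 159_231), "+"),
    "thai-R": ((181_951, 181_971), "-"),
    "ctl-F": ((167_701, 167_721), "+"),
    "ctl-R": ((168_801, 168_821), "-"),
    "anti42-F": ((175_101, 175_121), "+"),
    "anti42-R": ((167_201, 167_221), "-"),
    "round1-F": ((174_801, 174_821), "+"),
    "round1-R": ((181_628, 181_648), "-"),
}

CYCLING_ROUND1 = (
    "95C 5min; 5x (94C 30s, 70C 30s touchdown -1C/cycle, 72C 4min); "
    "35x (94C 30s, 65C 30s, 72C 4min); 72C 5min"
)
CYCLING_ROUND2 = (
    "95C 5min; 5x (94C 30s, 64C 30s touchdown -1C/cycle, 72C 4min); "
    "35x (94C 30s, 59C 30s, 72C 4min); 72C 5min"
)


def fixture_primers(ref: ReferenceCluster | None = None) -> dict[str, Primer]:
    """Panel primers extracted from the synthetic reference coordinates."""
    ref = ref or build_synthetic_reference()
    primers = {}
    for name, ((s, e), strand) in _FIXTURE_PRIMER_COORDS.items():
        seq = ref.slice(s, e)
        primers[name] = Primer(name, seq if strand == "+" else revcomp(seq))
    return primers


def default_assays(ref: ReferenceCluster | None = None) -> dict[str, Assay]:
    """The study's assay panel built against the synthetic reference."""
    p = fixture_primers(ref)
    multiplex = Assay(
        "multiplex_deletional",
        (
            PrimerPair(p["a37-F"], p["a37-R"], "a3.7-junction"),
            PrimerPair(p["a42-F"], p["a42-R"], "a4.2-junction"),
            PrimerPair(p["sea-F"], p["sea-R"], "SEA-junction"),
            PrimerPair(p["thai-F"], p["thai-R"], "THAI-junction"),
            PrimerPair(p["ctl-F"], p["ctl-R"], "alpha2-control"),
        ),
    )
    anti42 = Assay(
        "anti42_junction",
        (PrimerPair(p["anti42-F"], p["anti42-R"], "anti4.2-junction"),),
    )
    round1 = Assay(
        "nested_round1",
        (PrimerPair(p["round1-F"], p["round1-R"], "hkaa-round1"),),
        cycling_metadata=CYCLING_ROUND1,
    )
    round2 = Assay(
        "nested_round2",
        (
            PrimerPair(p["a37-F"], p["a37-R"], "a3.7-junction"),
            PrimerPair(p["anti42-F"], p["anti42-R"], "anti4.2-junction"),
        ),
        cycling_metadata=CYCLING_ROUND2,
    )
    return {
        "multiplex_deletional": multiplex,
        "anti42_junction": anti42,
        "nested_round1": round1,
        "nested_round2": round2,
    }


@dataclass
class NestedResult:
    round1_amplicons: list[Amplicon]
    round2_pattern: BandPattern
    positive: bool
    detected_junctions: frozenset[str] = field(default_factory=frozenset)


class PCRPanel:
    """Assay panel bound to an allele library for diploid genotypes."""

    def __init__(
        self,
        ref: ReferenceCluster | None = None,
        hkaa_cfg: HkaaCompositionConfig | None = None,
    ):
        self.ref = ref or build_synthetic_reference()
        self.alleles: dict[str, StructuralAllele] = build_allele_library(
            self.ref, hkaa_cfg, include_anti37=True
        )
        self.assays = default_assays(self.ref)
        self._multiplex_cache: dict[tuple[str, str], BandPattern] = {}

    def _templates(self, genotype: tuple[str, str]) -> dict[str, str]:
        t = {}
        for name in genotype:
            if name not in self.alleles:
                raise KeyError(f"unknown allele {name!r}")
            t[name] = self.alleles[name].sequence
        return t

    def run_multiplex(self, genotype: tuple[str, str]) -> BandPattern:
        """Single-tube multiplex deletional gap-PCR on a diploid genotype."""
        key = tuple(sorted(genotype))
        if key not in self._multiplex_cache:
            assay = self.assays["multiplex_deletional"]
            amps = amplify(self._templates(key), assay)
            self._multiplex_cache[key] = merge_bands(amps, assay.name)
        return self._multiplex_cache[key]

    def run_anti42(self, genotype: tuple[str, str]) -> BandPattern:
        assay = self.assays["anti42_junction"]
        return merge_bands(amplify(self._templates(genotype), assay), assay.name)

    def run_nested(self, genotype: tuple[str, str]) -> NestedResult:
        """Two-round nested PCR: round 2 runs on round-1 products only.

        A sample is HKαα-positive iff round 1 yields the long product and
        round 2 detects both the -α3.7 and the anti4.2 junctions on it —
        proving the two junctions lie in cis on one molecule.
        """
        r1 = self.assays["nested_round1"]
        r2 = self.assays["nested_round2"]
        round1 = amplify(self._templates(genotype), r1)
        templates2 = {
            f"round1:{a.template}:{i}": a.sequence for i, a in enumerate(round1)
        }
        round2 = amplify(templates2, r2) if templates2 else []
        pattern = merge_bands(round2, r2.name)
        junctions = frozenset(a.label for a in round2)
        # cis proof: both junctions must be detected on one round-1 molecule
        both = {"a3.7-junction", "anti4.2-junction"}
        per_template: dict[str, set[str]] = {}
        for a in round2:
            per_template.setdefault(a.template, set()).add(a.label)
        positive = any(both <= labels for labels in per_template.values())
        return NestedResult(round1, pattern, positive, junctions)
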