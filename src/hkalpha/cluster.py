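"""Synthetic alpha-globin cluster and breakpoint-defined structural alleles.

The alpha-globin gene cluster carries, in order, 5'-ζ-ψζ1-ψα2-ψα1-α2-α1-θ-3',
with the two functional alpha genes embedded in duplicated homologous regions
containing the X, Y and Z homology boxes.  Unequal crossover between the Z
boxes produces the rightward single-gene deletion (-α3.7) and its reciprocal
triplication (αααanti3.7); crossover between the X boxes produces the
leftward deletion (-α4.2) and the αααanti4.2 triplication.  The HKαα allele
is a compound allele carrying both the -α3.7 and the αααanti4.2 junctions in
cis, joined through a short "special" segment, with a net normal complement
of two functional alpha genes.

Coordinates are 1-based inclusive throughout; the default synthetic
reference is laid out so that the published coordinates 171,116 / 171,235 /
171,223 / 171,882 of the special segment are directly addressable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

# Fixed functional alpha-gene dose per named structural allele.
FUNCTIONAL_ALPHA_COUNT = {
    "AA": 2,
    "D37": 1,
    "D42": 1,
    "SEA": 0,
    "THAI": 0,
    "ANTI42": 3,
    "ANTI37": 3,
    "HKAA": 2,
}

# Human-readable genotype rendering, ordered by conventional severity-first
# display (compound allele first, then deletions, then triplication, then
# the normal allele) as used in clinical genotype strings.
ALLELE_DISPLAY = {
    "HKAA": "HKαα",
    "D37": "-α3.7",
    "D42": "-α4.2",
    "SEA": "--SEA",
    "THAI": "--THAI",
    "ANTI42": "αααanti4.2",
    "ANTI37": "αααanti3.7",
    "AA": "αα",
}
ALLELE_RANK = {name: i for i, name in enumerate(ALLELE_DISPLAY)}


class ConfigurationError(ValueError):
    """Raised when generator or composition parameters are inconsistent."""


@dataclass(frozen=True)
class FeatureAnnotation:
    """A labelled interval on the reference (gene, homology box or motif)."""

    label: str
    start: int  # 1-based inclusive
    end: int
    kind: str  # {"gene", "homology_box", "junction_motif"}

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigurationError(
                f"feature {self.label}: start {self.start} > end {self.end}"
            )
        if self.kind not in ("gene", "homology_box", "junction_motif"):
            raise ConfigurationError(f"unknown feature kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


GENE_ORDER = ("zeta", "psi_zeta1", "psi_alpha2", "psi_alpha1", "alpha2", "alpha1", "theta")


@dataclass
class ReferenceCluster:
    """Coordinate-addressed alpha-cluster sequence with annotated features."""

    name: str
    sequence: str
    coordinate_origin: int
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def end(self) -> int:
        return self.coordinate_origin + len(self.sequence) - 1

    def validate(self) -> None:
        lo, hi = self.coordinate_origin, self.end
        for f in self.features:
            if f.start < lo or f.end > hi:
                raise ConfigurationError(
                    f"feature {f.label} [{f.start},{f.end}] outside "
                    f"reference [{lo},{hi}]"
                )
        seen = set()
        for f in self.features:
            key = (f.label, f.kind)
            if key in seen:
                raise ConfigurationError(f"duplicate feature {key}")
            seen.add(key)
        genes = [f for f in self.features if f.kind == "gene"]
        by_label = {f.label: f for f in genes}
        ordered = [by_label[g] for g in GENE_ORDER if g in by_label]
        starts = [f.start for f in ordered]
        if starts != sorted(starts):
            raise ConfigurationError("genes out of canonical cluster order")
        # genes must not overlap one another
        intervals = sorted((f.start, f.end, f.label) for f in genes)
        for (s1, e1, l1), (s2, e2, l2) in zip(intervals, intervals[1:]):
            if s2 <= e1:
                raise ConfigurationError(f"genes {l1} and {l2} overlap")

    def feature(self, label: str, kind: str | None = None) -> FeatureAnnotation:
        for f in self.features:
            if f.label == label and (kind is None or f.kind == kind):
                return f
        raise KeyError(f"no feature {label!r}" + (f" of kind {kind!r}" if kind else ""))

    def slice(self, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive coordinate interval [start, end]."""
        if start > end:
            raise ValueError(f"empty/inverted interval [{start},{end}]")
        if start < self.coordinate_origin or end > self.end:
            raise ValueError(
                f"interval [{start},{end}] outside reference "
                f"[{self.coordinate_origin},{self.end}]"
            )
        off = self.coordinate_origin
        return self.sequence[start - off : end - off + 1]


@dataclass(frozen=True)
class CrossoverSpec:
    """An unequal crossover between two identical homology boxes."""

    box_a: str  # upstream box label, e.g. "Z-alpha2"
    box_b: str  # downstream box label, e.g. "Z-alpha1"
    breakpoint_rule: str = "midpoint"  # or "fixed_offset"
    offset: int = 0  # bp into the box when rule is fixed_offset


@dataclass(frozen=True)
class Segment:
    """One provenance segment of a constructed allele.

    ``source`` is "ref" for a reference interval (start/end are 1-based
    inclusive reference coordinates) or "N" for an undetected run of the
    given ``length``.
    """

    label: str
    source: str
    start: int = 0
    end: int = 0
    length: int = 0

    def materialize(self, ref: ReferenceCluster) -> str:
        if self.source == "N":
            return "N" * self.length
        return ref.slice(self.start, self.end)


@dataclass
class StructuralAllele:
    """A named haplotype sequence with breakpoint provenance and gene dose."""

    name: str
    sequence: str
    provenance: list[Segment]
    functional_alpha_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.functional_alpha_count <= 3:
            raise ValueError("functional_alpha_count must be in [0, 3]")

    def check_provenance(self, ref: ReferenceCluster) -> bool:
        """Provenance segments must concatenate to the stored sequence."""
        return "".join(s.materialize(ref) for s in self.provenance) == self.sequence


@dataclass(frozen=True)
class HkaaCompositionConfig:
    """Composition of the HKαα allele from its three sections.

    The special section is assembled as section 1 (default reference
    coordinates 171,116-171,235), an undetected run of ``gap_length`` N
    (default 22 bp), and section 2 (default 171,223-171,882), for a default
    total of 802 bp.  The published section intervals overlap by 13 bp; the
    overlap is reproduced verbatim rather than arbitrated.
    """

    section1_interval: tuple[int, int] = (171_116, 171_235)
    section2_interval: tuple[int, int] = (171_223, 171_882)
    gap_length: int = 22
    section_order: tuple[str, ...] = ("anti42_segment", "special_segment", "d37_segment")
    # reference intervals concatenated to form the two junction segments
    anti42_segment_intervals: tuple[tuple[int, int], ...] = (
        (173_201, 175_500),
        (167_001, 168_900),
    )
    d37_segment_intervals: tuple[tuple[int, int], ...] = (
        (168_851, 169_250),
        (180_951, 181_700),
    )

    def __post_init__(self) -> None:
        for label, (s, e) in (
            ("section1", self.section1_interval),
            ("section2", self.section2_interval),
        ):
            if e < s:
                raise ConfigurationError(f"{label} end {e} < start {s}")
        if self.gap_length < 0:
            raise ConfigurationError("gap_length must be >= 0")
        if set(self.section_order) != {"anti42_segment", "special_segment", "d37_segment"}:
            raise ConfigurationError("section_order must permute the three sections")


# --------------------------------------------------------------------------
# Default generator layout.
#
# The default reference spans coordinates 158,001..184,600 (26,600 bp) so the
# published special-segment coordinates fall in the spacer between the two
# duplicated alpha regions.  Paired homology boxes are byte-identical; all
# other sequence is i.i.d. random given the seed.
# --------------------------------------------------------------------------

DEFAULT_LAYOUT = {
    "coordinate_origin": 158_001,
    "length": 26_600,
    "genes": {
        "zeta": (158_101, 158_600),
        "psi_zeta1": (158_701, 158_900),
        "psi_alpha2": (159_001, 159_200),
        "psi_alpha1": (159_301, 159_500),
        "alpha2": (167_901, 168_742),
        "alpha1": (177_601, 178_400),
        "theta": (181_701, 181_900),
    },
    "boxes": {
        # paired boxes must have identical lengths (and get identical sequence)
        "X-alpha2": (166_901, 167_100),
        "X-alpha1": (175_401, 175_600),
        "Y-alpha2": (167_401, 167_600),
        "Y-alpha1": (176_401, 176_600),
        "Z-alpha2": (169_101, 169_400),
        "Z-alpha1": (180_801, 181_100),
    },
    # double-gene deletion breakpoints (not published; chosen so both alpha
    # genes are removed)
    "sea_interval": (166_901, 181_100),
    "thai_interval": (159_301, 181_900),
}

BOX_PAIRS = (("X-alpha2", "X-alpha1"), ("Y-alpha2", "Y-alpha1"), ("Z-alpha2", "Z-alpha1"))

# Splice points of the composed HKαα allele that abut unique (non-repeat)
# sequence are generated microhomology-free: the reference base just outside
# each special-segment edge must differ from the base the neighbouring
# junction segment contributes at the same assembled position.  Without this
# the breakpoint would be ambiguous by up to the chance microhomology run and
# structural decomposition could not recover the published coordinates
# exactly.  Each pair is (kept_position, adjusted_position); the adjusted
# position lies in anonymous spacer and is rotated to the next base when the
# two collide.  (Crossover breakpoints inside the X/Y/Z boxes are the
# opposite case: deliberately unidentifiable within the perfect repeat.)
DEFAULT_DISTINCT_PAIRS = (
    (168_900, 171_115),  # anti4.2-segment end vs base left of special upstream
    (168_851, 171_883),  # -α3.7-segment start vs base right of special downstream
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def build_synthetic_reference(
    config: dict | None = None, seed: int = 0
) -> ReferenceCluster:
    """Build the deterministic synthetic alpha-cluster reference.

    Paired X/Y/Z homology boxes are written with identical sequence so that
    unequal crossover between them is seamless, exactly as in the real
    cluster where the crossover breakpoint is unidentifiable inside the
    perfect repeat.
    """
    cfg = dict(DEFAULT_LAYOUT)
    if config:
        cfg.update(config)
    origin = cfg["coordinate_origin"]
    length = cfg["length"]

    features = [
        FeatureAnnotation(label, s, e, "gene") for label, (s, e) in cfg["genes"].items()
    ] + [
        FeatureAnnotation(label, s, e, "homology_box")
        for label, (s, e) in cfg["boxes"].items()
    ]
    # overlap among all features is a configuration error
    ordered = sorted(features, key=lambda f: f.start)
    for f1, f2 in zip(ordered, ordered[1:]):
        if f2.start <= f1.end:
            raise ConfigurationError(f"features {f1.label} and {f2.label} overlap")

    rng = np.random.default_rng(seed)
    arr = _random_dna(rng, length)
    boxes = cfg["boxes"]
    for a, b in BOX_PAIRS:
        if a not in boxes or b not in boxes:
            continue
        (sa, ea), (sb, eb) = boxes[a], boxes[b]
        if ea - sa != eb - sb:
            raise ConfigurationError(f"paired boxes {a}/{b} have unequal lengths")
        shared = _random_dna(rng, ea - sa + 1)
        arr[sa - origin : ea - origin + 1] = shared
        arr[sb - origin : eb - origin + 1] = shared

    for keep, adjust in cfg.get("distinct_pairs", DEFAULT_DISTINCT_PAIRS):
        i, j = keep - origin, adjust - origin
        if not (0 <= i < length and 0 <= j < length):
            raise ConfigurationError(f"distinct pair ({keep},{adjust}) outside reference")
        if arr[i] == arr[j]:
            k = int(np.nonzero(_BASES == arr[j])[0][0])
            arr[j] = _BASES[(k + 1) % 4]

    return ReferenceCluster(
        name="synthetic_alpha_cluster",
        sequence=arr.tobytes().decode("ascii"),
        coordinate_origin=origin,
        features=features,
    )


def _count_alpha_genes(ref: ReferenceCluster, provenance: list[Segment]) -> int:
    """Functional alpha genes fully contained in the provenance segments."""
    n = 0
    for gene in ("alpha2", "alpha1"):
        try:
            f = ref.feature(gene, "gene")
        except KeyError:
            continue
        for seg in provenance:
            if seg.source == "ref" and seg.start <= f.start and f.end <= seg.end:
                n += 1
    return n


def _allele_from_segments(
    ref: ReferenceCluster, name: str, segments: list[Segment]
) -> StructuralAllele:
    seq = "".join(s.materialize(ref) for s in segments)
    if name in FUNCTIONAL_ALPHA_COUNT:
        count = FUNCTIONAL_ALPHA_COUNT[name]
    else:
        count = min(3, _count_alpha_genes(ref, segments))
    return StructuralAllele(name, seq, segments, count)


def aa_allele(ref: ReferenceCluster) -> StructuralAllele:
    """The normal two-gene allele: the full reference haplotype."""
    seg = Segment("aa", "ref", ref.coordinate_origin, ref.end)
    return _allele_from_segments(ref, "AA", [seg])


def recombine(
    ref: ReferenceCluster, spec: CrossoverSpec
) -> tuple[StructuralAllele, StructuralAllele]:
    """Unequal crossover between two homology boxes.

    Returns ``(deleted, triplicated)``: the single-gene deletion product and
    its reciprocal triplication.  The two product lengths sum to exactly
    twice the normal allele length.  The breakpoint inside the (identical)
    boxes defaults to the box midpoint and is configurable because the true
    breakpoint is unidentifiable within a perfect repeat.
    """
    box_a = ref.feature(spec.box_a, "homology_box")
    box_b = ref.feature(spec.box_b, "homology_box")
    if box_a.length != box_b.length:
        raise ConfigurationError(
            f"boxes {spec.box_a} ({box_a.length} bp) and {spec.box_b} "
            f"({box_b.length} bp) have unequal lengths"
        )
    if box_a.start > box_b.start:
        box_a, box_b = box_b, box_a
    if spec.breakpoint_rule == "midpoint":
        off = box_a.length // 2
    elif spec.breakpoint_rule == "fixed_offset":
        if not 0 <= spec.offset <= box_a.length:
            raise ConfigurationError("offset outside box")
        off = spec.offset
    else:
        raise ConfigurationError(f"unknown breakpoint_rule {spec.breakpoint_rule!r}")

    cut_a = box_a.start + off - 1  # last retained base of upstream box
    cut_b = box_b.start + off - 1

    if spec.box_a.startswith("Z") or spec.box_b.startswith("Z"):
        del_name, tri_name = "D37", "ANTI37"
    elif spec.box_a.startswith("X") or spec.box_b.startswith("X"):
        del_name, tri_name = "D42", "ANTI42"
    else:
        del_name, tri_name = "custom", "custom"

    deleted = _allele_from_segments(
        ref,
        del_name,
        [
            Segment(f"{del_name}-left", "ref", ref.coordinate_origin, cut_a),
            Segment(f"{del_name}-right", "ref", cut_b + 1, ref.end),
        ],
    )
    triplicated = _allele_from_segments(
        ref,
        tri_name,
        [
            Segment(f"{tri_name}-left", "ref", ref.coordinate_origin, cut_b),
            Segment(f"{tri_name}-right", "ref", cut_a + 1, ref.end),
        ],
    )
    return deleted, triplicated


def make_deletion(
    ref: ReferenceCluster, interval: tuple[int, int], name: str
) -> StructuralAllele:
    """Simple deletion of a reference interval (e.g. --SEA, --THAI)."""
    start, end = interval
    if start > end:  # zero-length deletion: identical to AA
        allele = aa_allele(ref)
        return replace(allele, name=name)
    if start < ref.coordinate_origin or end > ref.end:
        raise ValueError(f"deletion interval [{start},{end}] outside reference")
    segs = []
    if start > ref.coordinate_origin:
        segs.append(Segment(f"{name}-left", "ref", ref.coordinate_origin, start - 1))
    if end < ref.end:
        segs.append(Segment(f"{name}-right", "ref", end + 1, ref.end))
    return _allele_from_segments(ref, name, segs)


def make_hkaa(
    ref: ReferenceCluster, cfg: HkaaCompositionConfig | None = None
) -> StructuralAllele:
    """Compose the HKαα allele from its three sections.

    In the default reading the allele is the αααanti4.2 junction segment,
    then the 802 bp special segment (section 1, a run of undetected N,
    section 2), then the -α3.7 junction segment.  The net functional
    alpha-gene count is 2: the allele carries an intact alpha-2 gene and the
    alpha2-alpha1 fusion gene.
    """
    cfg = cfg or HkaaCompositionConfig()
    sections: dict[str, list[Segment]] = {}
    sections["anti42_segment"] = [
        Segment("anti42_segment", "ref", s, e) for s, e in cfg.anti42_segment_intervals
    ]
    special = [
        Segment("special_upstream", "ref", *cfg.section1_interval),
    ]
    if cfg.gap_length > 0:
        special.append(Segment("undetected_gap", "N", length=cfg.gap_length))
    special.append(Segment("special_downstream", "ref", *cfg.section2_interval))
    sections["special_segment"] = special
    sections["d37_segment"] = [
        Segment("d37_segment", "ref", s, e) for s, e in cfg.d37_segment_intervals
    ]

    segments: list[Segment] = []
    for label in cfg.section_order:
        segments.extend(sections[label])
    for seg in segments:
        if seg.source == "ref" and not (
            ref.coordinate_origin <= seg.start and seg.end <= ref.end
        ):
            raise ValueError(
                f"HKαα segment {seg.label} [{seg.start},{seg.end}] outside reference"
            )
    return _allele_from_segments(ref, "HKAA", segments)


def special_segment_length(cfg: HkaaCompositionConfig | None = None) -> int:
    """Total assembled length of the special section (N positions counted)."""
    cfg = cfg or HkaaCompositionConfig()
    s1 = cfg.section1_interval[1] - cfg.section1_interval[0] + 1
    s2 = cfg.section2_interval[1] - cfg.section2_interval[0] + 1
    return s1 + cfg.gap_length + s2


# The seven-allele library used for diploid genotype candidates.  The
# anti-3.7 triplication is constructible (see recombine) but is not part of
# the clinical screening panel and is excluded from candidate genotypes.
GENOTYPE_LIBRARY = ("AA", "D37", "D42", "SEA", "THAI", "ANTI42", "HKAA")


def build_allele_library(
    ref: ReferenceCluster | None = None,
    hkaa_cfg: HkaaCompositionConfig | None = None,
    include_anti37: bool = False,
) -> dict[str, StructuralAllele]:
    """Construct all structural alleles on the (default) reference."""
    ref = ref or build_synthetic_reference()
    d37, anti37 = recombine(ref, CrossoverSpec("Z-alpha2", "Z-alpha1"))
    d42, anti42 = recombine(ref, CrossoverSpec("X-alpha2", "X-alpha1"))
    lib = {
        "AA": aa_allele(ref),
        "D37": d37,
        "D42": d42,
        "SEA": make_deletion(ref, DEFAULT_LAYOUT["sea_interval"], "SEA"),
        "THAI": make_deletion(ref, DEFAULT_LAYOUT["thai_interval"], "THAI"),
        "ANTI42": anti42,
        "HKAA": make_hkaa(ref, hkaa_cfg),
    }
    if include_anti37:
        lib["ANTI37"] = anti37
    return lib


def genotype_display(pair: tuple[str, str]) -> str:
    """Render an unordered allele pair as a clinical genotype string."""
    a, b = sorted(pair, key=ALLELE_RANK.__getitem__)
    return f"{ALLELE_DISPLAY[a]}/{ALLELE_DISPLAY[b]}"


def export_bed(ref: ReferenceCluster) -> str:
    """Feature annotations as BED text (0-based half-open)."""
    lines = []
    for f in sorted(ref.features, key=lambda f: f.start):
        lines.append(f"{ref.name}\t{f.start - 1}\t{f.end}\t{f.label}\t0\t+")
    return "\n".join(lines) + "\n"


def layout_to_json(cfg: dict | None = None) -> str:
    return json.dumps(cfg or DEFAULT_LAYOUT, indent=2)
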