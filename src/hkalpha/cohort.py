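"""Synthetic cohort: pedigree, Mendelian transmission, hematology, carriers.

The packaged pedigree fixture reproduces the study family: 11 individuals
(10 adults and one unborn fetus) across three generations, with the HKαα
allele segregating from the grandfather.  The spouse of II-3 was never
sampled, so III-3's father is recorded as unknown — which is exactly what
leaves III-3's second allele undetermined ("HKαα/?").

Hematology records are generated, not inferred: class-conditional Gaussian
draws anchored to the study's per-genotype rows, used only to exercise the
phenotype classifier.  Carrier sequences emulate the Sanger-assembled HKαα
alleles of the six sequenced samples: near-identical copies of one master
allele with rare substitutions and runs of undetected N.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hkalpha.cluster import FUNCTIONAL_ALPHA_COUNT, StructuralAllele

BETA_NAMES = {"B_N", "B41_42"}


class PedigreeLoadError(ValueError):
    pass


@dataclass
class HematologyRecord:
    RBC: float  # 10^12/L
    HGB: float  # g/L
    MCV: float  # fL
    MCH: float  # pg
    MCHC: float  # g/L
    HbA2: float  # percent

    def __post_init__(self) -> None:
        for name in ("RBC", "HGB", "MCV", "MCH", "MCHC", "HbA2"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass
class Individual:
    id: str
    sex: str = "unknown"  # {male, female, unknown}
    is_fetus: bool = False
    alpha_genotype: tuple[str, str] | None = None  # unordered, stored sorted
    beta_genotype: tuple[str, str] = ("B_N", "B_N")
    reported_genotype: str | None = None  # study-reported call, if any
    hematology: HematologyRecord | None = None

    def __post_init__(self) -> None:
        if self.is_fetus and self.hematology is not None:
            raise ValueError(f"fetus {self.id} cannot carry a hematology record")


@dataclass
class PedigreeGraph:
    individuals: dict[str, Individual] = field(default_factory=dict)
    # child id -> (father id or None, mother id or None)
    parent_links: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)

    def validate(self) -> None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for child, (father, mother) in self.parent_links.items():
            if child not in self.individuals:
                raise PedigreeLoadError(f"parent link for unknown individual {child!r}")
            for p in (father, mother):
                if p is None:
                    continue
                if p not in self.individuals:
                    raise PedigreeLoadError(
                        f"{child}: parent {p!r} does not exist in the pedigree"
                    )
                g.add_edge(p, child)
        if not nx.is_directed_acyclic_graph(g):
            raise PedigreeLoadError("pedigree contains a cycle")

    def parents(self, child: str) -> tuple[str | None, str | None]:
        return self.parent_links.get(child, (None, None))

    def __len__(self) -> int:
        return len(self.individuals)


def _parse_genotype(text: str) -> tuple[str, str] | None:
    text = text.strip()
    if not text or text in ("0", "NA", "?"):
        return None
    a, b = text.split("/")
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def load_pedigree(source) -> PedigreeGraph:
    """Load a PED-like tab-separated pedigree table.

    Required columns: id, father, mother, sex, is_fetus ("0" marks an
    unknown parent).  Optional: alpha_genotype, beta_genotype,
    reported_genotype and the six hematology columns.
    """
    try:
        df = pd.read_csv(source, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return PedigreeGraph()
    required = {"id", "father", "mother", "sex", "is_fetus"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeLoadError(f"missing columns: {sorted(missing)}")

    ped = PedigreeGraph()
    hem_cols = ["RBC", "HGB", "MCV", "MCH", "MCHC", "HbA2"]
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        hem = None
        if all(c in rec for c in hem_cols) and not any(
            pd.isna(rec[c]) or rec[c] == "NA" for c in hem_cols
        ):
            hem = HematologyRecord(*(float(rec[c]) for c in hem_cols))
        try:
            ind = Individual(
                id=rec["id"],
                sex=rec.get("sex", "unknown"),
                is_fetus=rec.get("is_fetus", "0") == "1",
                alpha_genotype=_parse_genotype(rec.get("alpha_genotype", "") or ""),
                beta_genotype=_parse_genotype(rec.get("beta_genotype", "") or "")
                or ("B_N", "B_N"),
                reported_genotype=rec.get("reported_genotype"),
                hematology=hem,
            )
        except ValueError as e:
            raise PedigreeLoadError(f"row {rownum}: {e}") from e
        if ind.id in ped.individuals:
            raise PedigreeLoadError(f"row {rownum}: duplicate id {ind.id!r}")
        ped.individuals[ind.id] = ind
        father = None if rec["father"] in ("0", None) else rec["father"]
        mother = None if rec["mother"] in ("0", None) else rec["mother"]
        if father or mother:
            ped.parent_links[ind.id] = (father, mother)
    try:
        ped.validate()
    except PedigreeLoadError:
        raise
    return ped


def packaged_pedigree() -> PedigreeGraph:
    """The study pedigree fixture: 11 individuals, one unborn fetus."""
    ref = importlib.resources.files("hkalpha.data").joinpath("pedigree.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_pedigree(fh)


def write_pedigree(ped: PedigreeGraph, path, ambiguity: dict[str, str] | None = None) -> None:
    """Write the pedigree back to PED-like TSV, optionally with call column."""
    rows = []
    for ind in ped.individuals.values():
        father, mother = ped.parents(ind.id)
        row = {
            "id": ind.id,
            "father": father or "0",
            "mother": mother or "0",
            "sex": ind.sex,
            "is_fetus": int(ind.is_fetus),
            "alpha_genotype": "/".join(ind.alpha_genotype) if ind.alpha_genotype else "NA",
            "beta_genotype": "/".join(ind.beta_genotype),
        }
        if ambiguity is not None:
            row["ambiguity_set"] = ambiguity.get(ind.id, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Mendelian transmission
# --------------------------------------------------------------------------


class UnknownParentalGenotype(ValueError):
    """Transmission needs known parents; unknowns go through the resolver."""


def transmit(
    father_genotype: tuple[str, str] | None,
    mother_genotype: tuple[str, str] | None,
    seed: int | np.random.Generator = 0,
) -> tuple[str, str]:
    """Draw a child genotype: one whole allele from each parent, uniformly.

    Structural alleles are transmitted atomically — in particular the HKαα
    fusion allele passes as a unit and is never split into its αααanti4.2
    and -α3.7 constituents.
    """
    if father_genotype is None or mother_genotype is None:
        raise UnknownParentalGenotype(
            "parental genotype unknown; use the pedigree resolver instead"
        )
    for g in (father_genotype, mother_genotype):
        for allele in g:
            if allele not in FUNCTIONAL_ALPHA_COUNT:
                raise ValueError(f"unknown allele {allele!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    paternal = father_genotype[rng.integers(0, 2)]
    maternal = mother_genotype[rng.integers(0, 2)]
    return tuple(sorted((paternal, maternal)))  # type: ignore[return-value]


# --------------------------------------------------------------------------
# Hematology simulation
# --------------------------------------------------------------------------

# Class-conditional means anchored to the study's per-genotype rows
# (RBC 10^12/L, HGB g/L, MCV fL, MCH pg, MCHC g/L, HbA2 %).
DEFAULT_HEMATOLOGY_CLASSES: dict[str, dict[str, float]] = {
    "normal": dict(RBC=4.69, HGB=145, MCV=93.6, MCH=30.9, MCHC=330, HbA2=2.9),
    "silent": dict(RBC=4.03, HGB=104, MCV=79.7, MCH=25.8, MCHC=324, HbA2=2.6),
    "trait": dict(RBC=5.85, HGB=123, MCV=70.0, MCH=21.0, MCHC=296, HbA2=2.5),
    "HbH": dict(RBC=5.38, HGB=90, MCV=58.6, MCH=16.7, MCHC=286, HbA2=1.3),
    "hydrops": dict(RBC=2.0, HGB=40, MCV=110.0, MCH=30.0, MCHC=250, HbA2=0.5),
    # beta-thalassemia trait overlay presents with raised HbA2 and
    # microcytosis regardless of the alpha class
    "beta_trait": dict(RBC=5.41, HGB=104, MCV=64.9, MCH=19.2, MCHC=296, HbA2=6.4),
}

DEFAULT_CV = 0.04  # relative standard deviation per analyte


def simulate_hematology(
    alpha_genotype: tuple[str, str],
    beta_genotype: tuple[str, str] = ("B_N", "B_N"),
    params: dict[str, dict[str, float]] | None = None,
    cv: float = DEFAULT_CV,
    seed: int | np.random.Generator = 0,
) -> HematologyRecord:
    """Draw a hematology record from the genotype's severity class."""
    from hkalpha.phenotype import predict_severity

    if cv < 0:
        raise ValueError("coefficient of variation must be non-negative")
    params = params or DEFAULT_HEMATOLOGY_CLASSES
    pred = predict_severity(alpha_genotype, beta_genotype)
    key = "beta_trait" if pred.beta_overlay == "beta_trait" else pred.alpha_class
    means = params[key]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = {}
    for name, mu in means.items():
        sd = cv * mu
        values[name] = float(max(mu + sd * rng.standard_normal(), 0.05 * mu)) if sd else mu
    return HematologyRecord(**values)


# --------------------------------------------------------------------------
# Carrier sequence emission
# --------------------------------------------------------------------------


@dataclass
class CarrierSequenceSet:
    sample_ids: list[str]
    sequences: dict[str, str]
    substitution_rate: float
    gap_spec: tuple[tuple[int, int], ...]
    seed: int


_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def emit_carrier_sequences(
    master: StructuralAllele | str,
    n: int = 6,
    substitution_rate: float = 0.001,
    gap_spec: tuple[tuple[int, int], ...] = (),
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> CarrierSequenceSet:
    """Near-identical copies of a master allele with noise and N runs.

    Each sequence is the master with independent substitutions at the given
    per-bp rate (N positions never mutate) plus additional undetected runs
    per ``gap_spec`` (1-based start, length).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= substitution_rate <= 1:
        raise ValueError("substitution_rate must be in [0, 1]")
    seq = master.sequence if isinstance(master, StructuralAllele) else master
    ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("sample_ids length must equal n")
    rng = np.random.default_rng(seed)
    arr0 = np.frombuffer(seq.encode("ascii"), dtype="S1")
    out = {}
    for sid in ids:
        arr = arr0.copy()
        if substitution_rate > 0:
            hits = np.flatnonzero(rng.random(len(arr)) < substitution_rate)
            for i in hits:
                base = arr[i].decode()
                if base == "N":
                    continue
                arr[i] = _OTHER[base][rng.integers(0, 3)].encode()
        for start, length in gap_spec:
            if start < 1 or start + length - 1 > len(arr):
                raise ValueError(f"gap ({start},{length}) outside sequence")
            arr[start - 1 : start - 1 + length] = b"N"
        out[sid] = arr.tobytes().decode("ascii")
    return CarrierSequenceSet(ids, out, substitution_rate, tuple(gap_spec), seed)
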