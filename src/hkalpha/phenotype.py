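"""Genotype to phenotype: functional alpha-gene dose and severity class.

Alpha-thalassemia severity tracks the number of functional alpha genes
summed over the two alleles: 4 normal, 3 silent carrier, 2 thalassemia
trait, 1 HbH disease, 0 Hb Bart's hydrops fetalis.  The HKαα allele carries
two functional alpha genes (an intact alpha-2 plus the alpha2-alpha1 fusion
gene), so HKαα/--SEA presents only as trait — much milder than -α3.7/--SEA,
which is HbH disease — and HKαα/-α4.2 is a silent carrier, the same class
as -α4.2/αα.  Beta-thalassemia trait is reported as an independent overlay
axis rather than merged into the alpha class.
"""

from __future__ import annotations

from dataclasses import dataclass

from hkalpha.cluster import FUNCTIONAL_ALPHA_COUNT, genotype_display
from hkalpha.cohort import HematologyRecord

ALPHA_CLASS_BY_DOSE = {4: "normal", 3: "silent", 2: "trait", 1: "HbH", 0: "hydrops"}

CLASS_DESCRIPTION = {
    "normal": "normal alpha-globin output",
    "silent": "silent carrier; usually hematologically unremarkable",
    "trait": "alpha-thalassemia minor trait: mild microcytic hypochromic indices",
    "HbH": "HbH disease: moderate hemolytic anemia from beta4 tetramers",
    "hydrops": "Hb Bart's hydrops fetalis: usually lethal in utero",
}


@dataclass
class SeverityPrediction:
    alpha_dose: int
    alpha_class: str
    beta_overlay: str  # {"none", "beta_trait"}
    narrative: str


def predict_severity(
    alpha_genotype: tuple[str, str],
    beta_genotype: tuple[str, str] = ("B_N", "B_N"),
) -> SeverityPrediction:
    """Severity from the fixed per-allele functional gene counts.

    The prediction is symmetric in allele order.  An HKαα/HKαα homozygote
    (never observed in the study) is dose 4/normal, with the caveat that no
    clinical description of the homozygote exists.
    """
    for allele in alpha_genotype:
        if allele not in FUNCTIONAL_ALPHA_COUNT:
            raise KeyError(f"unknown allele {allele!r}")
    dose = sum(FUNCTIONAL_ALPHA_COUNT[a] for a in alpha_genotype)
    # triplication carriers can exceed 4; excess alpha dose classes as normal
    alpha_class = ALPHA_CLASS_BY_DOSE[min(dose, 4)]
    beta_overlay = (
        "beta_trait"
        if sorted(beta_genotype) == ["B41_42", "B_N"]
        else "none"
    )
    narrative = (
        f"{genotype_display(alpha_genotype)}: {dose} functional alpha genes -> "
        f"{CLASS_DESCRIPTION[alpha_class]}"
    )
    if set(alpha_genotype) == {"HKAA"}:
        narrative += " (HKαα homozygote: dose-based prediction, no clinical reports)"
    if beta_overlay == "beta_trait":
        narrative += (
            "; heterozygous beta CD41-42(-CTTT): beta-thalassemia trait with "
            "raised HbA2 may dominate the picture"
        )
    return SeverityPrediction(dose, alpha_class, beta_overlay, narrative)


@dataclass
class HematologyFlags:
    microcytic: bool
    hypochromic: bool
    elevated_HbA2: bool


@dataclass(frozen=True)
class HematologyCuts:
    mcv_cut: float = 80.0  # fL
    mch_cut: float = 27.0  # pg
    hba2_cut: float = 3.5  # percent


def classify_hematology(
    record: HematologyRecord, cuts: HematologyCuts = HematologyCuts()
) -> HematologyFlags:
    """Pure threshold flags (strict inequalities) on a hematology record."""
    for name in ("MCV", "MCH", "HbA2"):
        if getattr(record, name, None) is None:
            raise ValueError(f"missing hematology field {name}")
    return HematologyFlags(
        microcytic=record.MCV < cuts.mcv_cut,
        hypochromic=record.MCH < cuts.mch_cut,
        elevated_HbA2=record.HbA2 > cuts.hba2_cut,
    )
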