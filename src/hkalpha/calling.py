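"""Staged reflex genotype calling from assay evidence.

The caller converts band patterns into ambiguity sets of diploid genotypes:
every genotype whose forward-simulated assay results match the observed
evidence survives.  Ambiguity is never collapsed by priors — the study
resolves residual ambiguity only through pedigree evidence, so the caller
must not guess.  The reflex plan mirrors the recommended clinical workflow:
an anti4.2 junction assay once -α3.7 positivity (or an HKαα candidate) is
seen, then the two-round nested PCR once anti4.2 positivity is confirmed,
because only the nested assay proves the two junctions lie in cis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

from hkalpha.cluster import GENOTYPE_LIBRARY, genotype_display
from hkalpha.pcr import BandPattern, PCRPanel, patterns_equal

Genotype = tuple[str, str]  # unordered, stored sorted

BETA_ALLELES = ("B_N", "B41_42")


def genotype_key(pair: tuple[str, str]) -> Genotype:
    return tuple(sorted(pair))  # type: ignore[return-value]


def all_genotypes(library: tuple[str, ...] = GENOTYPE_LIBRARY) -> list[Genotype]:
    return [genotype_key(g) for g in combinations_with_replacement(sorted(library), 2)]


@dataclass
class AssayResultSet:
    """Per-sample evidence: observed multiplex pattern, optional reflex assays."""

    multiplex: BandPattern
    anti42_positive: bool | None = None  # None = untested
    nested_positive: bool | None = None
    rdb_beta: frozenset[str] = frozenset()  # detected beta point mutations
    rdb_alpha: frozenset[str] = frozenset()  # nondeletional alpha mutations


@dataclass
class GenotypeCall:
    ambiguity_set: set[Genotype]
    beta_call: tuple[str, str]
    evidence_trail: list[tuple[str, str]] = field(default_factory=list)
    recommended_next_assay: str | None = None

    def display(self) -> str:
        """Clinical genotype string; unresolved second alleles render as '?'."""
        if not self.ambiguity_set:
            raise ValueError("empty ambiguity set")
        if len(self.ambiguity_set) == 1:
            return genotype_display(next(iter(self.ambiguity_set)))
        common = set.intersection(*(set(g) for g in self.ambiguity_set))
        # a shared allele across all candidates is reported with '?' partner
        for allele in ("HKAA", "D37", "D42", "SEA", "THAI", "ANTI42", "AA"):
            if allele in common:
                from hkalpha.cluster import ALLELE_DISPLAY

                return f"{ALLELE_DISPLAY[allele]}/?"
        return "?/?"

    def to_json(self) -> str:
        return json.dumps(
            {
                "ambiguity_set": sorted(genotype_display(g) for g in self.ambiguity_set),
                "display": self.display(),
                "beta": "/".join(self.beta_call),
                "evidence": [list(e) for e in self.evidence_trail],
                "recommended_next_assay": self.recommended_next_assay,
            },
            ensure_ascii=False,
            indent=2,
        )


class UninterpretablePattern(ValueError):
    pass


class InconsistentEvidence(ValueError):
    pass


class ReflexCaller:
    """Genotype caller over the seven-allele screening library."""

    def __init__(self, panel: PCRPanel | None = None,
                 library: tuple[str, ...] = GENOTYPE_LIBRARY):
        self.panel = panel or PCRPanel()
        self.library = library
        self._expected: dict[Genotype, BandPattern] = {
            g: self.panel.run_multiplex(g) for g in all_genotypes(library)
        }

    # -- single-assay interpreters -------------------------------------

    def call_deletional(self, pattern: BandPattern) -> set[Genotype]:
        """All genotypes whose predicted merged multiplex pattern matches."""
        candidates = {
            g for g, exp in self._expected.items() if patterns_equal(exp, pattern)
        }
        if not candidates:
            raise UninterpretablePattern(
                f"multiplex pattern {pattern.sizes} matches no genotype in the library"
            )
        return candidates

    @staticmethod
    def _anti42_expected(genotype: Genotype) -> bool:
        return any(a in ("ANTI42", "HKAA") for a in genotype)

    @staticmethod
    def _nested_expected(genotype: Genotype) -> bool:
        return "HKAA" in genotype

    # -- reflex plan ----------------------------------------------------

    @staticmethod
    def reflex_plan(call: GenotypeCall) -> str | None:
        """Next recommended assay given the current ambiguity set.

        The anti4.2 junction assay is indicated while any candidate carries
        a -α3.7 or HKαα allele and the anti4.2 status is untested; the
        nested PCR is indicated once anti4.2 positivity is confirmed but the
        cis/trans configuration is untested.
        """
        tested = {rule for rule, _ in call.evidence_trail}
        anyd37 = any(a in ("D37", "HKAA") for g in call.ambiguity_set for a in g)
        if anyd37 and "anti42_junction" not in tested:
            return "anti42_junction"
        anti42_pos = any(
            rule == "anti42_junction" and "positive" in note
            for rule, note in call.evidence_trail
        )
        if anti42_pos and "nested" not in tested:
            return "nested_round1"
        return None

    # -- evidence integration --------------------------------------------

    def integrate(self, results: AssayResultSet) -> GenotypeCall:
        """Intersect candidate genotypes across every recorded assay."""
        trail: list[tuple[str, str]] = []
        candidates = self.call_deletional(results.multiplex)
        trail.append(
            (
                "multiplex_deletional",
                f"observed bands {list(results.multiplex.sizes)} are consistent "
                f"with {len(candidates)} genotype(s)",
            )
        )
        if results.anti42_positive is not None:
            keep = {
                g
                for g in candidates
                if self._anti42_expected(g) == results.anti42_positive
            }
            state = "positive" if results.anti42_positive else "negative"
            trail.append(
                (
                    "anti42_junction",
                    f"anti4.2 junction {state}: {len(keep)} candidate(s) remain",
                )
            )
            if not keep:
                raise InconsistentEvidence(
                    "anti42_junction result contradicts the multiplex pattern"
                )
            candidates = keep
        if results.nested_positive is not None:
            keep = {
                g
                for g in candidates
                if self._nested_expected(g) == results.nested_positive
            }
            state = "positive" if results.nested_positive else "negative"
            trail.append(
                (
                    "nested",
                    f"two-round nested PCR {state}: the -α3.7 and anti4.2 "
                    f"junctions are {'in cis (HKαα present)' if results.nested_positive else 'not proven in cis'}; "
                    f"{len(keep)} candidate(s) remain",
                )
            )
            if not keep:
                raise InconsistentEvidence(
                    "nested PCR result contradicts earlier assays"
                )
            candidates = keep

        if "B41_42" in results.rdb_beta:
            beta = ("B41_42", "B_N")
            trail.append(("rdb_beta", "CD41-42(-CTTT) heterozygote detected by RDB"))
        else:
            beta = ("B_N", "B_N")
            trail.append(("rdb_beta", "no beta point mutation detected by RDB"))

        call = GenotypeCall(candidates, beta, trail)
        call.recommended_next_assay = self.reflex_plan(call)
        return call

    # -- full simulated workup -------------------------------------------

    def simulate_results(self, genotype: tuple[str, str],
                         beta: tuple[str, str] = ("B_N", "B_N")) -> AssayResultSet:
        """Forward-simulate the study's assay workup for a true genotype.

        The multiplex and the anti4.2 junction assay are run on every
        sample (as in the pedigree study); the two-round nested PCR is run
        once anti4.2 positivity is seen, per the reflex plan.
        """
        g = genotype_key(genotype)
        multiplex = self.panel.run_multiplex(g)
        res = AssayResultSet(
            multiplex=multiplex,
            rdb_beta=frozenset({"B41_42"} if "B41_42" in beta else set()),
        )
        res.anti42_positive = bool(self.panel.run_anti42(g).bands)
        if res.anti42_positive:
            res.nested_positive = self.panel.run_nested(g).positive
        return res

    def call_from_truth(self, genotype: tuple[str, str],
                        beta: tuple[str, str] = ("B_N", "B_N")) -> GenotypeCall:
        return self.integrate(self.simulate_results(genotype, beta))
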