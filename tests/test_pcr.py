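"""In-silico PCR engine tests, including a naive scanning oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hkalpha.calling import all_genotypes
from hkalpha.pcr import (
    Amplicon,
    Assay,
    MismatchPolicy,
    Primer,
    PrimerPair,
    ZW_F,
    ZW_R,
    amplify,
    find_binding_sites,
    merge_bands,
    patterns_equal,
    revcomp,
)

# ----------------------------------------------------------------------
# primer and site finding
# ----------------------------------------------------------------------


def test_primer_validation():
    with pytest.raises(ValueError):
        Primer("short", "ACGT")  # too short
    with pytest.raises(ValueError):
        Primer("bad", "ACGTACGTACGTACGTN")  # non-ACGT
    Primer("ok", "ACGTACGTACGTACGTA")


def test_published_round1_primers_packaged_verbatim():
    assert ZW_F.sequence == "CTCGGTAGCCGTTCCTCCTGC"
    assert ZW_R.sequence == "AAGTCTGGGAATAAAACTCGGGA"


def naive_sites(template: str, primer: str, max_mm: int, three_prime: int):
    """Independent oracle: brute-force scan of both strands."""
    out = []
    m = len(primer)
    w = min(three_prime, m)
    for strand, probe in (("+", primer), ("-", revcomp(primer))):
        for i in range(len(template) - m + 1):
            window = template[i : i + m]
            mm = sum(1 for a, b in zip(window, probe) if a != b or a == "N")
            if mm > max_mm:
                continue
            # 3'-terminal bases must match exactly: rightmost on +, leftmost on -
            tail = window[m - w :] if strand == "+" else window[:w]
            ptail = probe[m - w :] if strand == "+" else probe[:w]
            if any(a != b or a == "N" for a, b in zip(tail, ptail)):
                continue
            out.append((strand, i + 1, mm))
    return sorted(out, key=lambda s: (s[1], s[0]))


def test_site_finding_matches_naive_oracle_on_random_instances():
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    policy = MismatchPolicy(max_mismatches=1, three_prime_exact=3)
    for case in range(100):
        n = int(rng.integers(60, 400))
        template = "".join(rng.choice(bases, size=n))
        # plant the primer (possibly mutated or reverse-complemented)
        primer = "".join(rng.choice(bases, size=int(rng.integers(16, 26))))
        pos = int(rng.integers(0, n - len(primer)))
        planted = primer if rng.random() < 0.5 else revcomp(primer)
        if rng.random() < 0.3:  # single internal mismatch
            i = int(rng.integers(0, max(1, len(planted) - 3)))
            planted = planted[:i] + ("A" if planted[i] != "A" else "C") + planted[i + 1 :]
        if rng.random() < 0.2:  # sprinkle an N
            j = int(rng.integers(0, n))
            template = template[:j] + "N" + template[j + 1 :]
        template = template[:pos] + planted + template[pos + len(planted) :]
        got = [
            (s.strand, s.start, s.mismatches)
            for s in find_binding_sites(template, Primer("p", primer), policy)
        ]
        want = naive_sites(template, primer, policy.max_mismatches, policy.three_prime_exact)
        assert got == want, f"case {case}: {got} != {want}"


def test_empty_template_rejected():
    with pytest.raises(ValueError):
        find_binding_sites("", Primer("p", "ACGTACGTACGTACGT"))


# ----------------------------------------------------------------------
# amplification
# ----------------------------------------------------------------------


def _simple_assay(max_product=6000):
    fwd = Primer("F", "ACGTACGTACGTACGTAC")
    rev_site = "TTGACCTTGACCTTGACC"
    rev = Primer("R", revcomp(rev_site))
    return fwd, rev_site, Assay(
        "toy", (PrimerPair(fwd, rev, "pair"),), max_product_bp=max_product
    )


def test_amplify_simple_product():
    fwd, rev_site, assay = _simple_assay()
    rng = np.random.default_rng(0)
    filler = "".join(np.random.default_rng(1).choice(list("ACGT"), size=200))
    template = fwd.sequence + filler + rev_site
    amps = amplify({"t": template}, assay)
    assert len(amps) == 1
    assert amps[0].length == len(template)
    assert amps[0].sequence == template


def test_amplify_respects_product_cap():
    fwd, rev_site, assay = _simple_assay(max_product=100)
    filler = "".join(np.random.default_rng(1).choice(list("ACGT"), size=200))
    template = fwd.sequence + filler + rev_site
    assert amplify({"t": template}, assay) == []


@given(cap=st.integers(min_value=50, max_value=7000))
def test_product_set_monotone_in_cap(cap):
    fwd, rev_site, _ = _simple_assay()
    filler = "".join(np.random.default_rng(2).choice(list("ACGT"), size=300))
    template = fwd.sequence + filler + rev_site + filler + rev_site
    small = Assay("s", (PrimerPair(fwd, Primer("R", revcomp(rev_site)), "p"),), max_product_bp=cap)
    big = Assay("b", (PrimerPair(fwd, Primer("R", revcomp(rev_site)), "p"),), max_product_bp=cap + 500)
    lens_small = {a.length for a in amplify({"t": template}, small)}
    lens_big = {a.length for a in amplify({"t": template}, big)}
    assert lens_small <= lens_big


def test_merge_bands_comigration():
    amps = [
        Amplicon("a", "t", "x", 472, ""),
        Amplicon("a", "t", "y", 476, ""),  # within 2 % of 472
        Amplicon("a", "t", "z", 1121, ""),
    ]
    pattern = merge_bands(amps, "a")
    assert len(pattern.bands) == 2
    assert pattern.sizes == (474, 1121)
    assert {"x", "y"} == set(next(labels for size, labels in pattern.bands if size == 474))


def test_patterns_equal_tolerance():
    a = merge_bands([Amplicon("a", "t", "x", 472, "")], "a")
    b = merge_bands([Amplicon("a", "t", "y", 478, "")], "a")
    c = merge_bands([Amplicon("a", "t", "y", 600, "")], "a")
    assert patterns_equal(a, b)
    assert not patterns_equal(a, c)


# ----------------------------------------------------------------------
# the study's assay panel on the allele library
# ----------------------------------------------------------------------


def test_round1_on_hkaa_single_4500bp_product(panel):
    res = panel.run_nested(("HKAA", "AA"))
    assert [a.length for a in res.round1_amplicons] == [4500]


def test_round1_on_normal_allele_yields_nothing(panel):
    res = panel.run_nested(("AA", "AA"))
    assert res.round1_amplicons == []
    assert not res.positive


def test_multiplex_conceals_hkaa_as_d37(panel):
    """HKαα/αα and -α3.7/αα comigrate, as do the /--SEA compounds."""
    assert patterns_equal(panel.run_multiplex(("HKAA", "AA")), panel.run_multiplex(("D37", "AA")))
    assert patterns_equal(panel.run_multiplex(("HKAA", "SEA")), panel.run_multiplex(("D37", "SEA")))
    # but HKαα/αα is NOT the -α4.2 pattern
    assert not patterns_equal(panel.run_multiplex(("HKAA", "AA")), panel.run_multiplex(("D42", "AA")))


def test_nested_positive_exactly_for_hkaa_genotypes(panel):
    """Over every genotype from the 8-allele set: positive iff HKαα present."""
    names = sorted(panel.alleles)
    for g in itertools.combinations_with_replacement(names, 2):
        res = panel.run_nested(g)
        assert res.positive == ("HKAA" in g), g


def test_trans_configuration_is_nested_negative(panel):
    """-α3.7 and αααanti4.2 in trans carry both junctions but on two molecules."""
    res = panel.run_nested(("D37", "ANTI42"))
    assert not res.positive
    assert res.round1_amplicons == []
    # yet the anti4.2 junction assay alone is positive, i.e. the trans
    # compound is exactly what the nested assay exists to exclude
    assert panel.run_anti42(("D37", "ANTI42")).bands


def test_anti42_junction_assay_specificity(panel):
    positive = {g for g in all_genotypes(tuple(sorted(panel.alleles)))
                if panel.run_anti42(g).bands}
    expected = {g for g in all_genotypes(tuple(sorted(panel.alleles)))
                if any(a in ("ANTI42", "ANTI37", "HKAA") for a in g)}
    # ANTI37 carries no anti4.2 junction: remove genotypes that are
    # ANTI37-only on the triplication side
    expected = {g for g in expected if any(a in ("ANTI42", "HKAA") for a in g)}
    assert positive == expected
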