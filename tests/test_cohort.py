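"""Pedigree fixture, transmission, hematology and carrier-sequence tests."""

import io

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hkalpha.cluster import build_synthetic_reference, make_hkaa
from hkalpha.cohort import (
    DEFAULT_HEMATOLOGY_CLASSES,
    HematologyRecord,
    Individual,
    PedigreeLoadError,
    UnknownParentalGenotype,
    emit_carrier_sequences,
    load_pedigree,
    packaged_pedigree,
    simulate_hematology,
    transmit,
    write_pedigree,
)

# ----------------------------------------------------------------------
# packaged fixture
# ----------------------------------------------------------------------


def test_packaged_pedigree_composition():
    ped = packaged_pedigree()
    assert len(ped) == 11
    fetuses = [i for i in ped.individuals.values() if i.is_fetus]
    assert [f.id for f in fetuses] == ["III-2"]
    assert fetuses[0].hematology is None
    # every non-fetal member carries a hematology record
    assert all(
        i.hematology is not None for i in ped.individuals.values() if not i.is_fetus
    )


def test_packaged_pedigree_reported_genotypes_verbatim():
    ped = packaged_pedigree()
    reported = {i.id: i.reported_genotype for i in ped.individuals.values()}
    assert reported == {
        "I-1": "HKαα/-α3.7",
        "I-2": "--SEA/αα",
        "II-1": "-α4.2/αα",
        "II-2": "HKαα/--SEA",
        "II-3": "HKαα/--SEA",
        "II-4": "-α3.7/--SEA",
        "II-5": "-α3.7/αα",
        "II-6": "αα/αα",
        "III-1": "HKαα/-α4.2",
        "III-2": "HKαα/-α4.2",
        "III-3": "HKαα/?",
    }


def test_packaged_pedigree_structure():
    ped = packaged_pedigree()
    assert ped.parents("II-2") == ("I-1", "I-2")
    assert ped.parents("III-1") == ("II-2", "II-1")
    assert ped.parents("III-3") == (None, "II-3")  # father unsampled
    assert ped.parents("II-6") == (None, None)


def test_beta_carriers_in_fixture():
    ped = packaged_pedigree()
    betas = {i.id for i in ped.individuals.values() if "B41_42" in i.beta_genotype}
    assert betas == {"I-1", "II-5"}
    assert ped.individuals["I-1"].hematology.HbA2 == 6.4


# ----------------------------------------------------------------------
# loading and writing
# ----------------------------------------------------------------------

HEADER = "id\tfather\tmother\tsex\tis_fetus\n"


def test_dangling_parent_rejected():
    tsv = HEADER + "A\tZZZ\t0\tmale\t0\n"
    with pytest.raises(PedigreeLoadError, match="ZZZ"):
        load_pedigree(io.StringIO(tsv))


def test_cycle_rejected():
    tsv = HEADER + "A\tB\t0\tmale\t0\nB\tA\t0\tmale\t0\n"
    with pytest.raises(PedigreeLoadError, match="cycle"):
        load_pedigree(io.StringIO(tsv))


def test_duplicate_id_rejected():
    tsv = HEADER + "A\t0\t0\tmale\t0\nA\t0\t0\tmale\t0\n"
    with pytest.raises(PedigreeLoadError, match="duplicate"):
        load_pedigree(io.StringIO(tsv))


def test_missing_columns_rejected():
    with pytest.raises(PedigreeLoadError, match="missing columns"):
        load_pedigree(io.StringIO("id\tfather\nA\t0\n"))


def test_empty_file_loads_empty_pedigree():
    assert len(load_pedigree(io.StringIO(""))) == 0


def test_fetus_with_hematology_rejected():
    with pytest.raises(ValueError):
        Individual(
            "X",
            is_fetus=True,
            hematology=HematologyRecord(5.0, 140, 90, 30, 330, 2.5),
        )


def test_write_round_trip(tmp_path):
    ped = packaged_pedigree()
    out = tmp_path / "ped.tsv"
    write_pedigree(ped, out, ambiguity={"I-1": "D37/HKAA"})
    text = out.read_text()
    assert "ambiguity_set" in text.splitlines()[0]
    again = load_pedigree(out)
    assert len(again) == 11
    assert again.parents("II-2") == ("I-1", "I-2")


# ----------------------------------------------------------------------
# transmission
# ----------------------------------------------------------------------


def test_transmit_enumerates_four_combinations():
    rng = np.random.default_rng(0)
    seen = {transmit(("HKAA", "D37"), ("SEA", "AA"), rng) for _ in range(500)}
    assert seen == {
        ("HKAA", "SEA"), ("AA", "HKAA"), ("D37", "SEA"), ("AA", "D37"),
    }


def test_transmit_is_atomic_for_hkaa():
    """No draw ever splits HKαα into its -α3.7/αααanti4.2 constituents."""
    rng = np.random.default_rng(1)
    for _ in range(500):
        child = transmit(("HKAA", "AA"), ("AA", "AA"), rng)
        assert set(child) <= {"HKAA", "AA"}
        assert "D37" not in child and "ANTI42" not in child


def test_transmit_mendelian_frequency():
    rng = np.random.default_rng(2)
    n = 10_000
    hits = sum("HKAA" in transmit(("HKAA", "AA"), ("AA", "AA"), rng) for _ in range(n))
    assert abs(hits / n - 0.5) < 0.02


def test_transmit_requires_known_parents():
    with pytest.raises(UnknownParentalGenotype):
        transmit(None, ("AA", "AA"))
    with pytest.raises(ValueError):
        transmit(("AA", "NOPE"), ("AA", "AA"))


# ----------------------------------------------------------------------
# hematology simulation
# ----------------------------------------------------------------------


def test_zero_cv_returns_class_means():
    rec = simulate_hematology(("HKAA", "SEA"), cv=0.0, seed=0)
    means = DEFAULT_HEMATOLOGY_CLASSES["trait"]
    assert (rec.RBC, rec.HGB, rec.MCV) == (means["RBC"], means["HGB"], means["MCV"])


def test_beta_trait_overlay_dominates_hematology_class():
    rec = simulate_hematology(("HKAA", "D37"), ("B41_42", "B_N"), cv=0.0)
    assert rec.HbA2 == 6.4


def test_hematology_seed_determinism():
    a = simulate_hematology(("D37", "SEA"), seed=7)
    b = simulate_hematology(("D37", "SEA"), seed=7)
    c = simulate_hematology(("D37", "SEA"), seed=8)
    assert a == b
    assert a != c


def test_negative_cv_rejected():
    with pytest.raises(ValueError):
        simulate_hematology(("AA", "AA"), cv=-0.1)


# ----------------------------------------------------------------------
# carrier sequence emission
# ----------------------------------------------------------------------


@pytest.fixture(scope="module")
def hkaa_master():
    return make_hkaa(build_synthetic_reference(seed=0))


def test_rate_zero_copies_are_identical(hkaa_master):
    s = emit_carrier_sequences(hkaa_master, n=3, substitution_rate=0.0, seed=0)
    assert all(seq == hkaa_master.sequence for seq in s.sequences.values())


def test_substitution_count_within_binomial_bounds(hkaa_master):
    rate = 0.002
    s = emit_carrier_sequences(hkaa_master, n=8, substitution_rate=rate, seed=4)
    L = len(hkaa_master.sequence)
    mean = rate * L
    sd = (rate * (1 - rate) * L) ** 0.5
    for seq in s.sequences.values():
        diffs = sum(1 for a, b in zip(seq, hkaa_master.sequence) if a != b)
        assert abs(diffs - mean) <= 4 * sd
        assert len(seq) == L  # substitutions only, never indels


def test_gap_spec_writes_n_runs(hkaa_master):
    s = emit_carrier_sequences(hkaa_master, n=1, substitution_rate=0.0,
                               gap_spec=((11, 5),), seed=0)
    seq = next(iter(s.sequences.values()))
    assert seq[10:15] == "NNNNN"
    with pytest.raises(ValueError):
        emit_carrier_sequences(hkaa_master, n=1, gap_spec=((0, 5),))


def test_carrier_emission_seed_determinism(hkaa_master):
    a = emit_carrier_sequences(hkaa_master, n=2, seed=9).sequences
    b = emit_carrier_sequences(hkaa_master, n=2, seed=9).sequences
    assert a == b


@given(rate=st.sampled_from([0.0, 0.0005, 0.005]))
def test_master_n_positions_never_mutate(hkaa_master, rate):
    s = emit_carrier_sequences(hkaa_master, n=2, substitution_rate=rate, seed=3)
    n_at = [i for i, c in enumerate(hkaa_master.sequence) if c == "N"]
    for seq in s.sequences.values():
        assert all(seq[i] == "N" for i in n_at)
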