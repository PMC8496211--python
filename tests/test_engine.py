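import math
import random

import numpy as np
import pytest

from orthohunt import (
    CalibrationMissingError,
    ForwardStats,
    ProfileHMM,
    ProteinRecord,
    Proteome,
    evalue_from_bits,
    forward_bitscore,
    read_tblout,
    search_proteome,
)
from orthohunt.fixtures import emit_homolog, random_background_sequence
from oracle import brute_force_bitscore, random_reduced_profile, reduced_sequences


def _delta_profile():
    """M=1 profile emitting 'A' with probability 1, uniform background."""
    match = np.full((1, 20), -math.inf)
    match[0, 0] = 0.0  # ln 1
    insert = np.log(np.full((1, 20), 0.05))
    trans = np.array([[math.log(0.975), math.log(0.025), -math.inf,
                       math.log(0.8), math.log(0.2), 0.0, -math.inf]])
    return ProfileHMM(name="delta", match_emissions=match,
                      insert_emissions=insert, transitions=trans,
                      background=np.full(20, 0.05))


def test_single_state_profile_matches_closed_form():
    """For a 1-state delta profile on sequence 'A' only one path exists, so the
    score has a closed form: log2[ (1/0.05) * (2/(L+2))^2 / ((L/(L+1))^L / (L+1)) ]."""
    hmm = _delta_profile()
    L = 1
    expected = math.log2((1 / 0.05) * (2 / (L + 2)) ** 2
                         / ((L / (L + 1)) ** L * (1 / (L + 1))))
    assert forward_bitscore(hmm, "A") == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("M", [1, 2, 3])
def test_forward_agrees_with_path_enumeration(M):
    """DP forward equals exhaustive path-sum enumeration within 1e-9 bits on
    the reduced-alphabet harness (one profile per size here; the full sweep
    runs in the acceptance suite)."""
    rng = np.random.default_rng(100 + M)
    hmm = random_reduced_profile(M, rng)
    for seq in reduced_sequences(3):
        assert forward_bitscore(hmm, seq) == pytest.approx(
            brute_force_bitscore(hmm, seq), abs=1e-9
        ), seq


def test_background_sequences_score_at_or_below_zero(toy_profile):
    """The local model is a (sub)probability model, so sequences drawn from
    the profile's own background have non-positive expected log-odds."""
    rng = np.random.default_rng(42)
    scores = [
        forward_bitscore(toy_profile,
                         random_background_sequence(rng, 30, toy_profile.background))
        for _ in range(1000)
    ]
    assert np.mean(scores) <= 0.0
    assert np.median(scores) <= 0.0


def test_homolog_outscores_its_shuffled_version(toy_profile):
    """Order matters: a true homolog beats its own residue shuffle in >=95%
    of trials."""
    rnd = random.Random(7)
    wins = 0
    for trial in range(100):
        hom = emit_homolog(toy_profile, 0.1, seed=trial)
        shuffled = list(hom.residues)
        rnd.shuffle(shuffled)
        if forward_bitscore(toy_profile, hom.residues) > forward_bitscore(
            toy_profile, "".join(shuffled)
        ):
            wins += 1
    assert wins >= 95


def test_empty_sequence_is_a_domain_error(toy_profile):
    with pytest.raises(ValueError):
        forward_bitscore(toy_profile, "")


def test_scores_are_deterministic(toy_profile):
    seq = emit_homolog(toy_profile, 0.2, seed=5)
    assert forward_bitscore(toy_profile, seq) == forward_bitscore(toy_profile, seq)


def test_long_sequence_does_not_underflow(toy_profile):
    score = forward_bitscore(toy_profile, "ACDEFGHIKL" * 1000)
    assert math.isfinite(score)


# ---------------------------------------------------------------------------
# E-values


def test_evalue_at_tau_equals_Z():
    stats = ForwardStats(tau=-3.0, lam=0.693)
    assert evalue_from_bits(-3.0, stats, Z=100) == 100.0


def test_evalue_matches_independent_formula_and_decreases():
    stats = ForwardStats(tau=-3.0, lam=0.693)
    grid = [0.0, 5.0, 10.0, 50.0, 200.0]
    expected = [100 * min(1.0, math.e ** (-0.693 * (s + 3.0))) for s in grid]
    got = [evalue_from_bits(s, stats, Z=100) for s in grid]
    assert got == pytest.approx(expected, rel=1e-12)
    assert all(a > b for a, b in zip(got, got[1:]))
    assert got[-1] < 1e-50  # E -> 0 as score grows


def test_missing_calibration_raises_unless_fallback_requested():
    with pytest.raises(CalibrationMissingError):
        evalue_from_bits(10.0, None, Z=50)
    assert evalue_from_bits(10.0, None, Z=50, allow_missing_stats=True) == 50.0


# ---------------------------------------------------------------------------
# proteome search


def _proteome(records, label="px"):
    return Proteome(label=label, source_path="<mem>", records=tuple(records))


def test_search_finds_planted_homolog_among_decoys(toy_profile):
    rng = np.random.default_rng(9)
    records = [emit_homolog(toy_profile, 0.1, seed=1)]
    records += [
        ProteinRecord(id=f"decoy{i}", residues=random_background_sequence(rng, 30))
        for i in range(9)
    ]
    result = search_proteome(toy_profile, _proteome(records), evalue_max=0.001)
    assert [h.target_id for h in result.hits] == [records[0].id]
    assert result.Z == 10


def test_maximal_evalue_threshold_keeps_every_sequence(toy_profile):
    rng = np.random.default_rng(10)
    records = [
        ProteinRecord(id=f"d{i}", residues=random_background_sequence(rng, 30))
        for i in range(6)
    ]
    result = search_proteome(toy_profile, _proteome(records), evalue_max=len(records))
    assert len(result.hits) == 6  # P <= 1 so E <= Z always


def test_decoys_only_yields_empty_result(toy_profile):
    rng = np.random.default_rng(11)
    records = [
        ProteinRecord(id=f"d{i}", residues=random_background_sequence(rng, 30))
        for i in range(5)
    ]
    result = search_proteome(toy_profile, _proteome(records), evalue_max=0.001)
    assert result.hits == ()
    assert result.hmm_name == toy_profile.name


def test_hits_sorted_by_score_then_id(toy_profile):
    hom1 = emit_homolog(toy_profile, 0.05, seed=2, replicate=1)
    hom2 = ProteinRecord(id="aaa_twin", residues=hom1.residues)
    result = search_proteome(toy_profile, _proteome([hom1, hom2]), evalue_max=1.0)
    scores = [h.bitscore for h in result.hits]
    assert scores == sorted(scores, reverse=True)
    assert [h.target_id for h in result.hits] == ["aaa_twin", hom1.id]  # tie: id asc


def test_appending_a_sequence_rescales_evalues_linearly(toy_profile):
    """Bit scores are per-sequence; only Z (and hence E) changes, exactly
    linearly."""
    rng = np.random.default_rng(12)
    base = [emit_homolog(toy_profile, 0.1, seed=3)]
    base += [
        ProteinRecord(id=f"d{i}", residues=random_background_sequence(rng, 30))
        for i in range(4)
    ]
    extra = ProteinRecord(id="zzz", residues=random_background_sequence(rng, 30))
    r5 = search_proteome(toy_profile, _proteome(base), evalue_max=1e9)
    r6 = search_proteome(toy_profile, _proteome(base + [extra]), evalue_max=1e9)
    by_id5 = {h.target_id: h for h in r5.hits}
    for hit in r6.hits:
        if hit.target_id == "zzz":
            continue
        assert hit.bitscore == by_id5[hit.target_id].bitscore
        assert hit.evalue == pytest.approx(by_id5[hit.target_id].evalue * 6 / 5, rel=1e-12)


# ---------------------------------------------------------------------------
# external tblout adapter


def test_tblout_adapter_parses_hmmer_table(tmp_path):
    path = tmp_path / "hits.tbl"
    path.write_text(
        "# comment line\n"
        "AEE76455.1 - 1001705at2759 - 1.2e-70 242.5 0.1 "
        "1.3e-70 242.1 0.1 1.0 1 0 0 1 1 1 1 desc\n"
        "AEE78573.1 - 1001705at2759 - 2.0e-15 64.5 0.0 "
        "2.1e-15 64.1 0.0 1.0 1 0 0 1 1 1 1 desc\n"
    )
    (result,) = read_tblout(path, proteome_label="athaliana", Z=1000)
    assert result.hmm_name == "1001705at2759"
    assert [h.target_id for h in result.hits] == ["AEE76455.1", "AEE78573.1"]
    assert result.hits[0].bitscore == 242.5
    assert result.hits[1].evalue == 2.0e-15
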