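import itertools

import pytest

from orthohunt import (
    ConsistencyError,
    CopyNumberCall,
    ScoredMatch,
    SearchResult,
    TopHitSet,
)
from orthohunt.outputs import (
    LONG_HEADER,
    SHORT_HEADER,
    write_long_summary,
    write_search_output,
    write_short_summary,
)


def _call(hmm, label, n):
    status = "absent" if n == 0 else "single_copy" if n == 1 else "multi_copy"
    return CopyNumberCall(hmm_name=hmm, proteome_label=label, status=status,
                          count=n, kept_ids=tuple(f"{hmm}_h{i}" for i in range(n)))


def _top(hmm, label, scores):
    kept = tuple(
        ScoredMatch(target_id=f"{hmm}_h{i}", bitscore=s, evalue=1e-9)
        for i, s in enumerate(scores)
    )
    return TopHitSet(hmm_name=hmm, proteome_label=label, kept=kept,
                     fraction=0.85, best_score=scores[0] if scores else None)


# ---------------------------------------------------------------------------
# search tables


def test_one_search_table_per_pair_with_deterministic_names(tmp_path):
    results = [
        SearchResult(hmm_name=h, proteome_label=p, hits=(), Z=5)
        for p, h in itertools.product(["pA", "pB"], ["q1", "q2"])
    ]
    paths = write_search_output(results, tmp_path)
    assert [p.name for p in paths] == [
        "pA__q1.tsv", "pA__q2.tsv", "pB__q1.tsv", "pB__q2.tsv"
    ]
    assert paths[0].read_text() == "# target\tquery\tevalue\tbitscore\n"


def test_search_table_rows_round_trip_exactly(tmp_path):
    hits = (
        ScoredMatch(target_id="a", bitscore=123.456789012345, evalue=3.2e-41),
        ScoredMatch(target_id="b", bitscore=45.1, evalue=0.0009999999999),
    )
    result = SearchResult(hmm_name="q", proteome_label="p", hits=hits, Z=9)
    (path,) = write_search_output([result], tmp_path)
    rows = [line.split("\t") for line in path.read_text().splitlines()[1:]]
    parsed = [(r[0], float(r[3]), float(r[2])) for r in rows]
    assert parsed == [(h.target_id, h.bitscore, h.evalue) for h in hits]


# ---------------------------------------------------------------------------
# FASTA outputs driven by a real pipeline run


def _parse_fasta_headers(path):
    return [line[1:].split("|") for line in path.read_text().splitlines()
            if line.startswith(">")]


def test_all_sequences_headers_map_back_to_calls(small_run):
    _, fixture, _, summary = small_run
    kept = {
        (t.hmm_name, t.proteome_label): [h.target_id for h in t.kept]
        for t in summary.tophits
    }
    for fa in (summary.output_dir / "all_sequences").glob("*.fa"):
        hmm_name = fa.stem
        seen = {}
        for label, target in _parse_fasta_headers(fa):
            seen.setdefault((hmm_name, label), []).append(target)
        for cell, ids in seen.items():
            assert ids == kept[cell]


def test_scog_is_all_sequences_restricted_to_single_copy(small_run):
    _, _, _, summary = small_run
    status = {(c.hmm_name, c.proteome_label): c.status for c in summary.calls}
    for fa in (summary.output_dir / "scog").glob("*.fa"):
        allseq = summary.output_dir / "all_sequences" / fa.name
        scog_headers = {tuple(h) for h in _parse_fasta_headers(fa)}
        all_headers = {tuple(h) for h in _parse_fasta_headers(allseq)}
        expected = {
            (label, target) for label, target in all_headers
            if status[(fa.stem, label)] == "single_copy"
        }
        assert scog_headers == expected


def test_scog_has_at_most_one_sequence_per_proteome(small_run):
    _, _, _, summary = small_run
    for fa in (summary.output_dir / "scog").glob("*.fa"):
        labels = [label for label, _ in _parse_fasta_headers(fa)]
        assert len(labels) == len(set(labels))


# ---------------------------------------------------------------------------
# summaries


def test_short_summary_counts_and_percentages(tmp_path):
    """1 profile, 4 proteomes, statuses (single, single, multi, absent) ->
    2 / 50.00, 1 / 25.00, 1 / 25.00."""
    calls = [
        _call("q1", "p1", 1), _call("q1", "p2", 1),
        _call("q1", "p3", 2), _call("q1", "p4", 0),
    ]
    path = write_short_summary(calls, tmp_path / "short.txt")
    lines = path.read_text().splitlines()
    assert lines[0] == SHORT_HEADER
    assert lines[1] == "q1\t2\t50.00\t1\t25.00\t1\t25.00"


def test_short_summary_percentages_sum_to_100(tmp_path):
    calls = [_call("q1", f"p{i}", i % 3) for i in range(1, 8)]
    path = write_short_summary(calls, tmp_path / "short.txt")
    row = path.read_text().splitlines()[1].split("\t")
    assert abs(sum(float(row[i]) for i in (2, 4, 6)) - 100.0) <= 0.02


def test_long_summary_row_count_and_placeholders(tmp_path):
    calls = [_call("q1", "p1", 2), _call("q1", "p2", 0), _call("q2", "p1", 1),
             _call("q2", "p2", 1)]
    tops = [_top("q1", "p1", [90.0, 80.0]), _top("q1", "p2", []),
            _top("q2", "p1", [70.0]), _top("q2", "p2", [60.0])]
    path = write_long_summary(calls, tops, tmp_path / "long.txt")
    lines = path.read_text().splitlines()
    assert lines[0] == LONG_HEADER
    kept_total = sum(c.count for c in calls)
    absent_total = sum(1 for c in calls if c.status == "absent")
    assert len(lines) - 1 == kept_total + absent_total
    placeholder = [l for l in lines if "\tabsent\t" in l]
    assert placeholder == ["p2\tq1\tabsent\t-\t-\t-"]


def test_long_summary_missing_pair_is_a_consistency_error(tmp_path):
    calls = [_call("q1", "p1", 1)]
    with pytest.raises(ConsistencyError):
        write_long_summary(calls, [], tmp_path / "long.txt")


def test_empty_inputs_give_header_only_summaries(tmp_path):
    short = write_short_summary([], tmp_path / "short.txt")
    long_ = write_long_summary([], [], tmp_path / "long.txt")
    assert short.read_text() == SHORT_HEADER + "\n"
    assert long_.read_text() == LONG_HEADER + "\n"


def test_short_summary_recomputable_from_long_summary(small_run):
    """Cross-file consistency: tallying long_summary rows reproduces every
    short_summary count."""
    _, _, _, summary = small_run
    long_lines = (summary.output_dir / "long_summary.txt").read_text().splitlines()[1:]
    tally: dict = {}
    for line in long_lines:
        proteome, hmm, status = line.split("\t")[:3]
        tally.setdefault(hmm, set()).add((proteome, status))
    short_lines = (summary.output_dir / "short_summary.txt").read_text().splitlines()[1:]
    for line in short_lines:
        hmm, single, _, multi, _, absent, _ = line.split("\t")
        by_status = {"single_copy": 0, "multi_copy": 0, "absent": 0}
        for _, status in tally[hmm]:
            by_status[status] += 1
        assert (int(single), int(multi), int(absent)) == (
            by_status["single_copy"], by_status["multi_copy"], by_status["absent"]
        )
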