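"""The pipeline's output-file suite.

Three directories and two summary files per run:

* ``hmmsearch_output/`` — one TSV of E-value-passing hits per
  (proteome, profile) pair;
* ``all_sequences/`` — one multi-FASTA per profile holding every kept
  homologous sequence, headers ``>{proteome_label}|{target_id}``;
* ``scog/`` — one multi-FASTA per profile holding, for each proteome in
  which the gene is single-copy, that proteome's one kept sequence
  (phylogenomics-ready per-marker files);
* ``short_summary.txt`` — per-profile counts and percentages of
  single-copy / multi-copy / absent proteomes;
* ``long_summary.txt`` — one row per kept hit (plus a ``-`` placeholder row
  per absent pair) with score and E-value.

File names, column layouts and sort orders are fixed so the whole output
tree is byte-identical across repeated runs on the same inputs.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .core import ABSENT, SINGLE_COPY, CopyNumberCall, TopHitSet
from .engine import SearchResult
from .errors import ConsistencyError
from .io import ProteinRecord, Proteome, write_fasta

SEARCH_DIR = "hmmsearch_output"
ALLSEQ_DIR = "all_sequences"
SCOG_DIR = "scog"
SHORT_SUMMARY = "short_summary.txt"
LONG_SUMMARY = "long_summary.txt"

SHORT_HEADER = "hmm\tsingle_copy\tsingle_copy_pct\tmulti_copy\tmulti_copy_pct\tabsent\tabsent_pct"
LONG_HEADER = "proteome\thmm\tstatus\ttarget_id\tbitscore\tevalue"


def _pct(count: int, total: int) -> str:
    """Percentage over ``total`` proteomes, 2 decimals, half-up rounding."""
    value = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return f"{value:.2f}"


def write_search_output(results: list[SearchResult], dir: str | Path) -> list[Path]:
    """One hit table per (proteome, profile) pair, score-descending rows.

    Numeric cells use shortest-round-trip float formatting, so re-parsing a
    row reproduces the in-memory values exactly.
    """
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for result in sorted(results, key=lambda r: (r.proteome_label, r.hmm_name)):
        path = dir / f"{result.proteome_label}__{result.hmm_name}.tsv"
        with open(path, "w") as out:
            out.write("# target\tquery\tevalue\tbitscore\n")
            for hit in result.hits:
                out.write(
                    f"{hit.target_id}\t{result.hmm_name}\t{hit.evalue!r}\t{hit.bitscore!r}\n"
                )
        paths.append(path)
    return paths


def _kept_records(
    tophits: list[TopHitSet], proteomes: list[Proteome], *, single_copy_only: bool,
    calls: list[CopyNumberCall] | None = None,
) -> dict[str, list[ProteinRecord]]:
    """Per-profile homolog records in (proteome input order, kept order)."""
    status = {}
    if calls is not None:
        status = {(c.hmm_name, c.proteome_label): c.status for c in calls}
    by_label = {p.label: p for p in proteomes}
    per_hmm: dict[str, list[ProteinRecord]] = {t.hmm_name: [] for t in tophits}
    order = {p.label: i for i, p in enumerate(proteomes)}
    for top in sorted(tophits, key=lambda t: order.get(t.proteome_label, 0)):
        if single_copy_only and status.get((top.hmm_name, top.proteome_label)) != SINGLE_COPY:
            continue
        proteome = by_label.get(top.proteome_label)
        if proteome is None:
            raise ConsistencyError(f"unknown proteome label {top.proteome_label!r}")
        for hit in top.kept:
            try:
                rec = proteome.get(hit.target_id)
            except KeyError:
                raise ConsistencyError(
                    f"kept id {hit.target_id!r} not found in proteome "
                    f"{top.proteome_label!r} (upstream bug)"
                ) from None
            per_hmm[top.hmm_name].append(
                ProteinRecord(id=f"{top.proteome_label}|{hit.target_id}",
                              residues=rec.residues)
            )
    return per_hmm


def write_all_sequences(
    tophits: list[TopHitSet], proteomes: list[Proteome], dir: str | Path
) -> list[Path]:
    """One ``<hmm_name>.fa`` per profile with every kept homolog."""
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    per_hmm = _kept_records(tophits, proteomes, single_copy_only=False)
    paths = []
    for hmm_name in sorted(per_hmm):
        path = dir / f"{hmm_name}.fa"
        write_fasta(per_hmm[hmm_name], path)
        paths.append(path)
    return paths


def write_scog(
    calls: list[CopyNumberCall], tophits: list[TopHitSet],
    proteomes: list[Proteome], dir: str | Path,
) -> list[Path]:
    """One ``<hmm_name>.fa`` per profile, single-copy proteomes only.

    A proteome where the gene is multi-copy or absent contributes nothing to
    that profile's file; other proteomes still contribute, so a marker is
    dropped per-proteome, never wholesale.
    """
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    per_hmm = _kept_records(tophits, proteomes, single_copy_only=True, calls=calls)
    paths = []
    for hmm_name in sorted(per_hmm):
        path = dir / f"{hmm_name}.fa"
        write_fasta(per_hmm[hmm_name], path)
        paths.append(path)
    return paths


def write_short_summary(calls: list[CopyNumberCall], path: str | Path) -> Path:
    """Per-profile status counts and percentages over the proteome count."""
    path = Path(path)
    labels = sorted({c.proteome_label for c in calls})
    n = len(labels)
    per_hmm: dict[str, dict[str, int]] = {}
    for call in calls:
        row = per_hmm.setdefault(call.hmm_name, {s: 0 for s in ("single_copy", "multi_copy", "absent")})
        row[call.status] += 1
    with open(path, "w") as out:
        out.write(SHORT_HEADER + "\n")
        for hmm_name in sorted(per_hmm):
            row = per_hmm[hmm_name]
            if sum(row.values()) != n:
                raise ConsistencyError(
                    f"profile {hmm_name!r} has {sum(row.values())} calls for {n} proteomes"
                )
            out.write(
                f"{hmm_name}\t{row['single_copy']}\t{_pct(row['single_copy'], n)}"
                f"\t{row['multi_copy']}\t{_pct(row['multi_copy'], n)}"
                f"\t{row['absent']}\t{_pct(row['absent'], n)}\n"
            )
    return path


def write_long_summary(
    calls: list[CopyNumberCall], tophits: list[TopHitSet], path: str | Path
) -> Path:
    """One row per kept hit; absent pairs get a ``-`` placeholder row."""
    path = Path(path)
    top_index = {(t.hmm_name, t.proteome_label): t for t in tophits}
    rows = []
    for call in calls:
        top = top_index.get((call.hmm_name, call.proteome_label))
        if top is None:
            raise ConsistencyError(
                f"no top-hit set for {call.hmm_name!r} x {call.proteome_label!r}"
            )
        if call.status == ABSENT:
            rows.append((call.proteome_label, call.hmm_name, call.status, "-", "-", "-"))
        else:
            for hit in top.kept:
                rows.append(
                    (call.proteome_label, call.hmm_name, call.status,
                     hit.target_id, repr(hit.bitscore), repr(hit.evalue))
                )
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as out:
        out.write(LONG_HEADER + "\n")
        for row in rows:
            out.write("\t".join(row) + "\n")
    return path


def write_all_outputs(
    results: list[SearchResult], tophits: list[TopHitSet],
    calls: list[CopyNumberCall], proteomes: list[Proteome], out_dir: str | Path,
) -> list[Path]:
    """Write the full output tree under ``out_dir``; returns all file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    written += write_search_output(results, out_dir / SEARCH_DIR)
    written += write_all_sequences(tophits, proteomes, out_dir / ALLSEQ_DIR)
    written += write_scog(calls, tophits, proteomes, out_dir / SCOG_DIR)
    written.append(write_short_summary(calls, out_dir / SHORT_SUMMARY))
    written.append(write_long_summary(calls, tophits, out_dir / LONG_SUMMARY))
    return written
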