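"""Best-hit fraction filtering, copy-number classification, and orchestration.

The defining rule: within one profile-vs-proteome search, every hit whose bit
score is greater than or equal to ``fraction`` (default 0.85) times the best
hit's score is kept as a putative homolog — the same top-hit criterion the
BUSCO pipeline applies.  The number of kept hits then classifies the gene in
that proteome as single-copy, multi-copy, or absent.
"""

from __future__ import annotations

import logging
import math
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .engine import SearchResult, search_proteome
from .errors import PipelineError
from .io import Proteome, read_fasta, read_path_list, read_profile_hmms

log = logging.getLogger(__name__)

SINGLE_COPY = "single_copy"
MULTI_COPY = "multi_copy"
ABSENT = "absent"
STATUSES = (SINGLE_COPY, MULTI_COPY, ABSENT)


@dataclass(frozen=True)
class TopHitSet:
    """Hits surviving the bitscore-fraction filter for one (profile, proteome)."""

    hmm_name: str
    proteome_label: str
    kept: tuple  # of ScoredMatch, in SearchResult order
    fraction: float
    best_score: float | None  # None when the search had no hits


@dataclass(frozen=True)
class CopyNumberCall:
    hmm_name: str
    proteome_label: str
    status: str
    count: int
    kept_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        expected = ABSENT if self.count == 0 else SINGLE_COPY if self.count == 1 else MULTI_COPY
        if self.status != expected or self.count != len(self.kept_ids):
            raise ValueError("inconsistent copy-number call")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (defaults: E <= 0.001, fraction 0.85)."""

    hmm_list_path: str | Path
    fasta_list_path: str | Path
    output_dir: str | Path
    evalue_max: float = 0.001
    bitscore_fraction: float = 0.85
    allow_missing_stats: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.bitscore_fraction <= 1.0:
            raise ValueError(
                f"bitscore fraction must be in [0, 1], got {self.bitscore_fraction}"
            )
        if not self.evalue_max > 0:
            raise ValueError(f"E-value threshold must be positive, got {self.evalue_max}")


@dataclass
class RunSummary:
    """What a pipeline run produced: calls, per-profile tallies, file paths."""

    calls: list[CopyNumberCall]
    tophits: list[TopHitSet]
    results: list[SearchResult]
    output_dir: Path
    files_written: list[Path] = field(default_factory=list)

    def status_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in STATUSES}
        for call in self.calls:
            counts[call.status] += 1
        return counts

    def per_profile_counts(self) -> dict[str, dict[str, int]]:
        table: dict[str, dict[str, int]] = {}
        for call in self.calls:
            row = table.setdefault(call.hmm_name, {s: 0 for s in STATUSES})
            row[call.status] += 1
        return table


def select_top_hits(result: SearchResult, fraction: float) -> TopHitSet:
    """Keep every hit scoring >= ``fraction`` x the best hit's score.

    The comparison is inclusive, so a hit exactly at the threshold survives.
    At ``fraction == 0`` the threshold is taken as -inf, so every
    E-value-passing hit is kept (the relaxed, gene-family-census regime).
    The threshold is ``fraction * best`` algebraically, which for a negative
    best score exceeds the best score itself; only the best hit then survives.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if not result.hits:
        return TopHitSet(result.hmm_name, result.proteome_label, (), fraction, None)
    best = result.hits[0].bitscore
    threshold = -math.inf if fraction == 0.0 else fraction * best
    kept = tuple(h for h in result.hits if h.bitscore >= threshold or h.bitscore == best)
    return TopHitSet(result.hmm_name, result.proteome_label, kept, fraction, best)


def classify_copy_number(tophits: TopHitSet) -> CopyNumberCall:
    """Single-copy, multi-copy or absent, from the size of the kept set."""
    count = len(tophits.kept)
    status = ABSENT if count == 0 else SINGLE_COPY if count == 1 else MULTI_COPY
    return CopyNumberCall(
        hmm_name=tophits.hmm_name,
        proteome_label=tophits.proteome_label,
        status=status,
        count=count,
        kept_ids=tuple(h.target_id for h in tophits.kept),
    )


def run_pipeline(config: RunConfig) -> RunSummary:
    """Search every profile against every proteome, filter, classify, write.

    Outer loop over proteomes, inner over profiles.  All artifacts are
    written to a temporary directory and promoted to ``config.output_dir``
    only on success; the run is deterministic end-to-end for fixed inputs.
    """
    from . import outputs  # local import: outputs depends on core's types

    hmm_entries = read_path_list(config.hmm_list_path, "hmm")
    fasta_entries = read_path_list(config.fasta_list_path, "fasta")

    hmms = []
    for hmm_path, _ in hmm_entries:
        try:
            hmms.extend(read_profile_hmms(hmm_path))
        except Exception as exc:
            raise PipelineError(f"failed to parse profiles from {hmm_path}: {exc}") from exc
    proteomes: list[Proteome] = []
    for fasta_path, label in fasta_entries:
        try:
            proteomes.append(read_fasta(fasta_path, label=label))
        except Exception as exc:
            raise PipelineError(f"failed to parse proteome {fasta_path}: {exc}") from exc

    results: list[SearchResult] = []
    tophits: list[TopHitSet] = []
    calls: list[CopyNumberCall] = []
    for proteome in proteomes:
        for hmm in hmms:
            try:
                result = search_proteome(
                    hmm, proteome, config.evalue_max,
                    allow_missing_stats=config.allow_missing_stats,
                )
                top = select_top_hits(result, config.bitscore_fraction)
                call = classify_copy_number(top)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(
                    f"pipeline failed at profile {hmm.name!r} x proteome "
                    f"{proteome.label!r} (search/filter stage): {exc}"
                ) from exc
            log.info(
                "%s x %s: %d hit(s), %s",
                hmm.name, proteome.label, call.count, call.status,
            )
            results.append(result)
            tophits.append(top)
            calls.append(call)

    out_dir = Path(config.output_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=".orthohunt_", dir=out_dir.parent))
    try:
        written = outputs.write_all_outputs(results, tophits, calls, proteomes, tmp)
        if out_dir.exists():
            shutil.rmtree(out_dir)
        tmp.replace(out_dir)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    files = [out_dir / p.relative_to(tmp) for p in written]

    summary = RunSummary(
        calls=calls, tophits=tophits, results=results,
        output_dir=out_dir, files_written=files,
    )
    counts = summary.status_counts()
    assert sum(counts.values()) == len(hmms) * len(proteomes)
    return summary
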