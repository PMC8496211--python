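"""Seeded synthetic profiles and proteomes with planted ground truth.

Every stage of the pipeline is testable without downloads: this module
builds toy profile HMMs (sharply peaked match emissions on a random
consensus), emits diverged homologs from them, pads proteomes with
background-random decoy sequences, and writes the exact on-disk inputs the
pipeline consumes plus a ``truth.tsv`` recording the planted copy-number
status of every (profile, proteome) cell.

What it emulates: clear homology signal against a background of unrelated
sequences, recent gene duplications (a multi-copy cell holds a homolog and a
lightly re-substituted copy of it), and gene loss (absent cells).  What it
does not emulate: indels, site-rate heterogeneity, phylogenetic correlation
among proteomes, or compositional bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .engine import forward_bitscore
from .io import (
    AMINO_ALPHABET,
    ForwardStats,
    ProfileHMM,
    ProteinRecord,
    write_fasta,
    write_profile_hmm,
)

# default conditions of the synthetic study (see docs/methods.md)
DEFAULT_PROFILE_LENGTH = 60
DEFAULT_DOMINANT_P = 0.9
DEFAULT_DIVERGENCE = 0.10
DEFAULT_DUPLICATION_DIVERGENCE = 0.01
DEFAULT_N_DECOYS = 20

_CALIBRATION_N = 200
_CALIBRATION_QUANTILE = 0.90


@dataclass(frozen=True)
class FixtureScenario:
    """A planted study design: which status goes in which grid cell."""

    n_profiles: int
    n_proteomes: int
    status_grid: tuple[tuple[str, ...], ...]  # [profile][proteome]
    seed: int
    divergence: float = DEFAULT_DIVERGENCE
    duplication_divergence: float = DEFAULT_DUPLICATION_DIVERGENCE
    n_decoys: int = DEFAULT_N_DECOYS
    profile_length: int = DEFAULT_PROFILE_LENGTH
    #: also plant, in every non-absent cell, a homolog truncated to ~40% of
    #: the profile length: it passes the E-value filter but scores between
    #: the relaxed (0.25) and strict (0.85) fraction thresholds
    hard_decoys: bool = False

    def __post_init__(self) -> None:
        if len(self.status_grid) != self.n_profiles or any(
            len(row) != self.n_proteomes for row in self.status_grid
        ):
            raise ValueError("status grid does not match n_profiles x n_proteomes")
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")

    @classmethod
    def cycle(cls, n_profiles: int = 3, n_proteomes: int = 4, seed: int = 0, **kw):
        """Deterministic mixed grid cycling single/multi/absent across cells."""
        statuses = ("single_copy", "multi_copy", "absent")
        grid = tuple(
            tuple(statuses[(i + j) % 3] for j in range(n_proteomes))
            for i in range(n_profiles)
        )
        return cls(n_profiles=n_profiles, n_proteomes=n_proteomes,
                   status_grid=grid, seed=seed, **kw)

    @classmethod
    def all_single(cls, n_profiles: int = 3, n_proteomes: int = 2, seed: int = 0, **kw):
        grid = tuple(
            tuple("single_copy" for _ in range(n_proteomes)) for _ in range(n_profiles)
        )
        return cls(n_profiles=n_profiles, n_proteomes=n_proteomes,
                   status_grid=grid, seed=seed, **kw)


@dataclass
class FixturePaths:
    """Everything :func:`build_fixture` wrote."""

    root: Path
    hmm_list: Path
    fasta_list: Path
    truth_tsv: Path
    hmm_files: list[Path] = field(default_factory=list)
    fasta_files: list[Path] = field(default_factory=list)
    truth: dict[tuple[str, str], str] = field(default_factory=dict)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def make_toy_profile(
    length: int,
    seed,
    name: str | None = None,
    dominant_p: float = DEFAULT_DOMINANT_P,
    calibrate: bool = True,
) -> ProfileHMM:
    """Build a sharply peaked toy profile on a random consensus.

    Each match state emits a randomly chosen consensus residue with
    probability ``dominant_p`` and spreads the rest uniformly; insert states
    emit the (uniform) background.  Forward-score calibration is empirical:
    the profile is scored against background-random sequences and an
    exponential tail is fitted above the 90th percentile (tau is then the
    score at which the fitted tail probability reaches 1).
    """
    if length < 1:
        raise ValueError("profile length must be >= 1")
    rng = _rng(seed)
    consensus_idx = rng.integers(0, 20, size=length)
    match = np.full((length, 20), (1.0 - dominant_p) / 19.0)
    match[np.arange(length), consensus_idx] = dominant_p
    insert = np.full((length, 20), 0.05)
    trans = np.zeros((length, 7))
    # generic well-behaved node transitions; node M must exit (no m->d / d->d)
    trans[:] = np.log([0.95, 0.025, 0.025, 0.8, 0.2, 0.8, 0.2])
    trans[-1] = [math.log(0.975), math.log(0.025), -math.inf,
                 math.log(0.8), math.log(0.2), 0.0, -math.inf]
    hmm = ProfileHMM(
        name=name or f"toy{int(rng.integers(0, 10**6)):06d}",
        match_emissions=np.log(match),
        insert_emissions=np.log(insert),
        transitions=trans,
        background=np.full(20, 0.05),
    )
    if calibrate:
        hmm.forward_stats = calibrate_profile(hmm, seed=rng.integers(0, 2**31))
    hmm.validate()
    return hmm


def random_background_sequence(rng: np.random.Generator, length: int,
                               background: np.ndarray | None = None) -> str:
    p = background if background is not None else np.full(20, 0.05)
    idx = rng.choice(20, size=length, p=p / p.sum())
    return "".join(AMINO_ALPHABET[i] for i in idx)


def calibrate_profile(
    hmm: ProfileHMM, seed, n: int = _CALIBRATION_N,
) -> ForwardStats:
    """Fit the exponential score tail on background-random sequences.

    Null sequence lengths match the profile length.  With tail threshold
    ``u`` (90th percentile) and exceedance mean ``m``, the fit is
    ``lam = 1/m`` and ``tau = u + ln(0.1)/lam`` so that
    ``P(S >= s) ~= exp(-lam (s - tau))`` with P capped at 1.
    """
    rng = _rng(seed)
    scores = np.array([
        forward_bitscore(hmm, random_background_sequence(rng, hmm.M, hmm.background))
        for _ in range(n)
    ])
    u = float(np.quantile(scores, _CALIBRATION_QUANTILE))
    tail = scores[scores > u]
    if tail.size == 0:  # pathological tie at the quantile
        tail = np.array([u + 0.5])
    mean_excess = float(np.mean(tail - u))
    lam = 1.0 / max(mean_excess, 1e-3)
    tau = u + math.log(1.0 - _CALIBRATION_QUANTILE) / lam
    return ForwardStats(tau=tau, lam=lam)


def emit_homolog(
    hmm: ProfileHMM, divergence: float, seed, replicate: int = 1,
) -> ProteinRecord:
    """Sample a homolog: the consensus with per-site background substitutions.

    Each site is substituted with probability ``divergence``; the replacement
    is drawn from the background renormalised over the 19 other residues, so
    ``divergence`` is the expected Hamming fraction.  The record id encodes
    (profile name, replicate) for ground-truth tracking.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = _rng(seed)
    return mutate_record(
        ProteinRecord(id=f"{hmm.name}_h{replicate}", residues=hmm.consensus()),
        divergence, rng, hmm.background,
    )


def mutate_record(
    record: ProteinRecord, rate: float, rng: np.random.Generator,
    background: np.ndarray, new_id: str | None = None,
) -> ProteinRecord:
    """Re-substitute each site with probability ``rate`` (always to a
    different residue, background-weighted)."""
    residues = list(record.residues)
    for i, orig in enumerate(residues):
        if rng.random() < rate:
            p = background.copy()
            j = AMINO_ALPHABET.find(orig)
            if j >= 0:
                p[j] = 0.0
            p = p / p.sum()
            residues[i] = AMINO_ALPHABET[rng.choice(20, p=p)]
    return ProteinRecord(id=new_id or record.id, residues="".join(residues),
                         description=record.description)


def build_fixture(scenario: FixtureScenario, dir: str | Path) -> FixturePaths:
    """Materialise a scenario on disk: profiles, proteomes, lists, truth.

    Layout under ``dir``::

        hmms/fam01.hmm ...      proteomes/taxon01.faa ...
        hmm_list.txt            fasta_list.txt          truth.tsv

    Same scenario (including seed) -> byte-identical files.
    """
    root = Path(dir)
    (root / "hmms").mkdir(parents=True, exist_ok=True)
    (root / "proteomes").mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(scenario.seed)
    profile_seeds = master.integers(0, 2**31, size=scenario.n_profiles)
    hmms = [
        make_toy_profile(scenario.profile_length, int(profile_seeds[i]),
                         name=f"fam{i + 1:02d}")
        for i in range(scenario.n_profiles)
    ]
    hmm_files = []
    for hmm in hmms:
        path = root / "hmms" / f"{hmm.name}.hmm"
        write_profile_hmm(hmm, path)
        hmm_files.append(path)

    truth: dict[tuple[str, str], str] = {}
    fasta_files = []
    labels = [f"taxon{j + 1:02d}" for j in range(scenario.n_proteomes)]
    for j, label in enumerate(labels):
        rng = np.random.default_rng([scenario.seed, 1000 + j])
        records: list[ProteinRecord] = []
        for i, hmm in enumerate(hmms):
            status = scenario.status_grid[i][j]
            truth[(hmm.name, label)] = status
            if status == "absent":
                continue
            parent = emit_homolog(
                hmm, scenario.divergence, rng.integers(0, 2**31), replicate=1
            )
            records.append(parent)
            if status == "multi_copy":
                # recent duplication: a lightly re-substituted copy of the parent
                records.append(mutate_record(
                    parent, scenario.duplication_divergence, rng, hmm.background,
                    new_id=f"{hmm.name}_h2",
                ))
            if scenario.hard_decoys:
                stub = ProteinRecord(
                    id=f"{hmm.name}_trunc",
                    residues=hmm.consensus()[: max(5, int(0.4 * hmm.M))],
                )
                records.append(mutate_record(
                    stub, scenario.divergence, rng, hmm.background
                ))
        for d in range(scenario.n_decoys):
            length = int(rng.integers(
                max(10, scenario.profile_length // 2),
                scenario.profile_length * 3 // 2 + 1,
            ))
            records.append(ProteinRecord(
                id=f"decoy{d + 1:03d}",
                residues=random_background_sequence(rng, length),
            ))
        path = root / "proteomes" / f"{label}.faa"
        write_fasta(records, path)
        fasta_files.append(path)

    hmm_list = root / "hmm_list.txt"
    hmm_list.write_text("".join(f"hmms/{p.name}\n" for p in hmm_files))
    fasta_list = root / "fasta_list.txt"
    fasta_list.write_text(
        "".join(f"proteomes/{p.name}\t{lbl}\n" for p, lbl in zip(fasta_files, labels))
    )
    truth_tsv = root / "truth.tsv"
    with open(truth_tsv, "w") as out:
        out.write("hmm\tproteome\tstatus\n")
        for (hmm_name, label), status in sorted(truth.items()):
            out.write(f"{hmm_name}\t{label}\t{status}\n")
    return FixturePaths(
        root=root, hmm_list=hmm_list, fasta_list=fasta_list, truth_tsv=truth_tsv,
        hmm_files=hmm_files, fasta_files=fasta_files, truth=truth,
    )
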