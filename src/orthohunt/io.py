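"""On-disk formats: protein FASTA, HMMER3 text profiles, and path-list files.

Profiles are stored on disk in the plain-text ``HMMER3/f`` dialect, the format
written by ``hmmbuild``.  Stored values are negative natural logarithms of
probabilities; this module negates them on read, so :class:`ProfileHMM` holds
natural-log probabilities (``-inf`` marks an impossible event, stored as ``*``
in the file).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import FormatError, InputError

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: residue -> column index in emission matrices
AMINO_INDEX = {aa: i for i, aa in enumerate(AMINO_ALPHABET)}

#: order of the seven per-node transition probabilities in HMMER3 files
TRANSITION_ORDER = ("m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d")

#: uniform fallback background used when a profile file carries no COMPO line
DEFAULT_BACKGROUND = np.full(20, 0.05)

_EMISSION_SUM_TOL = 1e-3  # files store 5-decimal values; rows sum to 1 loosely


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence: FASTA id token, free-text description, residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid record id {self.id!r}")
        if not self.residues:
            raise FormatError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Proteome:
    """An ordered set of uniquely identified proteins with a taxon label."""

    label: str
    source_path: str
    records: tuple[ProteinRecord, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FormatError(
                    f"duplicate sequence id {rec.id!r} in proteome {self.label!r}"
                )
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, record_id: str) -> ProteinRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)


@dataclass(frozen=True)
class ForwardStats:
    """Exponential-tail calibration of forward bit scores.

    ``P(S >= s) = exp(-lam * (s - tau))`` (capped at 1), with ``tau`` in bits
    and ``lam`` the per-bit decay rate.
    """

    tau: float
    lam: float

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise FormatError(f"forward-stat lambda must be positive, got {self.lam}")


@dataclass
class ProfileHMM:
    """A position-specific scoring model over the 20-letter protein alphabet.

    Emission and transition matrices hold natural-log probabilities; rows of
    ``match_emissions`` / ``insert_emissions`` exponentiate-and-sum to 1.
    ``transitions`` has one row per match node in :data:`TRANSITION_ORDER`;
    row *M*'s forward moves point at the (implicit) end state.
    """

    name: str
    match_emissions: np.ndarray  # (M, 20) ln p
    insert_emissions: np.ndarray  # (M, 20) ln p
    transitions: np.ndarray  # (M, 7) ln p
    background: np.ndarray  # (20,) probabilities
    accession: str | None = None
    forward_stats: ForwardStats | None = None
    # node-0 lines of the file, kept only so serialization round-trips
    insert0_emissions: np.ndarray | None = None
    begin_transitions: np.ndarray | None = None
    _extra_header: list[str] = field(default_factory=list, repr=False)

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    def consensus(self) -> str:
        """Most probable residue of each match state."""
        return "".join(AMINO_ALPHABET[i] for i in np.argmax(self.match_emissions, axis=1))

    def validate(self) -> None:
        if self.M < 1:
            raise FormatError(f"profile {self.name!r}: M must be >= 1")
        for label, mat in (("match", self.match_emissions), ("insert", self.insert_emissions)):
            sums = np.exp(mat).sum(axis=1)
            bad = np.nonzero(np.abs(sums - 1.0) > _EMISSION_SUM_TOL)[0]
            if bad.size:
                raise FormatError(
                    f"profile {self.name!r}: {label} emission row {bad[0] + 1} "
                    f"sums to {sums[bad[0]]:.6f}, not 1"
                )
        if abs(float(self.background.sum()) - 1.0) > _EMISSION_SUM_TOL:
            raise FormatError(f"profile {self.name!r}: background does not sum to 1")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, label: str | None = None) -> Proteome:
    """Read a protein multi-FASTA file into a :class:`Proteome`.

    The record id is the first whitespace-delimited header token; the rest of
    the header becomes the description.  ``label`` defaults to the file
    basename without its extension.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).replace(" ", "").replace("\t", "")
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(ProteinRecord(id=rec.id, residues=seq, description=desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return Proteome(
        label=label if label is not None else path.stem,
        source_path=str(path),
        records=tuple(records),
    )


def write_fasta(records, path: str | Path, wrap: int = 80) -> None:
    """Write records as FASTA, sequence wrapped at ``wrap`` columns.

    Output is byte-deterministic for identical input (a file-level output
    contract of the pipeline), hence the explicit writer.
    """
    path = Path(path)
    try:
        with open(path, "w") as out:
            for rec in records:
                header = f">{rec.id} {rec.description}".rstrip()
                out.write(header + "\n")
                for i in range(0, len(rec.residues), wrap):
                    out.write(rec.residues[i:i + wrap] + "\n")
    except OSError as exc:
        raise InputError(f"cannot write FASTA to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# HMMER3 text profiles


def _parse_logprob(token: str) -> float:
    if token == "*":
        return -math.inf
    return -float(token)  # file stores -ln p


def _format_logprob(value: float) -> str:
    if value == -math.inf:
        return "*"
    return f"{-value:.5f}"


def _numeric_fields(tokens, n, context):
    if len(tokens) < n:
        raise FormatError(f"{context}: expected {n} values, found {len(tokens)}")
    return [_parse_logprob(t) for t in tokens[:n]]


def read_profile_hmms(path: str | Path) -> list[ProfileHMM]:
    """Parse every model in a HMMER3/f text file (models separated by ``//``)."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"profile file not found: {path}")
    models: list[ProfileHMM] = []
    with open(path) as handle:
        lines = iter(enumerate(handle, start=1))
        for lineno, line in lines:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if not line.startswith("HMMER3/f"):
                raise FormatError(
                    f"{path}:{lineno}: unsupported profile format "
                    f"(expected 'HMMER3/f', got {line.split()[0]!r})"
                )
            models.append(_parse_one_model(path, lines))
    if not models:
        raise FormatError(f"{path}: no profile models found")
    return models


def _parse_one_model(path, lines) -> ProfileHMM:
    name = accession = None
    leng = None
    forward_stats = None
    extra_header: list[str] = []
    background = None

    for lineno, line in lines:
        line = line.rstrip("\n")
        stripped = line.strip()
        if not stripped:
            continue
        key, _, value = stripped.partition(" ")
        value = value.strip()
        if key == "NAME":
            name = value
        elif key == "ACC":
            accession = value
        elif key == "LENG":
            leng = int(value)
        elif key == "ALPH":
            if value.lower() != "amino":
                raise FormatError(f"{path}:{lineno}: unsupported alphabet {value!r}")
        elif key in ("CONS", "RF", "MM", "CS", "MAP"):
            pass  # annotation-presence flags; annotations are regenerated on write
        elif key == "STATS":
            parts = value.split()
            if len(parts) == 4 and parts[0] == "LOCAL" and parts[1] == "FORWARD":
                forward_stats = ForwardStats(tau=float(parts[2]), lam=float(parts[3]))
            elif len(parts) == 4 and parts[0] == "LOCAL" and parts[1] in ("MSV", "VITERBI"):
                pass  # Viterbi/MSV Gumbel calibrations are not used here
            else:
                extra_header.append(stripped)
        elif key == "HMM":
            break
        else:
            extra_header.append(stripped)
    else:
        raise FormatError(f"{path}: model header ended without an HMM line")

    if name is None or leng is None:
        raise FormatError(f"{path}: model missing NAME or LENG")

    next(lines)  # transition-order header line

    match_rows, insert_rows, trans_rows = [], [], []
    insert0 = begin_trans = None

    lineno, line = next(lines)
    tokens = line.split()
    if tokens and tokens[0] == "COMPO":
        background = np.exp(_numeric_fields(tokens[1:], 20, f"{path}:{lineno} COMPO"))
        lineno, line = next(lines)
        tokens = line.split()
    # node 0: insert emissions then B-state transitions
    insert0 = np.array(_numeric_fields(tokens, 20, f"{path}:{lineno} insert0"))
    lineno, line = next(lines)
    begin_trans = np.array(_numeric_fields(line.split(), 7, f"{path}:{lineno} node0"))

    for node in range(1, leng + 1):
        lineno, line = next(lines)
        tokens = line.split()
        if not tokens or tokens[0] != str(node):
            raise FormatError(
                f"{path}:{lineno}: model {name!r} expected node {node}, got {tokens[:1]}"
            )
        match_rows.append(_numeric_fields(tokens[1:], 20, f"{path}:{lineno} node {node}"))
        lineno, line = next(lines)
        insert_rows.append(_numeric_fields(line.split(), 20, f"{path}:{lineno} insert {node}"))
        lineno, line = next(lines)
        trans_rows.append(_numeric_fields(line.split(), 7, f"{path}:{lineno} trans {node}"))

    for lineno, line in lines:
        if line.strip() == "//":
            break
    else:
        raise FormatError(f"{path}: model {name!r} not terminated by '//'")

    hmm = ProfileHMM(
        name=name,
        accession=accession,
        match_emissions=np.array(match_rows),
        insert_emissions=np.array(insert_rows),
        transitions=np.array(trans_rows),
        background=np.asarray(background) if background is not None else DEFAULT_BACKGROUND.copy(),
        forward_stats=forward_stats,
        insert0_emissions=insert0,
        begin_transitions=begin_trans,
        _extra_header=extra_header,
    )
    hmm.validate()
    return hmm


def write_profile_hmm(hmm: ProfileHMM, path: str | Path, append: bool = False) -> None:
    """Serialize a profile back to HMMER3/f text (5-decimal -ln values)."""
    hmm.validate()
    mode = "a" if append else "w"
    with open(path, mode) as out:
        out.write("HMMER3/f [orthohunt]\n")
        out.write(f"NAME  {hmm.name}\n")
        if hmm.accession:
            out.write(f"ACC   {hmm.accession}\n")
        out.write(f"LENG  {hmm.M}\n")
        out.write("ALPH  amino\n")
        out.write("CONS  yes\n")
        if hmm.forward_stats is not None:
            # MSV/VITERBI lines repeat the forward tail parameters: they are
            # unused by this engine but required by strict HMMER3/f readers.
            stats = f"{hmm.forward_stats.tau:8.4f} {hmm.forward_stats.lam:8.5f}\n"
            out.write(f"STATS LOCAL MSV     {stats}")
            out.write(f"STATS LOCAL VITERBI {stats}")
            out.write(f"STATS LOCAL FORWARD {stats}")
        out.write("HMM          " + "        ".join(AMINO_ALPHABET) + "\n")
        out.write("            " + "  ".join(TRANSITION_ORDER) + "\n")
        out.write("  COMPO   " + " ".join(f"{-math.log(b):.5f}" for b in hmm.background) + "\n")
        insert0 = hmm.insert0_emissions
        if insert0 is None:
            insert0 = np.log(hmm.background)
        out.write("          " + " ".join(_format_logprob(v) for v in insert0) + "\n")
        begin = hmm.begin_transitions
        if begin is None:
            # default B-state row: enter M1 with certainty; insert-0 self-loop off
            begin = np.array([0.0, -math.inf, -math.inf, 0.0, -math.inf, 0.0, -math.inf])
        out.write("          " + " ".join(_format_logprob(v) for v in begin) + "\n")
        consensus = hmm.consensus()
        for k in range(hmm.M):
            out.write(
                f"{k + 1:7d} "
                + " ".join(_format_logprob(v) for v in hmm.match_emissions[k])
                + f" {k + 1:7d} {consensus[k].lower()} - - -\n"
            )
            out.write("          " + " ".join(_format_logprob(v) for v in hmm.insert_emissions[k]) + "\n")
            out.write("          " + " ".join(_format_logprob(v) for v in hmm.transitions[k]) + "\n")
        out.write("//\n")


# ---------------------------------------------------------------------------
# path lists


def read_path_list(path: str | Path, kind: str) -> list[tuple[Path, str]]:
    """Read a one-path-per-line list file.

    Blank lines and ``#`` comments are skipped; relative paths resolve against
    the list file's directory.  For ``kind="fasta"`` an optional second
    tab-separated column supplies the taxon label; the label otherwise
    defaults to the listed file's basename without extension.
    """
    if kind not in ("hmm", "fasta"):
        raise ValueError(f"kind must be 'hmm' or 'fasta', got {kind!r}")
    path = Path(path)
    if not path.is_file():
        raise InputError(f"{kind} list file not found: {path}")
    base = path.parent
    entries: list[tuple[Path, str]] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            label = None
            if kind == "fasta" and "\t" in line:
                entry, label = line.split("\t", 1)
                entry, label = entry.strip(), label.strip()
            else:
                entry = line
            target = Path(entry)
            if not target.is_absolute():
                target = (base / target).resolve()
            if not target.is_file():
                raise InputError(f"{path}:{lineno}: listed file does not exist: {entry}")
            entries.append((target, label if label else target.stem))
    if not entries:
        raise InputError(f"{path}: list contains no usable entries")
    return entries
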