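"""Protein dataset handling: records, labelings, and project persistence.

A *project* is a directory holding ``sequences.fasta`` plus optional
``orf.fasta``, ``ss.fasta``, ``sa.fasta`` and ``labels/<name>.tsv`` files.
Sequences are validated against strict alphabets on every read; record
order is preserved across save/load round trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import validate_sequence

SEQ_KINDS = ("protein", "orf", "ss", "sa")


@dataclass
class ProteinRecord:
    """One protein with its amino-acid sequence and optional auxiliaries."""

    id: str
    aa_seq: str
    orf_seq: str | None = None
    ss_seq: str | None = None
    sa_seq: str | None = None

    def __post_init__(self) -> None:
        if not self.aa_seq:
            raise ValueError(f"empty amino-acid sequence for {self.id!r}")
        validate_sequence(self.aa_seq, "protein", self.id)
        for attr, kind in (("orf_seq", "orf"), ("ss_seq", "ss"), ("sa_seq", "sa")):
            seq = getattr(self, attr)
            if seq is None:
                continue
            validate_sequence(seq, kind, self.id)
            if kind in ("ss", "sa") and len(seq) != len(self.aa_seq):
                raise ValueError(
                    f"{kind} sequence of {self.id!r} has length {len(seq)}, "
                    f"expected {len(self.aa_seq)}"
                )
            if kind == "orf" and len(seq) % 3 != 0:
                raise ValueError(
                    f"ORF of {self.id!r} has length {len(seq)}, not divisible by 3"
                )


@dataclass
class Labeling:
    """A named assignment of class labels to protein ids."""

    name: str
    assignments: dict[str, str]
    class_names: list[str]

    def __post_init__(self) -> None:
        seen = set(self.assignments.values())
        missing = seen.difference(self.class_names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from class_names")

    def ids_for_class(self, cls: str) -> list[str]:
        return [i for i, c in self.assignments.items() if c == cls]


@dataclass
class ProteinSet:
    """Ordered collection of :class:`ProteinRecord` with attached labelings."""

    records: list[ProteinRecord] = field(default_factory=list)
    labelings: list[Labeling] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate protein ids: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, pid: str) -> ProteinRecord:
        for r in self.records:
            if r.id == pid:
                return r
        raise KeyError(pid)

    def labeling(self, name: str) -> Labeling:
        for lab in self.labelings:
            if lab.name == name:
                return lab
        raise KeyError(f"no labeling named {name!r}")


def _parse_fasta(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.read(1)
        if first != ">":
            raise ValueError(f"{path} is not FASTA (does not start with '>')")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        entries.append((rec.id, str(rec.seq).upper()))
    if not entries:
        raise ValueError(f"{path} contains no FASTA records")
    return entries


def read_fasta(path: str | Path, seq_kind: str = "protein"):
    """Read a FASTA file.

    For ``seq_kind='protein'`` returns a :class:`ProteinSet`; for ``orf``,
    ``ss`` and ``sa`` returns an id -> sequence dict to be attached to an
    existing set.  Sequences are uppercased and alphabet-validated.
    """
    if seq_kind not in SEQ_KINDS:
        raise ValueError(f"seq_kind must be one of {SEQ_KINDS}, got {seq_kind!r}")
    entries = _parse_fasta(path)
    if seq_kind == "protein":
        return ProteinSet(records=[ProteinRecord(i, s) for i, s in entries])
    for pid, seq in entries:
        validate_sequence(seq, seq_kind, pid)
    return dict(entries)


def read_labels(path: str | Path, pset: ProteinSet | None = None,
                name: str | None = None) -> Labeling:
    """Read a strict two-column TSV label file (id TAB label).

    Lines starting with ``#`` are ignored.  When ``pset`` is given, every
    labeled id must exist in it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    assignments: dict[str, str] = {}
    class_names: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            pid, label = parts
            if pid in assignments:
                if assignments[pid] != label:
                    raise ValueError(
                        f"{path}:{lineno}: id {pid!r} labeled both "
                        f"{assignments[pid]!r} and {label!r}"
                    )
                continue
            assignments[pid] = label
            if label not in class_names:
                class_names.append(label)
    if pset is not None:
        known = set(pset.ids)
        unknown = [i for i in assignments if i not in known]
        if unknown:
            raise ValueError(f"label file {path} references unknown ids: {unknown}")
    return Labeling(name=name or path.stem, assignments=assignments,
                    class_names=class_names)


def attach_orf(pset: ProteinSet, orf_map: dict[str, str]) -> ProteinSet:
    """Attach ORF sequences; length mismatch beyond a stop codon only warns."""
    known = set(pset.ids)
    unknown = [i for i in orf_map if i not in known]
    if unknown:
        raise ValueError(f"ORF ids not in protein set: {unknown}")
    for rec in pset.records:
        orf = orf_map.get(rec.id)
        if orf is None:
            continue
        if len(orf) % 3 != 0:
            raise ValueError(
                f"ORF of {rec.id!r} has length {len(orf)}, not divisible by 3"
            )
        n_codons = len(orf) // 3
        if n_codons not in (len(rec.aa_seq), len(rec.aa_seq) + 1):
            warnings.warn(
                f"ORF of {rec.id!r} has {n_codons} codons but the protein "
                f"has {len(rec.aa_seq)} residues; keeping the ORF anyway"
            )
        rec.orf_seq = orf
        rec.__post_init__()
    return pset


def attach_states(pset: ProteinSet, state_map: dict[str, str], kind: str) -> ProteinSet:
    """Attach per-residue SS or SA strings; lengths must match exactly."""
    if kind not in ("ss", "sa"):
        raise ValueError("kind must be 'ss' or 'sa'")
    known = set(pset.ids)
    unknown = [i for i in state_map if i not in known]
    if unknown:
        raise ValueError(f"{kind} ids not in protein set: {unknown}")
    attr = f"{kind}_seq"
    for rec in pset.records:
        seq = state_map.get(rec.id)
        if seq is None:
            continue
        if len(seq) != len(rec.aa_seq):
            raise ValueError(
                f"{kind} sequence of {rec.id!r} has length {len(seq)}, "
                f"expected {len(rec.aa_seq)}"
            )
        setattr(rec, attr, seq)
        rec.__post_init__()
    return pset


def _write_fasta(path: Path, entries: list[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in entries]
    SeqIO.write(recs, str(path), "fasta")


def save_project(pset: ProteinSet, project_dir: str | Path) -> Path:
    """Write a project directory (FASTA files + label TSVs)."""
    project_dir = Path(project_dir)
    project_dir.mkdir(parents=True, exist_ok=True)
    _write_fasta(project_dir / "sequences.fasta", [(r.id, r.aa_seq) for r in pset])
    for attr, fname in (("orf_seq", "orf.fasta"), ("ss_seq", "ss.fasta"),
                        ("sa_seq", "sa.fasta")):
        entries = [(r.id, getattr(r, attr)) for r in pset if getattr(r, attr)]
        if entries:
            _write_fasta(project_dir / fname, entries)
    if pset.labelings:
        labdir = project_dir / "labels"
        labdir.mkdir(exist_ok=True)
        for lab in pset.labelings:
            with open(labdir / f"{lab.name}.tsv", "w") as fh:
                for rec in pset:  # preserve record order
                    if rec.id in lab.assignments:
                        fh.write(f"{rec.id}\t{lab.assignments[rec.id]}\n")
    return project_dir


def load_project(project_dir: str | Path) -> ProteinSet:
    """Read a project directory back into a :class:`ProteinSet`."""
    project_dir = Path(project_dir)
    pset = read_fasta(project_dir / "sequences.fasta", "protein")
    if (project_dir / "orf.fasta").exists():
        attach_orf(pset, read_fasta(project_dir / "orf.fasta", "orf"))
    for kind in ("ss", "sa"):
        f = project_dir / f"{kind}.fasta"
        if f.exists():
            attach_states(pset, read_fasta(f, kind), kind)
    labdir = project_dir / "labels"
    if labdir.is_dir():
        for f in sorted(labdir.glob("*.tsv")):
            pset.labelings.append(read_labels(f, pset))
    return pset
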