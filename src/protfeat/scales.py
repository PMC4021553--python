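"""Amino-acid scales, distance matrix, and CTD property clusterings.

Scales map each of the 20 amino acids to a real number.  They can be read
from AAIndex1 flat files or taken from the bundled low-redundancy set of
19 scales.  Feature code always works with *normalized* scales: zero mean
and unit (population) standard deviation over the 20 residue values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .alphabet import AA20

_DATA = resources.files("protfeat") / "data"


@dataclass(frozen=True)
class AminoAcidScale:
    """A named mapping of the 20 amino acids to real values."""

    id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(AA20):
            missing = sorted(set(AA20) - set(self.values))
            extra = sorted(set(self.values) - set(AA20))
            raise ValueError(
                f"scale {self.id!r} must cover exactly the 20 amino acids "
                f"(missing {missing}, extra {extra})"
            )

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]


@dataclass
class ScaleSet:
    """An ordered, id-unique collection of scales."""

    scales: list[AminoAcidScale]
    source: str = "user"

    def __post_init__(self) -> None:
        ids = [s.id for s in self.scales]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate scale ids in ScaleSet")

    def __len__(self) -> int:
        return len(self.scales)

    def __iter__(self):
        return iter(self.scales)

    def get(self, scale_id: str) -> AminoAcidScale:
        for s in self.scales:
            if s.id == scale_id:
                return s
        raise KeyError(f"no scale with id {scale_id!r}")

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.scales]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric 20x20 amino-acid distance matrix with zero diagonal."""

    id: str
    d: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if len(self.d) != 400:
            raise ValueError(f"distance matrix {self.id!r} must have 400 entries")
        for a in AA20:
            if self.d[(a, a)] != 0.0:
                raise ValueError(f"nonzero diagonal entry for {a!r}")
            for b in AA20:
                if self.d[(a, b)] < 0:
                    raise ValueError(f"negative distance d({a},{b})")

    def __call__(self, a: str, b: str) -> float:
        return self.d[(a, b)]


@dataclass(frozen=True)
class CTDClustering:
    """Partition of the amino acids into three property groups A, B, C."""

    property_name: str
    groups: dict[str, frozenset[str]]  # keys "A", "B", "C"

    def __post_init__(self) -> None:
        if set(self.groups) != {"A", "B", "C"}:
            raise ValueError("groups must be keyed A, B, C")
        union: set[str] = set()
        for g, members in self.groups.items():
            if not members:
                raise ValueError(f"group {g} of {self.property_name!r} is empty")
            if union & members:
                raise ValueError(f"overlapping groups in {self.property_name!r}")
            union |= members
        if union != set(AA20):
            raise ValueError(
                f"clustering {self.property_name!r} does not cover the alphabet"
            )

    def letter(self, aa: str) -> str:
        for g, members in self.groups.items():
            if aa in members:
                return g
        raise KeyError(aa)


def normalize_scale(scale: AminoAcidScale) -> AminoAcidScale:
    """Return an affinely transformed scale with mean 0 and population sd 1.

    The population standard deviation (divide by 20) is used because the 20
    residue values are the full population of residue types.  Raises on a
    constant scale.
    """
    vals = [scale.values[a] for a in AA20]
    mean = sum(vals) / 20.0
    var = sum((v - mean) ** 2 for v in vals) / 20.0
    if var == 0.0:
        raise ValueError(f"scale {scale.id!r} is constant and cannot be normalized")
    sd = math.sqrt(var)
    return AminoAcidScale(
        id=scale.id, values={a: (scale.values[a] - mean) / sd for a in AA20}
    )


# AAIndex1 'I' line column order (two rows of ten values each).
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"


def load_aaindex(path: str | Path) -> ScaleSet:
    """Parse an AAIndex1 flat file into a :class:`ScaleSet`.

    Entries with missing ('NA') values are skipped with a warning naming
    the entry id.  Values are returned raw (not normalized).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scales: list[AminoAcidScale] = []
    with open(path) as fh:
        entry_id: str | None = None
        value_lines: list[str] = []
        in_values = False
        for line in fh:
            if line.startswith("H "):
                entry_id = line[2:].strip()
                value_lines, in_values = [], False
            elif line.startswith("I "):
                in_values = True
            elif in_values and line.startswith(" "):
                value_lines.append(line)
            elif line.startswith("//"):
                if entry_id is None:
                    raise ValueError(f"{path}: record terminator before header")
                if len(value_lines) != 2:
                    raise ValueError(
                        f"{path}: entry {entry_id} has {len(value_lines)} value "
                        f"lines, expected 2"
                    )
                tokens = value_lines[0].split() + value_lines[1].split()
                if len(tokens) != 20:
                    raise ValueError(
                        f"{path}: entry {entry_id} has {len(tokens)} values, "
                        f"expected 20"
                    )
                if any(t.upper() == "NA" for t in tokens):
                    warnings.warn(
                        f"skipping AAIndex entry {entry_id}: missing (NA) values"
                    )
                else:
                    order = _AAINDEX_ROW1 + _AAINDEX_ROW2
                    values = {aa: float(t) for aa, t in zip(order, tokens)}
                    scales.append(AminoAcidScale(id=entry_id, values=values))
                entry_id, value_lines, in_values = None, [], False
            elif line[:2] in ("D ", "R ", "A ", "T ", "J ", "* ", "C "):
                in_values = False
    return ScaleSet(scales=scales, source="aaindex")


def _read_data_tsv(name: str) -> list[list[str]]:
    rows = []
    for line in (_DATA / name).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def builtin_uncorrelated() -> ScaleSet:
    """The bundled set of 19 low-redundancy amino-acid scales (raw values)."""
    rows = _read_data_tsv("uncorrelated19.tsv")
    header, data = rows[0], rows[1:]
    aas = header[1:]
    scales = [
        AminoAcidScale(id=row[0], values={a: float(v) for a, v in zip(aas, row[1:])})
        for row in data
    ]
    return ScaleSet(scales=scales, source="uncorrelated-19")


def builtin_distance_matrix() -> DistanceMatrix:
    """The bundled physicochemical amino-acid distance matrix."""
    rows = _read_data_tsv("aa_distance.tsv")
    header, data = rows[0], rows[1:]
    cols = header[1:]
    d: dict[tuple[str, str], float] = {}
    for row in data:
        a = row[0]
        for b, v in zip(cols, row[1:]):
            d[(a, b)] = float(v)
    return DistanceMatrix(id="physicochemical", d=d)


def builtin_ctd_clusterings() -> list[CTDClustering]:
    """The seven bundled 3-group property partitions for CTD descriptors."""
    rows = _read_data_tsv("ctd_clusterings.tsv")
    assert rows[0] == ["property", "group", "residues"]
    by_prop: dict[str, dict[str, frozenset[str]]] = {}
    order: list[str] = []
    for prop, group, residues in rows[1:]:
        if prop not in by_prop:
            by_prop[prop] = {}
            order.append(prop)
        by_prop[prop][group] = frozenset(residues)
    return [CTDClustering(property_name=p, groups=by_prop[p]) for p in order]


def builtin_ctd_clustering(property_name: str) -> CTDClustering:
    for c in builtin_ctd_clusterings():
        if c.property_name == property_name:
            return c
    raise KeyError(f"no CTD clustering named {property_name!r}")
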