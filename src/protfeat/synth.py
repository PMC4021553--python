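"""Deterministic synthetic protein datasets for tests and benchmarks.

Generates labeled protein sets whose classes differ (by a controlled
effect size) in amino-acid composition, together with consistent ORFs
(uniformly sampled synonymous codons) and Markov-chain SS/SA strings.
Residues are sampled i.i.d. per position, so composition oracles stay
analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA20, SA2, SS3, SYNONYMOUS_FAMILIES
from .seqdata import Labeling, ProteinRecord, ProteinSet


def _uniform_freqs() -> dict[str, float]:
    return {aa: 1.0 / 20.0 for aa in AA20}


def shifted_freqs(delta: float, residues: tuple[str, ...] = ("A",)) -> dict[str, float]:
    """Uniform composition with ``delta`` added to each chosen residue,
    renormalized to sum 1."""
    freqs = _uniform_freqs()
    for r in residues:
        if r not in freqs:
            raise ValueError(f"unknown residue {r!r}")
        freqs[r] += delta
    total = sum(freqs.values())
    if any(v < 0 for v in freqs.values()):
        raise ValueError("delta drives a frequency negative")
    return {aa: v / total for aa, v in freqs.items()}


@dataclass
class SyntheticSpec:
    n_per_class: int = 50
    length_range: tuple[int, int] = (50, 200)
    class_freqs: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0
    with_orf: bool = True
    with_ss: bool = True
    with_sa: bool = True

    def __post_init__(self) -> None:
        if not self.class_freqs:
            self.class_freqs = {"low": _uniform_freqs(), "high": _uniform_freqs()}
        lo, hi = self.length_range
        if lo < 20 or hi < lo:
            raise ValueError("length range must satisfy 20 <= min <= max")
        for cls, freqs in self.class_freqs.items():
            if set(freqs) != set(AA20):
                raise ValueError(f"class {cls!r} must give all 20 frequencies")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"class {cls!r} frequencies do not sum to 1")
            if any(v < 0 for v in freqs.values()):
                raise ValueError(f"class {cls!r} has negative frequencies")


def two_class_spec(n_per_class: int, delta: float,
                   residues: tuple[str, ...] = ("A",), seed: int = 0,
                   length_range: tuple[int, int] = (50, 200)) -> SyntheticSpec:
    """Two classes: 'low' uniform, 'high' with ``delta`` shifted onto
    ``residues``.  ``delta = 0`` makes the classes exchangeable."""
    return SyntheticSpec(
        n_per_class=n_per_class,
        length_range=length_range,
        class_freqs={"low": _uniform_freqs(),
                     "high": shifted_freqs(delta, residues)},
        seed=seed,
    )


def _markov_chain(rng: np.random.Generator, states: str, n: int,
                  stay: float) -> str:
    switch = (1.0 - stay) / (len(states) - 1)
    out = [rng.choice(list(states))]
    for _ in range(n - 1):
        probs = [stay if s == out[-1] else switch for s in states]
        out.append(rng.choice(list(states), p=probs))
    return "".join(out)


def _orf_for(rng: np.random.Generator, aa_seq: str) -> str:
    codons = [
        rng.choice(SYNONYMOUS_FAMILIES[aa]) for aa in aa_seq
    ]
    return "".join(codons)


def generate(spec: SyntheticSpec) -> tuple[ProteinSet, Labeling]:
    """Generate a labeled protein set, deterministic for a given seed."""
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    assignments: dict[str, str] = {}
    class_names = list(spec.class_freqs)
    aas = list(AA20)
    for cls in class_names:
        probs = np.array([spec.class_freqs[cls][aa] for aa in AA20])
        probs = probs / probs.sum()
        for i in range(spec.n_per_class):
            pid = f"{cls}_{i:04d}"
            n = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            aa_seq = "".join(rng.choice(aas, size=n, p=probs))
            rec = ProteinRecord(
                id=pid,
                aa_seq=aa_seq,
                orf_seq=_orf_for(rng, aa_seq) if spec.with_orf else None,
                ss_seq=_markov_chain(rng, SS3, n, 0.8) if spec.with_ss else None,
                sa_seq=_markov_chain(rng, SA2, n, 0.85) if spec.with_sa else None,
            )
            records.append(rec)
            assignments[pid] = cls
    labeling = Labeling(name="synthetic", assignments=assignments,
                        class_names=class_names)
    pset = ProteinSet(records=records, labelings=[labeling])
    return pset, labeling


def permuted_labeling(labeling: Labeling, seed: int = 0,
                      name: str = "permuted") -> Labeling:
    """Random permutation of label assignments across the same ids."""
    rng = np.random.default_rng(seed)
    ids = list(labeling.assignments)
    values = [labeling.assignments[i] for i in ids]
    perm = rng.permutation(len(values))
    return Labeling(name=name,
                    assignments={i: values[p] for i, p in zip(ids, perm)},
                    class_names=list(labeling.class_names))
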