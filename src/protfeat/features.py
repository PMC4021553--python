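"""Sequence-based feature calculation.

Every public function maps one sequence (plus parameters) to an ordered
``dict`` of named feature values; :func:`extract` applies a category to a
whole :class:`~protfeat.seqdata.ProteinSet` and returns a pandas block with
one row per protein.  Feature names encode category, parameters and
component (e.g. ``aac_seg2of3_A``) so matrices from separate runs can be
merged unambiguously.

Composition features are relative frequencies; profile features operate on
per-residue property profiles built from normalized amino-acid scales.
Segment ``i`` of ``k`` covers the 0-based half-open residue range
``[floor((i-1)*N/k), floor(i*N/k))``.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .alphabet import AA20, CODONS64, SA2, SS3, SYNONYMOUS_FAMILIES
from .scales import (
    AminoAcidScale,
    CTDClustering,
    DistanceMatrix,
    builtin_ctd_clusterings,
    builtin_distance_matrix,
    builtin_uncorrelated,
    normalize_scale,
)
from .seqdata import ProteinSet

# ---------------------------------------------------------------------------
# composition features


def _segments(seq: str, k: int) -> list[str]:
    n = len(seq)
    if k < 1:
        raise ValueError("number of segments must be >= 1")
    if n < k:
        raise ValueError(f"sequence of length {n} cannot be split into {k} segments")
    return [seq[(i - 1) * n // k: i * n // k] for i in range(1, k + 1)]


def aa_composition(seq: str, num_segments: int = 1) -> dict[str, float]:
    """Per-segment relative amino-acid frequencies (20 values per segment)."""
    out: dict[str, float] = {}
    for i, seg in enumerate(_segments(seq, num_segments), start=1):
        for aa in AA20:
            out[f"aac_seg{i}of{num_segments}_{aa}"] = seg.count(aa) / len(seg)
    return out


def dipeptide_composition(seq: str, num_segments: int = 1) -> dict[str, float]:
    """Per-segment ordered amino-acid pair frequencies (400 per segment).

    The denominator is the number of adjacent pairs in the segment, i.e.
    segment length minus 1.
    """
    out: dict[str, float] = {}
    for i, seg in enumerate(_segments(seq, num_segments), start=1):
        if len(seg) < 2:
            raise ValueError(
                f"segment {i} of {num_segments} has length {len(seg)} < 2"
            )
        counts: dict[str, int] = {}
        for a, b in zip(seg, seg[1:]):
            counts[a + b] = counts.get(a + b, 0) + 1
        denom = len(seg) - 1
        for a in AA20:
            for b in AA20:
                out[f"dpc_seg{i}of{num_segments}_{a}{b}"] = (
                    counts.get(a + b, 0) / denom
                )
    return out


def terminal_end_count(seq: str, end: str = "N", length: int = 10) -> dict[str, float]:
    """Amino-acid counts over the first (N) or last (C) ``length`` residues."""
    if end not in ("N", "C"):
        raise ValueError("end must be 'N' or 'C'")
    if length < 1:
        raise ValueError("terminal window length must be >= 1")
    if length > len(seq):
        raise ValueError(
            f"terminal window of {length} exceeds sequence length {len(seq)}"
        )
    window = seq[:length] if end == "N" else seq[-length:]
    return {f"tec_{end}{length}_{aa}": float(window.count(aa)) for aa in AA20}


def state_composition(state_seq: str, alphabet: str,
                      num_segments: int = 1, prefix: str = "stc") -> dict[str, float]:
    """Per-segment composition over a reduced state alphabet (SS or SA)."""
    out: dict[str, float] = {}
    for i, seg in enumerate(_segments(state_seq, num_segments), start=1):
        for st in alphabet:
            out[f"{prefix}_seg{i}of{num_segments}_{st}"] = seg.count(st) / len(seg)
    return out


def per_state_aa_composition(aa_seq: str, state_seq: str, state_alphabet: str,
                             prefix: str = "staac") -> dict[str, float]:
    """Amino-acid composition of the residues in each state.

    For each state letter the denominator is the number of residues in that
    state; states absent from the sequence yield an all-zero block.
    """
    if len(aa_seq) != len(state_seq):
        raise ValueError(
            f"state sequence length {len(state_seq)} != protein length {len(aa_seq)}"
        )
    out: dict[str, float] = {}
    for st in state_alphabet:
        residues = [a for a, s in zip(aa_seq, state_seq) if s == st]
        n = len(residues)
        for aa in AA20:
            out[f"{prefix}_{st}_{aa}"] = residues.count(aa) / n if n else 0.0
    return out


def codon_composition(orf: str) -> dict[str, float]:
    """Relative codon frequencies over the 64 codons."""
    if not orf:
        raise ValueError("empty ORF")
    if len(orf) % 3 != 0:
        raise ValueError(f"ORF length {len(orf)} not divisible by 3")
    codons = [orf[i:i + 3] for i in range(0, len(orf), 3)]
    n = len(codons)
    return {f"codon_comp_{c}": codons.count(c) / n for c in CODONS64}


def codon_usage(orf: str) -> dict[str, float]:
    """Within-synonymous-family relative codon frequencies.

    Each codon's count is divided by the total count of codons encoding the
    same amino acid (standard genetic code; stop codons form one family).
    Codons of families absent from the ORF are 0.
    """
    if not orf:
        raise ValueError("empty ORF")
    if len(orf) % 3 != 0:
        raise ValueError(f"ORF length {len(orf)} not divisible by 3")
    codons = [orf[i:i + 3] for i in range(0, len(orf), 3)]
    counts = {c: codons.count(c) for c in CODONS64}
    out: dict[str, float] = {}
    for family in SYNONYMOUS_FAMILIES.values():
        total = sum(counts[c] for c in family)
        for c in family:
            out[f"codon_usage_{c}"] = counts[c] / total if total else 0.0
    return {f"codon_usage_{c}": out[f"codon_usage_{c}"] for c in CODONS64}


def protein_length(seq: str) -> dict[str, float]:
    return {"len": float(len(seq))}


# ---------------------------------------------------------------------------
# property-profile features


def property_profile(seq: str, scale: AminoAcidScale) -> np.ndarray:
    """Per-residue profile of (normalized) scale values."""
    return np.array([scale[aa] for aa in seq], dtype=float)


def triangular_weights(window: int, edge: float) -> np.ndarray:
    """Symmetric triangular filter weights, 1 at the center, ``edge`` at ends."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if not 0.0 <= edge <= 1.0:
        raise ValueError(f"edge must be in [0, 1], got {edge}")
    half = (window - 1) // 2
    if half == 0:
        return np.ones(1)
    offsets = np.abs(np.arange(-half, half + 1))
    return 1.0 - (1.0 - edge) * offsets / half


def triangular_smooth(profile: np.ndarray, window: int, edge: float) -> np.ndarray:
    """Convolve with a renormalized triangular filter.

    At sequence ends the window is truncated to in-range positions and the
    remaining weights renormalized to sum to 1, so a constant profile is
    unchanged everywhere.
    """
    w = triangular_weights(window, edge)
    half = (window - 1) // 2
    n = len(profile)
    if half == 0:
        return np.asarray(profile, dtype=float).copy()
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        ww = w[lo - (i - half): hi - (i - half)]
        out[i] = np.dot(profile[lo:hi], ww) / ww.sum()
    return out


def signal_average(seq: str, scale: AminoAcidScale, window: int = 1,
                   edge: float = 1.0) -> dict[str, float]:
    """Mean of the smoothed property profile (one value per scale)."""
    p = triangular_smooth(property_profile(seq, scale), window, edge)
    return {f"sigavg_{scale.id}_w{window}e{edge:g}": float(p.mean())}


def signal_peaks_area(seq: str, scale: AminoAcidScale, window: int = 1,
                      edge: float = 1.0, threshold: float = 1.0) -> dict[str, float]:
    """Length-normalized profile area above ``threshold`` and below its negative.

    top = sum(max(p_i - t, 0)) / N; bottom = sum(max(-t - p_i, 0)) / N,
    both computed on the smoothed profile.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    p = triangular_smooth(property_profile(seq, scale), window, edge)
    n = len(p)
    top = float(np.maximum(p - threshold, 0.0).sum() / n)
    bot = float(np.maximum(-threshold - p, 0.0).sum() / n)
    stem = f"sigpeak_{scale.id}_w{window}e{edge:g}t{threshold:g}"
    return {f"{stem}_top": top, f"{stem}_bot": bot}


AUTOCORR_KINDS = ("moreau_broto", "moran", "geary")


def autocorrelation(seq: str, scale: AminoAcidScale, kind: str,
                    lag: int) -> dict[str, float]:
    """Profile autocorrelation at one lag.

    With profile P of length N, mean Pbar and lag d:

    - moreau_broto:  (1/(N-d)) * sum_i P_i * P_{i+d}
    - moran:  [(1/(N-d)) * sum_i (P_i-Pbar)(P_{i+d}-Pbar)]
              / [(1/N) * sum_i (P_i-Pbar)^2]
    - geary:  [(1/(2(N-d))) * sum_i (P_i-P_{i+d})^2]
              / [(1/(N-1)) * sum_i (P_i-Pbar)^2]
    """
    if kind not in AUTOCORR_KINDS:
        raise ValueError(f"kind must be one of {AUTOCORR_KINDS}, got {kind!r}")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    p = property_profile(seq, scale)
    n = len(p)
    if n <= lag:
        raise ValueError(f"sequence length {n} must exceed lag {lag}")
    name = {"moreau_broto": "acmb", "moran": "acmoran", "geary": "acgeary"}[kind]
    key = f"{name}_{scale.id}_d{lag}"
    if kind == "moreau_broto":
        return {key: float(np.dot(p[:-lag], p[lag:]) / (n - lag))}
    mean = p.mean()
    dev = p - mean
    ss = float(np.dot(dev, dev))
    if ss == 0.0:
        raise ValueError(
            f"zero-variance profile for scale {scale.id!r}: {kind} undefined"
        )
    if kind == "moran":
        num = float(np.dot(dev[:-lag], dev[lag:])) / (n - lag)
        return {key: num / (ss / n)}
    diff = p[:-lag] - p[lag:]
    num = float(np.dot(diff, diff)) / (2.0 * (n - lag))
    return {key: num / (ss / (n - 1))}


def pseaac(seq: str, scales: Sequence[AminoAcidScale], lam: int,
           weight: float = 0.05, kind: int = 1) -> dict[str, float]:
    """Pseudo amino-acid composition with sequence-order correlation factors.

    Type 1 pools the selected scales into one correlation factor per lag
    (20 + lam features); type 2 keeps a per-scale factor series
    (20 + len(scales) * lam features, lag-major order).  With lam = 0 the
    output equals the plain amino-acid composition.
    """
    if kind not in (1, 2):
        raise ValueError("pseudo-composition type must be 1 or 2")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if weight <= 0:
        raise ValueError("weight must be > 0")
    n = len(seq)
    if n <= lam:
        raise ValueError(f"sequence length {n} must exceed lambda {lam}")
    if not scales:
        raise ValueError("at least one scale is required")
    profiles = [property_profile(seq, s) for s in scales]
    gamma = len(scales)
    thetas: list[tuple[str, float]] = []
    for j in range(1, lam + 1):
        per_scale = [
            float(np.mean((p[:-j] - p[j:]) ** 2)) for p in profiles
        ]
        if kind == 1:
            thetas.append((f"cf{j}", sum(per_scale) / gamma))
        else:
            for s, th in zip(scales, per_scale):
                thetas.append((f"cf{j}_{s.id}", th))
    denom = 1.0 + weight * sum(t for _, t in thetas)
    prefix = f"paac{kind}_l{lam}"
    out = {
        f"{prefix}_{aa}": (seq.count(aa) / n) / denom for aa in AA20
    }
    for name, th in thetas:
        out[f"{prefix}_{name}"] = weight * th / denom
    return out


# ---------------------------------------------------------------------------
# amino-acid distance-based features


def ctd(seq: str, clustering: CTDClustering) -> dict[str, float]:
    """Composition / transition / distribution descriptors (21 values).

    The sequence is mapped to the 3-letter group alphabet ABC:
    3 composition values (group count / N); 3 transition values (adjacent
    unordered pair counts AB, AC, BC divided by N - 1); 15 distribution
    values: for each group, the 1-based positions of the first occurrence,
    of the ceil(q * n)-th occurrence for q = 0.25, 0.5, 0.75, and of the
    last occurrence, each divided by N (absent groups give five zeros).
    """
    if not seq:
        raise ValueError("empty sequence")
    reduced = [clustering.letter(aa) for aa in seq]
    n = len(reduced)
    prop = clustering.property_name
    out: dict[str, float] = {}
    for g in "ABC":
        out[f"ctd_{prop}_c{g}"] = reduced.count(g) / n
    pair_counts = {"AB": 0, "AC": 0, "BC": 0}
    for a, b in zip(reduced, reduced[1:]):
        if a != b:
            pair_counts["".join(sorted(a + b))] += 1
    for pair in ("AB", "AC", "BC"):
        out[f"ctd_{prop}_t{pair}"] = pair_counts[pair] / (n - 1) if n > 1 else 0.0
    for g in "ABC":
        positions = [i for i, x in enumerate(reduced, start=1) if x == g]
        if positions:
            m = len(positions)
            marks = [
                positions[0],
                positions[math.ceil(0.25 * m) - 1],
                positions[math.ceil(0.50 * m) - 1],
                positions[math.ceil(0.75 * m) - 1],
                positions[-1],
            ]
            vals = [p / n for p in marks]
        else:
            vals = [0.0] * 5
        for idx, v in enumerate(vals, start=1):
            out[f"ctd_{prop}_d{g}{idx}"] = v
    return out


def qso(seq: str, dmatrix: DistanceMatrix, lam: int,
        weight: float = 0.1) -> dict[str, float]:
    """Quasi-sequence-order descriptors (20 + lam values).

    tau_j = sum_i d(R_i, R_{i+j})^2 for j = 1..lam; the 20 amino-acid
    frequencies and the weighted tau terms share the normalizer
    1 + weight * sum(tau).
    """
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    if weight <= 0:
        raise ValueError("weight must be > 0")
    n = len(seq)
    if n <= lam:
        raise ValueError(f"sequence length {n} must exceed lambda {lam}")
    taus = []
    for j in range(1, lam + 1):
        taus.append(sum(dmatrix(seq[i], seq[i + j]) ** 2 for i in range(n - j)))
    denom = 1.0 + weight * sum(taus)
    out = {f"qso_l{lam}_{aa}": (seq.count(aa) / n) / denom for aa in AA20}
    for j, tau in enumerate(taus, start=1):
        out[f"qso_l{lam}_so{j}"] = weight * tau / denom
    return out


# ---------------------------------------------------------------------------
# whole-set extraction


class MissingDataError(ValueError):
    """Raised when a category needs auxiliary data a protein does not have."""


def _normalized_scales(scale_ids: Sequence[str] | None) -> list[AminoAcidScale]:
    sset = builtin_uncorrelated()
    if scale_ids is None:
        scale_ids = sset.ids
    return [normalize_scale(sset.get(sid)) for sid in scale_ids]


def _require(pset: ProteinSet, attr: str, category: str) -> None:
    for rec in pset:
        if getattr(rec, attr) is None:
            kind = {"orf_seq": "ORF", "ss_seq": "secondary-structure",
                    "sa_seq": "solvent-accessibility"}[attr]
            raise MissingDataError(
                f"category {category!r} needs {kind} sequences; "
                f"protein {rec.id!r} has none"
            )


def extract(pset: ProteinSet, category: str, **params) -> pd.DataFrame:
    """Compute one feature category for every protein in the set.

    Returns a DataFrame indexed by protein id with deterministic feature
    names as columns.  ``params`` are the category's parameters; scale-based
    categories accept ``scales`` (list of built-in scale ids, default: all
    19), ``ctd`` accepts ``properties`` (default: all 7 clusterings).
    """
    rows: list[dict[str, float]] = []

    if category == "aac":
        k = int(params.get("num_segments", 1))
        rows = [aa_composition(r.aa_seq, k) for r in pset]
    elif category == "dpc":
        k = int(params.get("num_segments", 1))
        rows = [dipeptide_composition(r.aa_seq, k) for r in pset]
    elif category == "tec":
        end = params.get("end", "N")
        length = int(params.get("length", 10))
        rows = [terminal_end_count(r.aa_seq, end, length) for r in pset]
    elif category in ("ssc", "sac"):
        k = int(params.get("num_segments", 1))
        attr, alpha = (("ss_seq", SS3) if category == "ssc" else ("sa_seq", SA2))
        _require(pset, attr, category)
        rows = [
            state_composition(getattr(r, attr), alpha, k, prefix=category)
            for r in pset
        ]
    elif category in ("ssaac", "saaac"):
        attr, alpha = (("ss_seq", SS3) if category == "ssaac" else ("sa_seq", SA2))
        _require(pset, attr, category)
        rows = [
            per_state_aa_composition(r.aa_seq, getattr(r, attr), alpha,
                                     prefix=category)
            for r in pset
        ]
    elif category == "codon_comp":
        _require(pset, "orf_seq", category)
        rows = [codon_composition(r.orf_seq) for r in pset]
    elif category == "codon_usage":
        _require(pset, "orf_seq", category)
        rows = [codon_usage(r.orf_seq) for r in pset]
    elif category == "length":
        rows = [protein_length(r.aa_seq) for r in pset]
    elif category == "sigavg":
        scales = _normalized_scales(params.get("scales"))
        window = int(params.get("window", 1))
        edge = float(params.get("edge", 1.0))
        rows = [
            {k: v for s in scales for k, v in signal_average(
                r.aa_seq, s, window, edge).items()}
            for r in pset
        ]
    elif category == "sigpeak":
        scales = _normalized_scales(params.get("scales"))
        window = int(params.get("window", 1))
        edge = float(params.get("edge", 1.0))
        threshold = float(params.get("threshold", 1.0))
        rows = [
            {k: v for s in scales for k, v in signal_peaks_area(
                r.aa_seq, s, window, edge, threshold).items()}
            for r in pset
        ]
    elif category == "autocorr":
        scales = _normalized_scales(params.get("scales"))
        kind = params.get("kind", "moreau_broto")
        lags = params.get("lags", [int(params.get("lag", 1))])
        rows = [
            {k: v for s in scales for d in lags
             for k, v in autocorrelation(r.aa_seq, s, kind, int(d)).items()}
            for r in pset
        ]
    elif category in ("paac1", "paac2"):
        scales = _normalized_scales(params.get("scales"))
        lam = int(params.get("lam", 1))
        weight = float(params.get("weight", 0.05))
        kind = 1 if category == "paac1" else 2
        rows = [pseaac(r.aa_seq, scales, lam, weight, kind) for r in pset]
    elif category == "ctd":
        props = params.get("properties")
        clusterings = builtin_ctd_clusterings()
        if props is not None:
            byname = {c.property_name: c for c in clusterings}
            clusterings = [byname[p] for p in props]
        rows = [
            {k: v for c in clusterings for k, v in ctd(r.aa_seq, c).items()}
            for r in pset
        ]
    elif category == "qso":
        lam = int(params.get("lam", 1))
        weight = float(params.get("weight", 0.1))
        dm = params.get("distance_matrix") or builtin_distance_matrix()
        rows = [qso(r.aa_seq, dm, lam, weight) for r in pset]
    else:
        raise ValueError(f"unknown feature category {category!r}")

    return pd.DataFrame(rows, index=pd.Index(pset.ids, name="id"))


#: categories and the auxiliary sequence each one requires (None = none).
CATEGORIES: dict[str, str | None] = {
    "aac": None, "dpc": None, "tec": None, "length": None,
    "ssc": "ss", "ssaac": "ss", "sac": "sa", "saaac": "sa",
    "codon_comp": "orf", "codon_usage": "orf",
    "sigavg": None, "sigpeak": None, "autocorr": None,
    "paac1": None, "paac2": None, "ctd": None, "qso": None,
}
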