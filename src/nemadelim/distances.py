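"""Pairwise substitution counts and distance/similarity matrices.

Three estimators are provided on top of per-pair substitution counts:

* uncorrected p-distance (and its complement, percent similarity),
* Kimura 2-parameter (K2P), which separates transitions from transversions,
* Tamura-Nei 1993 (TN93), which additionally separates the two transition
  classes (A<->G vs C<->T) and uses the pair's empirical base frequencies.

Counting uses pairwise deletion: a column enters ``compared_sites`` only when
both sequences carry an unambiguous A/C/G/T there. Ambiguity codes are excluded
rather than partially matched — ambiguous calls are a documented source of
taxonomic error in this group, so they are conservatively dropped and tallied.
Gamma / invariant-site rate corrections are intentionally not applied; the
``model`` tag on every matrix records the plain estimator used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import MatrixModeError, SaturationError, UndefinedComparisonError
from .seq_io import UNAMBIGUOUS, Alignment, SequenceRecord

MODELS = ("p", "similarity_percent", "diff_count", "K2P", "TN93")

#: Fraction of ambiguous/gap residues above which strict mode rejects a record.
STRICT_AMBIGUITY_LIMIT = 0.02


@dataclass(frozen=True)
class SubstitutionCounts:
    """Classified pairwise differences over the comparable columns of a pair.

    ``base_freqs`` are the four proportions (g_A, g_C, g_G, g_T) pooled over
    both sequences at the compared sites, as the TN93 estimator requires.
    """

    compared_sites: int
    transitions_AG: int
    transitions_CT: int
    transversions: int
    base_freqs: tuple[float, float, float, float]

    @property
    def differences(self) -> int:
        return self.transitions_AG + self.transitions_CT + self.transversions

    @property
    def P1(self) -> float:
        return self.transitions_AG / self.compared_sites

    @property
    def P2(self) -> float:
        return self.transitions_CT / self.compared_sites

    @property
    def P(self) -> float:
        return self.P1 + self.P2

    @property
    def Q(self) -> float:
        return self.transversions / self.compared_sites


def ambiguity_fraction(record: SequenceRecord) -> float:
    """Fraction of residues that are not unambiguous A/C/G/T (gaps included)."""
    return sum(1 for ch in record.residues if ch not in UNAMBIGUOUS) / len(record)


_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def count_substitutions(x: SequenceRecord, y: SequenceRecord) -> SubstitutionCounts:
    """Count and classify substitutions between two aligned records.

    Pairwise deletion: columns with '-', 'N' or any IUPAC ambiguity code in
    either sequence are excluded. Raises UndefinedComparisonError when no
    column survives.
    """
    if len(x) != len(y):
        raise ValueError(f"records {x.isolate_id}/{y.isolate_id} not aligned to equal length")
    compared = ts_ag = ts_ct = tv = 0
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for a, b in zip(x.residues, y.residues):
        if a not in UNAMBIGUOUS or b not in UNAMBIGUOUS:
            continue
        compared += 1
        counts[a] += 1
        counts[b] += 1
        if a != b:
            pair = frozenset((a, b))
            if pair == frozenset("AG"):
                ts_ag += 1
            elif pair == frozenset("CT"):
                ts_ct += 1
            else:
                tv += 1
    if compared == 0:
        raise UndefinedComparisonError(
            f"no comparable sites between {x.isolate_id} and {y.isolate_id}"
        )
    total = 2 * compared
    freqs = (counts["A"] / total, counts["C"] / total, counts["G"] / total, counts["T"] / total)
    return SubstitutionCounts(compared, ts_ag, ts_ct, tv, freqs)


def p_distance(c: SubstitutionCounts) -> float:
    return c.differences / c.compared_sites


def percent_similarity(c: SubstitutionCounts) -> float:
    """100 * (1 - differences/compared_sites); full precision, round only at reporting."""
    return 100.0 * (1.0 - c.differences / c.compared_sites)


def k2p_distance(c: SubstitutionCounts) -> float:
    """Kimura 2-parameter distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    P, Q = c.P, c.Q
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P undefined for P={P:.4f}, Q={Q:.4f}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def tn93_distance(c: SubstitutionCounts) -> float:
    """Tamura-Nei 1993 distance from P1 (A<->G), P2 (C<->T), Q and base frequencies."""
    gA, gC, gG, gT = c.base_freqs
    if min(gA, gC, gG, gT) <= 0.0:
        raise SaturationError("TN93 undefined when a base frequency is zero")
    gR, gY = gA + gG, gC + gT
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gC * gT / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1.0 - c.P1 / k1 - c.Q / (2.0 * gR)
    w2 = 1.0 - c.P2 / k2 - c.Q / (2.0 * gY)
    w3 = 1.0 - c.Q / (2.0 * gR * gY)
    if w1 <= 0.0 or w2 <= 0.0 or w3 <= 0.0:
        raise SaturationError(
            f"TN93 undefined for P1={c.P1:.4f}, P2={c.P2:.4f}, Q={c.Q:.4f}"
        )
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


# residues -> codes: A=0, C=1, G=2, T=3, anything else (gap/ambiguity) = 4
_CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_TABLE[ord(_b)] = _i


def _encode(rows: list[SequenceRecord]) -> np.ndarray:
    return np.vstack(
        [_CODE_TABLE[np.frombuffer(r.residues.encode("ascii"), dtype=np.uint8)] for r in rows]
    )


def _pair_counts(a: np.ndarray, b: np.ndarray) -> SubstitutionCounts:
    """Vectorized equivalent of count_substitutions on encoded rows."""
    valid = (a < 4) & (b < 4)
    compared = int(valid.sum())
    if compared == 0:
        raise UndefinedComparisonError("no comparable sites")
    diff = valid & (a != b)
    sums = a.astype(np.int16) + b
    ts_ag = int((diff & (sums == 2)).sum())  # A(0)+G(2)
    ts_ct = int((diff & (sums == 4)).sum())  # C(1)+T(3)
    tv = int(diff.sum()) - ts_ag - ts_ct
    pooled = np.bincount(a[valid], minlength=4) + np.bincount(b[valid], minlength=4)
    total = 2 * compared
    freqs = tuple(float(c) / total for c in pooled)
    return SubstitutionCounts(compared, ts_ag, ts_ct, tv, freqs)


_ESTIMATORS = {
    "p": p_distance,
    "similarity_percent": percent_similarity,
    "diff_count": lambda c: float(c.differences),
    "K2P": k2p_distance,
    "TN93": tn93_distance,
}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance (or percent-similarity) matrix.

    ``values`` is dense and symmetric; the diagonal is 0 (100 in similarity
    mode). ``compared_sites`` records the pairwise-deletion denominator per
    pair so every report is auditable. Saturated pairs (undefined corrected
    distance) hold ``inf`` and appear in ``flagged_pairs``.
    """

    labels: list[str]
    values: np.ndarray
    model: str
    locus: str = ""
    compared_sites: np.ndarray | None = None
    flagged_pairs: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        finite = np.isfinite(self.values)
        if not np.allclose(self.values[finite], self.values.T[finite]):
            raise ValueError("matrix is not symmetric")

    @property
    def is_similarity(self) -> bool:
        return self.model == "similarity_percent"

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for i, j in combinations(range(len(self.labels)), 2):
            yield self.labels[i], self.labels[j], float(self.values[i, j])

    def to_tsv(self, path: str | Path, decimals: int = 1) -> None:
        """Square labeled TSV; similarity percentages are reported to one decimal."""
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.values):
                cells = "\t".join(f"{v:.{decimals}f}" if np.isfinite(v) else "inf" for v in row)
                fh.write(f"{label}\t{cells}\n")

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP-style square matrix for interoperability with tree tools."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                cells = "  ".join(f"{v:.6f}" for v in row)
                fh.write(f"{label:<10s}  {cells}\n")


def build_distance_matrix(
    alignment: Alignment,
    model: str,
    strict: bool = False,
) -> DistanceMatrix:
    """All-pairs matrix under one model tag; symmetric by construction.

    ``strict`` rejects records whose ambiguity fraction exceeds
    STRICT_AMBIGUITY_LIMIT (2%) instead of silently excluding columns.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    rows = alignment.rows
    if len(rows) < 2:
        raise ValueError("distance matrix needs at least 2 rows")
    if strict:
        for r in rows:
            frac = ambiguity_fraction(r)
            if frac > STRICT_AMBIGUITY_LIMIT:
                raise ValueError(
                    f"record {r.isolate_id} has {frac:.1%} ambiguous residues (strict limit 2%)"
                )
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"rows not aligned to equal length: {sorted(lengths)}")
    n = len(rows)
    encoded = _encode(rows)
    values = np.zeros((n, n))
    compared = np.zeros((n, n), dtype=int)
    flagged: list[tuple[str, str]] = []
    estimator = _ESTIMATORS[model]
    for i, j in combinations(range(n), 2):
        try:
            counts = _pair_counts(encoded[i], encoded[j])
        except UndefinedComparisonError as exc:
            raise UndefinedComparisonError(
                f"pair ({rows[i].isolate_id}, {rows[j].isolate_id}): {exc}"
            ) from exc
        compared[i, j] = compared[j, i] = counts.compared_sites
        try:
            value = estimator(counts)
        except SaturationError:
            value = math.inf
            flagged.append((rows[i].isolate_id, rows[j].isolate_id))
        values[i, j] = values[j, i] = value
    if model == "similarity_percent":
        np.fill_diagonal(values, 100.0)
    return DistanceMatrix(
        labels=[r.isolate_id for r in rows],
        values=values,
        model=model,
        locus=alignment.locus,
        compared_sites=compared,
        flagged_pairs=flagged,
    )
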