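"""Pairwise similarity and model-corrected genetic distances over aligned barcodes.

Supported quantities per sequence pair:

* percent similarity (the DSC criterion),
* p-distance with its transition/transversion decomposition (P, Q),
* Jukes–Cantor (JC69), Kimura 2-parameter (K2P) and Tamura–Nei (TN93)
  corrected distances,

all under an explicit :class:`SitePolicy` controlling gap and IUPAC-ambiguity
handling.  Ambiguity codes are treated by their base-set semantics: under the
default ``intersect-is-match`` policy a hybrid's Y matches both parental C
and T, which is what makes hybrid individuals similar to *both* parental
species.  Mismatches involving ambiguity codes are apportioned between
transitions and transversions by the fraction of unequal cross-pairs of the
two base sets, so p = P + Q holds exactly under every policy.

Site comparisons are precomputed as 16x16 lookup tables over the IUPAC+gap
alphabet and evaluated with numpy, so full distance matrices (and the many
matrices needed for bootstrapping) stay cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from musselid.seqio import (
    IUPAC_BASES,
    AlignedSet,
    BarcodeRecord,
    is_transition,
)

GAP_HANDLING = ("pairwise-delete", "complete-delete")
AMBIGUITY_MATCH = ("intersect-is-match", "mismatch", "fractional")

MODELS = ("p", "similarity_percent", "JC69", "K2P", "TN93")


@dataclass(frozen=True)
class SitePolicy:
    """How gapped and ambiguous sites enter a pairwise comparison.

    gap_handling
        ``pairwise-delete`` drops a column only for pairs where either
        sequence is gapped; ``complete-delete`` drops columns gapped in any
        record of the alignment (only meaningful for whole-matrix calls).
    ambiguity_match
        ``intersect-is-match``: a site matches when the two base sets share
        a base (default — a hybrid's heterozygous code matches both parents).
        ``mismatch``: only identical characters match (strict barcoding).
        ``fractional``: match weight is the probability two bases drawn
        uniformly from each set are equal.
    """

    gap_handling: str = "pairwise-delete"
    ambiguity_match: str = "intersect-is-match"

    def __post_init__(self) -> None:
        if self.gap_handling not in GAP_HANDLING:
            raise ValueError(f"unknown gap_handling: {self.gap_handling!r}")
        if self.ambiguity_match not in AMBIGUITY_MATCH:
            raise ValueError(f"unknown ambiguity_match: {self.ambiguity_match!r}")


class ZeroComparableSitesError(ValueError):
    """No alignment column survived the site policy for a pair."""


# ---------------------------------------------------------------------------
# 16x16 site-pair lookup tables over the IUPAC+gap alphabet
# ---------------------------------------------------------------------------

_CODES = list(IUPAC_BASES)  # fixed order; '-' is last
_NCODES = len(_CODES)
_IDX = {c: i for i, c in enumerate(_CODES)}
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}

_ORD2IDX = np.full(256, -1, dtype=np.int8)
for _c, _i in _IDX.items():
    _ORD2IDX[ord(_c)] = _i

_COMPARABLE = np.zeros((_NCODES, _NCODES))
_MATCH_INTERSECT = np.zeros((_NCODES, _NCODES))
_MATCH_IDENTITY = np.zeros((_NCODES, _NCODES))
_MATCH_FRACTIONAL = np.zeros((_NCODES, _NCODES))
_TS_PUR_FRAC = np.zeros((_NCODES, _NCODES))  # A<->G share of unequal cross-pairs
_TS_PYR_FRAC = np.zeros((_NCODES, _NCODES))  # C<->T share
_TV_FRAC = np.zeros((_NCODES, _NCODES))
_FREQ = np.zeros((_NCODES, 4))  # fractional base-frequency contribution

for _ci, _seti in ((c, IUPAC_BASES[c]) for c in _CODES):
    if _seti:
        for _b in _seti:
            _FREQ[_IDX[_ci], _BASE_IDX[_b]] = 1.0 / len(_seti)
    for _cj, _setj in ((c, IUPAC_BASES[c]) for c in _CODES):
        i, j = _IDX[_ci], _IDX[_cj]
        if not _seti or not _setj:  # gap on either side: never compared
            continue
        _COMPARABLE[i, j] = 1.0
        inter = _seti & _setj
        _MATCH_INTERSECT[i, j] = 1.0 if inter else 0.0
        _MATCH_IDENTITY[i, j] = 1.0 if _ci == _cj else 0.0
        npairs = len(_seti) * len(_setj)
        _MATCH_FRACTIONAL[i, j] = len(inter) / npairs
        unequal = [(x, y) for x in _seti for y in _setj if x != y]
        if unequal:
            ts_pur = sum(1 for x, y in unequal if {x, y} == {"A", "G"})
            ts_pyr = sum(1 for x, y in unequal if {x, y} == {"C", "T"})
            tv = len(unequal) - ts_pur - ts_pyr
            _TS_PUR_FRAC[i, j] = ts_pur / len(unequal)
            _TS_PYR_FRAC[i, j] = ts_pyr / len(unequal)
            _TV_FRAC[i, j] = tv / len(unequal)

_MATCH_TABLE = {
    "intersect-is-match": _MATCH_INTERSECT,
    "mismatch": _MATCH_IDENTITY,
    "fractional": _MATCH_FRACTIONAL,
}


def encode(seq: str) -> np.ndarray:
    """Encode a normalized IUPAC sequence as int8 codes for table lookups."""
    idx = _ORD2IDX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (idx < 0).any():
        raise ValueError("sequence contains characters outside the IUPAC+gap alphabet")
    return idx


class PairStats(NamedTuple):
    """Raw comparison of one aligned pair under a site policy."""

    n_sites: float        # columns compared
    match: float          # (possibly fractional) matching columns
    P1: float             # purine-transition mismatch weight (A<->G)
    P2: float             # pyrimidine-transition mismatch weight (C<->T)
    Q: float              # transversion mismatch weight
    base_freqs: np.ndarray  # fractional (A, C, G, T) frequencies over compared sites


_POLICY_TABLES: dict[str, tuple[np.ndarray, ...]] = {}


def _policy_tables(ambiguity_match: str) -> tuple[np.ndarray, ...]:
    # cache (match, mm*ts_pur, mm*ts_pyr, mm*tv) per ambiguity policy
    if ambiguity_match not in _POLICY_TABLES:
        match = _MATCH_TABLE[ambiguity_match]
        mm = _COMPARABLE - match  # match tables are zero on non-comparable pairs
        _POLICY_TABLES[ambiguity_match] = (
            match,
            mm * _TS_PUR_FRAC,
            mm * _TS_PYR_FRAC,
            mm * _TV_FRAC,
        )
    return _POLICY_TABLES[ambiguity_match]


def _pair_stats(
    ei: np.ndarray,
    ej: np.ndarray,
    policy: SitePolicy,
    column_mask: np.ndarray | None = None,
) -> PairStats:
    match_t, p1_t, p2_t, q_t = _policy_tables(policy.ambiguity_match)
    comp = _COMPARABLE[ei, ej]
    if column_mask is not None:
        comp = comp * column_mask
        masked = column_mask > 0
        n = float(comp.sum())
        if n == 0:
            raise ZeroComparableSitesError("no comparable sites under the site policy")
        match = float(match_t[ei, ej][masked].sum())
        p1 = float(p1_t[ei, ej][masked].sum())
        p2 = float(p2_t[ei, ej][masked].sum())
        q = float(q_t[ei, ej][masked].sum())
    else:
        n = float(comp.sum())
        if n == 0:
            raise ZeroComparableSitesError("no comparable sites under the site policy")
        match = float(match_t[ei, ej].sum())
        p1 = float(p1_t[ei, ej].sum())
        p2 = float(p2_t[ei, ej].sum())
        q = float(q_t[ei, ej].sum())
    freqs = ((_FREQ[ei] + _FREQ[ej]) * comp[:, None]).sum(axis=0) / (2.0 * n)
    return PairStats(n, match, p1 / n, p2 / n, q / n, freqs)


def _require_equal_length(a: BarcodeRecord, b: BarcodeRecord) -> None:
    if len(a) != len(b):
        raise ValueError(f"records {a.id!r} and {b.id!r} differ in length")


class Similarity(NamedTuple):
    percent: float
    n_sites: int


def similarity_percent(
    a: BarcodeRecord, b: BarcodeRecord, policy: SitePolicy = SitePolicy()
) -> Similarity:
    """Percent similarity: 100 x matches / compared sites."""
    _require_equal_length(a, b)
    st = _pair_stats(encode(a.seq), encode(b.seq), policy)
    return Similarity(100.0 * st.match / st.n_sites, int(round(st.n_sites)))


class PDistance(NamedTuple):
    """Proportion of differing sites, decomposed into transitions and transversions."""

    p: float
    P: float   # transition proportion (P1 + P2)
    Q: float   # transversion proportion
    P1: float  # purine transitions
    P2: float  # pyrimidine transitions
    n_sites: int


def p_distance(
    a: BarcodeRecord, b: BarcodeRecord, policy: SitePolicy = SitePolicy()
) -> PDistance:
    """p-distance with P/Q split; p = P + Q holds exactly under every policy."""
    _require_equal_length(a, b)
    st = _pair_stats(encode(a.seq), encode(b.seq), policy)
    P = st.P1 + st.P2
    return PDistance(P + st.Q, P, st.Q, st.P1, st.P2, int(round(st.n_sites)))


class DistanceValue(NamedTuple):
    value: float
    saturated: bool = False


def k2p_distance(P: float, Q: float) -> DistanceValue:
    """Kimura 2-parameter distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).

    When a log argument is non-positive the pair is saturated: the distance
    is reported as NaN with the ``saturated`` flag set rather than raising.
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return DistanceValue(math.nan, saturated=True)
    return DistanceValue(-0.5 * math.log(w1) - 0.25 * math.log(w2))


def jc69_distance(p: float) -> DistanceValue:
    """Jukes–Cantor distance d = -3/4 ln(1 - 4p/3)."""
    w = 1.0 - 4.0 * p / 3.0
    if w <= 0.0:
        return DistanceValue(math.nan, saturated=True)
    return DistanceValue(-0.75 * math.log(w))


def _tn93_from_stats(st: PairStats, freqs: np.ndarray) -> DistanceValue:
    gA, gC, gG, gT = (float(x) for x in freqs)
    gR, gY = gA + gG, gC + gT
    if gR <= 0 or gY <= 0 or gA * gG <= 0 or gC * gT <= 0:
        return DistanceValue(math.nan, saturated=True)
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gC * gT / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1.0 - st.P1 / k1 - st.Q / (2.0 * gR)
    w2 = 1.0 - st.P2 / k2 - st.Q / (2.0 * gY)
    w3 = 1.0 - st.Q / (2.0 * gR * gY)
    if w1 <= 0.0 or w2 <= 0.0 or w3 <= 0.0:
        return DistanceValue(math.nan, saturated=True)
    return DistanceValue(-k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3))


def tn93_distance(
    a: BarcodeRecord,
    b: BarcodeRecord,
    policy: SitePolicy = SitePolicy(),
    base_freqs: np.ndarray | None = None,
) -> DistanceValue:
    """Tamura–Nei (TN93) distance with separate purine/pyrimidine transition rates.

    Base frequencies are estimated from the compared sites of the pair by
    default; pass ``base_freqs`` (A, C, G, T) to use e.g. whole-alignment
    frequencies instead.  Reduces to K2P when base frequencies are equal and
    the two transition classes are balanced.
    """
    _require_equal_length(a, b)
    st = _pair_stats(encode(a.seq), encode(b.seq), policy)
    freqs = st.base_freqs if base_freqs is None else np.asarray(base_freqs, dtype=float)
    return _tn93_from_stats(st, freqs)


def alignment_base_freqs(aln: AlignedSet) -> np.ndarray:
    """Fractional (A, C, G, T) frequencies over all non-gap positions."""
    total = np.zeros(4)
    n = 0.0
    for rec in aln:
        e = encode(rec.seq)
        nongap = _COMPARABLE[e, e] > 0
        total += _FREQ[e][nongap].sum(axis=0)
        n += float(nongap.sum())
    return total / n


# ---------------------------------------------------------------------------
# Whole-matrix computation
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance (or percent-similarity) matrix.

    ``values`` holds substitutions/site for distance models and percent for
    the similarity model (diagonal 0, or 100 for similarity).  Saturated
    pairs are NaN in ``values`` with the corresponding ``saturated`` flag set.
    """

    ids: list[str]
    values: np.ndarray
    model: str
    policy: SitePolicy = field(default_factory=SitePolicy)
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match ids")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)
        self._index = {rid: i for i, rid in enumerate(self.ids)}

    def pair(self, id1: str, id2: str) -> float:
        return float(self.values[self._index[id1], self._index[id2]])

    def row(self, id1: str) -> np.ndarray:
        return self.values[self._index[id1]]

    def condensed(self) -> np.ndarray:
        """Upper-triangle values (i<j) as a flat array."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(
            ids=list(ids),
            values=self.values[np.ix_(idx, idx)],
            model=self.model,
            policy=self.policy,
            saturated=self.saturated[np.ix_(idx, idx)],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for rid, row in zip(self.ids, self.values):
                cells = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{rid:<12s}{cells}\n")


def _complete_delete_mask(encoded: np.ndarray) -> np.ndarray:
    # a column survives only if no record is gapped there
    gap_idx = _IDX["-"]
    return (encoded != gap_idx).all(axis=0).astype(float)


def encode_alignment(aln: AlignedSet) -> np.ndarray:
    """Encode all records as an (n, length) int8 matrix for table lookups."""
    return np.stack([encode(rec.seq) for rec in aln])


def distance_matrix(
    aln: AlignedSet,
    model: str = "K2P",
    policy: SitePolicy = SitePolicy(),
) -> DistanceMatrix:
    """All-pairs distance/similarity matrix under a named model and site policy."""
    if len(aln) < 2:
        raise ValueError("distance matrix needs at least 2 records")
    return distance_matrix_from_encoded(encode_alignment(aln), aln.ids, model, policy)


def distance_matrix_from_encoded(
    encoded: np.ndarray,
    ids: list[str],
    model: str = "K2P",
    policy: SitePolicy = SitePolicy(),
) -> DistanceMatrix:
    """Distance matrix from an already-encoded alignment (see encode_alignment).

    Exists so that column-resampling consumers (bootstrap) skip re-encoding.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    column_mask = (
        _complete_delete_mask(encoded)
        if policy.gap_handling == "complete-delete"
        else None
    )
    n = len(ids)
    vals = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    if model == "similarity_percent":
        np.fill_diagonal(vals, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            st = _pair_stats(encoded[i], encoded[j], policy, column_mask)
            if model == "similarity_percent":
                v = DistanceValue(100.0 * st.match / st.n_sites)
            elif model == "p":
                v = DistanceValue(st.P1 + st.P2 + st.Q)
            elif model == "JC69":
                v = jc69_distance(st.P1 + st.P2 + st.Q)
            elif model == "K2P":
                v = k2p_distance(st.P1 + st.P2, st.Q)
            else:  # TN93, per-pair frequencies (whole-alignment offered via tn93_distance)
                v = _tn93_from_stats(st, st.base_freqs)
            vals[i, j] = vals[j, i] = v.value
            sat[i, j] = sat[j, i] = v.saturated
    return DistanceMatrix(ids=list(ids), values=vals, model=model, policy=policy, saturated=sat)
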