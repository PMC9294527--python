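"""Simplified automatic barcode gap discovery (ABGD).

The barcode gap is the separation between the distributions of intraspecific
and interspecific pairwise distances.  This implementation follows the
recursive-gap scheme: sort all pairwise distances; above a prior maximum
intraspecific divergence ``prior_P``, find the first jump between
consecutive distances that is more than ``relative_gap_width_X`` times the
mean jump among the distances below it (and wider than the prior itself);
single-linkage-cluster at a cutoff inside the gap; recurse into each
resulting group until no gap is found.  No gap, or a gap that single-linkage
chaining bridges (as happens when hybrids sit between the two species),
leaves the group unsplit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from musselid.distances import DistanceMatrix


@dataclass(frozen=True)
class AbgdParams:
    """Prior maximum intraspecific divergence and relative gap width."""

    prior_P: float = 0.01
    relative_gap_width_X: float = 1.5
    model: str = "K2P"  # recorded; the caller picks the matrix model

    def __post_init__(self) -> None:
        if not (0.0 < self.prior_P < 1.0):
            raise ValueError("prior_P must lie in (0, 1)")
        if self.relative_gap_width_X <= 0:
            raise ValueError("relative_gap_width_X must be positive")


@dataclass
class AbgdPartition:
    """Finest stable partition plus where (if anywhere) the first gap opened."""

    groups: list[list[str]]
    gap_found: bool
    gap_cutoff: float | None = None
    params: AbgdParams = field(default_factory=AbgdParams)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self) -> dict[str, int]:
        return {rid: gi for gi, grp in enumerate(self.groups) for rid in grp}


_ZERO_TOL = 1e-12


def _first_gap(dists: np.ndarray, params: AbgdParams) -> float | None:
    """Cutoff inside the first significant gap of sorted distances, or None.

    A candidate gap must end above the prior intraspecific divergence
    (distances at or below the prior are assumed conspecific by definition)
    and must exceed ``X`` times the *largest* jump among the distances below
    it.  Comparing against the largest rather than the mean jump matters on
    a short amplicon: distances are near-quantized to multiples of 1/length,
    so a sorted distance list climbs in steps of that size and the mean jump
    (diluted by ties) would make every quantization step look like a barcode
    gap.  A real barcode gap has to dominate all within-group jumps.
    """
    d = np.sort(dists)
    for i in range(1, d.size):
        if d[i] <= params.prior_P:
            continue
        gap = d[i] - d[i - 1]
        if gap <= _ZERO_TOL:
            continue
        below = np.diff(d[:i])
        max_below = float(below.max()) if below.size else 0.0
        if gap > params.relative_gap_width_X * max_below:
            return float((d[i - 1] + d[i]) / 2.0)
    return None


def _single_linkage_groups(dm: DistanceMatrix, cutoff: float) -> list[list[str]]:
    condensed = squareform(dm.values, checks=False)
    labels = fcluster(linkage(condensed, method="single"), t=cutoff, criterion="distance")
    groups: dict[int, list[str]] = {}
    for rid, lab in zip(dm.ids, labels):
        groups.setdefault(int(lab), []).append(rid)
    return [groups[k] for k in sorted(groups)]


def abgd_partition(dm: DistanceMatrix, params: AbgdParams = AbgdParams()) -> AbgdPartition:
    """Partition ids by recursive barcode-gap detection.

    Returns a single group when no significant gap exists, or when the gap
    does not survive single-linkage clustering (intermediate individuals
    chain the clusters together).  Saturated (NaN) cells are rejected.
    """
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix contains saturated/undefined cells")
    if len(dm.ids) == 1:
        return AbgdPartition(groups=[list(dm.ids)], gap_found=False, params=params)

    first_cutoff: float | None = None
    gap_found = False

    def split(ids: list[str]) -> list[list[str]]:
        nonlocal first_cutoff, gap_found
        if len(ids) < 2:
            return [ids]
        sub = dm.submatrix(ids)
        cutoff = _first_gap(sub.condensed(), params)
        if cutoff is None:
            return [ids]
        if first_cutoff is None:
            first_cutoff = cutoff
            gap_found = True
        groups = _single_linkage_groups(sub, cutoff)
        if len(groups) == 1:
            return groups  # chained through intermediates: stable, stop here
        out: list[list[str]] = []
        for grp in groups:
            out.extend(split(grp))
        return out

    groups = split(list(dm.ids))
    return AbgdPartition(groups=groups, gap_found=gap_found, gap_cutoff=first_cutoff, params=params)
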