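"""Best close match (BCM) and all barcodes (AB) distance-threshold classifiers.

Both methods share a data-driven threshold: the 95th percentile of all
intraspecific pairwise distances among the labelled references (expressed in
percent substitutions/site).  BCM assigns the species of the closest
reference(s) provided the minimum distance is within the threshold; AB is
stricter and additionally requires every conspecific reference to outrank
every heterospecific one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from musselid.classifiers.result import AMBIGUOUS, NO_MATCH, IdentificationResult
from musselid.distances import DistanceMatrix, SitePolicy, distance_matrix
from musselid.seqio import AlignedSet

#: distances within this of the minimum are treated as tied
_TIE_TOL = 1e-12


@dataclass
class BcmThreshold:
    """95th percentile of intraspecific pairwise distances, as a percentage."""

    value: float              # percent (substitutions/site x 100)
    percentile: float
    n_intraspecific_pairs: int
    model: str


def _labelled_matrix(
    refs: AlignedSet, model: str, policy: SitePolicy, dm: DistanceMatrix | None
) -> DistanceMatrix:
    return dm if dm is not None else distance_matrix(refs, model=model, policy=policy)


def bcm_threshold(
    refs: AlignedSet,
    model: str = "K2P",
    policy: SitePolicy = SitePolicy(),
    percentile: float = 95.0,
    dm: DistanceMatrix | None = None,
) -> BcmThreshold:
    """Threshold = 95th percentile (linear interpolation) of intraspecific distances."""
    dm = _labelled_matrix(refs, model, policy, dm)
    intra = []
    recs = list(refs)
    for i, a in enumerate(recs):
        for b in recs[i + 1:]:
            if a.label and b.label and a.label == b.label:
                intra.append(dm.pair(a.id, b.id))
    if not intra:
        raise ValueError("no intraspecific reference pair; cannot set a BCM threshold")
    value = float(np.percentile(np.asarray(intra), percentile, method="linear"))
    return BcmThreshold(
        value=100.0 * value,
        percentile=percentile,
        n_intraspecific_pairs=len(intra),
        model=model,
    )


def _ranked_refs(query_id: str, refs: AlignedSet, dm: DistanceMatrix):
    """Labelled references sorted by (distance to query, id)."""
    out = []
    for ref in refs:
        if ref.id == query_id or not ref.label:
            continue
        out.append((dm.pair(query_id, ref.id), ref.id, ref.label))
    if not out:
        raise ValueError("no labelled reference available")
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def bcm_classify(
    query_id: str,
    refs: AlignedSet,
    threshold: BcmThreshold,
    dm: DistanceMatrix,
) -> IdentificationResult:
    """Best close match: species of the closest reference(s) within the threshold.

    The query must be excluded from the reference side (leave-one-out when
    evaluating a labelled set); ``dm`` must cover the query and all refs.
    Ties at the minimum distance across species yield ambiguous.
    """
    ranked = _ranked_refs(query_id, refs, dm)
    dmin = ranked[0][0]
    evidence = {"min_distance": dmin, "threshold_pct": threshold.value}
    if not np.isfinite(dmin) or 100.0 * dmin > threshold.value:
        call = NO_MATCH
    else:
        species_at_min = {lab for d, _, lab in ranked if d <= dmin + _TIE_TOL}
        call = AMBIGUOUS if len(species_at_min) > 1 else next(iter(species_at_min))
        evidence["species_at_min"] = sorted(species_at_min)
    return IdentificationResult(query_id=query_id, method="BCM", call=call, evidence=evidence)


def ab_classify(
    query_id: str,
    refs: AlignedSet,
    threshold: BcmThreshold,
    dm: DistanceMatrix,
) -> IdentificationResult:
    """All barcodes: every conspecific reference must top the ranked match list.

    Let S be the species of the nearest reference and C its reference set.
    The call is S only when C has at least two members and the top |C| ranks
    are exactly C.  The distance threshold applies to the best match, as in
    BCM: a minimum distance beyond it (or fewer than two conspecific
    references) is no_match; an interleaved heterospecific reference
    (including a tie with the worst conspecific) is ambiguous.
    """
    ranked = _ranked_refs(query_id, refs, dm)
    dmin = ranked[0][0]
    evidence = {"min_distance": dmin, "threshold_pct": threshold.value}
    # same comparison arithmetic as bcm_classify, so AB is never stricter
    # than BCM through floating-point noise alone
    if not np.isfinite(dmin) or 100.0 * dmin > threshold.value:
        return IdentificationResult(query_id, "AB", NO_MATCH, evidence)
    species = ranked[0][2]
    conspecific = [t for t in ranked if t[2] == species]
    evidence["species"] = species
    evidence["n_conspecific"] = len(conspecific)
    if len(conspecific) < 2:
        return IdentificationResult(query_id, "AB", NO_MATCH, evidence)
    top = ranked[: len(conspecific)]
    top_is_conspecific = all(t[2] == species for t in top)
    # a heterospecific tie with the worst conspecific also breaks the block
    worst_consp = max(t[0] for t in conspecific)
    het_within = any(t[0] <= worst_consp + _TIE_TOL for t in ranked if t[2] != species)
    if not top_is_conspecific or het_within:
        return IdentificationResult(query_id, "AB", AMBIGUOUS, evidence)
    return IdentificationResult(query_id, "AB", species, evidence)
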