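"""Direct sequence comparison (DSC): percent-similarity threshold classification.

A query is assigned to species S when its similarity to the S references
clears a fixed threshold (98 % by convention for this amplicon) and no other
species also clears it.  Queries already flagged as putative hybrids by
diagnostic-site detection pass through with the hybrid outcome — a hybrid's
heterozygous sites make it highly similar to *both* parental species, so a
similarity threshold cannot place it.
"""

from __future__ import annotations

from musselid.classifiers.result import (
    AMBIGUOUS,
    NO_MATCH,
    PUTATIVE_HYBRID,
    IdentificationResult,
)
from musselid.distances import SitePolicy, similarity_percent
from musselid.seqio import AlignedSet, BarcodeRecord


def dsc_classify(
    query: BarcodeRecord,
    refs: AlignedSet,
    threshold_pct: float = 98.0,
    policy: SitePolicy = SitePolicy(),
    aggregate: str = "min",
    hybrid_flagged: bool = False,
) -> IdentificationResult:
    """Classify one query by percent similarity against labelled references.

    A species qualifies when the aggregated (``min`` of all, or ``mean``)
    query-to-reference similarity strictly exceeds ``threshold_pct``.
    Exactly one qualifying species is the call; two or more is ambiguous;
    none is no_match.  ``hybrid_flagged`` queries return putative_hybrid.
    """
    if aggregate not in ("min", "mean"):
        raise ValueError("aggregate must be 'min' or 'mean'")
    labelled = [r for r in refs if r.label and r.id != query.id]
    if not labelled:
        raise ValueError("DSC needs at least one labelled reference")
    if hybrid_flagged:
        return IdentificationResult(
            query_id=query.id, method="DSC", call=PUTATIVE_HYBRID, evidence={}
        )
    by_species: dict[str, list[float]] = {}
    for ref in labelled:
        sim = similarity_percent(query, ref, policy).percent
        by_species.setdefault(ref.label, []).append(sim)
    agg = {
        sp: (min(sims) if aggregate == "min" else sum(sims) / len(sims))
        for sp, sims in by_species.items()
    }
    qualifying = sorted(sp for sp, v in agg.items() if v > threshold_pct)
    evidence = {"similarity_by_species": agg, "threshold_pct": threshold_pct}
    if len(qualifying) == 1:
        call = qualifying[0]
    elif len(qualifying) > 1:
        call = AMBIGUOUS
    else:
        call = NO_MATCH
    return IdentificationResult(query_id=query.id, method="DSC", call=call, evidence=evidence)
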