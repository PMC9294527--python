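"""Shared per-query outcome type for all identification methods."""

from __future__ import annotations

from dataclasses import dataclass, field

AMBIGUOUS = "ambiguous"
INCORRECT = "incorrect"
NO_MATCH = "no_match"
PUTATIVE_HYBRID = "putative_hybrid"

#: Non-species outcome categories a method may emit.
CATEGORIES = frozenset({AMBIGUOUS, INCORRECT, NO_MATCH, PUTATIVE_HYBRID})


@dataclass
class IdentificationResult:
    """Outcome of one method on one query.

    ``call`` is either a species name or one of the outcome categories
    (ambiguous, no_match, putative_hybrid).  ``evidence`` carries
    method-specific support: closest distance, similarity, clade support,
    partition id, ...
    """

    query_id: str
    method: str
    call: str
    evidence: dict = field(default_factory=dict)

    @property
    def is_species_call(self) -> bool:
        return self.call not in CATEGORIES
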