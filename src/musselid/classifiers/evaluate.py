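"""Leave-one-out evaluation of the identification methods on a labelled set.

Each labelled record is queried in turn against all remaining records, and
the per-query outcomes are summarized as the percentage of individuals
identified correctly / ambiguously / incorrectly (the conventional way such
method comparisons are tabulated).  ``no_match`` and ``putative_hybrid``
outcomes count as ambiguous unless configured otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from musselid.classifiers.abgd import AbgdParams, abgd_partition
from musselid.classifiers.bcm import BcmThreshold, ab_classify, bcm_classify, bcm_threshold
from musselid.classifiers.dsc import dsc_classify
from musselid.classifiers.fins import bootstrap_support, fins_classify
from musselid.classifiers.result import AMBIGUOUS, NO_MATCH, PUTATIVE_HYBRID
from musselid.distances import SitePolicy, distance_matrix
from musselid.seqio import AlignedSet

METHODS = ("FINS", "DSC", "BCM", "AB", "ABGD")

#: outcome categories folded into the "ambiguous" column by default
DEFAULT_AMBIGUOUS = frozenset({AMBIGUOUS, NO_MATCH, PUTATIVE_HYBRID})


@dataclass
class MethodSummary:
    """Per-method outcome counts and percentages over a labelled set."""

    method: str
    n: int
    n_correct: int
    n_ambiguous: int
    n_incorrect: int
    calls: dict[str, str] = field(default_factory=dict)

    @property
    def pct_correct(self) -> float:
        return round(100.0 * self.n_correct / self.n, 1)

    @property
    def pct_ambiguous(self) -> float:
        return round(100.0 * self.n_ambiguous / self.n, 1)

    @property
    def pct_incorrect(self) -> float:
        return round(100.0 * self.n_incorrect / self.n, 1)


def summarize_calls(
    method: str,
    calls: dict[str, str],
    truth: dict[str, str],
    ambiguous_categories: frozenset[str] = DEFAULT_AMBIGUOUS,
) -> MethodSummary:
    """Score per-query calls against truth labels."""
    n_c = n_a = n_i = 0
    for rid, call in calls.items():
        if call in ambiguous_categories:
            n_a += 1
        elif call == truth[rid]:
            n_c += 1
        else:
            n_i += 1
    return MethodSummary(
        method=method, n=len(calls), n_correct=n_c, n_ambiguous=n_a,
        n_incorrect=n_i, calls=calls,
    )


def calls_dsc(
    aln: AlignedSet,
    threshold_pct: float = 98.0,
    policy: SitePolicy = SitePolicy(),
    hybrid_flags: set[str] | None = None,
    aggregate: str = "min",
) -> dict[str, str]:
    hybrid_flags = hybrid_flags or set()
    calls = {}
    for rec in aln:
        res = dsc_classify(
            rec,
            aln,
            threshold_pct=threshold_pct,
            policy=policy,
            aggregate=aggregate,
            hybrid_flagged=rec.id in hybrid_flags,
        )
        calls[rec.id] = res.call
    return calls


def calls_bcm(
    aln: AlignedSet,
    model: str = "K2P",
    policy: SitePolicy = SitePolicy(),
    threshold: BcmThreshold | None = None,
) -> dict[str, str]:
    dm = distance_matrix(aln, model=model, policy=policy)
    if threshold is None:
        threshold = bcm_threshold(aln, model=model, policy=policy, dm=dm)
    return {rec.id: bcm_classify(rec.id, aln, threshold, dm).call for rec in aln}


def calls_ab(
    aln: AlignedSet,
    model: str = "K2P",
    policy: SitePolicy = SitePolicy(),
    threshold: BcmThreshold | None = None,
) -> dict[str, str]:
    dm = distance_matrix(aln, model=model, policy=policy)
    if threshold is None:
        threshold = bcm_threshold(aln, model=model, policy=policy, dm=dm)
    return {rec.id: ab_classify(rec.id, aln, threshold, dm).call for rec in aln}


def calls_abgd(
    aln: AlignedSet,
    model: str = "K2P",
    policy: SitePolicy = SitePolicy(),
    params: AbgdParams = AbgdParams(),
) -> dict[str, str]:
    """ABGD as a classifier: groups are named by their majority nominal label.

    A partition with a single group carries no species signal, so every
    individual is ambiguous; with several groups, each individual is called
    by its group's majority label (ties are ambiguous).
    """
    dm = distance_matrix(aln, model=model, policy=policy)
    part = abgd_partition(dm, params)
    if part.n_groups == 1:
        return {rec.id: AMBIGUOUS for rec in aln}
    labels = {rec.id: rec.label for rec in aln}
    calls: dict[str, str] = {}
    for group in part.groups:
        tally: dict[str, int] = {}
        for rid in group:
            if labels.get(rid):
                tally[labels[rid]] = tally.get(labels[rid], 0) + 1
        if tally:
            top = max(tally.values())
            winners = [sp for sp, c in tally.items() if c == top]
            call = winners[0] if len(winners) == 1 else AMBIGUOUS
        else:
            call = AMBIGUOUS
        for rid in group:
            calls[rid] = call
    return {rec.id: calls[rec.id] for rec in aln}


def calls_fins(
    aln: AlignedSet,
    model: str = "TN93",
    policy: SitePolicy = SitePolicy(),
    replicates: int = 100,
    seed: int = 0,
    min_support: float = 70.0,
    outgroup_id: str | None = None,
) -> dict[str, str]:
    tree, supports = bootstrap_support(
        aln, model=model, replicates=replicates, seed=seed, policy=policy
    )
    all_labels = {rec.id: rec.label for rec in aln if rec.label}
    calls = {}
    for rec in aln:
        labels = {rid: lab for rid, lab in all_labels.items() if rid != rec.id}
        res = fins_classify(
            tree, supports, rec.id, labels,
            min_support=min_support, outgroup_id=outgroup_id,
        )
        calls[rec.id] = res.call
    return calls


def evaluate_method(
    method: str,
    aln: AlignedSet,
    truth: dict[str, str] | None = None,
    **params,
) -> MethodSummary:
    """Leave-one-out evaluation of one method over a labelled aligned set.

    ``truth`` defaults to the records' own nominal labels.  Method-specific
    keyword arguments are forwarded (thresholds, site policy, ABGD params,
    bootstrap replicates/seed, ...).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if truth is None:
        truth = {rec.id: rec.label for rec in aln}
    if any(v is None for v in truth.values()):
        raise ValueError("every record needs a truth label for evaluation")
    dispatch = {
        "DSC": calls_dsc,
        "BCM": calls_bcm,
        "AB": calls_ab,
        "ABGD": calls_abgd,
        "FINS": calls_fins,
    }
    calls = dispatch[method](aln, **params)
    return summarize_calls(method, calls, truth)
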