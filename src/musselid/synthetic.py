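"""Seeded generator of two-species-plus-hybrids barcode datasets.

The generator emulates the statistical structure of a short nuclear barcode
(a ~397 bp histone amplicon) sampled from two closely related mussel species
and their F1 hybrids:

* two species consensus sequences separated by ~2 % divergence, a fixed
  number of which are *diagnostic* columns (fixed in every individual of
  each species);
* individuals carrying private substitutions so that intraspecific pairwise
  diversity sits near ``intraspecific_theta``;
* F1 hybrids that are heterozygous — encoded as the IUPAC code combining the
  two parental alleles — at every column where the consensuses differ, on a
  parental background that alternates between the species to avoid
  artifactual asymmetry.

Substitutions follow a transition:transversion bias (2:1 by default); there
are no indels, so the output is gap-free and aligned by construction.  The
same seed always yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from musselid.hybrid_detect import DiagnosticPanel, DiagnosticSite
from musselid.seqio import AlignedSet, BarcodeRecord, iupac_code

_BASES = ("A", "C", "G", "T")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

SPECIES_A = "speciesA"
SPECIES_B = "speciesB"
F1_HYBRID = "F1_hybrid"


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters.

    ``interspecific_divergence`` is the expected proportion of columns at
    which the two species consensuses differ (the diagnostic sites are among
    them); ``intraspecific_theta`` is the expected *pairwise* intraspecific
    p-distance, so each individual mutates away from its consensus at
    Poisson(length x theta / 2) positions.  Defaults mirror a study of 61
    mussels: 7 + 42 pure individuals plus 12 F1 hybrids over a 397 bp
    amplicon with five diagnostic sites, ~2 % interspecific divergence and
    ~0.5 % intraspecific polymorphism.
    """

    length: int = 397
    n_A: int = 7
    n_B: int = 42
    n_hybrids: int = 12
    n_diagnostic_sites: int = 5
    interspecific_divergence: float = 0.02
    intraspecific_theta: float = 0.005
    transition_bias: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diagnostic_sites > self.length:
            raise ValueError("more diagnostic sites than alignment columns")
        if min(self.n_A, self.n_B, self.n_hybrids, self.n_diagnostic_sites) < 0:
            raise ValueError("counts must be non-negative")
        if self.interspecific_divergence < self.intraspecific_theta:
            raise ValueError(
                "interspecific divergence must exceed intraspecific theta "
                "(the generator models the barcoding-gap-exists regime)"
            )


@dataclass
class TruthTable:
    """True class per simulated individual plus the planted diagnostic panel."""

    classes: dict[str, str]  # id -> speciesA | speciesB | F1_hybrid
    panel: DiagnosticPanel
    config: SimConfig = field(default=None)

    def ids_of(self, cls: str) -> list[str]:
        return [rid for rid, c in self.classes.items() if c == cls]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\ttrue_class\n")
            for rid, cls in self.classes.items():
                fh.write(f"{rid}\t{cls}\n")


def _substitute(base: str, rng: np.random.Generator, bias: float) -> str:
    """Replace a base honouring the transition:transversion bias."""
    if rng.random() < bias / (bias + 1.0):
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][rng.integers(0, 2)]


def simulate_dataset(cfg: SimConfig) -> tuple[AlignedSet, TruthTable]:
    """Generate one aligned dataset of pure individuals and F1 hybrids.

    The number of consensus-divergent columns is max(n_diagnostic_sites,
    Poisson(length x divergence)); the diagnostic columns are drawn from
    them and protected from within-species mutation so the panel invariant
    (every pure individual fixed for its species' allele) holds by
    construction.  Hybrids are heterozygous at every divergent column.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.length
    ancestor = rng.choice(len(_BASES), size=L)
    cons_A = [_BASES[i] for i in ancestor]

    # divergence between the species consensuses is a structural property of
    # the pair, not a per-replicate sample: fix the column count at its
    # expectation (sampling noise enters through individual mutations)
    n_div = max(cfg.n_diagnostic_sites, round(L * cfg.interspecific_divergence))
    n_div = min(n_div, L)
    div_cols = np.sort(rng.choice(L, size=n_div, replace=False))
    diag_cols = np.sort(rng.choice(div_cols, size=cfg.n_diagnostic_sites, replace=False))
    diag_set = set(int(c) for c in diag_cols)
    div_set = set(int(c) for c in div_cols)

    cons_B = list(cons_A)
    for col in div_cols:
        cons_B[col] = _substitute(cons_A[col], rng, cfg.transition_bias)

    panel = DiagnosticPanel(
        sites=[
            DiagnosticSite(column=int(c) + 1, allele_A=cons_A[c], allele_B=cons_B[c])
            for c in diag_cols
        ],
        species_A=SPECIES_A,
        species_B=SPECIES_B,
    )

    mutable_cols = np.array([c for c in range(L) if c not in diag_set], dtype=int)
    lam = L * cfg.intraspecific_theta / 2.0

    def individual(consensus: list[str]) -> str:
        seq = list(consensus)
        n_mut = min(int(rng.poisson(lam)), len(mutable_cols))
        for col in rng.choice(mutable_cols, size=n_mut, replace=False):
            seq[col] = _substitute(seq[col], rng, cfg.transition_bias)
        return "".join(seq)

    hybrid_mutable = np.array(
        [c for c in range(L) if c not in div_set], dtype=int
    )

    def hybrid(background: list[str]) -> str:
        seq = list(background)
        for col in div_cols:
            seq[col] = iupac_code({cons_A[col], cons_B[col]})
        n_mut = min(int(rng.poisson(lam)), len(hybrid_mutable))
        for col in rng.choice(hybrid_mutable, size=n_mut, replace=False):
            seq[col] = _substitute(seq[col], rng, cfg.transition_bias)
        return "".join(seq)

    records: list[BarcodeRecord] = []
    classes: dict[str, str] = {}
    for i in range(cfg.n_A):
        rid = f"A{i + 1:02d}"
        records.append(BarcodeRecord(id=rid, seq=individual(cons_A), label=SPECIES_A))
        classes[rid] = SPECIES_A
    for i in range(cfg.n_B):
        rid = f"B{i + 1:02d}"
        records.append(BarcodeRecord(id=rid, seq=individual(cons_B), label=SPECIES_B))
        classes[rid] = SPECIES_B
    for i in range(cfg.n_hybrids):
        rid = f"H{i + 1:02d}"
        background = cons_A if i % 2 == 0 else cons_B  # alternate parental background
        records.append(BarcodeRecord(id=rid, seq=hybrid(background)))
        classes[rid] = F1_HYBRID

    return AlignedSet(records), TruthTable(classes=classes, panel=panel, config=cfg)


#: canonical seed for the study-shaped dataset (fixed once, a priori)
PAPERLIKE_SEED = 2020


def simulate_paperlike(
    seed: int = PAPERLIKE_SEED, **overrides
) -> tuple[AlignedSet, dict[str, dict[str, str]], TruthTable]:
    """Fixed study-shaped dataset of 61 individuals with HRM-like labels.

    7 pure speciesA + 42 pure speciesB + 12 F1 hybrids; the HRM-like
    labelling scheme (the independent wet-lab comparator, which cannot see
    hybrids) records 9 speciesA and 52 speciesB: the first two hybrids are
    labelled speciesA and the remaining ten speciesB.  Records carry the
    HRM-like call as their nominal label, so downstream leave-one-out
    evaluation sees exactly the label structure of the study.

    ``overrides`` adjust SimConfig fields (e.g. a lower
    ``intraspecific_theta`` for a cleaner-diversity regime) while keeping
    the study's label structure.
    """
    cfg = SimConfig(seed=seed, **overrides)
    aln, truth = simulate_dataset(cfg)
    labels: dict[str, dict[str, str]] = {}
    hybrids = truth.ids_of(F1_HYBRID)
    hrm_A = set(truth.ids_of(SPECIES_A)) | set(hybrids[:2])
    for rec in aln:
        call = SPECIES_A if rec.id in hrm_A else SPECIES_B
        rec.label = call
        rec.aux_labels["HRM"] = call
        labels[rec.id] = {"nominal_species": call, "HRM": call}
    return aln, labels, truth
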