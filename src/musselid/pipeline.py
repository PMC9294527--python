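"""End-to-end orchestration: load/simulate -> hybrid detection -> dataset split
-> identification methods -> concordance report.

The workflow mirrors how a barcoding comparison study is run: putative
hybrids are flagged from diagnostic sites first; ``dataset1`` is the full
sample and ``dataset2`` is derived from it by excluding the flagged hybrids
(never supplied independently); every method is then evaluated leave-one-out
on both datasets, and pairwise agreement between the methods (plus the
independent HRM-like labelling scheme) is summarized with kappa/MCC and
BH-FDR-adjusted p-values.  All randomness flows from one seed recorded in
the run manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from musselid import __version__
from musselid.classifiers.abgd import AbgdParams
from musselid.classifiers.evaluate import (
    MethodSummary,
    calls_ab,
    calls_abgd,
    calls_bcm,
    calls_dsc,
    calls_fins,
    summarize_calls,
)
from musselid.classifiers.fins import annotate_support, bootstrap_support
from musselid.concordance import agreement_matrix
from musselid.distances import SitePolicy
from musselid.hybrid_detect import call_hybrids, find_diagnostic_sites, hybrid_ids, write_hybrid_report
from musselid.seqio import AlignedSet, read_fasta, read_labels, write_fasta, write_labels, write_newick
from musselid.synthetic import simulate_paperlike


@dataclass
class RunConfig:
    """Pipeline configuration; ``fasta=None`` simulates a study-shaped dataset."""

    outdir: str | Path = "musselid_run"
    fasta: str | Path | None = None
    labels: str | Path | None = None
    seed: int = 2020
    methods: tuple[str, ...] = ("FINS", "DSC", "BCM", "AB", "ABGD")
    dsc_pct: float = 98.0
    dsc_aggregate: str = "min"
    bcm_model: str = "K2P"
    fins_model: str = "TN93"
    fins_min_support: float = 70.0
    fins_replicates: int = 200
    abgd_prior: float = 0.01
    abgd_X: float = 1.5
    min_het_sites: int = 1
    outgroup_id: str | None = None
    #: overlap semantics for similarity (DSC), partitioning (ABGD) and trees
    #: (FINS): a hybrid's heterozygous code matches both parental alleles
    ambiguity_match: str = "intersect-is-match"
    #: strict-barcoding semantics for the distance-threshold methods
    #: (BCM/AB): an ambiguity code differing from the reference base counts
    #: as a difference, as barcode gap software treats Sanger ambiguities
    bcm_ambiguity: str = "mismatch"

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method must be selected")


@dataclass
class RunResult:
    """Everything the pipeline produced, plus where it was written."""

    outdir: Path
    aln: AlignedSet
    hybrids: list[str]
    summaries: dict[str, dict[str, MethodSummary]]  # dataset -> method -> summary
    agreement: dict[str, object]  # dataset -> tidy DataFrame
    manifest: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _load_or_simulate(cfg: RunConfig):
    if cfg.fasta is None:
        aln, labels, truth = simulate_paperlike(seed=cfg.seed)
        return aln, labels, truth
    aln = read_fasta(cfg.fasta)
    labels = read_labels(cfg.labels) if cfg.labels else {}
    for rec in aln:
        calls = labels.get(rec.id, {})
        if "nominal_species" in calls:
            rec.label = calls["nominal_species"]
        for scheme, call in calls.items():
            if scheme != "nominal_species":
                rec.aux_labels[scheme] = call
    return aln, labels, None


def _species_pair(aln: AlignedSet) -> tuple[str, str]:
    tally: dict[str, int] = {}
    for rec in aln:
        if rec.label:
            tally[rec.label] = tally.get(rec.label, 0) + 1
    if len(tally) < 2:
        raise ValueError("need two labelled species for hybrid detection")
    top = sorted(tally, key=lambda s: (-tally[s], s))[:2]
    return top[0], top[1]


def _write_summary_tsv(path: Path, summaries: dict[str, MethodSummary]) -> None:
    with open(path, "w") as fh:
        fh.write("method\tn\tpct_correct\tpct_ambiguous\tpct_incorrect\n")
        for method, s in summaries.items():
            fh.write(
                f"{method}\t{s.n}\t{s.pct_correct}\t{s.pct_ambiguous}\t{s.pct_incorrect}\n"
            )


def _write_calls_tsv(path: Path, summaries: dict[str, MethodSummary], ids: list[str]) -> None:
    methods = list(summaries)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(methods) + "\n")
        for rid in ids:
            fh.write(rid + "\t" + "\t".join(summaries[m].calls[rid] for m in methods) + "\n")


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Run the full workflow; deterministic given the config seed."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    policy = SitePolicy(ambiguity_match=cfg.ambiguity_match)
    bcm_policy = SitePolicy(ambiguity_match=cfg.bcm_ambiguity)

    stage = "load"
    try:
        aln, labels, truth = _load_or_simulate(cfg)
        paths["fasta"] = outdir / "dataset.fasta"
        write_fasta(aln, paths["fasta"])
        if labels:
            paths["labels"] = outdir / "labels.tsv"
            write_labels(labels, paths["labels"])
        if truth is not None:
            paths["truth"] = outdir / "truth.tsv"
            truth.to_tsv(paths["truth"])

        stage = "hybrid_detection"
        sp_a, sp_b = _species_pair(aln)
        refs_a = [r.id for r in aln if r.label == sp_a and not r.is_ambiguous()]
        refs_b = [r.id for r in aln if r.label == sp_b and not r.is_ambiguous()]
        panel = find_diagnostic_sites(aln, refs_a, refs_b, species_A=sp_a, species_B=sp_b)
        if panel.sites:
            hcalls = call_hybrids(aln, panel, min_het_sites=cfg.min_het_sites)
            flagged = hybrid_ids(hcalls)
            paths["panel"] = outdir / "panel.tsv"
            panel.to_tsv(paths["panel"])
            paths["hybrids"] = outdir / "hybrids.tsv"
            write_hybrid_report(hcalls, paths["hybrids"])
        else:
            flagged = []

        stage = "datasets"
        datasets = {"dataset1": aln}
        if flagged:
            datasets["dataset2"] = aln.without(flagged)

        stage = "identify"
        summaries: dict[str, dict[str, MethodSummary]] = {}
        for ds_name, ds in datasets.items():
            ds_dir = outdir / ds_name
            ds_dir.mkdir(exist_ok=True)
            truth_labels = {rec.id: rec.label for rec in ds}
            ds_flagged = set(flagged) & set(ds.ids)
            per_method: dict[str, MethodSummary] = {}
            for method in cfg.methods:
                if method == "DSC":
                    calls = calls_dsc(
                        ds, threshold_pct=cfg.dsc_pct, policy=policy,
                        hybrid_flags=ds_flagged, aggregate=cfg.dsc_aggregate,
                    )
                elif method == "BCM":
                    calls = calls_bcm(ds, model=cfg.bcm_model, policy=bcm_policy)
                elif method == "AB":
                    calls = calls_ab(ds, model=cfg.bcm_model, policy=bcm_policy)
                elif method == "ABGD":
                    calls = calls_abgd(
                        ds, model=cfg.bcm_model, policy=policy,
                        params=AbgdParams(prior_P=cfg.abgd_prior,
                                          relative_gap_width_X=cfg.abgd_X),
                    )
                else:  # FINS
                    calls = calls_fins(
                        ds, model=cfg.fins_model, policy=policy,
                        replicates=cfg.fins_replicates, seed=cfg.seed,
                        min_support=cfg.fins_min_support,
                        outgroup_id=cfg.outgroup_id,
                    )
                per_method[method] = summarize_calls(method, calls, truth_labels)
            summaries[ds_name] = per_method
            _write_summary_tsv(ds_dir / "summary.tsv", per_method)
            _write_calls_tsv(ds_dir / "calls.tsv", per_method, ds.ids)
            paths[f"{ds_name}_summary"] = ds_dir / "summary.tsv"
            paths[f"{ds_name}_calls"] = ds_dir / "calls.tsv"

        stage = "concordance"
        agreement = {}
        for ds_name, ds in datasets.items():
            calls_by_method = {"HRM": {rec.id: rec.label for rec in ds}}
            for method, s in summaries[ds_name].items():
                calls_by_method[method] = s.calls
            df = agreement_matrix(calls_by_method)
            agreement[ds_name] = df
            path = outdir / ds_name / "agreement.tsv"
            df.to_csv(path, sep="\t", index=False, float_format="%.6g")
            paths[f"{ds_name}_agreement"] = path

        stage = "tree"
        if "FINS" in cfg.methods:
            tree, supports = bootstrap_support(
                aln, model=cfg.fins_model, replicates=cfg.fins_replicates,
                seed=cfg.seed, policy=policy,
            )
            annotate_support(tree, supports)
            paths["tree"] = outdir / "tree_dataset1.nwk"
            paths["tree"].write_text(write_newick(tree))

        stage = "manifest"
        manifest = {
            "package": "musselid",
            "version": __version__,
            "config": {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in dataclasses.asdict(cfg).items()
            },
            "seed": cfg.seed,
            "n_records": len(aln),
            "n_putative_hybrids": len(flagged),
            "putative_hybrids": flagged,
            "datasets": {k: len(v) for k, v in datasets.items()},
            "outputs": {k: str(v) for k, v in paths.items()},
        }
        paths["manifest"] = outdir / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    return RunResult(
        outdir=outdir,
        aln=aln,
        hybrids=flagged,
        summaries=summaries,
        agreement=agreement,
        manifest=manifest,
        paths=paths,
    )
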