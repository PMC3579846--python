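"""End-to-end workflow runner: validated config, staged execution, report.

Stages mirror the order of a targeting campaign: candidate-site discovery
(``sites``), genome-wide off-target counting (``offtargets``), somatic
lesion analysis of cloned amplicons (``lesions``), and the pooled founder
screen (``screen``).  Each run writes its outputs plus a machine-readable
``manifest.json`` (inputs, package version, seed, thresholds) and a
Markdown report that states the go/no-go reading of the numbers: a ZFN
with clear somatic activity is worth growing to adulthood for founder
screening, one without is a candidate for redesign or a higher dose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import zfnscreen
from zfnscreen import io as zio
from zfnscreen.founders import call_pool_peaks, design_screen, estimate_transmission
from zfnscreen.lesions import classify_allele, summarize_lesions
from zfnscreen.sites import count_offtargets, scan_candidate_sites

STAGE_ORDER = ("sites", "offtargets", "lesions", "screen")


class MissingInputError(Exception):
    """An upstream artifact or config section needed by a stage is absent."""


@dataclass
class RunConfig:
    """Validated run configuration (one YAML document)."""

    output_dir: Path
    seed: int = 0
    sites: dict = field(default_factory=dict)
    offtargets: dict = field(default_factory=dict)
    lesions: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "output_dir" not in raw:
            raise ValueError("config must set output_dir")
        known = {"output_dir", "seed", "sites", "offtargets", "lesions", "screen"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            output_dir=Path(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            sites=raw.get("sites") or {},
            offtargets=raw.get("offtargets") or {},
            lesions=raw.get("lesions") or {},
            screen=raw.get("screen") or {},
        )


def _require(section: dict, stage: str, *keys: str) -> None:
    if not section:
        raise MissingInputError(
            f"stage '{stage}' requested but config has no '{stage}' section")
    missing = [k for k in keys if k not in section]
    if missing:
        raise MissingInputError(
            f"stage '{stage}' config missing keys: {missing}")


def run_workflow(config: RunConfig,
                 stages: set[str] | None = None) -> Path:
    """Execute the requested stages and write report + manifest.

    Returns the path of the Markdown report.  Stage inputs are plain files
    named in the config; a stage whose inputs are missing raises
    :class:`MissingInputError` naming what to provide.
    """
    if stages is None:
        stages = set(STAGE_ORDER)
    bad = stages - set(STAGE_ORDER)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    report: list[str] = ["# zfnscreen run report", ""]
    manifest: dict = {
        "package": "zfnscreen",
        "version": zfnscreen.__version__,
        "seed": config.seed,
        "stages": sorted(stages),
        "inputs": {},
        "thresholds": {},
    }

    if "sites" in stages:
        cfg = config.sites
        _require(cfg, "sites", "cds_fasta")
        cds = next(iter(zio.read_fasta(cfg["cds_fasta"]).values()))
        specs = scan_candidate_sites(
            cds,
            left_len=int(cfg.get("left_len", 9)),
            right_len=int(cfg.get("right_len", 9)),
            spacer_range=(int(cfg.get("spacer_min", 5)),
                          int(cfg.get("spacer_max", 7))),
            first_half_only=bool(cfg.get("first_half_only", True)),
            gene_id=str(cfg.get("gene_id", "gene")),
        )
        manifest["inputs"]["cds_fasta"] = str(cfg["cds_fasta"])
        with open(outdir / "candidate_sites.tsv", "w") as fh:
            fh.write("gene_id\tstart_1based\tleft_site\tspacer_len\tright_site\n")
            for s in specs:
                fh.write(f"{s.gene_id}\t{s.cds_position + 1}\t{s.left_site}"
                         f"\t{s.spacer_len_range[0]}\t{s.right_site}\n")
        report += [
            "## Candidate target sites",
            "",
            f"{len(specs)} candidate [left][spacer][right] windows "
            "(see candidate_sites.tsv).",
            "",
        ]

    if "offtargets" in stages:
        cfg = config.offtargets
        _require(cfg, "offtargets", "genome_fasta", "query")
        genome = zio.read_fasta(cfg["genome_fasta"])
        k = int(cfg.get("mismatches", 3))
        matches = count_offtargets(genome, str(cfg["query"]), k)
        manifest["inputs"]["genome_fasta"] = str(cfg["genome_fasta"])
        manifest["thresholds"]["mismatches"] = k
        zio.write_bed(matches, query_id=str(cfg.get("query_id", "query")),
                      k=k, path=outdir / "offtargets.bed")
        zio.mismatch_summary(matches, k).to_csv(
            outdir / "offtarget_summary.tsv", sep="\t", index=False)
        report += [
            "## Off-target scan",
            "",
            f"{len(matches)} genome-wide matches of the query at <= {k} "
            "mismatches, both strands (offtargets.bed). A site with few "
            "near-perfect secondary matches is preferred.",
            "",
        ]

    lesion_freq = None
    if "lesions" in stages:
        cfg = config.lesions
        _require(cfg, "lesions", "wt_fasta", "clones_fasta",
                 "cut_start", "cut_end")
        wt = next(iter(zio.read_fasta(cfg["wt_fasta"]).values()))
        clones = zio.read_fasta(cfg["clones_fasta"])
        window = (int(cfg["cut_start"]), int(cfg["cut_end"]))
        calls = [classify_allele(wt, seq, window, clone_id=name)
                 for name, seq in clones.items()]
        summary = summarize_lesions(calls)
        lesion_freq = summary.frequency
        manifest["inputs"]["clones_fasta"] = str(cfg["clones_fasta"])
        manifest["thresholds"]["cut_window"] = list(window)
        with open(outdir / "clone_calls.tsv", "w") as fh:
            fh.write("clone_id\tallele_class\tnet_delta\tinserted_seq\t"
                     "deleted_seq\tis_duplication\tevent_start_1based\n")
            for c in calls:
                fh.write(f"{c.clone_id}\t{c.allele_class}\t{c.net_delta}\t"
                         f"{c.inserted_seq or '.'}\t{c.deleted_seq or '.'}\t"
                         f"{int(c.is_duplication)}\t{c.event_start + 1}\n")
        with open(outdir / "lesion_summary.json", "w") as fh:
            json.dump({"n_mutant": summary.n_mutant,
                       "n_total": summary.n_total,
                       "frequency_pct": summary.frequency,
                       "ci95_pct": [round(summary.ci_low, 2),
                                    round(summary.ci_high, 2)]}, fh, indent=2)
        if summary.frequency >= 10:
            advice = ("High activity: proceed to founder screening, and "
                      "consider injecting a reduced dose to limit "
                      "off-target load.")
        elif summary.n_mutant > 0:
            advice = ("Activity detected: proceed to founder screening; "
                      "expect fewer transmitting founders.")
        else:
            advice = ("No lesions detected: sequence more clones, raise the "
                      "mRNA dose, or redesign the nuclease pair.")
        report += [
            "## Somatic lesion analysis",
            "",
            f"Mutant clones: {summary.n_mutant}/{summary.n_total} "
            f"({summary.frequency}%; 95% CI {summary.ci_low:.1f}-"
            f"{summary.ci_high:.1f}%).",
            "",
            advice,
            "",
        ]

    if "screen" in stages:
        cfg = config.screen
        _require(cfg, "screen", "peaks_csv", "wt_size", "pool_size",
                 "n_embryos")
        tables = zio.read_peak_tables(cfg["peaks_csv"])
        plan = design_screen(int(cfg["n_embryos"]), int(cfg["pool_size"]),
                             plate_wells=int(cfg.get("plate_wells", 96)),
                             wells_per_founder_columns=int(
                                 cfg.get("wells_per_founder_columns", 2)))
        min_rel = float(cfg.get("min_rel_height", 0.05))
        tol = float(cfg.get("size_tol", 0.5))
        calls = [call_pool_peaks(t, float(cfg["wt_size"]), plan.pool_size,
                                 min_rel_height=min_rel, size_tol=tol,
                                 merge_plus_a=bool(cfg.get("merge_plus_a",
                                                           False)))
                 for t in tables]
        estimates = estimate_transmission(calls, plan)
        manifest["inputs"]["peaks_csv"] = str(cfg["peaks_csv"])
        manifest["thresholds"].update(
            {"min_rel_height": min_rel, "size_tol": tol})
        with open(outdir / "pool_calls.tsv", "w") as fh:
            fh.write("well_id\tfailed\tmutant_size_bp\tnet_delta\t"
                     "height\test_carriers\n")
            for c in calls:
                if c.failed:
                    fh.write(f"{c.well_id}\t1\t.\t.\t.\t.\n")
                elif not c.mutant_peaks:
                    fh.write(f"{c.well_id}\t0\t.\t.\t.\t.\n")
                for mp in c.mutant_peaks:
                    fh.write(f"{c.well_id}\t0\t{mp.size:g}\t{mp.net_delta}\t"
                             f"{mp.height:g}\t{mp.est_carriers}\n")
        with open(outdir / "transmission.json", "w") as fh:
            json.dump({e.allele_id: {
                "net_delta": e.net_delta,
                "k_positive_pools": e.k_positive_pools,
                "lower_bound_pct": round(e.lower_bound, 2),
                "mle_pct": round(e.mle, 2),
                "ci95_pct": [round(e.ci[0], 2), round(e.ci[1], 2)],
            } for e in estimates.values()}, fh, indent=2)
        report += [
            "## Pooled founder screen",
            "",
            f"Design: {plan.n_pools} pools of {plan.pool_size} embryos "
            f"({plan.n_embryos} embryos, sensitivity {plan.sensitivity}%, "
            f"{plan.founders_per_plate} founders per plate).",
            "",
        ]
        if estimates:
            report.append("| allele | positive pools | lower bound | MLE | 95% CI |")
            report.append("|---|---|---|---|---|")
            for e in estimates.values():
                report.append(
                    f"| {e.allele_id} | {e.k_positive_pools}/{plan.n_pools} | "
                    f"{e.lower_bound:.1f}% | {e.mle:.2f}% | "
                    f"{e.ci[0]:.2f}-{e.ci[1]:.2f}% |")
            report.append("")
            report.append("This founder transmits; genotype F1 adults to "
                          "recover carriers.")
        else:
            report.append("No mutant peaks called: founder does not transmit "
                          "at detectable frequency.")
        report.append("")

    report_path = outdir / "report.md"
    report_path.write_text("\n".join(report))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report_path
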