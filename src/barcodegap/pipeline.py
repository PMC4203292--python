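"""End-to-end comparative analysis of one barcode data set.

Runs the three identification approaches — distance summaries with
barcoding-gap assessment, neighbor-joining monophyly, automatic
gap partitioning, and diagnostic characters — and assembles a single
comparative report.  Every number in the report is produced by exactly
one upstream module; this module formats and files, it does not compute.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .abgd import AbgdConfig, initial_partition, partition_concordance, partition_grid, grid_table
from .distances import (
    barcoding_gap,
    distance_summaries,
    gap_histogram,
    pairwise_matrix,
)
from .diagnostics import diagnostic_success_ratio, find_diagnostics
from .io import BarcodeAlignment, TaxonomyMap
from .nj import bootstrap_supports, monophyly_report, nj_tree
from .stats import bernoulli_ci, success_rate

__all__ = ["PipelineConfig", "run_all", "report_rows", "write_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Default parameters pinned to standard barcode practice:
    1000 bootstrap replicates, gap-partition priors 0.001-0.1 over 10
    steps with relative gap width 1.5 and 20 bins, K80 TS/TV 2.0."""

    n_bootstrap: int = 1000
    seed: int = 0
    n_bins: int = 20
    alpha: float = 0.05
    abgd: AbgdConfig = field(default_factory=AbgdConfig)
    # headline partition prior: mid-grid value, above typical intraspecific
    # tails but below barcode gaps (a too-low prior splits haplotype groups)
    headline_prior: float = 0.0215
    outgroup: tuple = ()


def _ci_block(method: str, hits: int, tests: int, alpha: float) -> dict:
    res = success_rate(hits, tests)
    ci = bernoulli_ci(float(res.rate), tests, alpha)
    return {
        "method": method,
        "hits": hits,
        "tests": tests,
        "rate_pct": res.rate_pct,
        "ci_lower": round(ci.lower, 4),
        "ci_upper": round(ci.upper, 4),
        "alpha": alpha,
    }


def run_all(
    alignment: BarcodeAlignment,
    taxonomy: TaxonomyMap,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Run all three approaches and return the comparative report dict."""
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "n_records": alignment.n_records,
            "alignment_length": alignment.length,
            "alignment_sha256": hashlib.sha256(
                "".join(alignment.sequences).encode()
            ).hexdigest(),
            "seed": config.seed,
            "n_bootstrap": config.n_bootstrap,
            "abgd": {
                "p_min": config.abgd.p_min,
                "p_max": config.abgd.p_max,
                "steps": config.abgd.steps,
                "relative_gap_width": config.abgd.relative_gap_width,
                "n_bins": config.abgd.n_bins,
                "ts_tv": config.abgd.ts_tv,
            },
        }
    }

    try:
        matrix = pairwise_matrix(alignment)
        intra, inter = distance_summaries(matrix, taxonomy)
        gap = barcoding_gap(intra, inter)
        hist = gap_histogram(matrix, taxonomy, config.n_bins)
        report["distances"] = {
            "intraspecific": {
                "mean": round(intra.mean, 4),
                "min": round(intra.minimum, 4),
                "max": round(intra.maximum, 4),
                "sd": round(intra.sd, 4),
                "se": intra.se,
                "n_pairs": intra.n_pairs,
            },
            "interspecific": {
                "mean": round(inter.mean, 4),
                "min": round(inter.minimum, 4),
                "max": round(inter.maximum, 4),
                "sd": round(inter.sd, 4),
                "se": inter.se,
                "n_pairs": inter.n_pairs,
            },
            "barcoding_gap": {
                "positive": gap.positive,
                "gap_range": [round(x, 4) for x in gap.gap_range]
                if gap.gap_range
                else None,
            },
            "histogram": hist.to_dataframe().to_dict(orient="list"),
        }
    except Exception as exc:
        raise RuntimeError(f"[distances] stage failed: {exc}") from exc

    try:
        if config.n_bootstrap > 0:
            tree = bootstrap_supports(
                alignment, n_replicates=config.n_bootstrap, seed=config.seed
            )
        else:
            tree = nj_tree(matrix)
        mono_sp = monophyly_report(
            tree, taxonomy, "species", outgroup=config.outgroup or None
        )
        mono_gen = monophyly_report(
            tree, taxonomy, "genus", outgroup=config.outgroup or None
        )
        report["tree"] = {
            "newick": tree.to_newick(),
            "monophyly": {
                "species": {
                    "n_monophyletic": mono_sp.n_monophyletic,
                    "n_total": mono_sp.n_total,
                    "ratio_pct": round(mono_sp.ratio, 2),
                    "non_monophyletic": mono_sp.non_monophyletic(),
                },
                "genus": {
                    "n_monophyletic": mono_gen.n_monophyletic,
                    "n_total": mono_gen.n_total,
                    "ratio_pct": round(mono_gen.ratio, 2),
                    "non_monophyletic": mono_gen.non_monophyletic(),
                },
            },
        }
    except Exception as exc:
        raise RuntimeError(f"[tree] stage failed: {exc}") from exc

    try:
        partitions = partition_grid(matrix, config.abgd)
        headline = initial_partition(matrix, config.headline_prior, config.abgd)
        concordance = partition_concordance(headline, taxonomy)
        report["abgd"] = {
            "grid": grid_table(partitions).to_dict(orient="list"),
            "headline_prior": config.headline_prior,
            "headline": concordance,
        }
    except Exception as exc:
        raise RuntimeError(f"[abgd] stage failed: {exc}") from exc

    try:
        diag_sp = find_diagnostics(alignment, taxonomy, "species")
        report["diagnostics"] = {
            "species": {
                "n_with": diag_sp.n_taxa_with_diagnostics,
                "n_total": diag_sp.n_taxa_total,
                "success_ratio_pct": round(diagnostic_success_ratio(diag_sp), 2),
            }
        }
        if len(taxonomy.groups("family")) >= 2:
            diag_fam = find_diagnostics(alignment, taxonomy, "family")
            report["diagnostics"]["family"] = {
                "n_with": diag_fam.n_taxa_with_diagnostics,
                "n_total": diag_fam.n_taxa_total,
                "success_ratio_pct": round(diagnostic_success_ratio(diag_fam), 2),
            }
    except Exception as exc:
        raise RuntimeError(f"[diagnostics] stage failed: {exc}") from exc

    report["confidence_intervals"] = [
        _ci_block(
            "monophyly_species",
            mono_sp.n_monophyletic,
            mono_sp.n_total,
            config.alpha,
        ),
        _ci_block(
            "monophyly_genus",
            mono_gen.n_monophyletic,
            mono_gen.n_total,
            config.alpha,
        ),
        _ci_block(
            "abgd_matching_groups",
            concordance["n_matching_groups"],
            concordance["n_groups"],
            config.alpha,
        ),
        _ci_block(
            "diagnostics_species",
            diag_sp.n_taxa_with_diagnostics,
            diag_sp.n_taxa_total,
            config.alpha,
        ),
    ]
    if "family" in report["diagnostics"]:
        fam = report["diagnostics"]["family"]
        report["confidence_intervals"].append(
            _ci_block(
                "diagnostics_family", fam["n_with"], fam["n_total"], config.alpha
            )
        )
    return report


def report_rows(report: dict):
    """The comparative success-ratio rows as a small table."""
    import pandas as pd

    rows = [
        ("monophyletic_ratio_genus_pct", report["tree"]["monophyly"]["genus"]["ratio_pct"]),
        ("monophyletic_ratio_species_pct", report["tree"]["monophyly"]["species"]["ratio_pct"]),
        ("abgd_group_match_ratio_pct", round(report["abgd"]["headline"]["match_ratio"], 2)),
        ("diagnostic_ratio_species_pct", report["diagnostics"]["species"]["success_ratio_pct"]),
    ]
    if "family" in report["diagnostics"]:
        rows.append(
            ("diagnostic_ratio_family_pct", report["diagnostics"]["family"]["success_ratio_pct"])
        )
    rows.append(
        ("barcoding_gap_positive", int(report["distances"]["barcoding_gap"]["positive"]))
    )
    return pd.DataFrame(rows, columns=["statistic", "value"])


def write_report(report: dict, outdir) -> None:
    """Write report.json, report.tsv and the Newick tree to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    report_rows(report).to_csv(outdir / "report.tsv", sep="\t", index=False)
    (outdir / "tree.nwk").write_text(report["tree"]["newick"] + "\n")
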