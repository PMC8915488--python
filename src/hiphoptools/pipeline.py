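"""End-to-end orchestration: score → hits → similarity → cluster →
signatures → cross-dataset match, with every artifact written to disk and a
manifest recording the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

from . import __version__
from .compare import ComparisonReport, match_signatures, merge_datasets
from .hits import screen_hits, target_frequency
from .io import (AnalysisConfig, ScreenMatrix, ScreenMeta, write_json,
                 write_matrix)
from .scoring import harmonize_orientation
from .signatures import (ClusterParams, ResponseSignature, dynamic_cut,
                         extract_signatures, filter_signatures, ward_dendrogram)
from .similarity import coinhibition

logger = logging.getLogger(__name__)


def cluster_site(fd: ScreenMatrix, config: AnalysisConfig,
                 params: ClusterParams,
                 gmt_sets: dict[str, list[str]] | None = None,
                 alpha: float | None = None):
    """One site's clustering leg: coinhibition → Ward → dynamic cut →
    signatures (filtered).  Returns (dendrogram, assignment, signatures)."""
    sim = coinhibition(fd, config, zero=True)
    dend = ward_dendrogram(sim)
    assignment = dynamic_cut(dend, params)
    sigs = extract_signatures(assignment, fd,
                              alpha=alpha or config.alpha_significant,
                              gmt_sets=gmt_sets)
    sigs = filter_signatures(sigs)
    return dend, assignment, sigs


def run_pipeline(matrices: dict[str, ScreenMatrix], meta: ScreenMeta,
                 outdir: str | Path,
                 config: AnalysisConfig | None = None,
                 params: ClusterParams | None = None,
                 gmt_sets: dict[str, list[str]] | None = None,
                 merge_policy: str = "union") -> ComparisonReport:
    """Run the full comparative analysis over two (or more) sites' FD matrices.

    Each site's matrix is harmonized to ``sensitivity_positive``, screened
    for HIP hits, clustered into response signatures, and the first two
    sites' signatures are matched by overlap coefficient.  All intermediate
    artifacts (harmonized and merged matrices, hit tables, cluster
    assignments, Newick dendrograms, signature and comparison JSON, a
    manifest) land under *outdir*.  Deterministic given inputs and config.
    """
    config = config or AnalysisConfig()
    params = params or ClusterParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sites = list(matrices)
    harmonized: dict[str, ScreenMatrix] = {}
    all_hits: dict[str, list[str]] = {}
    site_sigs: dict[str, list[ResponseSignature]] = {}

    for site in sites:
        logger.info("pipeline: site %s — harmonize + hits", site)
        try:
            fd = harmonize_orientation(matrices[site])
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"stage harmonize failed for site {site}: {exc}")
        harmonized[site] = fd
        write_matrix(fd, outdir / f"fd_{site}.tsv")

        hits = screen_hits(fd, config)
        all_hits.update({s: r.hits for s, r in hits.items()})
        write_json({s: r.to_dict() for s, r in hits.items()},
                   outdir / f"hits_{site}.json")

        logger.info("pipeline: site %s — cluster + signatures", site)
        dend, assignment, sigs = cluster_site(fd, config, params, gmt_sets)
        (outdir / f"dendrogram_{site}.nwk").write_text(dend.to_newick() + "\n")
        assignment.labels.rename("cluster").to_csv(
            outdir / f"clusters_{site}.tsv", sep="\t", index_label="screen")
        write_json([s.to_dict() for s in sigs], outdir / f"signatures_{site}.json")
        site_sigs[site] = sigs

    freq = target_frequency(all_hits, meta)
    freq.to_csv(outdir / "target_frequency.tsv", sep="\t")

    if len(sites) >= 2:
        a, b = sites[0], sites[1]
        merged = merge_datasets(harmonized[a], harmonized[b], policy=merge_policy)
        write_matrix(merged, outdir / "merged_fd.tsv")
        # combined-dataset signatures use the relaxed threshold: medians over
        # both sites shrink, so P < alpha_signature_combined (default 0.05)
        logger.info("pipeline: combined dataset — cluster + signatures")
        _, _, combined_sigs = cluster_site(
            merged, config, params, gmt_sets,
            alpha=config.alpha_signature_combined)
        write_json([s.to_dict() for s in combined_sigs],
                   outdir / "signatures_combined.json")
        report = match_signatures(site_sigs[a], site_sigs[b], config)
    else:
        report = match_signatures(site_sigs[sites[0]], site_sigs[sites[0]], config)
    report.target_frequency = {
        "genes": [str(g) for g in freq.index],
        "total": [int(t) for t in freq["total"]] if len(freq) else [],
    }
    write_json(report.to_dict(), outdir / "comparison_report.json")

    manifest = {
        "version": __version__,
        "sites": sites,
        "n_screens": {s: matrices[s].shape[1] for s in sites},
        "n_strains": {s: matrices[s].shape[0] for s in sites},
        "merge_policy": merge_policy,
        "analysis_config": dataclasses.asdict(config),
        "cluster_params": dataclasses.asdict(params),
    }
    write_json(manifest, outdir / "manifest.json")
    return report
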