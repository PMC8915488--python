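"""Clearance-based HIP hit calling.

A compound that inhibits a single protein typically makes only the strain
heterozygous for that protein's gene hypersensitive, leaving a large *gap*
between that strain's fitness defect and everyone else's.  The clearance
statistic formalizes this: strains are ranked by FD; the gap after rank *i*
is ``FD_(i) − FD_(i+1)``; ``clearance_max`` is the largest gap among
positive-FD strains, and every strain scoring at or above the FD at that gap
(``fd_max``) inherits ``clearance_max`` as its clearance — so a tight group
of co-targets above a wide gap are all credited with the full gap.  Strains
with a significant FD and clearance ≥ 5.75 are designated HIP hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnalysisConfig, ScreenMatrix, ScreenMeta
from .scoring import significance_mask


@dataclass
class ClearanceResult:
    """Ranked FDs, inter-rank gaps and the clearance assignment for one screen."""

    screen_id: str
    ranked: pd.DataFrame          # columns: strain_id, fd, gap_after, clearance
    clearance_max: float
    fd_max: float
    hits: list[str] = field(default_factory=list)

    def clearance_of(self, strain_id: str) -> float:
        row = self.ranked.loc[self.ranked["strain_id"] == strain_id]
        if row.empty:
            raise KeyError(strain_id)
        return float(row["clearance"].iloc[0])

    def to_dict(self) -> dict:
        return {
            "screen_id": self.screen_id,
            "clearance_max": self.clearance_max,
            "fd_max": self.fd_max,
            "hits": list(self.hits),
        }


def clearance_scores(profile: pd.Series, config: AnalysisConfig | None = None,
                     screen_id: str = "") -> ClearanceResult:
    """Compute per-strain clearance for one screen's FD profile.

    The profile must be in ``sensitivity_positive`` orientation (high FD =
    sensitive).  Strains are ordered by FD descending, ties broken
    lexicographically by strain id; the gap after rank *i* is
    ``FD_(i) − FD_(i+1)``.  ``clearance_max`` is the largest gap at a
    position whose FD is > 0 (``config.clearance_positive_only``, the
    default; set False to search every position); with
    several equal maxima the one at the highest FD wins.  Every strain with
    FD ≥ ``fd_max`` is assigned ``clearance_max``; every other strain its
    own gap (0 where no gap is defined).
    """
    config = config or AnalysisConfig()
    x = profile.dropna().astype(float)
    df = pd.DataFrame({"strain_id": x.index.astype(str), "fd": x.to_numpy()})
    df = df.sort_values(["fd", "strain_id"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    n = len(df)
    fd_sorted = df["fd"].to_numpy()
    gaps = np.full(n, np.nan)
    if n >= 2:
        gaps[:-1] = fd_sorted[:-1] - fd_sorted[1:]
    df["gap_after"] = gaps

    # clearance_max is searched only among positive-FD positions by default
    defined = df["gap_after"].notna()
    if config.clearance_positive_only:
        defined &= df["fd"] > 0
    if defined.sum() == 0 or n < 2:
        df["clearance"] = df["gap_after"].fillna(0.0)
        return ClearanceResult(screen_id=screen_id, ranked=df,
                               clearance_max=0.0, fd_max=float("nan"))

    clearance_max = float(df.loc[defined, "gap_after"].max())
    # among equal maximal gaps, the highest-FD position wins
    at_max = df.index[defined & (df["gap_after"] == clearance_max)]
    fd_max = float(df.at[at_max[0], "fd"])

    df["clearance"] = df["gap_after"].fillna(0.0)
    df.loc[df["fd"] >= fd_max, "clearance"] = clearance_max
    return ClearanceResult(screen_id=screen_id, ranked=df,
                           clearance_max=clearance_max, fd_max=fd_max)


def call_hip_hits(result: ClearanceResult, significant: pd.Series,
                  config: AnalysisConfig | None = None) -> list[str]:
    """Designate HIP hits: significant FD and assigned clearance ≥ threshold.

    *significant* is a boolean Series indexed by strain id (typically one
    column of :func:`hiphoptools.scoring.significance_mask`).  The default
    threshold is 5.75 FD units; a screen whose ``clearance_max`` falls below
    it yields no hits.
    """
    config = config or AnalysisConfig()
    df = result.ranked
    sig = df["strain_id"].map(significant).fillna(False).astype(bool)
    ok = sig & (df["clearance"] >= config.clearance_threshold)
    hits = df.loc[ok, "strain_id"].tolist()
    result.hits = hits
    return hits


def screen_hits(matrix: ScreenMatrix, config: AnalysisConfig | None = None
                ) -> dict[str, ClearanceResult]:
    """Clearance + hit calling for every screen of a harmonized FD matrix."""
    config = config or AnalysisConfig()
    if matrix.orientation != "sensitivity_positive":
        raise ValueError("hit calling requires sensitivity_positive orientation; "
                         "run harmonize_orientation first")
    mask = significance_mask(matrix, config)
    out: dict[str, ClearanceResult] = {}
    for screen in matrix.values.columns:
        res = clearance_scores(matrix.values[screen], config, screen_id=str(screen))
        call_hip_hits(res, mask[screen], config)
        out[str(screen)] = res
    return out


def target_frequency(hits: dict[str, list[str]],
                     meta: ScreenMeta | None = None) -> pd.DataFrame:
    """Tabulate how often each gene is a HIP hit, split by site.

    *hits* maps screen id → hit strain list.  Returns a DataFrame indexed by
    gene with one count column per site plus ``total``, sorted by total
    descending (ties by gene name), and an ``exclusive_to`` column naming the
    single site where the gene was hit, if any.
    """
    site_of: dict[str, str] = {}
    if meta is not None:
        site_of = dict(zip(meta.table["screen_id"], meta.table["site"]))
    rows = []
    for screen, genes in hits.items():
        site = site_of.get(screen, "all")
        for g in genes:
            rows.append((g, site))
    if not rows:
        return pd.DataFrame(columns=["total", "exclusive_to"])
    df = pd.DataFrame(rows, columns=["gene", "site"])
    counts = df.pivot_table(index="gene", columns="site", aggfunc="size",
                            fill_value=0)
    counts.columns = [str(c) for c in counts.columns]
    counts["total"] = counts.sum(axis=1)
    site_cols = [c for c in counts.columns if c != "total"]
    if len(site_cols) > 1:
        nonzero = counts[site_cols].gt(0)
        excl = nonzero.apply(
            lambda r: site_cols[list(r).index(True)] if r.sum() == 1 else "", axis=1)
        counts["exclusive_to"] = excl
    else:
        counts["exclusive_to"] = ""
    counts.index.name = "gene"
    counts = (counts.reset_index()
              .sort_values(["total", "gene"], ascending=[False, True])
              .set_index("gene"))
    return counts
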